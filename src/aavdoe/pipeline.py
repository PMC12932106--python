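"""Reproducible mixture -> FCCD optimization pipeline with run-table I/O.

The workflow mirrors upstream rAAV process development: select a D-optimal
mixture design over the bounded plasmid simplex, measure (or simulate) the
runs, fit Scheffe models and choose a blend by combined desirability; then
fix the blend, run an FCCD on total DNA and transfection-reagent ratio, fit
second-order models and choose the process point.  The report compares the
optimized point with the unoptimized reference condition (1:1:1 plasmid
ratio, center DNA/reagent levels) through the same fitted models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .designs import (
    DEFAULT_FCCD_LIMITS,
    MixtureBounds,
    fccd_design,
    d_optimal_select,
    simplex_candidates,
)
from .desirability import (
    DesirabilitySpec,
    SimplexRegion,
    SquareRegion,
    optimize_desirability,
)
from .models import (
    RESPONSE_NAMES,
    anova_model,
    fit_rsm,
    fit_scheffe,
    log_vp,
    pct_full,
)

RUN_TABLE_COLUMNS = (
    "run_id",
    "pHelper",
    "pRepCap",
    "pGOI",
    "dna_total",
    "fv_ratio",
    "time_days",
    "vg_titer",
    "capsid_titer",
    "viability",
)

_COMPOSITION_COLS = ("pHelper", "pRepCap", "pGOI")


def attach_derived_responses(df: pd.DataFrame) -> pd.DataFrame:
    """Add the derived log_vp / pct_full columns (and the >100 % flag)."""
    out = df.copy()
    out["log_vp"] = log_vp(out["vg_titer"].to_numpy(), out["time_days"].to_numpy())
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pf = pct_full(out["vg_titer"].to_numpy(), out["capsid_titer"].to_numpy())
    out["pct_full"] = pf
    out["pct_full_inconsistent"] = out["pct_full"] > 100
    return out


def read_run_table(path, check_composition: bool = True) -> pd.DataFrame:
    """Read and validate a run-table CSV; derived responses computed on load.

    Mandatory columns are the documented schema; unknown extra columns are
    preserved untouched.  Raises with the offending column name on a missing
    column, with row/column coordinates on a non-numeric cell, and on
    composition rows not summing to 1 within 1e-6.
    """
    df = pd.read_csv(path)
    missing = [c for c in RUN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"run table missing mandatory column(s): {missing}")
    numeric_cols = [c for c in RUN_TABLE_COLUMNS if c != "run_id"]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad) or converted.isna().any():
            row = int(bad[0]) if len(bad) else int(df.index[converted.isna()][0])
            raise ValueError(
                f"non-numeric value in column {col!r}, row {row}: {df[col].iloc[row]!r}"
            )
        df[col] = converted
    if check_composition:
        comp_sum = df[list(_COMPOSITION_COLS)].sum(axis=1)
        bad = np.abs(comp_sum - 1) > 1e-6
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"composition in row {row} sums to {comp_sum.iloc[row]:.8f}, not 1"
            )
    return attach_derived_responses(df)


def write_run_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if c not in ("log_vp", "pct_full", "pct_full_inconsistent")]
    df[cols].to_csv(path, index=False)


def select_harvest(df: pd.DataFrame, rule: str = "max_log_vp") -> pd.DataFrame:
    """Collapse multiple harvests per run to one row.

    ``max_log_vp`` keeps, per run_id, the harvest with the highest Log(Vp)
    (its paired % full and viability travel with it); ``last`` keeps the
    latest harvest time.
    """
    if "log_vp" not in df.columns:
        df = attach_derived_responses(df)
    if rule == "max_log_vp":
        idx = df.groupby("run_id")["log_vp"].idxmax()
    elif rule == "last":
        idx = df.groupby("run_id")["time_days"].idxmax()
    else:
        raise ValueError(f"unknown harvest rule {rule!r}")
    return df.loc[idx].sort_index().reset_index(drop=True)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All knobs of the two-stage pipeline, with simulation defaults."""

    archetype: str = "egfp_like"
    lower: tuple[float, float, float] = (0.1, 0.1, 0.1)
    upper: tuple[float, float, float] = (0.6, 0.6, 0.6)
    candidate_step: float = 0.05
    n_runs: int = 13
    n_starts: int = 10
    fccd_centers: int = 3
    fccd_limits: dict = field(default_factory=lambda: dict(DEFAULT_FCCD_LIMITS))
    simplex_grid_step: float = 0.02
    square_grid_step: float = 0.05
    top_m: int = 1
    replicates: int = 1
    sigma_log_vp: float = 0.1
    sigma_pct_full: float = 2.0
    sigma_viability: float = 2.0
    seed: int = 0
    harvest_rule: str = "max_log_vp"
    desirability_r: float = 1.0

    def bounds(self) -> MixtureBounds:
        return MixtureBounds(tuple(self.lower), tuple(self.upper))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lower", "upper"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "fccd_limits" in raw:
            raw["fccd_limits"] = {
                k: tuple(v) for k, v in raw["fccd_limits"].items()
            }
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["lower"] = list(data["lower"])
        data["upper"] = list(data["upper"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# report


def _model_summary(model, table_anova) -> dict:
    return {
        "coefficients": model.coef_dict(),
        "residual_variance": model.residual_variance,
        "anova_p": None if not np.isfinite(table_anova.p_value) else table_anova.p_value,
        "anova_f": None if not np.isfinite(table_anova.f_statistic) else table_anova.f_statistic,
    }


def _optimum_summary(opt) -> dict:
    return {
        "point": [float(x) for x in opt.point],
        "D": opt.D,
        "d_individual": {k: float(v) for k, v in opt.d_individual.items()},
        "predictions": {k: float(v) for k, v in opt.predictions.items()},
    }


@dataclass
class Report:
    """JSON-serializable record of one pipeline execution."""

    config: dict
    md_models: dict
    md_optima: list
    md_design_hash: str
    fccd_models: dict
    fccd_optimum: dict
    fccd_design_hash: str
    chosen_ratio: list
    chosen_coded: list
    chosen_actual: dict
    reference: dict
    fold_improvement: dict
    seeds: dict

    def to_dict(self) -> dict:
        # canonical JSON form (tuples -> lists) so round trips compare equal
        return json.loads(json.dumps(dataclasses.asdict(self)))

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "Report":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(**data)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _hash_design(arr: np.ndarray) -> str:
    return hashlib.sha256(np.round(arr, 9).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Report:
    """Execute the full simulated mixture -> FCCD optimization workflow."""
    from .synthetic import NoiseModel, make_archetype, simulate_runs

    noise = NoiseModel(config.sigma_log_vp, config.sigma_pct_full, config.sigma_viability)
    ss = np.random.SeedSequence(config.seed)
    seed_design, seed_md, seed_fccd = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )
    seeds = {"design": seed_design, "md_sim": seed_md, "fccd_sim": seed_fccd}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-tag with stage context
            raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc

    archetype = stage("archetype", lambda: make_archetype(config.archetype))
    bounds = config.bounds()

    candidates = stage(
        "mixture-candidates", lambda: simplex_candidates(bounds, config.candidate_step)
    )
    design = stage(
        "mixture-design",
        lambda: d_optimal_select(
            candidates, n_runs=config.n_runs, n_starts=config.n_starts, seed=seed_design
        ),
    )
    table = stage(
        "mixture-simulation",
        lambda: simulate_runs(
            design, archetype, noise, replicates=config.replicates, seed=seed_md
        ),
    )
    table = attach_derived_responses(table)
    md_models = stage(
        "mixture-fit",
        lambda: {r: fit_scheffe(design, table[r].to_numpy()) for r in RESPONSE_NAMES},
    )
    region = SimplexRegion(bounds, config.simplex_grid_step)
    top_m = max(config.top_m, archetype.top_m)
    md_opt = stage(
        "mixture-optimize",
        lambda: optimize_desirability(
            md_models, region, top_m=top_m, seed=config.seed
        ),
    )
    chosen_ratio = md_opt.best.point

    fccd = stage(
        "fccd-design",
        lambda: fccd_design(n_center=config.fccd_centers, limits=config.fccd_limits),
    )
    ftable = stage(
        "fccd-simulation",
        lambda: simulate_runs(
            fccd,
            archetype,
            noise,
            replicates=config.replicates,
            seed=seed_fccd,
            ratio=chosen_ratio,
        ),
    )
    ftable = attach_derived_responses(ftable)
    coded = np.repeat(fccd.coded_runs, config.replicates, axis=0)
    fccd_models = stage(
        "fccd-fit",
        lambda: {r: fit_rsm(coded, ftable[r].to_numpy()) for r in RESPONSE_NAMES},
    )
    square = SquareRegion(config.square_grid_step)
    fccd_opt = stage(
        "fccd-optimize",
        lambda: optimize_desirability(fccd_models, square, seed=config.seed),
    )
    chosen_coded = fccd_opt.best.point

    # reference condition: 1:1:1 plasmid ratio, center (1:1-equivalent) levels,
    # evaluated through the same fitted models
    ref_ratio = np.full(3, 1 / 3)
    ref_md = {r: float(md_models[r].predict(ref_ratio[None, :])[0]) for r in RESPONSE_NAMES}
    ref_coded = np.zeros(2)
    ref_fccd = {
        r: float(fccd_models[r].predict(ref_coded[None, :])[0]) for r in RESPONSE_NAMES
    }
    # compose: blend effect (MD model, reference vs chosen) + process effect
    # (FCCD model, reference vs chosen), sharing the chosen-blend baseline
    opt_pred = fccd_opt.best.predictions
    reference = {
        "ratio": ref_ratio.tolist(),
        "coded": ref_coded.tolist(),
        "md_predictions": ref_md,
        "fccd_predictions": ref_fccd,
    }
    ref_combined = {
        r: ref_md[r] + (ref_fccd[r] - float(fccd_models[r].beta0))
        for r in RESPONSE_NAMES
    }
    folds = _fold_from_predictions(opt_pred, ref_combined)

    report = Report(
        config=dataclasses.asdict(config),
        md_models={r: _model_summary(m, anova_model(m)) for r, m in md_models.items()},
        md_optima=[_optimum_summary(o) for o in md_opt.optima],
        md_design_hash=_hash_design(design.runs),
        fccd_models={r: _model_summary(m, anova_model(m)) for r, m in fccd_models.items()},
        fccd_optimum=_optimum_summary(fccd_opt.best),
        fccd_design_hash=_hash_design(fccd.coded_runs),
        chosen_ratio=[float(x) for x in chosen_ratio],
        chosen_coded=[float(x) for x in chosen_coded],
        chosen_actual={
            name: float(v)
            for name, v in zip(fccd.factor_names, fccd.decode(chosen_coded)[0])
        },
        reference=reference,
        fold_improvement=folds,
        seeds=seeds,
    )
    return report


def _fold_from_predictions(opt_pred: dict, ref_pred: dict) -> dict:
    vp_fold = 10.0 ** (opt_pred["log_vp"] - ref_pred["log_vp"])
    ref_pf = ref_pred["pct_full"]
    if ref_pf <= 0:
        pf_fold, pf_infinite = np.inf, True
    else:
        pf_fold, pf_infinite = opt_pred["pct_full"] / ref_pf, False
    return {
        "vp_fold": float(vp_fold),
        "pct_full_fold": float(pf_fold),
        "pct_full_fold_infinite": pf_infinite,
        "viability_delta": float(opt_pred["viability"] - ref_pred["viability"]),
    }


def fold_improvement(report: Report) -> dict:
    """Per-response improvement of the optimized point over the reference.

    Vp fold = 10^(delta Log(Vp)); % full fold is a direct ratio (flagged
    infinite when the reference predicts zero).
    """
    return dict(report.fold_improvement)
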