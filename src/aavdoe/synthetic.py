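"""Ground-truth response surfaces and simulated run tables.

Three GOI archetypes encode the qualitative optimization landscapes seen in
triple-transfection rAAV production, as phenomenological quadratics over the
bounded plasmid simplex plus deviation surfaces over the coded DNA/reagent
square:

* ``egfp_like`` — productivity Log(Vp) rises with pHelper/pRepCap and falls
  with pGOI, viability moves the other way, and the full-capsid percentage
  peaks in the interior; a benign, single-optimum landscape.
* ``msh2_like`` — all three responses peak together at a RepCap-dominated
  blend (0.2 : 0.6 : 0.2 pHelper:pRepCap:pGOI), with very low full-capsid
  percentages throughout.
* ``bdnf_like`` — Log(Vp) and % full pull in opposite directions across the
  simplex and viability has a saddle, producing two distinct local optima of
  the combined desirability (a productivity-focused and a packaging-focused
  blend).

Each archetype self-verifies its qualitative constraints at construction
(gradient signs, Hessian indefiniteness, optimum locations, response ranges)
and fails loudly otherwise.  Simulated run tables add Gaussian measurement
noise and back-compute vector-genome and capsid titers so the derived
Log(Vp) and % full round-trip exactly through the response transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .designs import FCCDDesign, MixtureBounds, MixtureDesign, fccd_design, simplex_candidates, d_optimal_select
from .desirability import (
    DesirabilitySpec,
    OptimizationResult,
    SimplexRegion,
    SquareRegion,
    optimize_desirability,
)
from .models import (
    RESPONSE_NAMES,
    fit_rsm,
    fit_scheffe,
    rsm_matrix,
    scheffe_matrix,
)

ARCHETYPE_NAMES = ("egfp_like", "msh2_like", "bdnf_like")

#: harvest time used when back-computing titers from Log(Vp), days
SIMULATED_HARVEST_DAYS = 2.0
#: total DNA (ug/mL) and reagent:DNA ratio held fixed during the mixture stage
MD_STAGE_DNA = 2.0
MD_STAGE_FV = 1.0
#: floor applied when clipping simulated % full, keeps titers finite
PCT_FULL_FLOOR = 1e-3


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement-noise standard deviations per response.

    Defaults emulate run-to-run scatter of the assays: 0.1 log10 units for
    Log(Vp) (qPCR), 2 percentage points for % full (qPCR/ELISA ratio) and
    viability (dye-exclusion count).
    """

    sigma_log_vp: float = 0.1
    sigma_pct_full: float = 2.0
    sigma_viability: float = 2.0

    def __post_init__(self) -> None:
        for name in ("sigma_log_vp", "sigma_pct_full", "sigma_viability"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def sigmas(self) -> dict[str, float]:
        return {
            "log_vp": self.sigma_log_vp,
            "pct_full": self.sigma_pct_full,
            "viability": self.sigma_viability,
        }


ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0)


class ScheffeSurface:
    """True mixture response surface from fixed Scheffe coefficients."""

    def __init__(self, coef: np.ndarray):
        self.coef = np.asarray(coef, dtype=float)

    def predict(self, points: np.ndarray) -> np.ndarray:
        return scheffe_matrix(points) @ self.coef


class RSMSurface:
    """True coded-square response surface from fixed RSM coefficients."""

    def __init__(self, coef: np.ndarray):
        self.coef = np.asarray(coef, dtype=float)

    def predict(self, points: np.ndarray) -> np.ndarray:
        return rsm_matrix(points) @ self.coef


def _reduced_quadratic_to_scheffe(a: np.ndarray) -> np.ndarray:
    """Exact Scheffe coefficients for q(h, g) with r = 1 - h - g implicit.

    ``a`` holds (a0, ah, ag, ahh, agg, ahg) of the reduced quadratic in the
    pHelper (h) and pGOI (g) fractions.  Any quadratic in (h, g) has a unique
    Scheffe-quadratic representation on the simplex; it is recovered by
    solving the 6x6 interpolation system at generic simplex points.
    """
    support = np.array(
        [
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
            [0.5, 0.5, 0],
            [0.5, 0, 0.5],
            [0, 0.5, 0.5],
        ],
        dtype=float,
    )
    h, g = support[:, 0], support[:, 2]
    vals = a[0] + a[1] * h + a[2] * g + a[3] * h**2 + a[4] * g**2 + a[5] * h * g
    return np.linalg.solve(scheffe_matrix(support), vals)


def _reduced_gradient(a: np.ndarray, h: float, g: float) -> np.ndarray:
    return np.array(
        [a[1] + 2 * a[3] * h + a[5] * g, a[2] + 2 * a[4] * g + a[5] * h]
    )


def _reduced_hessian(a: np.ndarray) -> np.ndarray:
    return np.array([[2 * a[3], a[5]], [a[5], 2 * a[4]]])


class ArchetypeConstructionError(RuntimeError):
    """An archetype's qualitative self-checks failed."""


@dataclass(frozen=True)
class GOIArchetype:
    """Fixed ground-truth surfaces for one GOI archetype.

    ``reduced_quadratics`` hold the defining (a0, ah, ag, ahh, agg, ahg)
    coefficients per response in the reduced (pHelper, pGOI) coordinates;
    ``scheffe_coef`` is their exact Scheffe representation.  ``rsm_dev_coef``
    are deviation surfaces over the coded DNA/FV square with zero intercept:
    the full FCCD-stage surface at a fixed plasmid ratio is the Scheffe value
    at that ratio plus the deviation.
    """

    name: str
    reduced_quadratics: dict[str, np.ndarray]
    rsm_dev_coef: dict[str, np.ndarray]
    top_m: int = 1
    bounds: MixtureBounds = field(default_factory=MixtureBounds)
    noise_defaults: NoiseModel = field(default_factory=NoiseModel)

    @property
    def scheffe_coef(self) -> dict[str, np.ndarray]:
        return {
            r: _reduced_quadratic_to_scheffe(a)
            for r, a in self.reduced_quadratics.items()
        }

    def scheffe_surfaces(self) -> dict[str, ScheffeSurface]:
        return {r: ScheffeSurface(c) for r, c in self.scheffe_coef.items()}

    def rsm_surfaces(self, ratio: np.ndarray) -> dict[str, RSMSurface]:
        """FCCD-stage true surfaces at a fixed plasmid ratio."""
        ratio = np.asarray(ratio, dtype=float)
        base = {
            r: float(surf.predict(ratio[None, :])[0])
            for r, surf in self.scheffe_surfaces().items()
        }
        out = {}
        for r, dev in self.rsm_dev_coef.items():
            coef = dev.copy()
            coef[0] += base[r]
            out[r] = RSMSurface(coef)
        return out

    def true_md_optima(
        self, grid_step: float = 0.02, top_m: int | None = None
    ) -> OptimizationResult:
        """Combined-desirability optima of the true mixture surfaces."""
        region = SimplexRegion(self.bounds, grid_step)
        return optimize_desirability(
            self.scheffe_surfaces(),
            region,
            top_m=self.top_m if top_m is None else top_m,
        )

    def true_fccd_optimum(
        self, ratio: np.ndarray, grid_step: float = 0.05
    ) -> OptimizationResult:
        region = SquareRegion(grid_step)
        return optimize_desirability(self.rsm_surfaces(ratio), region)


_CENTROID_HG = (1 / 3, 1 / 3)
#: direction "raise pGOI, lower pHelper and pRepCap equally" in (h, g) coords
_TOWARD_GOI = np.array([-0.5, 1.0])


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ArchetypeConstructionError(f"{name}: {msg}")


def _verify_common(arch: GOIArchetype) -> None:
    grid = SimplexRegion(arch.bounds, 0.02).grid()
    surfaces = arch.scheffe_surfaces()
    for resp, lo, hi in (("viability", 0, 100), ("pct_full", 0, 100)):
        vals = surfaces[resp].predict(grid)
        _check(
            vals.min() >= lo and vals.max() <= hi,
            arch.name,
            f"true {resp} leaves [{lo}, {hi}] on the simplex "
            f"(range {vals.min():.3g}..{vals.max():.3g})",
        )
    # composed FCCD surfaces stay physical at every true optimum ratio
    square = SquareRegion(0.05).grid()
    for opt in arch.true_md_optima().optima:
        fccd = arch.rsm_surfaces(opt.point)
        for resp, lo, hi in (("viability", 0, 100), ("pct_full", 0, 100)):
            vals = fccd[resp].predict(square)
            _check(
                vals.min() >= lo and vals.max() <= hi,
                arch.name,
                f"composed {resp} leaves [{lo}, {hi}] on the coded square at "
                f"ratio {np.round(opt.point, 3)}",
            )


def _verify_egfp(arch: GOIArchetype) -> None:
    q = arch.reduced_quadratics
    g_lv = _reduced_gradient(q["log_vp"], *_CENTROID_HG)
    g_v = _reduced_gradient(q["viability"], *_CENTROID_HG)
    _check(
        float(g_lv @ _TOWARD_GOI) < 0,
        arch.name,
        "Log(Vp) must fall as pGOI displaces pHelper/pRepCap at the centroid",
    )
    _check(
        float(g_v @ _TOWARD_GOI) > 0,
        arch.name,
        "viability must recover as pGOI displaces pHelper/pRepCap at the centroid",
    )


def _verify_msh2(arch: GOIArchetype) -> None:
    target = np.array([0.2, 0.6, 0.2])
    opt = arch.true_md_optima().best.point
    _check(
        np.linalg.norm(opt - target) <= 0.02 * np.sqrt(2) + 1e-9,
        arch.name,
        f"combined-desirability optimum {np.round(opt, 3)} is not within one "
        "grid cell of (0.2, 0.6, 0.2)",
    )


def _verify_bdnf(arch: GOIArchetype) -> None:
    q = arch.reduced_quadratics
    eig = np.linalg.eigvalsh(_reduced_hessian(q["viability"]))
    _check(
        eig[0] < 0 < eig[-1],
        arch.name,
        "viability quadratic form must be indefinite (saddle)",
    )
    g_lv = _reduced_gradient(q["log_vp"], *_CENTROID_HG)
    g_pf = _reduced_gradient(q["pct_full"], *_CENTROID_HG)
    cos = float(g_lv @ g_pf / (np.linalg.norm(g_lv) * np.linalg.norm(g_pf)))
    _check(cos < 0, arch.name, "Log(Vp) and %full centroid gradients must oppose")
    result = arch.true_md_optima(top_m=2)
    _check(
        len(result.optima) >= 2,
        arch.name,
        "combined desirability must carry two distinct local optima",
    )
    p1, p2 = result.optima[0].point, result.optima[1].point
    _check(
        np.linalg.norm(p1 - p2) > 3 * 0.02,
        arch.name,
        "the two desirability optima coincide",
    )
    surf = arch.scheffe_surfaces()
    lv = surf["log_vp"].predict(np.vstack([p1, p2]))
    pf = surf["pct_full"].predict(np.vstack([p1, p2]))
    _check(
        (lv[0] - lv[1]) * (pf[0] - pf[1]) < 0,
        arch.name,
        "the two optima must rank oppositely on Log(Vp) vs %full",
    )


_ARCHETYPE_TABLE: dict[str, dict] = {
    # reduced quadratics (a0, ah, ag, ahh, agg, ahg) in (pHelper, pGOI);
    # RSM deviations (b0, b_dna, b_fv, b_dna2, b_fv2, b_dna*fv), b0 = 0
    "egfp_like": {
        "reduced_quadratics": {
            "log_vp": np.array([10.5, 0.5, -2.5, 0.0, 0.0, 0.0]),
            "pct_full": np.array(
                [48 - 160 * (0.4**2 + 0.35**2), 160 * 2 * 0.4, 160 * 2 * 0.35, -160.0, -160.0, 0.0]
            ),
            "viability": np.array([78.0, -4.0, 20.0, 0.0, 0.0, 0.0]),
        },
        "rsm_dev_coef": {
            "log_vp": np.array([0.0, 0.0, 0.0, 0.0, 0.0, -1.0]),
            "pct_full": np.array([0.0, -1.25, 1.25, 0.0, 0.0, 0.0]),
            "viability": np.array([0.0, 0.0, 0.0, -1.0, -1.0, 0.0]),
        },
        "top_m": 1,
    },
    "msh2_like": {
        "reduced_quadratics": {
            "log_vp": np.array([9.1 - 8 * 2 * 0.04, 8 * 2 * 0.2, 8 * 2 * 0.2, -8.0, -8.0, 0.0]),
            "pct_full": np.array(
                [1.0 - 2.5 * 2 * 0.04, 2.5 * 2 * 0.2, 2.5 * 2 * 0.2, -2.5, -2.5, 0.0]
            ),
            "viability": np.array(
                [92.0 - 30 * 2 * 0.04, 30 * 2 * 0.2, 30 * 2 * 0.2, -30.0, -30.0, 0.0]
            ),
        },
        "rsm_dev_coef": {
            "log_vp": np.array([0.0, 0.0, -0.4, 0.0, 0.0, 0.0]),
            "pct_full": np.array([0.0, 0.0, -0.3, 0.0, 0.2, -0.1]),
            "viability": np.array([0.0, 1.2, -1.2, 0.0, 0.0, 0.0]),
        },
        "top_m": 1,
    },
    "bdnf_like": {
        "reduced_quadratics": {
            "log_vp": np.array([10.2 - 3 * 0.45**2, 3 * 2 * 0.45, -3.0, -3.0, 0.0, 0.0]),
            "pct_full": np.array([-3.0, 0.0, 40.0, 0.0, 0.0, 0.0]),
            "viability": np.array([88.0 - 60 * 0.35**2, 60 * 0.35, 60 * 0.35, 0.0, 0.0, -60.0]),
        },
        "rsm_dev_coef": {
            "log_vp": np.array([0.0, -0.5, -0.5, 0.0, 0.0, 0.0]),
            "pct_full": np.array([0.0, 0.6, -0.6, 0.0, 0.0, 0.0]),
            "viability": np.array([0.0, 0.0, -0.8, 0.0, 0.0, 0.0]),
        },
        "top_m": 2,
    },
}

_VERIFIERS = {
    "egfp_like": _verify_egfp,
    "msh2_like": _verify_msh2,
    "bdnf_like": _verify_bdnf,
}


def make_archetype(name: str, seed: int = 0, jitter: float = 0.0) -> GOIArchetype:
    """Construct and self-verify a GOI archetype.

    The coefficient table is fixed; ``jitter`` optionally perturbs the linear
    reduced coefficients by a seed-controlled relative Gaussian amount (the
    perturbed archetype is re-verified, so a too-large jitter fails loudly).
    """
    if name not in _ARCHETYPE_TABLE:
        raise ValueError(f"unknown archetype {name!r}; choose from {ARCHETYPE_NAMES}")
    entry = _ARCHETYPE_TABLE[name]
    quads = {r: a.copy() for r, a in entry["reduced_quadratics"].items()}
    if jitter > 0:
        rng = np.random.default_rng(seed)
        for a in quads.values():
            a[1:3] *= 1.0 + jitter * rng.standard_normal(2)
    arch = GOIArchetype(
        name=name,
        reduced_quadratics=quads,
        rsm_dev_coef={r: a.copy() for r, a in entry["rsm_dev_coef"].items()},
        top_m=entry["top_m"],
    )
    _verify_common(arch)
    _VERIFIERS[name](arch)
    return arch


# ---------------------------------------------------------------------------
# simulation


def simulate_runs(
    design,
    archetype: GOIArchetype,
    noise: NoiseModel | None = None,
    replicates: int = 1,
    seed: int = 0,
    ratio: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate a run table for a mixture or FCCD design.

    Per run, each response is the archetype's true surface value plus
    Gaussian noise.  % full and viability are clipped to their physical
    ranges (``df.attrs['clip_events']`` counts occurrences; % full uses a
    tiny positive floor so titers stay finite).  Vector-genome and capsid
    titers are back-computed at a fixed 2-day harvest so that the derived
    Log(Vp) and % full reproduce the simulated responses exactly.

    For an FCCD design, ``ratio`` fixes the plasmid blend (default: the
    archetype's top true mixture optimum).  Deterministic per ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    noise = archetype.noise_defaults if noise is None else noise
    rng = np.random.default_rng(seed)

    if isinstance(design, MixtureDesign) or (
        hasattr(design, "runs") and not hasattr(design, "coded_runs")
    ):
        comps = np.repeat(design.runs, replicates, axis=0)
        truth = {
            r: surf.predict(comps) for r, surf in archetype.scheffe_surfaces().items()
        }
        dna = np.full(comps.shape[0], MD_STAGE_DNA)
        fv = np.full(comps.shape[0], MD_STAGE_FV)
        extra = {}
    elif isinstance(design, FCCDDesign) or hasattr(design, "coded_runs"):
        if ratio is None:
            ratio = archetype.true_md_optima().best.point
        ratio = np.asarray(ratio, dtype=float)
        coded = np.repeat(design.coded_runs, replicates, axis=0)
        surfaces = archetype.rsm_surfaces(ratio)
        truth = {r: surf.predict(coded) for r, surf in surfaces.items()}
        comps = np.tile(ratio, (coded.shape[0], 1))
        actual = design.decode(coded)
        dna, fv = actual[:, 0], actual[:, 1]
        extra = {"dna_coded": coded[:, 0], "fv_coded": coded[:, 1]}
    else:
        raise TypeError(f"unsupported design type: {type(design).__name__}")

    n = comps.shape[0]
    sig = noise.sigmas
    lv = truth["log_vp"] + sig["log_vp"] * rng.standard_normal(n)
    pf = truth["pct_full"] + sig["pct_full"] * rng.standard_normal(n)
    vb = truth["viability"] + sig["viability"] * rng.standard_normal(n)

    clip_events = {
        "pct_full": int(np.sum((pf < PCT_FULL_FLOOR) | (pf > 100))),
        "viability": int(np.sum((vb < 0) | (vb > 100))),
    }
    pf = np.clip(pf, PCT_FULL_FLOOR, 100.0)
    vb = np.clip(vb, 0.0, 100.0)

    vg_titer = SIMULATED_HARVEST_DAYS * 10.0**lv
    capsid_titer = vg_titer / (pf / 100.0)

    df = pd.DataFrame(
        {
            "run_id": np.arange(1, n + 1),
            "pHelper": comps[:, 0],
            "pRepCap": comps[:, 1],
            "pGOI": comps[:, 2],
            "dna_total": dna,
            "fv_ratio": fv,
            "time_days": SIMULATED_HARVEST_DAYS,
            "vg_titer": vg_titer,
            "capsid_titer": capsid_titer,
            "viability": vb,
            **extra,
        }
    )
    df.attrs["clip_events"] = clip_events
    df.attrs["seed"] = seed
    df.attrs["archetype"] = archetype.name
    return df


# ---------------------------------------------------------------------------
# end-to-end recovery


@dataclass
class RecoveryReport:
    """Outcome of a simulated mixture -> FCCD optimization campaign."""

    archetype: str
    recovered_ratios: list[np.ndarray]
    true_ratios: list[np.ndarray]
    md_recovery_error: list[float]
    recovered_fccd_point: np.ndarray
    true_fccd_point: np.ndarray
    fccd_recovery_error: float
    d_stage1_true: float
    d_stage2_true: float
    seeds: dict[str, int]

    @property
    def d_improvement(self) -> float:
        return self.d_stage2_true - self.d_stage1_true


def _nearest_distance(point: np.ndarray, targets: list[np.ndarray]) -> float:
    return float(min(np.linalg.norm(point - t) for t in targets))


def end_to_end_recovery(
    archetype: GOIArchetype,
    noise: NoiseModel | None = None,
    seed: int = 0,
    n_runs: int = 13,
    candidate_step: float = 0.05,
    simplex_grid_step: float = 0.02,
    square_grid_step: float = 0.05,
    fccd_centers: int = 3,
    replicates: int = 1,
) -> RecoveryReport:
    """Run design -> simulate -> fit -> optimize for both stages and score it.

    Stage 1 selects a D-optimal mixture design, fits Scheffe models to the
    simulated responses and locates the combined-desirability optimum
    (top-2 for the bimodal archetype).  Stage 2 fixes the recovered blend,
    runs an FCCD on total DNA and reagent ratio, fits RSM models and
    optimizes again.  Recovery error is the distance from each recovered
    optimum to the nearest true optimum; the true-desirability improvement
    compares the stage-2 point against center factor levels at the same
    blend, both scored on the true surfaces.
    """
    noise = ZERO_NOISE if noise is None else noise
    ss = np.random.SeedSequence(seed)
    seed_design, seed_md, seed_fccd = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )

    # stage 1: mixture design
    candidates = simplex_candidates(archetype.bounds, candidate_step)
    design = d_optimal_select(candidates, n_runs=n_runs, seed=seed_design)
    table = simulate_runs(design, archetype, noise, replicates=replicates, seed=seed_md)
    from .pipeline import attach_derived_responses

    table = attach_derived_responses(table)
    fitted = {
        r: fit_scheffe(design, table[r].to_numpy()) for r in RESPONSE_NAMES
    }
    region = SimplexRegion(archetype.bounds, simplex_grid_step)
    md_result = optimize_desirability(fitted, region, top_m=archetype.top_m)
    recovered = [o.point for o in md_result.optima]

    truth = archetype.true_md_optima(grid_step=simplex_grid_step / 5)
    true_pts = [o.point for o in truth.optima]
    md_err = [_nearest_distance(p, true_pts) for p in recovered]

    # stage 2: FCCD at the recovered blend
    blend = recovered[0]
    fccd = fccd_design(n_center=fccd_centers)
    ftable = simulate_runs(
        fccd, archetype, noise, replicates=replicates, seed=seed_fccd, ratio=blend
    )
    ftable = attach_derived_responses(ftable)
    coded = np.repeat(fccd.coded_runs, replicates, axis=0)
    fitted_rsm = {r: fit_rsm(coded, ftable[r].to_numpy()) for r in RESPONSE_NAMES}
    square = SquareRegion(square_grid_step)
    fccd_result = optimize_desirability(fitted_rsm, square)
    fccd_point = fccd_result.best.point

    # true-surface scoring on the same region and blend
    true_surfaces = archetype.rsm_surfaces(blend)
    true_spec = DesirabilitySpec.from_models(true_surfaces, square)
    true_fccd = optimize_desirability(true_surfaces, square, spec=true_spec)
    true_point = true_fccd.best.point

    def true_D(point: np.ndarray) -> float:
        from .desirability import _eval_point

        return _eval_point(true_surfaces, true_spec, point)[2]

    d_stage1 = true_D(np.zeros(2))
    d_stage2 = true_D(fccd_point)

    return RecoveryReport(
        archetype=archetype.name,
        recovered_ratios=recovered,
        true_ratios=true_pts,
        md_recovery_error=md_err,
        recovered_fccd_point=fccd_point,
        true_fccd_point=true_point,
        fccd_recovery_error=float(np.linalg.norm(fccd_point - true_point)),
        d_stage1_true=d_stage1,
        d_stage2_true=d_stage2,
        seeds={"design": seed_design, "md": seed_md, "fccd": seed_fccd},
    )
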