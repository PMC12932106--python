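"""Experimental designs for triple-transfection optimization.

Two design families are implemented:

* **Constrained mixture designs** over the 3-component plasmid simplex
  (pHelper, pRepCap, pGOI mass fractions summing to 1, each bounded, e.g.
  10-60 %).  Candidate points are a regular barycentric lattice; a D-optimal
  subset is selected by Fedorov point exchange, maximizing the log-determinant
  of the Scheffe-quadratic information matrix X'X.

* **Face-centered central composite designs (FCCD)** for the two process
  factors (total DNA amount, transfection-reagent ratio) on the coded
  square {-1, 0, +1}^2: four factorial corners, four face centers, and
  replicated center points, with an affine decode map to physical units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import scheffe_matrix

DEFAULT_COMPONENT_NAMES = ("pHelper", "pRepCap", "pGOI")
DEFAULT_FACTOR_NAMES = ("dna", "fv")

#: physical factor ranges used throughout the examples: total DNA in ug/mL
#: around the 2 ug/mL mixture-stage condition, reagent:DNA ratio around 1:1.
DEFAULT_FCCD_LIMITS = {"dna": (1.0, 3.0), "fv": (0.5, 2.0)}

_SUM_TOL = 1e-9


class InfeasibleBoundsError(ValueError):
    """The per-component bounds admit no point on the simplex."""


@dataclass(frozen=True)
class MixtureBounds:
    """Per-component lower/upper bounds on mixture mass fractions.

    Feasibility on the simplex requires ``sum(lower) <= 1 <= sum(upper)``
    in addition to ``0 <= lower_i < upper_i <= 1``.
    """

    lower: tuple[float, ...] = (0.1, 0.1, 0.1)
    upper: tuple[float, ...] = (0.6, 0.6, 0.6)
    component_names: tuple[str, ...] = DEFAULT_COMPONENT_NAMES

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise InfeasibleBoundsError("lower and upper must be equal-length vectors")
        if len(self.component_names) != lo.size:
            raise InfeasibleBoundsError("component_names must match bound dimension")
        if np.any(lo < 0) or np.any(hi > 1) or np.any(lo >= hi):
            raise InfeasibleBoundsError(
                "bounds must satisfy 0 <= lower_i < upper_i <= 1 for every component"
            )
        if lo.sum() > 1 + _SUM_TOL:
            raise InfeasibleBoundsError(
                f"sum of lower bounds {lo.sum():.4g} exceeds 1: empty constrained simplex"
            )
        if hi.sum() < 1 - _SUM_TOL:
            raise InfeasibleBoundsError(
                f"sum of upper bounds {hi.sum():.4g} is below 1: empty constrained simplex"
            )

    @property
    def n_components(self) -> int:
        return len(self.lower)

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask of rows inside the bounds and on the simplex."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        ok = np.all(pts >= lo - tol, axis=1) & np.all(pts <= hi + tol, axis=1)
        return ok & (np.abs(pts.sum(axis=1) - 1) <= max(tol, _SUM_TOL))


@dataclass(frozen=True)
class CandidateSet:
    """Lattice of feasible mixture compositions used as D-optimal support."""

    points: np.ndarray
    step: float
    bounds: MixtureBounds

    def __len__(self) -> int:
        return self.points.shape[0]


def simplex_candidates(bounds: MixtureBounds, step: float = 0.05) -> CandidateSet:
    """Enumerate the regular lattice of feasible compositions.

    Every returned composition has coordinates that are integer multiples of
    ``step``, sums to 1, and lies inside ``bounds``.  Ordering is
    lexicographic, so the candidate set is deterministic.
    """
    if not np.isfinite(step) or step <= 0:
        raise ValueError(f"step must be a positive fraction, got {step}")
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} does not divide 1 within tolerance")

    lo = np.asarray(bounds.lower)
    hi = np.asarray(bounds.upper)
    k = bounds.n_components
    # integer bounds on lattice counts per component
    lo_i = np.ceil(lo * m - 1e-9).astype(int)
    hi_i = np.floor(hi * m + 1e-9).astype(int)

    pts: list[tuple[int, ...]] = []

    def recurse(prefix: list[int], remaining: int, depth: int) -> None:
        if depth == k - 1:
            if lo_i[depth] <= remaining <= hi_i[depth]:
                pts.append(tuple(prefix + [remaining]))
            return
        lo_rest = int(lo_i[depth + 1 :].sum())
        hi_rest = int(hi_i[depth + 1 :].sum())
        start = max(lo_i[depth], remaining - hi_rest)
        stop = min(hi_i[depth], remaining - lo_rest)
        for v in range(start, stop + 1):
            recurse(prefix + [v], remaining - v, depth + 1)

    recurse([], m, 0)
    if not pts:
        raise InfeasibleBoundsError(
            f"no lattice point at step {step} lies inside the bounds"
        )
    arr = np.array(sorted(pts), dtype=float) / m
    return CandidateSet(points=arr, step=step, bounds=bounds)


@dataclass
class MixtureDesign:
    """A selected mixture design with its D-criterion value.

    ``criterion_value`` is ``logdet(X'X)`` for the Scheffe-quadratic model
    matrix of the runs.  ``trace`` records the criterion after each accepted
    exchange of the winning start (monotone nondecreasing by construction).
    """

    runs: np.ndarray
    criterion_value: float
    bounds: MixtureBounds
    trace: list[float] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def replicate_counts(self) -> dict[tuple[float, ...], int]:
        uniq, counts = np.unique(np.round(self.runs, 9), axis=0, return_counts=True)
        return {tuple(row): int(c) for row, c in zip(uniq, counts)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.runs, columns=list(self.bounds.component_names))
        df.insert(0, "run_id", np.arange(1, self.n_runs + 1))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_mixture_design(path, bounds: MixtureBounds | None = None) -> MixtureDesign:
    """Read a mixture design written by :meth:`MixtureDesign.to_csv`."""
    bounds = bounds or MixtureBounds()
    df = pd.read_csv(path)
    cols = list(bounds.component_names)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"design file missing component columns: {missing}")
    runs = df[cols].to_numpy(dtype=float)
    X = scheffe_matrix(runs)
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return MixtureDesign(
        runs=runs,
        criterion_value=float(logdet) if sign > 0 else -np.inf,
        bounds=bounds,
    )


def _log_det(X: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return float(logdet) if sign > 0 else -np.inf


def d_optimal_select(
    candidates: CandidateSet,
    n_runs: int = 13,
    model: str = "scheffe_quadratic",
    n_starts: int = 10,
    seed: int = 0,
    improvement_tol: float = 1e-10,
) -> MixtureDesign:
    """Select an ``n_runs``-point D-optimal design by Fedorov point exchange.

    Selection is without replacement: the design is a distinct-point subset
    of the candidates (replicate measurement of a run is handled at
    simulation/measurement time).  Each pass considers every (design point,
    candidate) swap and applies the best strictly improving one; ties are
    broken by the lowest candidate index.  The best of ``n_starts`` random
    starts is returned.  Deterministic for a fixed ``seed``.
    """
    if model != "scheffe_quadratic":
        raise ValueError(f"unknown model form: {model!r}")
    cand = candidates.points
    n_cand = cand.shape[0]
    if n_cand == 0:
        raise ValueError("candidate set is empty")
    F = scheffe_matrix(cand)  # (n_cand, p)
    p = F.shape[1]
    if n_runs < p:
        raise ValueError(
            f"n_runs={n_runs} is below the {p} Scheffe-quadratic model terms"
        )
    if n_runs > n_cand:
        raise ValueError(
            f"n_runs={n_runs} exceeds the {n_cand} distinct candidates; refine "
            "the candidate lattice or lower n_runs"
        )

    rng = np.random.default_rng(seed)
    best_idx: np.ndarray | None = None
    best_val = -np.inf
    best_trace: list[float] = []

    for _ in range(n_starts):
        idx = rng.permutation(n_cand)[:n_runs]
        val = _log_det(F[idx])
        trace = [val]
        improved = True
        while improved:
            improved = False
            cur_best_delta = improvement_tol
            cur_swap: tuple[int, int] | None = None
            in_design = np.zeros(n_cand, dtype=bool)
            in_design[idx] = True
            for i in range(n_runs):
                trial = np.repeat(idx[None, :], n_cand, axis=0)
                trial[:, i] = np.arange(n_cand)
                mats = F[trial]  # (n_cand, n_runs, p)
                gram = np.einsum("kij,kil->kjl", mats, mats)
                sign, logdet = np.linalg.slogdet(gram)
                vals = np.where(sign > 0, logdet, -np.inf)
                vals[in_design & (np.arange(n_cand) != idx[i])] = -np.inf
                j = int(np.argmax(vals))  # argmax returns lowest index on ties
                if np.isfinite(vals[j]) and vals[j] - val > cur_best_delta:
                    cur_best_delta = vals[j] - val
                    cur_swap = (i, j)
            if cur_swap is not None:
                i, j = cur_swap
                new_idx = idx.copy()
                new_idx[i] = j
                # accept on the recomputed criterion: protects against the
                # batched prediction differing by rounding, and guarantees a
                # strictly increasing (terminating) trace
                new_val = _log_det(F[new_idx])
                if new_val > val + improvement_tol:
                    idx, val = new_idx, new_val
                    trace.append(val)
                    improved = True
        if val > best_val:
            best_val = val
            best_idx = idx
            best_trace = trace

    if best_idx is None or not np.isfinite(best_val):
        raise np.linalg.LinAlgError(
            "information matrix singular for all starts; increase n_runs or refine "
            "the candidate lattice"
        )
    runs = cand[np.sort(best_idx)]
    return MixtureDesign(
        runs=runs,
        criterion_value=best_val,
        bounds=candidates.bounds,
        trace=best_trace,
        seed=seed,
    )


def exhaustive_d_optimal(candidates: CandidateSet, n_runs: int) -> float:
    """Exact maximum log-det over all candidate subsets (oracle; small sets only)."""
    F = scheffe_matrix(candidates.points)
    best = -np.inf
    for combo in itertools.combinations(range(len(candidates)), n_runs):
        best = max(best, _log_det(F[list(combo)]))
    return best


# ---------------------------------------------------------------------------
# FCCD


@dataclass(frozen=True)
class FCCDDesign:
    """Two-factor face-centered central composite design on the coded square.

    ``coded_runs`` holds the 4 factorial corners, 4 face centers, and
    ``n_center`` center replicates, every coordinate in {-1, 0, +1}.
    ``limits`` maps each factor name to its (low, high) physical values;
    decode is the affine map sending -1/0/+1 to low/midpoint/high.
    """

    coded_runs: np.ndarray
    n_center: int
    limits: dict[str, tuple[float, float]]
    factor_names: tuple[str, ...] = DEFAULT_FACTOR_NAMES

    @property
    def n_runs(self) -> int:
        return self.coded_runs.shape[0]

    def decode(self, coded: np.ndarray) -> np.ndarray:
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        lo = np.array([self.limits[f][0] for f in self.factor_names])
        hi = np.array([self.limits[f][1] for f in self.factor_names])
        return (lo + hi) / 2 + coded * (hi - lo) / 2

    @property
    def actual_runs(self) -> np.ndarray:
        return self.decode(self.coded_runs)

    def to_frame(self) -> pd.DataFrame:
        actual = self.actual_runs
        df = pd.DataFrame(
            {
                "run_id": np.arange(1, self.n_runs + 1),
                "dna_coded": self.coded_runs[:, 0],
                "fv_coded": self.coded_runs[:, 1],
                "dna_actual": actual[:, 0],
                "fv_actual": actual[:, 1],
            }
        )
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def fccd_design(
    n_center: int = 3,
    limits: dict[str, tuple[float, float]] | None = None,
) -> FCCDDesign:
    """Construct the standard two-factor FCCD.

    4 factorial corners (+-1, +-1), 4 face centers, and ``n_center``
    replicates of the center (0, 0); 8 + n_center runs in total.
    """
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    limits = dict(limits or DEFAULT_FCCD_LIMITS)
    for name, (lo, hi) in limits.items():
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError(f"non-finite limits for factor {name!r}")
        if lo >= hi:
            raise ValueError(f"factor {name!r} requires low < high, got ({lo}, {hi})")
    corners = np.array([[-1, -1], [-1, 1], [1, -1], [1, 1]], dtype=float)
    faces = np.array([[-1, 0], [1, 0], [0, -1], [0, 1]], dtype=float)
    centers = np.zeros((n_center, 2))
    coded = np.vstack([corners, faces, centers])
    return FCCDDesign(coded_runs=coded, n_center=n_center, limits=limits)


def read_fccd_design(path) -> FCCDDesign:
    """Read an FCCD written by :meth:`FCCDDesign.to_csv`."""
    df = pd.read_csv(path)
    for col in ("dna_coded", "fv_coded", "dna_actual", "fv_actual"):
        if col not in df.columns:
            raise ValueError(f"FCCD file missing column {col!r}")
    coded = df[["dna_coded", "fv_coded"]].to_numpy(dtype=float)
    limits = {}
    for name, coded_col, actual_col in (
        ("dna", "dna_coded", "dna_actual"),
        ("fv", "fv_coded", "fv_actual"),
    ):
        lo = df.loc[df[coded_col] == -1, actual_col]
        hi = df.loc[df[coded_col] == 1, actual_col]
        if lo.empty or hi.empty:
            raise ValueError(f"cannot infer limits for factor {name!r}")
        limits[name] = (float(lo.iloc[0]), float(hi.iloc[0]))
    n_center = int(np.sum(np.all(coded == 0, axis=1)))
    return FCCDDesign(coded_runs=coded, n_center=n_center, limits=limits)
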