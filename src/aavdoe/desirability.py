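"""Multi-response desirability optimization over design regions.

Each maximized response y is mapped to an individual desirability

    d = 0                      if y < L
    d = ((y - L)/(T - L))^r    if L <= y <= T
    d = 1                      if y > T

with lower limit L, target T and shape exponent r in (0, 1].  Responses are
combined as the geometric mean D = prod d_i^(1/k), so any fully undesirable
response (d_i = 0) annihilates the overall score.

The optimizer scans a dense lattice over the feasible region (the bounded
plasmid simplex or the coded FCCD square), identifies grid local maxima of D,
and polishes the top-m of them with a derivative-free Nelder-Mead search.
Threshold-region masks mark where every response clears a per-response
threshold — the "white area" of a mixture/contour profiler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .designs import MixtureBounds, simplex_candidates


class EmptyRegionError(ValueError):
    """The feasible region contains no grid point."""


# ---------------------------------------------------------------------------
# individual / overall desirability


def desirability_one(y, L: float, T: float, r: float = 1.0):
    """Individual desirability of a larger-is-better response."""
    if not L < T:
        raise ValueError(f"lower limit must be below target, got L={L}, T={T}")
    if not 0 < r <= 1:
        raise ValueError(f"shape exponent r must be in (0, 1], got {r}")
    y = np.asarray(y, dtype=float)
    scaled = np.clip((y - L) / (T - L), 0.0, 1.0)
    out = scaled**r
    return float(out) if out.ndim == 0 else out


def desirability_overall(d, k: int | None = None):
    """Geometric mean D = prod d_i^(1/k) of individual desirabilities."""
    d = np.asarray(d, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("individual desirabilities must lie in [0, 1]")
    k_len = d.shape[0] if d.ndim >= 1 else 1
    if k is not None and k != k_len:
        raise ValueError(f"k={k} does not match {k_len} desirabilities")
    return float(np.prod(d ** (1.0 / k_len), axis=0)) if d.ndim == 1 else np.prod(
        d ** (1.0 / k_len), axis=0
    )


@dataclass(frozen=True)
class DesirabilitySpec:
    """Per-response (L, T, r) settings for the desirability transform."""

    responses: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for name, (L, T, r) in self.responses.items():
            if not np.isfinite(L) or not np.isfinite(T) or L >= T:
                raise ValueError(f"response {name!r}: need finite L < T, got ({L}, {T})")
            if not 0 < r <= 1:
                raise ValueError(f"response {name!r}: r must be in (0, 1], got {r}")

    @property
    def k(self) -> int:
        return len(self.responses)

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        return self.responses[name]

    @classmethod
    def from_models(cls, models: Mapping, region, r=1.0) -> "DesirabilitySpec":
        """Default spec: L/T are the min/max predictions over the region grid.

        ``r`` may be a scalar applied to every response or a per-response
        mapping.  Raises on a degenerate (constant) surface.
        """
        grid = region.grid()
        responses = {}
        for name, model in models.items():
            pred = np.asarray(model.predict(grid), dtype=float)
            L, T = float(pred.min()), float(pred.max())
            if not T > L:
                raise ValueError(
                    f"response {name!r} is constant over the region (T == L); "
                    "supply explicit limits"
                )
            r_i = float(r[name]) if isinstance(r, Mapping) else float(r)
            responses[name] = (L, T, r_i)
        return cls(responses)


# ---------------------------------------------------------------------------
# regions


@dataclass(frozen=True)
class SimplexRegion:
    """Bounded 3-component simplex with a barycentric lattice grid."""

    bounds: MixtureBounds = field(default_factory=MixtureBounds)
    grid_step: float = 0.02

    def grid(self) -> np.ndarray:
        return simplex_candidates(self.bounds, self.grid_step).points

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.bounds.contains(points)

    @property
    def ndim_reduced(self) -> int:
        return self.bounds.n_components - 1

    def to_full(self, reduced: np.ndarray) -> np.ndarray:
        red = np.atleast_2d(np.asarray(reduced, dtype=float))
        last = 1.0 - red.sum(axis=1, keepdims=True)
        return np.hstack([red, last])

    def to_reduced(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(points, dtype=float))[:, :-1]


@dataclass(frozen=True)
class SquareRegion:
    """Coded factor square [-1, 1]^2 with a regular grid."""

    grid_step: float = 0.05
    low: float = -1.0
    high: float = 1.0

    def grid(self) -> np.ndarray:
        n = round((self.high - self.low) / self.grid_step)
        ax = self.low + self.grid_step * np.arange(n + 1)
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        tol = 1e-9
        return np.all((pts >= self.low - tol) & (pts <= self.high + tol), axis=1)

    @property
    def ndim_reduced(self) -> int:
        return 2

    def to_full(self, reduced: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(reduced, dtype=float))

    def to_reduced(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(points, dtype=float))


# ---------------------------------------------------------------------------
# optimization


@dataclass
class Optimum:
    """One located optimum with its predicted responses."""

    point: np.ndarray
    D: float
    d_individual: dict[str, float]
    predictions: dict[str, float]


@dataclass
class OptimizationResult:
    """Ranked optima of the overall desirability over a region."""

    optima: list[Optimum]
    spec: DesirabilitySpec
    grid_step: float
    plateau: bool
    all_zero: bool
    seed: int | None = None
    polish_iterations: int = 0

    @property
    def best(self) -> Optimum:
        return self.optima[0]

    @property
    def point(self) -> np.ndarray:
        return self.best.point

    @property
    def D(self) -> float:
        return self.best.D


def _eval_point(models: Mapping, spec: DesirabilitySpec, point: np.ndarray):
    preds = {name: float(np.asarray(m.predict(point[None, :]))[0]) for name, m in models.items()}
    d = {name: float(desirability_one(preds[name], *spec[name])) for name in models}
    D = desirability_overall(np.array(list(d.values())))
    return preds, d, D


def optimize_desirability(
    models: Mapping,
    region,
    spec: DesirabilitySpec | None = None,
    top_m: int = 1,
    seed: int | None = None,
    polish: bool = True,
    polish_maxiter: int = 200,
    min_separation: float | None = None,
) -> OptimizationResult:
    """Maximize overall desirability by dense grid scan plus local polish.

    Grid local maxima of D are ranked; the ``top_m`` best (kept at least
    ``min_separation`` apart, default 3 grid steps) are each polished with a
    Nelder-Mead search capped at ``polish_maxiter`` iterations.  Deterministic
    for fixed inputs; ``seed`` is recorded in the result metadata.
    """
    grid = region.grid()
    if grid.shape[0] == 0:
        raise EmptyRegionError("feasible region contains no grid point")
    if spec is None:
        spec = DesirabilitySpec.from_models(models, region, r=1.0)
    if set(spec.responses) != set(models):
        raise ValueError("spec responses do not match the supplied models")

    preds = {name: np.asarray(m.predict(grid), dtype=float) for name, m in models.items()}
    d_grid = np.vstack(
        [desirability_one(preds[name], *spec[name]) for name in models]
    )
    D_grid = desirability_overall(d_grid)

    all_zero = bool(np.all(D_grid == 0))
    plateau = bool(np.ptp(D_grid) < 1e-12)

    # local maxima over the lattice neighbor graph
    step = region.grid_step
    tree = cKDTree(grid)
    pairs = tree.query_pairs(r=step * 1.5, output_type="ndarray")
    is_max = np.ones(grid.shape[0], dtype=bool)
    if pairs.size:
        a, b = pairs[:, 0], pairs[:, 1]
        lower = D_grid[a] < D_grid[b]
        is_max[a[lower]] = False
        is_max[b[~lower & (D_grid[a] > D_grid[b])]] = False
    order = np.argsort(-D_grid, kind="stable")
    maxima_idx = [i for i in order if is_max[i]]

    min_sep = 3 * step if min_separation is None else min_separation
    chosen: list[int] = []
    for i in maxima_idx:
        if all(np.linalg.norm(grid[i] - grid[j]) >= min_sep for j in chosen):
            chosen.append(i)
        if len(chosen) == top_m:
            break
    if not chosen:  # fully flat surface: keep the first grid point
        chosen = [int(order[0])]

    optima: list[Optimum] = []
    polish_iters = 0
    for i in chosen:
        point = grid[i].copy()
        _, _, D_best = _eval_point(models, spec, point)
        if polish and not plateau:

            def neg_D(reduced):
                full = region.to_full(reduced)[0]
                if not region.contains(full[None, :])[0]:
                    return 2.0  # outside: worse than any D in [-1, 0]
                _, _, D_val = _eval_point(models, spec, full)
                return -D_val

            res = minimize(
                neg_D,
                region.to_reduced(point[None, :])[0],
                method="Nelder-Mead",
                options={"maxiter": polish_maxiter, "xatol": step * 1e-3, "fatol": 1e-12},
            )
            polish_iters += int(res.nit)
            cand = region.to_full(res.x)[0]
            if region.contains(cand[None, :])[0] and -res.fun > D_best:
                point, D_best = cand, -res.fun
        p, d, D = _eval_point(models, spec, point)
        optima.append(Optimum(point=point, D=D, d_individual=d, predictions=p))

    optima.sort(key=lambda o: -o.D)
    # polish can merge basins: drop optima that collapsed onto a better one
    deduped: list[Optimum] = []
    for o in optima:
        if all(np.linalg.norm(o.point - kept.point) >= min_sep for kept in deduped):
            deduped.append(o)
    optima = deduped
    return OptimizationResult(
        optima=optima,
        spec=spec,
        grid_step=step,
        plateau=plateau,
        all_zero=all_zero,
        seed=seed,
        polish_iterations=polish_iters,
    )


# ---------------------------------------------------------------------------
# threshold regions


@dataclass
class RegionMask:
    """Per-grid-point response thresholds: the profiler's white area."""

    points: np.ndarray
    predictions: dict[str, np.ndarray]
    passes: dict[str, np.ndarray]
    combined: np.ndarray
    thresholds: dict[str, float]

    def to_frame(self, coord_names=None) -> pd.DataFrame:
        k = self.points.shape[1]
        coord_names = coord_names or [f"x{i+1}" for i in range(k)]
        df = pd.DataFrame(self.points, columns=coord_names)
        for name in self.predictions:
            df[f"pred_{name}"] = self.predictions[name]
            df[f"pass_{name}"] = self.passes[name]
        df["combined"] = self.combined
        return df

    def to_csv(self, path, coord_names=None) -> None:
        self.to_frame(coord_names).to_csv(path, index=False)


def threshold_region(
    models: Mapping,
    thresholds: Mapping[str, float],
    region,
    grid_step: float | None = None,
) -> RegionMask:
    """Mark grid points where every predicted response clears its threshold."""
    if grid_step is not None:
        if grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        region = type(region)(**{**region.__dict__, "grid_step": grid_step})
    for name, thr in thresholds.items():
        if not np.isfinite(thr) and not thr == -np.inf:
            raise ValueError(f"threshold for {name!r} must be finite or -inf")
    grid = region.grid()
    preds = {name: np.asarray(m.predict(grid), dtype=float) for name, m in models.items()}
    passes = {name: preds[name] >= thresholds[name] for name in models}
    combined = np.logical_and.reduce(list(passes.values()))
    return RegionMask(
        points=grid,
        predictions=preds,
        passes=passes,
        combined=combined,
        thresholds=dict(thresholds),
    )


def equal_weight_thresholds(
    models: Mapping,
    region,
    level: float,
    spec: DesirabilitySpec | None = None,
) -> dict[str, float]:
    """Per-response thresholds at a common individual-desirability level.

    Inverts the desirability transform: the returned y* per response satisfies
    d(y*) = level given that response's (L, T, r), so drawing each threshold
    weights the responses equally in the combined score.
    """
    if not 0 < level <= 1:
        raise ValueError(f"level must be in (0, 1], got {level}")
    if spec is None:
        spec = DesirabilitySpec.from_models(models, region, r=1.0)
    out = {}
    for name in models:
        L, T, r = spec[name]
        out[name] = L + (T - L) * level ** (1.0 / r)
    return out
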