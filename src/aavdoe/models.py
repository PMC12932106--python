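"""Response transforms and polynomial response models.

Responses
---------
Volumetric productivity ``Vp = titer / time`` (vg mL^-1 day^-1) is analyzed
as ``Log(Vp) = log10(titer / time)``.  The full-capsid percentage is
``% full = 100 * genome_titer / capsid_titer`` (qPCR vector-genome titer over
ELISA total-capsid titer).  Viability is a percentage of live cells.

Models
------
* The **Scheffe quadratic** for mixture factors (plasmid mass fractions
  summing to 1): ``y = sum_i b_i x_i + sum_{i<j} b_ij x_i x_j`` with no
  intercept — b_i is the expected response of the pure blend x_i = 1.
* The **second-order RSM polynomial** for the coded FCCD factors:
  ``y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j``.

Both are fitted by ordinary least squares (statsmodels OLS); whole-model
significance is a single F test.  Because mixture fractions sum to one, the
Scheffe column span contains the constant vector, so the mean-corrected
ANOVA partition applies to both families with ``df_model = p - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

AVOGADRO = 6.02214076e23
#: mean molar mass of one base pair of double-stranded DNA, g/mol
DS_BP_GRAMS_PER_MOL = 650.0
#: mean molar mass of one base of single-stranded DNA, g/mol
SS_BASE_GRAMS_PER_MOL = 330.0

RESPONSE_NAMES = ("log_vp", "pct_full", "viability")


def log_vp(titer, time_days):
    """Log10 volumetric productivity, ``log10(titer / time)``.

    Parameters are the vector-genome titer (vg/mL) and the harvest time in
    days; both must be strictly positive.
    """
    titer = np.asarray(titer, dtype=float)
    time_days = np.asarray(time_days, dtype=float)
    if np.any(titer <= 0):
        raise ValueError("titer must be > 0 for a defined Log(Vp)")
    if np.any(time_days <= 0):
        raise ValueError("time must be > 0 days")
    out = np.log10(titer / time_days)
    return float(out) if out.ndim == 0 else out


def pct_full(genome_titer, capsid_titer):
    """Percentage of capsids carrying a full vector genome.

    ``100 * genome_titer / capsid_titer``.  Values above 100 % indicate an
    inconsistency between the qPCR and ELISA titers; they are returned
    unchanged but a warning is emitted.
    """
    genome_titer = np.asarray(genome_titer, dtype=float)
    capsid_titer = np.asarray(capsid_titer, dtype=float)
    if np.any(capsid_titer <= 0):
        raise ValueError("capsid titer must be > 0")
    if np.any(genome_titer < 0):
        raise ValueError("genome titer must be >= 0")
    out = 100.0 * genome_titer / capsid_titer
    if np.any(out > 100):
        warnings.warn(
            "pct_full above 100%: genome titer exceeds capsid titer "
            "(qPCR/ELISA inconsistency)",
            UserWarning,
            stacklevel=2,
        )
    return float(out) if out.ndim == 0 else out


def mass_to_copies(mass_ug_per_ml, length_bp, double_stranded: bool = True):
    """Convert a plasmid mass concentration (ug/mL) to copies/mL.

    copies/mL = mass(g/mL) * N_A / (length * molar mass per bp), using
    650 g/mol/bp for double-stranded DNA (330 g/mol/base single-stranded).
    """
    mass = np.asarray(mass_ug_per_ml, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("sequence length must be > 0")
    if np.any(mass < 0):
        raise ValueError("mass concentration must be >= 0")
    per_unit = DS_BP_GRAMS_PER_MOL if double_stranded else SS_BASE_GRAMS_PER_MOL
    out = mass * 1e-6 * AVOGADRO / (length_bp * per_unit)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# model matrices


def scheffe_matrix(points: np.ndarray) -> np.ndarray:
    """Scheffe-quadratic model matrix: columns x_i then x_i*x_j (i < j)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    k = pts.shape[1]
    cols = [pts[:, i] for i in range(k)]
    cols += [pts[:, i] * pts[:, j] for i in range(k) for j in range(i + 1, k)]
    return np.column_stack(cols)


def scheffe_term_labels(names=("pHelper", "pRepCap", "pGOI")) -> list[str]:
    k = len(names)
    labels = list(names)
    labels += [f"{names[i]}*{names[j]}" for i in range(k) for j in range(i + 1, k)]
    return labels


def rsm_matrix(points: np.ndarray) -> np.ndarray:
    """Second-order RSM model matrix: 1, x_i, x_i^2, x_i*x_j (i < j)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, k = pts.shape
    cols = [np.ones(n)]
    cols += [pts[:, i] for i in range(k)]
    cols += [pts[:, i] ** 2 for i in range(k)]
    cols += [pts[:, i] * pts[:, j] for i in range(k) for j in range(i + 1, k)]
    return np.column_stack(cols)


def rsm_term_labels(names=("dna", "fv")) -> list[str]:
    k = len(names)
    labels = ["intercept"] + list(names)
    labels += [f"{n}^2" for n in names]
    labels += [f"{names[i]}*{names[j]}" for i in range(k) for j in range(i + 1, k)]
    return labels


# ---------------------------------------------------------------------------
# fitted models


@dataclass
class AnovaTable:
    """Whole-model F test with the mean-corrected sum-of-squares partition."""

    df_model: int
    df_residual: int
    ss_model: float
    ss_residual: float
    f_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_value) and self.p_value < 0.05

    @property
    def ss_total(self) -> float:
        return self.ss_model + self.ss_residual

    def to_dict(self) -> dict:
        return {
            "df_model": self.df_model,
            "df_residual": self.df_residual,
            "ss_model": self.ss_model,
            "ss_residual": self.ss_residual,
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
        }


@dataclass
class _PolyModel:
    """Shared OLS plumbing for the two polynomial families."""

    coef: np.ndarray
    term_labels: list[str]
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    residual_variance: float

    def _matrix(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_runs(self) -> int:
        return self.X.shape[0]

    @property
    def n_terms(self) -> int:
        return self.X.shape[1]

    @property
    def fitted(self) -> np.ndarray:
        return self.X @ self.coef

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.fitted

    def predict(self, points: np.ndarray) -> np.ndarray:
        out = self._matrix(points) @ self.coef
        return out

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Per-coefficient (lower, upper) t confidence intervals."""
        df = self.n_runs - self.n_terms
        if df < 1:
            raise ValueError("no residual degrees of freedom for intervals")
        se = np.sqrt(np.diag(self.cov))
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return np.column_stack([self.coef - tcrit * se, self.coef + tcrit * se])

    def coef_dict(self) -> dict[str, float]:
        return {lab: float(c) for lab, c in zip(self.term_labels, self.coef)}


@dataclass
class ScheffeModel(_PolyModel):
    """Fitted Scheffe quadratic: prediction at a pure blend e_i is b_i."""

    component_names: tuple[str, ...] = ("pHelper", "pRepCap", "pGOI")

    def _matrix(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if np.any(np.abs(pts.sum(axis=1) - 1) > 1e-6):
            bad = np.argmax(np.abs(pts.sum(axis=1) - 1))
            raise ValueError(
                f"mixture point {pts[bad]} does not sum to 1 (within 1e-6)"
            )
        return scheffe_matrix(pts)

    @property
    def beta_linear(self) -> np.ndarray:
        k = len(self.component_names)
        return self.coef[:k]

    @property
    def beta_blend(self) -> np.ndarray:
        k = len(self.component_names)
        return self.coef[k:]


@dataclass
class RSMModel(_PolyModel):
    """Fitted second-order polynomial on the coded factor square."""

    factor_names: tuple[str, ...] = ("dna", "fv")

    def _matrix(self, points: np.ndarray) -> np.ndarray:
        return rsm_matrix(points)

    @property
    def beta0(self) -> float:
        return float(self.coef[0])

    @property
    def beta_linear(self) -> np.ndarray:
        k = len(self.factor_names)
        return self.coef[1 : 1 + k]

    @property
    def beta_quad(self) -> np.ndarray:
        k = len(self.factor_names)
        return self.coef[1 + k : 1 + 2 * k]

    @property
    def beta_interact(self) -> np.ndarray:
        k = len(self.factor_names)
        return self.coef[1 + 2 * k :]


def _ols_fit(X: np.ndarray, y: np.ndarray, labels: list[str]):
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the collinear terms via the QR pivot pattern
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [labels[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise np.linalg.LinAlgError(
            f"model matrix rank deficient (rank {rank} < {p} terms); "
            f"collinear terms: {bad or 'unidentified'}"
        )
    res = sm.OLS(y, X).fit()
    df_resid = n - p
    sigma2 = float(res.ssr / df_resid) if df_resid > 0 else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    return res, sigma2, sigma2 * xtx_inv


def fit_scheffe(design, y, component_names=("pHelper", "pRepCap", "pGOI")) -> ScheffeModel:
    """Fit the Scheffe quadratic to a mixture design by least squares.

    ``design`` is a MixtureDesign or an (n, k) array of compositions.
    Requires at least as many runs as model terms (6 for 3 components).
    """
    runs = np.asarray(getattr(design, "runs", design), dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.abs(runs.sum(axis=1) - 1) > 1e-6):
        raise ValueError("design rows must sum to 1")
    X = scheffe_matrix(runs)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least {p} runs to fit {p} Scheffe terms, got {n}")
    labels = scheffe_term_labels(component_names)
    res, sigma2, cov = _ols_fit(X, y, labels)
    return ScheffeModel(
        coef=np.asarray(res.params, dtype=float),
        term_labels=labels,
        X=X,
        y=y,
        cov=cov,
        residual_variance=sigma2,
        component_names=tuple(component_names),
    )


def fit_rsm(design, y, factor_names=("dna", "fv")) -> RSMModel:
    """Fit the second-order polynomial to a coded FCCD by least squares.

    ``design`` is an FCCDDesign or an (n, k) array of coded points.
    """
    coded = np.asarray(getattr(design, "coded_runs", design), dtype=float)
    y = np.asarray(y, dtype=float)
    X = rsm_matrix(coded)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least {p} runs to fit {p} RSM terms, got {n}")
    labels = rsm_term_labels(factor_names)
    res, sigma2, cov = _ols_fit(X, y, labels)
    return RSMModel(
        coef=np.asarray(res.params, dtype=float),
        term_labels=labels,
        X=X,
        y=y,
        cov=cov,
        residual_variance=sigma2,
        factor_names=tuple(factor_names),
    )


def anova_model(model: _PolyModel, y=None) -> AnovaTable:
    """Whole-model ANOVA F test for a fitted polynomial model.

    Uses the mean-corrected partition: SS_total = sum (y - ybar)^2 splits into
    model and residual components with ``df_model = p - 1`` (the constant is
    in the column span of both families).  With zero residual degrees of
    freedom the F statistic and p-value are returned as NaN.
    """
    y = model.y if y is None else np.asarray(y, dtype=float)
    fitted = model.X @ model.coef if y is model.y else None
    if fitted is None:
        # re-fit projection for externally supplied y
        coef, *_ = np.linalg.lstsq(model.X, y, rcond=None)
        fitted = model.X @ coef
    n, p = model.X.shape
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_residual = float(np.sum((y - fitted) ** 2))
    ss_model = ss_total - ss_residual
    df_model = p - 1
    df_residual = n - p
    if df_residual < 1:
        return AnovaTable(df_model, df_residual, ss_model, ss_residual, np.nan, np.nan)
    ms_model = ss_model / df_model
    ms_residual = ss_residual / df_residual
    if ms_residual == 0:
        return AnovaTable(df_model, df_residual, ss_model, ss_residual, np.inf, 0.0)
    f_stat = ms_model / ms_residual
    p_value = float(stats.f.sf(f_stat, df_model, df_residual))
    return AnovaTable(df_model, df_residual, ss_model, ss_residual, float(f_stat), p_value)


def predict(model: _PolyModel, points) -> np.ndarray:
    """Evaluate a fitted model on new points (vectorized)."""
    return model.predict(points)
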