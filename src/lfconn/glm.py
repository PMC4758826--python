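"""First-level GLM fitting, ROI summaries and behavioural statistics.

Per-subject timecourses are fitted by ordinary least squares against a
:class:`~lfconn.task_design.DesignMatrix`; contrast estimates and their
t-statistics follow the textbook GLM formulae.  Behavioural response-time
tables are screened by winsorisation (values beyond 2.5 SD replaced by the
boundary) and compared across learning stages with one-way repeated-measures
ANOVA and paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .task_design import Contrast, DesignMatrix


@dataclass
class GLMFit:
    betas: dict[str, float]
    residuals: np.ndarray
    residual_variance: float
    dof: int
    design: DesignMatrix
    xtx_inv: np.ndarray

    def beta_vector(self, names: list[str]) -> np.ndarray:
        return np.array([self.betas[n] for n in names])


def fit_glm(timecourse: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares fit of one timecourse on a design matrix.

    Raises on NaNs or a rank-deficient design; residuals are orthogonal to
    every design column.
    """
    y = np.asarray(timecourse, dtype=float)
    X = design.values
    if y.ndim != 1 or y.size != X.shape[0]:
        raise ValueError("timecourse length must match the design")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in data or design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = y.size - rank
    sigma2 = float(resid @ resid / dof) if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    return GLMFit(
        betas=dict(zip(design.columns, beta)),
        residuals=resid,
        residual_variance=sigma2,
        dof=dof,
        design=design,
        xtx_inv=xtx_inv,
    )


def contrast_estimate(
    fit: GLMFit, contrast: Contrast, columns: list[str] | None = None
) -> tuple[float, float]:
    """Contrast scalar wᵀβ and its t-statistic.

    ``columns`` names the regressors the contrast weights refer to; by
    default the stage regressors ``stage_1 … stage_k`` with k = len(weights).
    """
    if columns is None:
        columns = [f"stage_{i + 1}" for i in range(contrast.weights.size)]
    for c in columns:
        if c not in fit.betas:
            raise KeyError(f"contrast column {c!r} not in fit")
    all_cols = fit.design.columns
    w_full = np.zeros(len(all_cols))
    for c, w in zip(columns, contrast.weights):
        w_full[all_cols.index(c)] = w
    est = float(w_full @ np.array([fit.betas[c] for c in all_cols]))
    var = fit.residual_variance * float(w_full @ fit.xtx_inv @ w_full)
    t = est / np.sqrt(var) if var > 0 else np.nan
    return est, t


# ---------------------------------------------------------------------------
# ROI summaries


def roi_mean_timecourse(voxel_timecourses: np.ndarray) -> np.ndarray:
    """Arithmetic mean across voxels at each scan (n_scans × n_voxels input)."""
    Y = np.atleast_2d(np.asarray(voxel_timecourses, dtype=float))
    if Y.ndim != 2 or Y.shape[1] < 1 or Y.size == 0:
        raise ValueError("need at least one voxel column")
    return Y.mean(axis=1)


def roi_eigenvariate(voxel_timecourses: np.ndarray) -> np.ndarray:
    """First principal-component timecourse of a voxel set.

    Sign convention: flipped so its correlation with the ROI mean timecourse
    is positive.  Scaled so its standard deviation equals the mean standard
    deviation of the voxel set (comparable amplitude to a single voxel).
    """
    Y = np.atleast_2d(np.asarray(voxel_timecourses, dtype=float))
    if Y.ndim != 2 or Y.shape[1] < 1 or Y.size == 0:
        raise ValueError("need at least one voxel column")
    Yc = Y - Y.mean(axis=0)
    u, s, _ = np.linalg.svd(Yc, full_matrices=False)
    e = u[:, 0]
    m = Yc.mean(axis=1)
    if np.dot(e, m) < 0:
        e = -e
    scale = Yc.std(axis=0).mean()
    sd = e.std()
    if sd > 0:
        e = e / sd * scale
    return e


# ---------------------------------------------------------------------------
# behavioural statistics


def winsorise(values: np.ndarray, threshold_sd: float = 2.5) -> np.ndarray:
    """Single-pass winsorisation at mean ± threshold_sd · SD of the input.

    Outliers are replaced by the boundary value itself; the mean and SD are
    those of the *input* vector (sample SD), so the operation is a single
    pass and is not required to be idempotent.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mu, sd = v.mean(), v.std(ddof=1)
    lo, hi = mu - threshold_sd * sd, mu + threshold_sd * sd
    return np.clip(v, lo, hi)


def rm_anova(table: np.ndarray) -> tuple[float, tuple[int, int], float]:
    """One-way repeated-measures ANOVA on a subjects × conditions table.

    Returns (F, (df1, df2), p) with df1 = k−1 and df2 = (k−1)(n−1); no
    sphericity correction is applied by default (see ``greenhouse_geisser``
    for the corrected variant).
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or np.any(~np.isfinite(X)):
        raise ValueError("need a complete balanced subjects × conditions table")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need >=2 subjects and >=2 conditions")
    grand = X.mean()
    ss_cond = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((X - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else 0.0
    p = float(stats.f.sf(F, df1, df2))
    return float(F), (df1, df2), p


def greenhouse_geisser(table: np.ndarray) -> tuple[float, tuple[float, float], float]:
    """RM-ANOVA with Greenhouse–Geisser corrected degrees of freedom."""
    X = np.asarray(table, dtype=float)
    F, (df1, df2), _ = rm_anova(X)
    # epsilon from the double-centred covariance of conditions
    S = np.cov(X.T, ddof=1)
    k = S.shape[0]
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    eps = np.trace(Sc) ** 2 / ((k - 1) * np.sum(Sc * Sc))
    d1, d2 = df1 * eps, df2 * eps
    p = float(stats.f.sf(F, d1, d2))
    return F, (d1, d2), p


def paired_t(
    a: np.ndarray, b: np.ndarray, tail: str = "two-sided"
) -> tuple[float, float]:
    """Paired t-test; the tail is always explicit, never a silent default.

    ``tail`` is one of ``"two-sided"``, ``"greater"``, ``"less"``.
    """
    if tail not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown tail {tail!r}")
    res = stats.ttest_rel(np.asarray(a, float), np.asarray(b, float), alternative=tail)
    return float(res.statistic), float(res.pvalue)
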