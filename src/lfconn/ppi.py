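"""Psychophysiological interaction (PPI) analysis between region pairs.

A PPI asks whether the coupling between a seed and a target region changes
with a psychological condition.  Because the interaction happens at the
neural level, the seed BOLD timecourse is first deconvolved (ridge-
regularised inversion of the canonical-HRF convolution on a discrete cosine
basis), multiplied with the psychological timecourse at microtime
resolution, and all three terms — physiological, psychological and their
interaction — are re-convolved with the HRF before entering the target GLM
alongside motion nuisance regressors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .hrf import MICROTIME_RES, canonical_hrf, convolve_microtime, event_boxcar, sample_at_scans
from .task_design import DesignMatrix, EventTrain, assemble_design
from .glm import fit_glm

#: default ridge-weight grid for generalised cross-validation
_LAMBDA_GRID = np.logspace(-4, 4, 33)


@dataclass
class PPIModel:
    """The three PPI predictors plus nuisance columns, sampled at TR."""

    physiological: np.ndarray
    psychological: np.ndarray
    interaction: np.ndarray
    TR: float
    ridge_lambda: float | None = None

    def design(self, nuisance: np.ndarray | None = None) -> DesignMatrix:
        return assemble_design(
            {
                "physiological": self.physiological,
                "psychological": self.psychological,
                "ppi": self.interaction,
            },
            nuisance,
            self.TR,
            self.physiological.size,
        )


def deconvolve_bold(
    seed_timecourse: np.ndarray, TR: float, lam: float | None = None
) -> tuple[np.ndarray, float]:
    """Estimate the neural signal underlying a BOLD timecourse.

    Ridge-regularised least squares on a discrete cosine basis: the neural
    estimate is x = D·c with D the DCT basis and c minimising
    ‖y − H·D·c‖² + λ‖c‖², where H is the Toeplitz convolution matrix of the
    canonical HRF at TR resolution.  λ is chosen by generalised
    cross-validation unless given.  Returns (neural estimate, λ used); the
    operation is linear, hence scale-equivariant.
    """
    y = np.asarray(seed_timecourse, dtype=float)
    T = y.size
    h = canonical_hrf(TR)
    if T < h.size:
        raise ValueError("series too short for the deconvolution basis")
    col = np.zeros(T)
    col[: h.size] = h
    H = toeplitz(col, np.zeros(T))
    # orthonormal DCT-II basis
    k = np.arange(T)
    D = np.cos(np.pi * np.outer(2 * k + 1, np.arange(T)) / (2 * T)) * np.sqrt(2.0 / T)
    D[:, 0] /= np.sqrt(2.0)
    M = H @ D
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    uty = U.T @ y
    if lam is None:
        best = (np.inf, _LAMBDA_GRID[0])
        for L in _LAMBDA_GRID:
            shrink = s**2 / (s**2 + L)
            rss = float(np.sum(((1 - shrink) * uty) ** 2))
            edf = float(np.sum(shrink))
            gcv = rss / (T - edf) ** 2
            if gcv < best[0]:
                best = (gcv, L)
        lam = best[1]
    c = Vt.T @ (s / (s**2 + lam) * uty)
    return D @ c, float(lam)


def _upsample(x: np.ndarray, oversample: int) -> np.ndarray:
    """Linear interpolation from scan grid to microtime grid."""
    T = x.size
    t_scan = np.arange(T)
    t_micro = np.arange(T * oversample) / oversample
    return np.interp(t_micro, t_scan, x)


def build_ppi(
    neural_seed: np.ndarray,
    psych_train: EventTrain,
    TR: float,
    oversample: int = MICROTIME_RES,
) -> PPIModel:
    """Form the PPI predictors from a neural seed estimate and a psych train.

    The psychological timecourse is built as a weighted boxcar at microtime,
    mean-centred over the session (so the interaction does not alias the main
    effects), multiplied element-wise with the up-sampled neural seed, and
    all three terms are HRF-convolved and sampled at scan onsets.
    """
    x = np.asarray(neural_seed, dtype=float)
    T = x.size
    dt = TR / oversample
    K = T * oversample
    if len(psych_train) and psych_train.end > T * TR + 1e-9:
        raise ValueError("psychological events extend beyond the session")
    psych_micro = event_boxcar(
        psych_train.onsets, psych_train.durations, psych_train.weights, dt, K
    )
    psych_micro = psych_micro - psych_micro.mean()
    seed_micro = _upsample(x, oversample)
    inter_micro = seed_micro * psych_micro

    def conv(v):
        return sample_at_scans(convolve_microtime(v, dt), oversample, T)

    return PPIModel(
        physiological=conv(seed_micro),
        psychological=conv(psych_micro),
        interaction=conv(inter_micro),
        TR=TR,
    )


def fit_ppi(
    target_timecourse: np.ndarray,
    model: PPIModel,
    nuisance: np.ndarray | None = None,
) -> tuple[float, float]:
    """GLM of the target on physiological + psychological + interaction.

    Returns the interaction (PPI) beta and its t-statistic.  The beta scales
    inversely with any joint rescaling of the psychological weights, so
    weight units must be held fixed across subjects for group tests.
    """
    design = model.design(nuisance)
    fit = fit_glm(np.asarray(target_timecourse, float), design)
    cols = design.columns
    w = np.zeros(len(cols))
    w[cols.index("ppi")] = 1.0
    beta = fit.betas["ppi"]
    var = fit.residual_variance * float(w @ fit.xtx_inv @ w)
    t = beta / np.sqrt(var) if var > 0 else np.nan
    return float(beta), float(t)
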