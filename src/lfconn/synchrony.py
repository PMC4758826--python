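"""Global phase synchrony of region timecourses (Kuramoto order parameter).

Each timecourse is high-pass filtered (60-s cutoff, zero-phase Butterworth),
its instantaneous phase Θ extracted with the Hilbert transform, and the
per-timepoint synchrony summarised as

    R(t) = | (1/N) Σₙ exp(i Θₙ(t)) |

which is 1 when all N phases coincide and 0 when they are evenly dispersed
around the circle.  R(t) is then treated as a dependent variable and the
subject's full first-level model (condition regressors, motion, constant) is
regressed onto it, giving per-condition synchrony effects for group tests.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .glm import GLMFit, fit_glm
from .task_design import DesignMatrix

DEFAULT_CUTOFF_S = 60.0


def highpass(
    timecourse: np.ndarray, TR: float, cutoff_period: float = DEFAULT_CUTOFF_S
) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth high-pass filter, mean removed.

    ``cutoff_period`` is the period (s) above which fluctuations are
    attenuated.  Applied forward-backward (filtfilt) so no lag is introduced.
    Works on a 1-D series or a (n_scans, N) matrix column-wise.
    """
    x = np.asarray(timecourse, dtype=float)
    if cutoff_period <= 2 * TR:
        raise ValueError("cutoff period must exceed 2 TR")
    n = x.shape[0]
    if n < 3 * cutoff_period / TR:
        raise ValueError("series shorter than 3 cycles of the cutoff period")
    fs = 1.0 / TR
    b, a = signal.butter(2, (1.0 / cutoff_period) / (fs / 2.0), btype="highpass")
    y = signal.filtfilt(b, a, x - x.mean(axis=0), axis=0)
    return y - y.mean(axis=0)


def instantaneous_phase(timecourse: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal (Hilbert transform) of a filtered series."""
    x = np.asarray(timecourse, dtype=float)
    if np.allclose(x, 0.0):
        raise ValueError("instantaneous phase undefined for an all-zero series")
    return np.angle(signal.hilbert(x, axis=0))


def phase_matrix(timecourses: np.ndarray, TR: float,
                 cutoff_period: float = DEFAULT_CUTOFF_S) -> np.ndarray:
    """Filter each region independently and return the N × t phase matrix."""
    X = np.atleast_2d(np.asarray(timecourses, dtype=float))
    if X.shape[0] < X.shape[1]:  # expect (n_scans, N)
        raise ValueError("expected timecourses as (n_scans, N) with n_scans > N")
    filt = highpass(X, TR, cutoff_period)
    return instantaneous_phase(filt).T


def kuramoto_order(theta: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """Kuramoto order parameter R(t) from an N × t phase matrix.

    The complex mean phasor is accumulated over timecourses in chunks, so
    arbitrarily large N (e.g. every voxel in a brain) is handled in a single
    pass without ever forming an N × N matrix.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    N, t = theta.shape
    if N < 2:
        raise ValueError("need at least two timecourses")
    acc = np.zeros(t, dtype=complex)
    for i in range(0, N, chunk):
        acc += np.exp(1j * theta[i : i + chunk]).sum(axis=0)
    R = np.abs(acc / N)
    return np.clip(R, 0.0, 1.0)


def synchrony_timecourse(
    timecourses: np.ndarray, TR: float, cutoff_period: float = DEFAULT_CUTOFF_S
) -> np.ndarray:
    """R(t) for a set of region timecourses (filter → phase → order parameter)."""
    return kuramoto_order(phase_matrix(timecourses, TR, cutoff_period))


def edge_mask(n_scans: int, TR: float, cutoff_period: float = DEFAULT_CUTOFF_S) -> np.ndarray:
    """Boolean mask excluding one cutoff period at each end of the session.

    The Hilbert transform and the forward-backward filter both distort the
    series ends; those samples are discarded before regression.
    """
    n_edge = int(np.ceil(cutoff_period / TR))
    mask = np.ones(n_scans, dtype=bool)
    if 2 * n_edge < n_scans:
        mask[:n_edge] = False
        mask[-n_edge:] = False
    return mask


def synchrony_regression(
    R: np.ndarray,
    design: DesignMatrix,
    trim_edges: bool = True,
    cutoff_period: float = DEFAULT_CUTOFF_S,
) -> GLMFit:
    """Regress the first-level model onto the synchrony timecourse R(t).

    The design is the same HRF-convolved model used for the BOLD GLM
    (conditions + motion + constant); per-subject parameter estimates are
    collated for group-level tests of task-related connectivity change.
    """
    R = np.asarray(R, dtype=float)
    if R.size != design.n_scans:
        raise ValueError("R length must match the design")
    if trim_edges:
        mask = edge_mask(R.size, design.TR, cutoff_period)
        sub = DesignMatrix(design.frame.loc[mask].reset_index(drop=True), design.TR)
        return fit_glm(R[mask], sub)
    return fit_glm(R, design)
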