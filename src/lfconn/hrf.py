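"""Canonical haemodynamic response function and event-train convolution.

The canonical HRF is the community-standard double-gamma: a positive gamma
density peaking ~6 s after the event minus a later gamma density (undershoot
peaking ~16 s) scaled by 1/6.  Here it is normalised to unit peak so that a
unit-weight impulse produces a regressor whose maximum is 1; regression
coefficients then carry the units of the data.

Convolution is performed on a microtime grid (default TR/16) before
down-sampling at scan onsets, which keeps sub-TR event timing (1.7-s trials
against a 2-s TR) from aliasing into the regressors.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma

#: default microtime oversampling factor (microtime step = TR / MICROTIME_RES)
MICROTIME_RES = 16

#: HRF kernel length in seconds
HRF_LENGTH = 32.0


def canonical_hrf(dt: float, length: float = HRF_LENGTH) -> np.ndarray:
    """Sample the canonical double-gamma HRF on a grid of step ``dt``.

    Parameters use the standard values: response gamma with shape 6 and
    unit scale (peak at 6 s), undershoot gamma with shape 16 (peak at 16 s),
    undershoot ratio 1/6.  The kernel is normalised to unit peak.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length, dt)
    h = _gamma.pdf(t, a=6.0, scale=1.0) - _gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / h.max()


def event_boxcar(
    onsets: np.ndarray,
    durations: np.ndarray,
    weights: np.ndarray,
    dt: float,
    n_steps: int,
) -> np.ndarray:
    """Weighted boxcar stick function on a microtime grid.

    Events with zero duration are treated as single-bin impulses so that
    brief events (e.g. feedback flashes) still contribute.
    """
    u = np.zeros(n_steps)
    for onset, dur, w in zip(onsets, durations, weights):
        i0 = int(np.round(onset / dt))
        i1 = max(i0 + 1, int(np.round((onset + dur) / dt)))
        if i0 >= n_steps:
            raise ValueError(
                f"event at {onset:.2f}s lies beyond the sampled session"
            )
        u[i0 : min(i1, n_steps)] += w
    return u


def convolve_microtime(u: np.ndarray, dt: float) -> np.ndarray:
    """Convolve a microtime stick function with the canonical HRF.

    The result is scaled by nothing beyond the unit-peak kernel: a single
    microtime impulse of weight 1 yields the HRF samples themselves.
    """
    h = canonical_hrf(dt)
    return np.convolve(u, h)[: u.size]


def sample_at_scans(x_micro: np.ndarray, oversample: int, n_scans: int) -> np.ndarray:
    """Down-sample a microtime series at scan onsets (t = 0, TR, 2TR, ...)."""
    idx = np.arange(n_scans) * oversample
    if idx[-1] >= x_micro.size:
        raise ValueError("microtime series shorter than the scan grid")
    return x_micro[idx]
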