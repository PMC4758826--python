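"""Forward simulation: bilinear neural ODE and balloon haemodynamics.

Both integrators use fixed-step classical RK4 on the microtime grid, with
inputs held constant over each step.  The balloon states (flow, volume,
deoxyhaemoglobin) are integrated in log space, which enforces positivity and
keeps the scheme stable for the parameter excursions that occur during model
inversion.  Kernels are JIT-compiled with numba; inversion calls them tens
of thousands of times.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import DCMModel, HemodynamicParams, stable

#: hard bound on the neural state; beyond this the trajectory is declared
#: divergent (physiological neural states are O(1))
STATE_BOUND = 1e3


@njit(cache=True, error_model="numpy")
def _rk4_neural(A, B, C, U, dt):
    """RK4 integration of dz/dt = (A + Σ uⱼ Bⱼ) z + C u from z(0)=0.

    Returns (z trajectory (K, n), diverged flag).  Inputs are held constant
    over each step; the step Jacobian J = A + Σ uⱼ Bⱼ is rebuilt only when
    u changes between steps.
    """
    K, m = U.shape
    n = A.shape[0]
    z = np.zeros((K, n))
    zk = np.zeros(n)
    J = np.zeros((n, n))
    cu = np.zeros(n)
    k1 = np.zeros(n)
    k2 = np.zeros(n)
    k3 = np.zeros(n)
    k4 = np.zeros(n)
    tmp = np.zeros(n)
    stale = True
    for t in range(K - 1):
        if t > 0:
            for j in range(m):
                if U[t, j] != U[t - 1, j]:
                    stale = True
                    break
        if stale:
            for i in range(n):
                cu[i] = 0.0
                for j in range(n):
                    J[i, j] = A[i, j]
            for jj in range(m):
                uj = U[t, jj]
                if uj != 0.0:
                    for i in range(n):
                        cu[i] += C[i, jj] * uj
                        for j in range(n):
                            J[i, j] += uj * B[jj, i, j]
            stale = False
        k_cu = cu
        for i in range(n):
            acc = k_cu[i]
            for j in range(n):
                acc += J[i, j] * zk[j]
            k1[i] = acc
        for i in range(n):
            tmp[i] = zk[i] + 0.5 * dt * k1[i]
        for i in range(n):
            acc = k_cu[i]
            for j in range(n):
                acc += J[i, j] * tmp[j]
            k2[i] = acc
        for i in range(n):
            tmp[i] = zk[i] + 0.5 * dt * k2[i]
        for i in range(n):
            acc = k_cu[i]
            for j in range(n):
                acc += J[i, j] * tmp[j]
            k3[i] = acc
        for i in range(n):
            tmp[i] = zk[i] + dt * k3[i]
        for i in range(n):
            acc = k_cu[i]
            for j in range(n):
                acc += J[i, j] * tmp[j]
            k4[i] = acc
        mx = 0.0
        for i in range(n):
            zk[i] = zk[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            z[t + 1, i] = zk[i]
            if abs(zk[i]) > mx:
                mx = abs(zk[i])
        if mx > STATE_BOUND:
            return z, True
    return z, False


@njit(cache=True, error_model="numpy", fastmath=True)
def _balloon_deriv(zt, s, lf, lv, lq, kappa, gamma, taui, ia, log1mrho, rho):
    """Time derivatives of (s, log f, log v, log q) at one balloon state.

    Working in log states keeps flow/volume/deoxyHb positive; the outflow
    v^(1/alpha) and extraction 1-(1-rho)^(1/f) are computed via exp to avoid
    generic pow.  States are clamped to a physiological envelope so that the
    derivatives stay finite for the parameter excursions a line search may
    probe; divergence is handled upstream by the neural state bound.
    """
    if s > 1e3:
        s = 1e3
    elif s < -1e3:
        s = -1e3
    if lf > 8.0:
        lf = 8.0
    elif lf < -8.0:
        lf = -8.0
    if lv > 8.0:
        lv = 8.0
    elif lv < -8.0:
        lv = -8.0
    if lq > 8.0:
        lq = 8.0
    elif lq < -8.0:
        lq = -8.0
    f = np.exp(lf)
    inv_f = 1.0 / f
    emlv = np.exp(-lv)
    via = np.exp(ia * lv)
    ds = zt - kappa * s - gamma * (f - 1.0)
    dlf = s * inv_f
    dlv = (f - via) * emlv / taui
    E = 1.0 - np.exp(log1mrho * inv_f)
    dlq = (f * E / rho * np.exp(-lq) - via * emlv) / taui
    return ds, dlf, dlv, dlq


#: largest balloon integration step (s); the v^(1/alpha) outflow term makes
#: the volume equation stiff, so coarser neural grids are sub-stepped
BALLOON_DT_MAX = 0.25


@njit(cache=True, error_model="numpy", fastmath=True)
def _balloon(z, dt, kappa, gamma, tau, alpha, rho, V0):
    """Balloon/windkessel haemodynamics driven by neural states z (K, n).

    ``tau`` is per-region transit time; other parameters are shared.
    The neural input is held constant within a grid interval while the
    balloon states take RK4 substeps of at most BALLOON_DT_MAX.
    Returns percent-signal-change BOLD (K, n).
    """
    K, n = z.shape
    bold = np.zeros((K, n))
    ia = 1.0 / alpha
    log1mrho = np.log(1.0 - rho)
    k1c = 7.0 * rho
    k2c = 2.0
    k3c = 2.0 * rho - 0.2
    nsub = int(np.ceil(dt / BALLOON_DT_MAX - 1e-12))
    if nsub < 1:
        nsub = 1
    h = dt / nsub
    for i in range(n):
        s = 0.0
        lf = 0.0
        lv = 0.0
        lq = 0.0
        taui = tau[i]
        for t in range(K - 1):
            zt = z[t, i]
            for _ in range(nsub):
                a1, b1, c1, d1 = _balloon_deriv(
                    zt, s, lf, lv, lq, kappa, gamma, taui, ia, log1mrho, rho
                )
                a2, b2, c2, d2 = _balloon_deriv(
                    zt, s + 0.5 * h * a1, lf + 0.5 * h * b1,
                    lv + 0.5 * h * c1, lq + 0.5 * h * d1,
                    kappa, gamma, taui, ia, log1mrho, rho,
                )
                a3, b3, c3, d3 = _balloon_deriv(
                    zt, s + 0.5 * h * a2, lf + 0.5 * h * b2,
                    lv + 0.5 * h * c2, lq + 0.5 * h * d2,
                    kappa, gamma, taui, ia, log1mrho, rho,
                )
                a4, b4, c4, d4 = _balloon_deriv(
                    zt, s + h * a3, lf + h * b3, lv + h * c3, lq + h * d3,
                    kappa, gamma, taui, ia, log1mrho, rho,
                )
                s += h / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
                lf += h / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
                lv += h / 6.0 * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
                lq += h / 6.0 * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
            v = np.exp(lv)
            q = np.exp(lq)
            bold[t + 1, i] = 100.0 * V0 * (
                k1c * (1.0 - q) + k2c * (1.0 - q / v) + k3c * (1.0 - v)
            )
    return bold


class DivergentModelError(RuntimeError):
    """Raised when the neural trajectory of a model diverges."""


def integrate_neural(model: DCMModel, U: np.ndarray, dt: float,
                     check_stability: bool = True) -> np.ndarray:
    """Neural trajectory z(t) on the microtime grid for a valued model.

    Raises :class:`DivergentModelError` if A has an eigenvalue with positive
    real part (when ``check_stability``) or if the state exceeds the bound
    during integration.
    """
    if check_stability and not stable(model.A):
        raise DivergentModelError(
            f"model {model.name!r}: A has an eigenvalue with positive real part"
        )
    z, diverged = _rk4_neural(model.A, model.B, model.C, np.ascontiguousarray(U), dt)
    if diverged:
        raise DivergentModelError(f"model {model.name!r}: neural state diverged")
    return z


def hemodynamic_forward(
    z: np.ndarray,
    dt: float,
    oversample: int,
    n_scans: int,
    hparams: HemodynamicParams = HemodynamicParams(),
    tau: np.ndarray | None = None,
) -> np.ndarray:
    """BOLD (percent signal change) sampled at scan onsets, per region.

    ``tau`` optionally overrides the transit time per region.
    """
    if min(hparams.kappa, hparams.gamma, hparams.tau, hparams.alpha,
           hparams.rho, hparams.V0) <= 0:
        raise ValueError("haemodynamic parameters must be positive")
    n = z.shape[1]
    tau_vec = np.full(n, hparams.tau) if tau is None else np.asarray(tau, float)
    if np.any(tau_vec <= 0):
        raise ValueError("transit times must be positive")
    bold = _balloon(
        np.ascontiguousarray(z), dt, hparams.kappa, hparams.gamma,
        tau_vec, hparams.alpha, hparams.rho, hparams.V0,
    )
    idx = np.arange(n_scans) * oversample
    if idx[-1] >= bold.shape[0]:
        raise ValueError("trajectory shorter than the scan grid")
    return bold[idx]


def simulate_bold(
    model: DCMModel,
    U: np.ndarray,
    TR: float,
    n_scans: int,
    oversample: int = 16,
    hparams: HemodynamicParams = HemodynamicParams(),
    tau: np.ndarray | None = None,
) -> np.ndarray:
    """Noiseless BOLD prediction (n_scans × n_nodes) for a valued model."""
    dt = TR / oversample
    z = integrate_neural(model, U, dt)
    return hemodynamic_forward(z, dt, oversample, n_scans, hparams, tau)
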