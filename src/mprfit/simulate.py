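"""Voltage-clamp simulation of the PD neuron model.

With the membrane voltage prescribed, only the three gating variables
(m_H, m_Ca, h_Ca) evolve:

    dx/dt = (x_inf(V(t)) - x) / tau_x(V(t))

integrated with Heun's explicit trapezoidal (predictor-corrector) scheme at
a fixed step, the standard reading of the "modified Euler" method.  The
clamp current is decomposed sample-by-sample into

    I_clamp = I_Cm + I_L + I_Ca + I_H

with I_Cm = C_m dV/dt taken from the analytic derivative of the command when
available.  Steps where a time constant falls below the integration step are
relaxed directly to steady state (the gate is then effectively
instantaneous); gates are clipped to [0, 1] as a numerical safety net.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import FixedConstants, ModelParams

__all__ = [
    "VoltageClampTrace",
    "gate_steady_state",
    "tau_mH_of_V",
    "simulate_clamp",
    "sine_probe",
]


@dataclass
class VoltageClampTrace:
    """Paired time/voltage/current series from one simulated clamp run.

    Arrays share a uniform time grid (ms); currents are in nA and satisfy
    I_total = I_Cm + I_L + I_Ca + I_H at every sample.  Gating trajectories
    are kept for diagnostics.  ``steady`` optionally marks the final
    (steady-state) cycle of a constant-frequency probe.
    """

    t: np.ndarray
    V: np.ndarray
    I_total: np.ndarray
    I_L: np.ndarray
    I_Cm: np.ndarray
    I_Ca: np.ndarray
    I_H: np.ndarray
    m_H: np.ndarray
    m_Ca: np.ndarray
    h_Ca: np.ndarray
    dt: float
    steady: slice | None = None

    def to_frame(self):
        """Trace as a DataFrame with the standard column names."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t_ms": self.t,
                "V_mV": self.V,
                "I_total_nA": self.I_total,
                "I_L_nA": self.I_L,
                "I_Cm_nA": self.I_Cm,
                "I_Ca_nA": self.I_Ca,
                "I_H_nA": self.I_H,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def gate_steady_state(V, V_half, k):
    """Sigmoid steady state 1 / (1 + exp((V - V_half)/k)).

    Increasing in V for k < 0 (activation), decreasing for k > 0
    (inactivation).  ``k = 0`` is rejected.
    """
    if k == 0:
        raise ValueError("slope factor k must be nonzero")
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + np.exp((V - V_half) / k))
    return float(out) if out.ndim == 0 else out


def tau_mH_of_V(V, tau_mH_max, consts: FixedConstants | None = None):
    """Voltage-dependent I_H activation time constant (ms).

    tau_mH(V) = tau_mH_max / (1 + exp((V + shift)/slope)); rises toward
    ``tau_mH_max`` with depolarization.
    """
    if tau_mH_max < 0:
        raise ValueError("tau_mH_max must be non-negative")
    c = consts or FixedConstants()
    V = np.asarray(V, dtype=float)
    out = tau_mH_max / (1.0 + np.exp((V + c.tauH_shift) / c.tauH_slope))
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _clamp_kernel(
    V,
    dVdt,
    dt,
    g_L,
    g_H,
    g_Ca,
    tau_mH_max,
    Vh_mCa,
    tau_mCa,
    Vh_hCa,
    tau_hCa,
    C_m,
    k_mCa,
    k_hCa,
    k_mH,
    Vh_mH,
    t_shift,
    t_slope,
    E_L,
    E_Ca,
    E_H,
    p_Ca,
    q_Ca,
    p_H,
    store,
):  # pragma: no cover - exercised through simulate_clamp
    n = V.shape[0]
    I_total = np.empty(n)
    m = n if store else 1
    I_L = np.empty(m)
    I_Cm = np.empty(m)
    I_Ca = np.empty(m)
    I_H = np.empty(m)
    mH_arr = np.empty(m)
    mCa_arr = np.empty(m)
    hCa_arr = np.empty(m)

    # steady-state initial conditions at the first command voltage
    v = V[0]
    mH = 1.0 / (1.0 + np.exp((v - Vh_mH) / k_mH))
    mCa = 1.0 / (1.0 + np.exp((v - Vh_mCa) / k_mCa))
    hCa = 1.0 / (1.0 + np.exp((v - Vh_hCa) / k_hCa))

    inf_mH0 = mH
    inf_mCa0 = mCa
    inf_hCa0 = hCa
    tau_mH0 = tau_mH_max / (1.0 + np.exp((v + t_shift) / t_slope))

    for i in range(n):
        v = V[i]
        iL = g_L * (v - E_L)
        iCm = C_m * dVdt[i]
        iCa = g_Ca * mCa**p_Ca * hCa**q_Ca * (v - E_Ca)
        iH = g_H * mH**p_H * (v - E_H)
        I_total[i] = iL + iCm + iCa + iH
        if store:
            I_L[i] = iL
            I_Cm[i] = iCm
            I_Ca[i] = iCa
            I_H[i] = iH
            mH_arr[i] = mH
            mCa_arr[i] = mCa
            hCa_arr[i] = hCa

        if i == n - 1:
            break

        v1 = V[i + 1]
        inf_mH1 = 1.0 / (1.0 + np.exp((v1 - Vh_mH) / k_mH))
        inf_mCa1 = 1.0 / (1.0 + np.exp((v1 - Vh_mCa) / k_mCa))
        inf_hCa1 = 1.0 / (1.0 + np.exp((v1 - Vh_hCa) / k_hCa))
        tau_mH1 = tau_mH_max / (1.0 + np.exp((v1 + t_shift) / t_slope))

        # Heun step per gate; fast gates (tau < dt) snap to steady state
        if tau_mH0 < dt or tau_mH1 < dt:
            mH = inf_mH1
        else:
            k1 = (inf_mH0 - mH) / tau_mH0
            k2 = (inf_mH1 - (mH + dt * k1)) / tau_mH1
            mH = mH + 0.5 * dt * (k1 + k2)
            if mH < 0.0:
                mH = 0.0
            elif mH > 1.0:
                mH = 1.0

        if tau_mCa < dt:
            mCa = inf_mCa1
        else:
            k1 = (inf_mCa0 - mCa) / tau_mCa
            k2 = (inf_mCa1 - (mCa + dt * k1)) / tau_mCa
            mCa = mCa + 0.5 * dt * (k1 + k2)
            if mCa < 0.0:
                mCa = 0.0
            elif mCa > 1.0:
                mCa = 1.0

        if tau_hCa < dt:
            hCa = inf_hCa1
        else:
            k1 = (inf_hCa0 - hCa) / tau_hCa
            k2 = (inf_hCa1 - (hCa + dt * k1)) / tau_hCa
            hCa = hCa + 0.5 * dt * (k1 + k2)
            if hCa < 0.0:
                hCa = 0.0
            elif hCa > 1.0:
                hCa = 1.0

        inf_mH0, inf_mCa0, inf_hCa0, tau_mH0 = inf_mH1, inf_mCa1, inf_hCa1, tau_mH1

    return I_total, I_L, I_Cm, I_Ca, I_H, mH_arr, mCa_arr, hCa_arr


def _kernel_args(p: ModelParams, c: FixedConstants):
    return (
        p.g_L,
        p.g_H,
        p.g_Ca,
        p.tau_mH_max,
        p.V_half_mCa,
        p.tau_mCa,
        p.V_half_hCa,
        p.tau_hCa,
        c.C_m,
        c.k_mCa,
        c.k_hCa,
        c.k_mH,
        c.V_half_mH,
        c.tauH_shift,
        c.tauH_slope,
        c.E_L,
        c.E_Ca,
        c.E_H,
        c.p_Ca,
        c.q_Ca,
        c.p_H,
    )


def total_current(params: ModelParams, consts: FixedConstants, V, dVdt, dt: float) -> np.ndarray:
    """Lean path: only the total clamp current (used by the optimizer)."""
    out = _clamp_kernel(
        np.ascontiguousarray(V, dtype=float),
        np.ascontiguousarray(dVdt, dtype=float),
        float(dt),
        *_kernel_args(params, consts),
        False,
    )
    return out[0]


def simulate_clamp(
    params: ModelParams,
    consts: FixedConstants,
    t,
    V,
    dt: float | None = None,
    dVdt=None,
) -> VoltageClampTrace:
    """Integrate the gating ODEs under a prescribed voltage command.

    ``t`` (ms) must be a uniform grid; ``dVdt`` (mV/ms) is used for the
    capacitive current when supplied (analytic command derivative), else a
    second-order finite difference of ``V`` is taken.  Gating starts at
    steady state for ``V[0]``.
    """
    t = np.asarray(t, dtype=float)
    V = np.ascontiguousarray(V, dtype=float)
    if t.shape != V.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("t and V must be 1-d arrays of equal length >= 2")
    steps = np.diff(t)
    if dt is None:
        dt = float(steps[0])
    if not np.allclose(steps, dt, rtol=1e-9, atol=1e-9 * dt):
        raise ValueError("time grid must be uniform")
    if not np.isfinite(V).all():
        raise ValueError("command voltage must be finite")

    if dVdt is None:
        dVdt = np.gradient(V, dt)
    dVdt = np.ascontiguousarray(dVdt, dtype=float)

    tau_min = min(
        params.tau_mCa,
        params.tau_hCa,
        float(np.min(tau_mH_of_V(V, params.tau_mH_max, consts))) if params.tau_mH_max > 0 else np.inf,
    )
    if dt > tau_min / 2.0:
        warnings.warn(
            f"integration step dt={dt} ms exceeds half the smallest time constant "
            f"({tau_min:.3g} ms); fast gates are relaxed to steady state",
            RuntimeWarning,
            stacklevel=2,
        )

    I_total, I_L, I_Cm, I_Ca, I_H, mH, mCa, hCa = _clamp_kernel(
        V, dVdt, float(dt), *_kernel_args(params, consts), True
    )
    return VoltageClampTrace(
        t=t, V=V, I_total=I_total, I_L=I_L, I_Cm=I_Cm, I_Ca=I_Ca, I_H=I_H,
        m_H=mH, m_Ca=mCa, h_Ca=hCa, dt=float(dt),
    )


def sine_probe(
    params: ModelParams,
    consts: FixedConstants,
    f: float,
    v0: float = -45.0,
    v1: float = 15.0,
    n_cycles: int = 4,
    dt: float = 0.2,
) -> VoltageClampTrace:
    """Constant-frequency sinusoidal clamp; the last full trough-to-trough
    cycle is flagged as the steady-state cycle (earlier cycles absorb the
    transient).

    Used for current-versus-cycle-phase diagrams: within the flagged cycle,
    cycle phase = (t - t_start) * f, so the voltage trough sits at phase 0
    and the voltage peak at phase 0.5.
    """
    if f <= 0:
        raise ValueError("probe frequency must be positive")
    if n_cycles < 2:
        raise ValueError("need n_cycles >= 2 (first cycles are transient)")
    period_ms = 1000.0 / f
    n = int(round(n_cycles * period_ms / dt)) + 1
    t = np.arange(n, dtype=float) * dt
    w = 2.0 * np.pi * f / 1000.0  # rad/ms
    V = v0 + v1 * np.sin(w * t)
    dVdt = v1 * w * np.cos(w * t)
    trace = simulate_clamp(params, consts, t, V, dt=dt, dVdt=dVdt)
    # troughs of v0 + v1 sin at t = (k + 3/4) * period
    start = int(round((n_cycles - 1.25) * period_ms / dt))
    stop = int(round((n_cycles - 0.25) * period_ms / dt)) + 1
    trace.steady = slice(start, stop)
    return trace
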