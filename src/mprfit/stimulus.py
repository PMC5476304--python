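"""Voltage-clamp command waveforms: logarithmic ZAP sweeps and sine probes.

The impedance probe is a logarithmic chirp ("ZAP") holding the cell between
``v0 - v1`` and ``v0 + v1`` while the instantaneous frequency sweeps from
``f_lo`` to ``f_hi`` over ``T`` seconds.  The phase argument (in cycles) is

    F(t) = f_lo * t * (f_hi / f_lo) ** (t / T),   t in seconds,

implemented exactly in this printed form; downstream analysis labels each
cycle by its measured period rather than by F'(t), so the fact that the
literal F exceeds ``f_hi`` near ``t = T`` only produces trailing fast cycles
that the profile builder truncates.  The sweep is preceded by
``n_precycles`` sine cycles at ``f_lo`` that join the chirp with continuous
value and derivative; they serve as an equilibration period.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ZapConfig", "zap_voltage", "zap_derivative", "shifted_range_config"]


@dataclass(frozen=True)
class ZapConfig:
    """Configuration of one ZAP voltage-clamp sweep.

    v0/v1 in mV (offset and half-amplitude), frequencies in Hz, T in s,
    dt in ms.
    """

    v0: float = -45.0
    v1: float = 15.0
    f_lo: float = 0.1
    f_hi: float = 4.0
    T: float = 100.0
    n_precycles: int = 3
    dt: float = 0.2

    def __post_init__(self):
        if not (self.f_hi > self.f_lo > 0):
            raise ValueError("need f_hi > f_lo > 0")
        if self.T <= 0 or self.dt <= 0:
            raise ValueError("T and dt must be positive")
        if self.v1 <= 0:
            raise ValueError("half-amplitude v1 must be positive")
        if self.n_precycles < 0:
            raise ValueError("n_precycles must be >= 0")

    @property
    def pre_duration_s(self) -> float:
        return self.n_precycles / self.f_lo

    @property
    def total_duration_s(self) -> float:
        return self.pre_duration_s + self.T

    @property
    def n_samples(self) -> int:
        # inclusive endpoint
        return int(round(self.total_duration_s * 1000.0 / self.dt)) + 1

    @property
    def v_low(self) -> float:
        return self.v0 - self.v1

    @property
    def v_high(self) -> float:
        return self.v0 + self.v1

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples, dtype=float) * self.dt

    def replace(self, **kwargs) -> "ZapConfig":
        return replace(self, **kwargs)


def _phase_cycles(cfg: ZapConfig, t_s: np.ndarray):
    """Phase argument in cycles and its rate (Hz) at each sample."""
    pre = cfg.pre_duration_s
    r = cfg.f_hi / cfg.f_lo
    logr = np.log(r)
    tau = np.maximum(t_s - pre, 0.0)
    growth = r ** (tau / cfg.T)
    in_pre = t_s < pre
    phase = np.where(in_pre, cfg.f_lo * t_s, cfg.f_lo * pre + cfg.f_lo * tau * growth)
    rate = np.where(in_pre, cfg.f_lo, cfg.f_lo * growth * (1.0 + tau * logr / cfg.T))
    return phase, rate


def zap_voltage(cfg: ZapConfig):
    """Return ``(t_ms, V_mV)`` for the full pre-cycle + ZAP command."""
    t_ms = cfg.time_ms()
    phase, _ = _phase_cycles(cfg, t_ms / 1000.0)
    V = cfg.v0 + cfg.v1 * np.sin(2.0 * np.pi * phase)
    return t_ms, V


def zap_derivative(cfg: ZapConfig):
    """Return ``(t_ms, dV/dt)`` in mV/ms, analytically.

    Used for the capacitive current so that phase estimates are free of
    finite-difference noise.
    """
    t_ms = cfg.time_ms()
    phase, rate = _phase_cycles(cfg, t_ms / 1000.0)
    # rate is in Hz (cycles/s); convert to mV/ms
    dVdt = cfg.v1 * 2.0 * np.pi * rate * np.cos(2.0 * np.pi * phase) / 1000.0
    return t_ms, dVdt


def shifted_range_config(base: ZapConfig, v_low: float, v_high: float) -> ZapConfig:
    """Retarget the clamp range to [v_low, v_high] mV, keeping the sweep."""
    if not v_high > v_low:
        raise ValueError("need v_high > v_low")
    return base.replace(v0=0.5 * (v_low + v_high), v1=0.5 * (v_high - v_low))
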