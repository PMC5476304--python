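"""Matplotlib views of profiles, populations and current-phase diagrams."""

from __future__ import annotations

import numpy as np

from .impedance import AttributeSet, ImpedanceProfile
from .simulate import VoltageClampTrace

__all__ = ["plot_profile", "plot_current_phase", "plot_population_profiles"]


def plot_profile(profile: ImpedanceProfile, target: AttributeSet | None = None, axes=None):
    """Z(f) and phi(f) panels, optionally with the target points overlaid."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    ax_z, ax_p = axes
    ax_z.plot(profile.f, profile.Z, "o-", ms=3, lw=1, label="model")
    ax_p.plot(profile.f, profile.phi, "o-", ms=3, lw=1)
    if target is not None:
        t = target
        ax_z.plot(
            [t.f0, t.f_res, t.f_half_lo, t.f_half_hi, t.f1],
            [t.Z0, t.Z_max, t.Z_half_lo, t.Z_half_hi, t.Z_f1],
            "ro", label="target",
        )
        ax_p.plot(
            [t.f0, t.f_phimax, t.f_phi0, 2.0, t.f_phimin],
            [t.phi_f0, t.phi_max, 0.0, t.phi_f2, t.phi_min],
            "ro",
        )
    ax_p.axhline(0.0, color="grey", lw=0.5)
    ax_z.set_ylabel("|Z| (MOhm)")
    ax_p.set_ylabel("phase (rad)")
    ax_p.set_xlabel("f (Hz)")
    ax_z.set_xscale("log")
    ax_z.legend(loc="best", frameon=False)
    return axes


def plot_current_phase(trace: VoltageClampTrace, f: float, ax=None):
    """Steady-state currents of a sine probe against cycle phase.

    The voltage trough sits at phase 0 and its peak at 0.5; the passive leak
    peaks exactly at 0.5, a capacitive current a quarter cycle earlier.
    """
    import matplotlib.pyplot as plt

    if trace.steady is None:
        raise ValueError("trace has no steady-state cycle flagged (use sine_probe)")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sl = trace.steady
    t = trace.t[sl]
    phase = (t - t[0]) * f / 1000.0
    for name, y in (("I_total", trace.I_total), ("I_L", trace.I_L),
                    ("I_Ca", trace.I_Ca), ("I_H", trace.I_H), ("I_Cm", trace.I_Cm)):
        ax.plot(phase, y[sl], label=name)
    ax.axvline(0.5, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("cycle phase")
    ax.set_ylabel("current (nA)")
    ax.set_title(f"f = {f:g} Hz")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_population_profiles(profiles, target: AttributeSet | None = None, axes=None, max_n: int = 100):
    """Overlay many model profiles (thin lines) against the target points."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    ax_z, ax_p = axes
    for p in profiles[:max_n]:
        ax_z.plot(p.f, p.Z, color="steelblue", alpha=0.2, lw=0.8)
        ax_p.plot(p.f, p.phi, color="steelblue", alpha=0.2, lw=0.8)
    if target is not None:
        plot_profile(profiles[0], target=target, axes=axes) if profiles else None
    ax_z.set_xscale("log")
    return axes
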