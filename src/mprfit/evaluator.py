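"""Fast simulate -> profile -> attributes -> objectives pipeline.

The optimizer evaluates thousands of candidate parameter sets against the
same ZAP command, so everything that depends only on the command (the
waveform, its analytic derivative, the cycle boundaries, the per-cycle
voltage amplitudes and peak times) is computed once and reused; each
candidate then only pays for the gating integration and the current-side
cycle statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import impedance as imp
from .impedance import AttributeSet, ImpedanceProfile, attribute_errors, objective_vector
from .params import FixedConstants, ModelParams
from .simulate import total_current
from .stimulus import ZapConfig, zap_derivative, zap_voltage

__all__ = ["AttributeEvaluator", "FAILURE_PENALTY"]

#: Objective value assigned to candidates whose simulation fails (NaN/Inf
#: currents or degenerate cycles); large but finite so the individual still
#: flows through the sorting machinery.
FAILURE_PENALTY = 1e6

#: Attribute columns carried alongside the objectives in population tables.
ATTR_COLUMNS = (
    "Z0",
    "f_res",
    "Z_max",
    "Q_Z",
    "Lambda_half",
    "Z_f1",
    "f_half_lo",
    "Z_half_lo",
    "f_half_hi",
    "Z_half_hi",
    "f_cross_lo",
    "f_cross_hi",
    "phi_f0",
    "f_phimax",
    "phi_max",
    "f_phi0",
    "phi_f2",
    "f_phimin",
    "phi_min",
    "has_resonance",
    "has_phasonance",
)


class AttributeEvaluator:
    """Evaluate candidate parameter vectors against a target attribute set.

    Parameters
    ----------
    target : AttributeSet
        The attribute points the objectives measure distance to.
    consts : FixedConstants
        Fixed model constants (variant midpoints, reversal potentials...).
    zap : ZapConfig
        The voltage-clamp command; its dt is the integration step.
    """

    def __init__(
        self,
        target: AttributeSet,
        consts: FixedConstants | None = None,
        zap: ZapConfig | None = None,
    ):
        self.target = target
        self.consts = consts or FixedConstants()
        self.zap = zap or ZapConfig()

        t, V = zap_voltage(self.zap)
        _, dVdt = zap_derivative(self.zap)
        self.t = t
        self.V = np.ascontiguousarray(V)
        self.dVdt = np.ascontiguousarray(dVdt)

        class _Cmd:  # minimal trace-like view for segmentation
            pass

        cmd = _Cmd()
        cmd.t, cmd.V = t, self.V
        pairs = imp.segment_cycles(cmd, exclude_before_ms=imp.profile_exclusion_ms(self.zap))
        starts = np.array([p[0] for p in pairs], dtype=np.int64)
        ends = np.array([p[1] for p in pairs], dtype=np.int64)
        freqs = 1000.0 / (t[ends] - t[starts])
        order = np.argsort(freqs)
        keep = freqs[order] <= self.zap.f_hi * 1.15
        self.starts = starts[order][keep]
        self.ends = ends[order][keep]
        self.freqs = freqs[order][keep]
        vmin, vmax, tV = imp._cycle_stats(self.V, t, self.starts, self.ends)
        self.v_pp = vmax - vmin
        self.t_peakV = tV

    # -- single candidate ---------------------------------------------------

    def profile_of(self, x: np.ndarray) -> ImpedanceProfile:
        """Impedance profile of one parameter vector (no objective scoring)."""
        params = ModelParams.from_array(x)
        I = total_current(params, self.consts, self.V, self.dVdt, self.zap.dt)
        if not np.isfinite(I).all():
            raise FloatingPointError("simulation produced non-finite currents")
        imin, imax, tI = imp._cycle_stats(I, self.t, self.starts, self.ends)
        dI = imax - imin
        if (dI <= 0).any():
            raise FloatingPointError("degenerate current cycle")
        Z = self.v_pp / dI
        phi = imp._wrap_phase(2.0 * np.pi * self.freqs * (tI - self.t_peakV) / 1000.0)
        return ImpedanceProfile(self.freqs, Z, np.atleast_1d(phi), config=self.zap)

    def attributes_of(self, x: np.ndarray) -> AttributeSet:
        pins = (self.target.f_half_lo, self.target.f_half_hi)
        return imp.extract_attributes(
            self.profile_of(x), f0=self.target.f0, f1=min(self.target.f1, self.zap.f_hi),
            half_pins=pins,
        )

    def evaluate_one(self, x: np.ndarray) -> tuple[np.ndarray, AttributeSet | None]:
        """(10 objectives, attributes); failures get the penalty objectives."""
        try:
            attrs = self.attributes_of(x)
        except (FloatingPointError, ValueError):
            return np.full(10, FAILURE_PENALTY), None
        return objective_vector(attrs, self.target), attrs

    # -- batches ------------------------------------------------------------

    def evaluate(self, X: np.ndarray) -> tuple[np.ndarray, list[AttributeSet | None]]:
        """Evaluate an (n, 8) array of parameter vectors."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        F = np.empty((X.shape[0], 10))
        attrs: list[AttributeSet | None] = []
        for i, x in enumerate(X):
            F[i], a = self.evaluate_one(x)
            attrs.append(a)
        return F, attrs

    def errors_of(self, x: np.ndarray) -> dict[str, float]:
        return attribute_errors(self.attributes_of(x), self.target)


def attrs_to_row(a: AttributeSet | None) -> dict:
    """Flatten an AttributeSet (or a failure) into population-table columns."""
    if a is None:
        row = {k: np.nan for k in ATTR_COLUMNS}
        row["has_resonance"] = False
        row["has_phasonance"] = False
        return row
    d = a.to_dict()
    return {k: d[k] for k in ATTR_COLUMNS}
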