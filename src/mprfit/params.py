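"""Free parameters, fixed constants and search bounds for the PD neuron model.

The model is a single-compartment voltage-clamp description of the crab
pyloric dilator (PD) neuron with a passive leak, a hyperpolarization-activated
inward current (I_H, one activation gate) and a low-threshold calcium current
(I_Ca, cubed activation times one inactivation gate).  Eight parameters are
free and searched by the optimizer; everything else (slopes, exponents,
capacitance, reversal potentials) is held fixed.

Unit system: mV / ms / uS / nF, so that conductance x voltage and
capacitance x dV/dt both come out in nA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "ModelParams",
    "FixedConstants",
    "ParameterBounds",
    "DEFAULT_BOUNDS",
    "MEDIAN_PARAMS",
]

#: Canonical ordering of the eight free parameters.
PARAM_NAMES = (
    "g_L",
    "g_H",
    "g_Ca",
    "tau_mH_max",
    "V_half_mCa",
    "tau_mCa",
    "V_half_hCa",
    "tau_hCa",
)


@dataclass(frozen=True)
class ModelParams:
    """The eight free parameters of one candidate PD model.

    Conductances in uS, voltages in mV, time constants in ms.
    """

    g_L: float
    g_H: float
    g_Ca: float
    tau_mH_max: float
    V_half_mCa: float
    tau_mCa: float
    V_half_hCa: float
    tau_hCa: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "ModelParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got shape {x.shape}")
        return cls(**dict(zip(PARAM_NAMES, map(float, x))))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_dict(json.loads(s))

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def validate(self, bounds: "ParameterBounds | None" = None) -> None:
        """Raise ValueError if any parameter is negative where it must not be,
        or falls outside ``bounds``."""
        for name in ("g_L", "g_H", "g_Ca", "tau_mH_max", "tau_mCa", "tau_hCa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if bounds is not None:
            x = self.to_array()
            bad = (x < bounds.low - 1e-12) | (x > bounds.high + 1e-12)
            if bad.any():
                names = [PARAM_NAMES[i] for i in np.flatnonzero(bad)]
                raise ValueError(f"parameters outside bounds: {names}")


@dataclass(frozen=True)
class FixedConstants:
    """Quantities held fixed during fitting.

    In the sigmoid convention x_inf = 1/(1 + exp((V - V_half)/k)), a negative
    slope k gives a gate that opens with depolarization and a positive slope
    one that opens with hyperpolarization.  Calcium activation (k_mCa = -8)
    opens with depolarization and calcium inactivation (k_hCa = +6) closes
    with it.  The H-current gate is hyperpolarization-activated (k_mH = +7):
    it carries inward current at the bottom of the oscillation range and
    slowly deactivates on depolarization, which is what lets it shape the
    lower envelope of the clamp current.  The I_H midpoint ``V_half_mH``
    defaults to the crab measurement (-70 mV); -96 mV reproduces the lobster
    variant (which simply rescales the fitted g_H upward ~10x).
    ``tauH_shift``/``tauH_slope`` parameterize the voltage dependence of the
    I_H activation time constant, tau_mH(V) = tau_mH_max / (1 + exp((V +
    shift)/slope)).

    Reversal potentials are not experimentally pinned for this preparation;
    the defaults are typical crustacean stomatogastric values (E_L = -60,
    E_Ca = +120, E_H = -20 mV).  Fitted maximal conductances trade off
    against the chosen driving forces, so they are comparable across
    studies only up to that scaling.
    """

    C_m: float = 1.0            # nF
    k_mCa: float = -8.0         # mV
    k_hCa: float = 6.0          # mV
    k_mH: float = 7.0           # mV (positive: hyperpolarization-activated)
    V_half_mH: float = -70.0    # mV (-96 for the lobster variant)
    p_Ca: int = 3
    q_Ca: int = 1
    p_H: int = 1
    q_H: int = 0
    tauH_shift: float = 110.0   # mV
    tauH_slope: float = -13.0   # mV
    E_L: float = -60.0          # mV
    E_Ca: float = 120.0         # mV
    E_H: float = -20.0          # mV

    def __post_init__(self):
        if self.k_mCa >= 0:
            raise ValueError("calcium activation slope must be negative")
        if self.k_hCa <= 0:
            raise ValueError("calcium inactivation slope must be positive")
        if self.k_mH == 0:
            raise ValueError("H activation slope must be nonzero")
        for name in ("p_Ca", "q_Ca", "p_H", "q_H"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer")
        if self.q_H != 0:
            raise ValueError("I_H carries no inactivation gate (q_H must be 0)")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")

    def replace(self, **kwargs) -> "FixedConstants":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter [low, high] box used both to sample and to clip."""

    low: np.ndarray
    high: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "low", np.asarray(self.low, dtype=float))
        object.__setattr__(self, "high", np.asarray(self.high, dtype=float))
        if self.low.shape != (len(PARAM_NAMES),) or self.high.shape != (len(PARAM_NAMES),):
            raise ValueError("bounds must have one entry per parameter")
        if (self.high < self.low).any():
            raise ValueError("upper bounds must be >= lower bounds")

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.low, self.high)

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool((x >= self.low - 1e-12).all() and (x <= self.high + 1e-12).all())

    def replace_param(self, name: str, low: float, high: float) -> "ParameterBounds":
        i = PARAM_NAMES.index(name)
        lo, hi = self.low.copy(), self.high.copy()
        lo[i], hi[i] = low, high
        return ParameterBounds(lo, hi)

    @property
    def span(self) -> np.ndarray:
        return self.high - self.low


#: Search box for the eight free parameters (conductances in uS, voltages in
#: mV, time constants in ms), as used to constrain the PD model population.
DEFAULT_BOUNDS = ParameterBounds(
    low=np.array([0.0, 0.0, 0.0, 0.0, -75.0, 0.0, -75.0, 0.0]),
    high=np.array([0.15, 0.35, 0.35, 3000.0, -30.0, 100.0, -30.0, 1000.0]),
)

#: Median parameter values over a large fitted PD population; a convenient
#: representative resonant model for examples and synthetic ground truths.
MEDIAN_PARAMS = ModelParams(
    g_L=0.096,
    g_H=0.164,
    g_Ca=0.172,
    tau_mH_max=2179.0,
    V_half_mCa=-51.0,
    tau_mCa=70.0,
    V_half_hCa=-67.0,
    tau_hCa=458.0,
)
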