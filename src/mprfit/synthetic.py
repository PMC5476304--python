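"""Synthetic ground truths and targets for end-to-end testing.

A synthetic target plays the role of the biological neuron: a known
parameter set ("truth") is simulated through the full ZAP -> profile ->
attributes chain and its attribute set becomes the optimization target,
optionally with multiplicative noise on the Z and phi values (frequencies
are left clean; the fitting targets are attributes, not traces, so noise is
applied where the fit actually reads data).  Because the truth is known,
parameter recovery by the optimizer can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluator import AttributeEvaluator
from .impedance import AttributeSet, reference_target
from .params import DEFAULT_BOUNDS, FixedConstants, ModelParams, PARAM_NAMES, ParameterBounds
from .stimulus import ZapConfig

__all__ = ["SyntheticTarget", "sample_params", "make_target", "sample_resonant_truth", "recovery_report"]

#: Minimal resonance prominence Q_Z / Z_0 for a truth to define a well-posed
#: resonant target.
MIN_Q_RATIO = 0.1

#: Parameters the attribute screen constrains tightly (small population CoV);
#: recovery is judged by whether the truth falls inside the accepted range.
TIGHT_PARAMS = ("g_L", "tau_mCa", "V_half_mCa")

#: Parameters identified only up to correlation manifolds (large CoV).
LOOSE_PARAMS = ("g_Ca", "g_H", "tau_mH_max")


@dataclass(frozen=True)
class SyntheticTarget:
    truth: ModelParams
    target: AttributeSet
    noise_level: float
    seed: int | None


def sample_params(
    rng: np.random.Generator | int | None = None,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
) -> ModelParams:
    """Uniform draw of one parameter set inside the search box."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return ModelParams.from_array(rng.uniform(bounds.low, bounds.high))


_NOISY_FIELDS = (
    "Z0", "Z_max", "Z_f1", "Z_half_lo", "Z_half_hi",
    "phi_f0", "phi_max", "phi_f2", "phi_min",
)


def _repin(attrs):
    """Anchor a truth's attribute set at its own half-height crossings.

    A synthetic target plays the role of the reference neuron, so its
    bandwidth pin frequencies are its own measured half-height crossings
    (where Z equals the level midway between Z_max and Z(f1)); models fitted
    to it are then pinned at those frequencies.
    """
    level = 0.5 * (attrs.Z_max + attrs.Z_f1)
    return attrs.replace(
        f_half_lo=attrs.f_cross_lo,
        f_half_hi=attrs.f_cross_hi,
        Z_half_lo=level,
        Z_half_hi=level,
    )


def make_target(
    truth: ModelParams,
    zap: ZapConfig | None = None,
    consts: FixedConstants | None = None,
    noise_level: float = 0.0,
    rng: np.random.Generator | int | None = None,
    seed: int | None = None,
) -> SyntheticTarget:
    """Measure a truth model's attributes and wrap them as a fitting target.

    Raises when the truth is not usefully resonant (Q_Z / Z0 < 0.1); use
    :func:`sample_resonant_truth` to draw valid truths.  With
    ``noise_level > 0`` each Z/phi value is multiplied by
    ``1 + noise_level * N(0, 1)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ev = AttributeEvaluator(reference_target(), consts=consts, zap=zap or ZapConfig())
    attrs = ev.attributes_of(truth.to_array())
    if not attrs.has_resonance or attrs.Q_Z / attrs.Z0 < MIN_Q_RATIO:
        raise ValueError("truth model is not resonant enough to define a target")
    if not (np.isfinite(attrs.f_cross_lo) and np.isfinite(attrs.f_cross_hi)):
        raise ValueError("truth model has no measurable half-height bandwidth")
    attrs = _repin(attrs)
    if noise_level > 0:
        noisy = {k: getattr(attrs, k) * (1.0 + noise_level * rng.standard_normal()) for k in _NOISY_FIELDS}
        attrs = attrs.replace(**noisy)
    return SyntheticTarget(truth=truth, target=attrs, noise_level=noise_level, seed=seed)


def sample_resonant_truth(
    rng: np.random.Generator | int | None = None,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    zap: ZapConfig | None = None,
    consts: FixedConstants | None = None,
    noise_level: float = 0.0,
    max_tries: int = 500,
) -> SyntheticTarget:
    """Rejection-sample a ground truth with a well-posed resonant profile."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ev = AttributeEvaluator(reference_target(), consts=consts, zap=zap or ZapConfig())
    for _ in range(max_tries):
        truth = sample_params(rng, bounds)
        try:
            attrs = ev.attributes_of(truth.to_array())
        except (FloatingPointError, ValueError):
            continue
        if (
            attrs.has_resonance
            and attrs.has_phasonance
            and attrs.Q_Z / attrs.Z0 >= MIN_Q_RATIO
            and np.isfinite(attrs.f_cross_lo)
            and np.isfinite(attrs.f_cross_hi)
        ):
            target = _repin(attrs)
            if noise_level > 0:
                noisy = {
                    k: getattr(attrs, k) * (1.0 + noise_level * rng.standard_normal())
                    for k in _NOISY_FIELDS
                }
                target = attrs.replace(**noisy)
            return SyntheticTarget(truth=truth, target=target, noise_level=noise_level, seed=None)
    raise RuntimeError(f"no resonant truth found in {max_tries} draws")


def recovery_report(truth: ModelParams, accepted: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter recovery summary for a fitted set against a known truth.

    Reports each parameter's accepted range, whether the truth falls inside
    it, and the accepted set's median-normalized CoV.  The expected pattern:
    tightly constrained parameters (g_L, tau_mCa, V_half_mCa) bracket the
    truth narrowly; the rest are recovered only up to their correlation
    manifolds and show large CoV.
    """
    if accepted.empty:
        raise ValueError("empty accepted set")
    truth.validate(DEFAULT_BOUNDS)
    from .analysis import normalized_cov

    rows = []
    for name in PARAM_NAMES:
        vals = accepted[name].to_numpy(dtype=float)
        tv = getattr(truth, name)
        rows.append(
            {
                "parameter": name,
                "truth": tv,
                "low": float(vals.min()),
                "high": float(vals.max()),
                "contains_truth": bool(vals.min() <= tv <= vals.max()),
                "cov": normalized_cov(vals),
                "n": vals.size,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
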