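"""Local sensitivity of resonance attributes to parameters.

One-dimensional sensitivity is the slope of the (log-scale) relative
attribute change against the relative parameter change.  Multiplicative
parameters (conductances, time constants) are stepped on a log scale,

    p_n = exp(+/- dp_n) * p_0,   dp_n = 0.001 * 1.15 ** n,

and both axes use log changes (x = ln(p/p0), y = ln(a/a0)), so a power law
p -> c p^k has sensitivity exactly k at every step size and a sensitivity
of 1 means a 2-fold parameter change produces a 2-fold attribute change.
Additive parameters (voltage midpoints) are stepped by +/- 0.5 mV
increments with x the raw change in mV.  Symmetric point pairs are added
until the linear fit's R^2 drops below 0.98; the slope of the retained fit
is the sensitivity.

Two-dimensional sensitivity co-varies a correlated parameter pair along a
line parallel or perpendicular to the pair's population correlation line.
Perpendicularity is taken in median-normalized space (each multiplicative
parameter divided by the group median; additive voltage parameters kept in
raw mV), since raw parameter units make "perpendicular" meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .params import DEFAULT_BOUNDS, PARAM_NAMES, ParameterBounds

__all__ = [
    "SensitivityResult",
    "CorrelationLine",
    "multiplicative_steps",
    "sensitivity_1d",
    "correlation_line_family",
    "sensitivity_2d",
    "ADDITIVE_PARAMS",
]

#: Parameters stepped additively (voltage midpoints, mV); all others are
#: multiplicative.
ADDITIVE_PARAMS = ("V_half_mCa", "V_half_hCa")


@dataclass(frozen=True)
class SensitivityResult:
    parameters: tuple[str, ...]
    attribute: str
    slope: float
    r_squared: float
    n_points: int
    direction: str  # 'single', 'parallel' or 'perpendicular'


def multiplicative_steps(n: int) -> np.ndarray:
    """The geometric step schedule dp_n = 0.001 * 1.15**n."""
    return 0.001 * 1.15 ** np.arange(n)


def _log_change(a: float, a0: float) -> float | None:
    """ln(a / a0) for a sign-preserving attribute change; None when the
    attribute is undefined, zero or flips sign (the local log-linear
    description no longer applies)."""
    if not np.isfinite(a) or a == 0 or np.sign(a) != np.sign(a0):
        return None
    return float(np.log(abs(a) / abs(a0)))


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2.  A perfectly flat response (zero total
    variance) counts as a perfect linear fit with slope 0."""
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    if syy <= 1e-24:
        return 0.0, 1.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2 = 1.0 - np.sum(resid**2) / syy
    return float(slope), float(r2)


def _expand_fit(
    point_fn: Callable[[int, int], tuple[float, float] | None],
    r2_min: float,
    max_steps: int,
    label: tuple[str, ...],
    attribute: str,
    direction: str,
) -> SensitivityResult:
    """Shared expansion loop: add symmetric step pairs until R^2 < r2_min.

    ``point_fn(n, sign)`` returns (parameter change, attribute log-change)
    for step index n in direction sign, or None when the point is
    unavailable (bounds hit, attribute lost).  The first pair is always
    retained (a fit needs three points including the baseline); later pairs
    are dropped again if they push R^2 below the threshold.
    """
    xs, ys = [0.0], [0.0]
    slope, r2 = 0.0, 1.0
    have_fit = False
    for n in range(max_steps):
        new = [pt for s in (+1, -1) if (pt := point_fn(n, s)) is not None]
        if not new:
            break
        trial_x = xs + [p[0] for p in new]
        trial_y = ys + [p[1] for p in new]
        if len(trial_x) >= 3:
            s_try, r2_try = _fit_line(np.array(trial_x), np.array(trial_y))
            if have_fit and r2_try < r2_min:
                break
            slope, r2, have_fit = s_try, r2_try, True
        xs, ys = trial_x, trial_y
    if len(xs) < 3:
        raise ValueError("fewer than 3 valid points for the sensitivity fit")
    return SensitivityResult(label, attribute, slope, r2, len(xs), direction)


def sensitivity_1d(
    attr_fn: Callable[[float], float],
    p0: float,
    param_name: str = "p",
    attribute: str = "attribute",
    multiplicative: bool | None = None,
    r2_min: float = 0.98,
    max_steps: int = 40,
    additive_step: float = 0.5,
    bounds: tuple[float, float] | None = None,
) -> SensitivityResult:
    """Sensitivity of ``attr_fn`` to a single parameter around ``p0``.

    ``attr_fn(p)`` returns the attribute value (NaN when undefined, e.g.
    resonance lost).  The baseline attribute must be defined.  For additive
    parameters the x-axis is the raw change in mV.
    """
    if multiplicative is None:
        multiplicative = param_name not in ADDITIVE_PARAMS
    a0 = attr_fn(p0)
    if not np.isfinite(a0):
        raise ValueError("attribute undefined at the baseline parameter value")
    if a0 == 0:
        raise ValueError("zero baseline attribute; relative change undefined")
    steps = multiplicative_steps(max_steps)

    def point(n: int, sign: int):
        if multiplicative:
            p = float(np.exp(sign * steps[n]) * p0)
            x = sign * steps[n]  # = ln(p / p0) exactly
        else:
            p = p0 + sign * additive_step * (n + 1)
            x = p - p0
        if bounds is not None and not (bounds[0] <= p <= bounds[1]):
            return None
        a = attr_fn(p)
        y = _log_change(a, a0)
        if y is None:
            return None
        return x, y

    return _expand_fit(point, r2_min, max_steps, (param_name,), attribute, "single")


# ---------------------------------------------------------------------------
# 2-d sensitivity along correlation lines


@dataclass(frozen=True)
class CorrelationLine:
    """A pairwise correlation line in (partly) median-normalized space.

    ``scale`` holds the normalization divisor of each coordinate (the group
    median for multiplicative parameters, 1.0 for additive voltage
    parameters).  ``slope`` is d(u2)/d(u1) of the population fit in that
    space; the perpendicular direction has slope -1/slope.
    """

    pair: tuple[str, str]
    slope: float
    intercept: float
    scale: tuple[float, float]
    R: float

    def p2_of_p1(self, p1: float, through: tuple[float, float], perpendicular: bool = False) -> float:
        """Co-varied second parameter for the line shifted through a model."""
        s = -1.0 / self.slope if perpendicular else self.slope
        u1 = p1 / self.scale[0]
        u1_0 = through[0] / self.scale[0]
        u2_0 = through[1] / self.scale[1]
        return (u2_0 + s * (u1 - u1_0)) * self.scale[1]


def correlation_line_family(
    group: pd.DataFrame,
    pair: tuple[str, str],
    n_models: int = 50,
    rng: np.random.Generator | int | None = None,
    p_max: float = 0.05,
) -> tuple[CorrelationLine, pd.DataFrame]:
    """Fit the pair's correlation line and sample models to carry it.

    The line is fit by least squares in median-normalized space; the sampled
    models define the family of parallel (and perpendicular) lines, each
    shifted to pass through one model's parameter point.  Raises when the
    pair is not significantly correlated in the group (guard against
    shuffled or unstructured populations).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a, b = pair
    x = group[a].to_numpy(dtype=float)
    y = group[b].to_numpy(dtype=float)
    r, p = stats.pearsonr(x, y)
    if not np.isfinite(r) or p > p_max:
        raise ValueError(f"pair {pair} not significantly correlated (R={r:.3f}, p={p:.3g})")
    sx = 1.0 if a in ADDITIVE_PARAMS else float(np.median(x))
    sy = 1.0 if b in ADDITIVE_PARAMS else float(np.median(y))
    if sx == 0 or sy == 0:
        raise ValueError("zero median; cannot normalize")
    u, v = x / sx, y / sy
    slope, intercept = np.polyfit(u, v, 1)
    if not np.isfinite(slope) or slope == 0:
        raise ValueError("degenerate correlation line")
    line = CorrelationLine(pair, float(slope), float(intercept), (sx, sy), float(r))
    k = min(n_models, len(group))
    sample = group.sample(n=k, random_state=np.random.RandomState(int(rng.integers(2**31 - 1))))
    return line, sample.reset_index(drop=True)


def sensitivity_2d(
    attr_fn: Callable[[np.ndarray], float],
    params: np.ndarray,
    pair: tuple[str, str],
    line: CorrelationLine,
    attribute: str = "attribute",
    perpendicular: bool = False,
    r2_min: float = 0.98,
    max_steps: int = 40,
    additive_step: float = 0.5,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
) -> SensitivityResult:
    """Sensitivity when the pair is co-varied along a correlation line.

    ``attr_fn`` maps a full 8-parameter vector to the attribute value.  The
    first parameter of the pair is stepped with the 1-d schedule; the second
    follows from the (parallel or perpendicular) line through the model's
    own point.  Steps leaving the search box truncate the explored segment.
    When the line is axis-aligned (slope 0 parallel) this reduces to the
    1-d sensitivity of the first parameter.
    """
    params = np.asarray(params, dtype=float)
    i1, i2 = PARAM_NAMES.index(pair[0]), PARAM_NAMES.index(pair[1])
    p1_0, p2_0 = params[i1], params[i2]
    mult1 = pair[0] not in ADDITIVE_PARAMS

    a0 = attr_fn(params)
    if not np.isfinite(a0) or a0 == 0:
        raise ValueError("attribute undefined (or zero) at the baseline model")
    steps = multiplicative_steps(max_steps)

    def point(n: int, sign: int):
        if mult1:
            p1 = float(np.exp(sign * steps[n]) * p1_0)
            x = sign * steps[n]  # = ln(p1 / p1_0)
        else:
            p1 = p1_0 + sign * additive_step * (n + 1)
            x = p1 - p1_0
        p2 = line.p2_of_p1(p1, (p1_0, p2_0), perpendicular=perpendicular)
        trial = params.copy()
        trial[i1], trial[i2] = p1, p2
        if not (bounds.low[i1] <= p1 <= bounds.high[i1] and bounds.low[i2] <= p2 <= bounds.high[i2]):
            return None
        y = _log_change(attr_fn(trial), a0)
        if y is None:
            return None
        return x, y

    direction = "perpendicular" if perpendicular else "parallel"
    return _expand_fit(point, r2_min, max_steps, tuple(pair), attribute, direction)
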