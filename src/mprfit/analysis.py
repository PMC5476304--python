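"""Statistics over the fitted model population.

Three analyses: (i) pairwise Pearson correlations between parameters with a
permutation test repeated over random 20-model subsets; (ii) partition of
the population into low and high g_Ca groups at 0.05 uS, with a triangular
per-group p-value table; (iii) the hyperpolarized-range experiment:
re-profile each accepted model with the lower clamp bound moved from -60 to
-70 mV, measure the shifts in f_res and Z_max, and keep the "intermediate"
subset that reproduces the biological shift (f_res down, Z_max unchanged,
within 5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluator import AttributeEvaluator
from .params import FixedConstants, ModelParams, PARAM_NAMES
from .stimulus import ZapConfig, shifted_range_config

__all__ = [
    "CorrelationResult",
    "pearson_permutation",
    "correlation_table",
    "partition_gca",
    "group_pvalue_table",
    "vlow_shift",
    "vlow_shift_population",
    "intermediate_filter",
    "normalized_cov",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation of one parameter pair across the population."""

    pair: tuple[str, str]
    R: float
    p_perm: float
    slope: float
    slope_p: float
    pct_significant: float  # % of subset repetitions with permutation p < alpha
    n: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    den = np.sqrt((xm**2).sum() * (ym**2).sum())
    return float((xm * ym).sum() / den) if den > 0 else np.nan


def _perm_pvalue(x, y, n_perms, rng, two_sided=True):
    r_obs = _pearson(x, y)
    if not np.isfinite(r_obs):
        return r_obs, np.nan
    idx = np.argsort(rng.random((n_perms, y.size)), axis=1)
    yp = y[idx]
    xm = x - x.mean()
    ym = yp - yp.mean(axis=1, keepdims=True)
    r_perm = (xm * ym).sum(axis=1) / np.sqrt((xm**2).sum() * (ym**2).sum(axis=1))
    if two_sided:
        p = float(np.mean(np.abs(r_perm) >= abs(r_obs)))
    else:
        p = float(np.mean(r_perm >= r_obs))
    return r_obs, p


def pearson_permutation(
    pop: pd.DataFrame,
    param_x: str,
    param_y: str,
    rng: np.random.Generator | int | None = None,
    subset_size: int = 20,
    n_subsets: int = 2000,
    n_perms: int = 1000,
    alpha: float = 0.01,
    two_sided: bool = True,
) -> CorrelationResult:
    """Pearson correlation with a subset-resampled permutation test.

    The pooled-population R is returned together with its permutation
    p-value and the regression-slope t-test.  In addition, ``n_subsets``
    random subsets of ``subset_size`` models are drawn; for each, y is
    permuted ``n_perms`` times and the subset p-value is the fraction of
    permuted |R| at least as large as the observed |R| (two-sided default;
    set ``two_sided=False`` for the one-sided variant).  ``pct_significant``
    is the percentage of subsets with p < ``alpha``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = pop[param_x].to_numpy(dtype=float)
    y = pop[param_y].to_numpy(dtype=float)
    if x.size < subset_size:
        raise ValueError(f"population smaller than subset_size={subset_size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"zero-variance parameter in pair ({param_x}, {param_y})", RuntimeWarning)
        return CorrelationResult((param_x, param_y), np.nan, np.nan, np.nan, np.nan, np.nan, x.size)

    r_obs, p_pool = _perm_pvalue(x, y, n_perms, rng, two_sided)
    lr = stats.linregress(x, y)

    n_sig = 0
    for _ in range(n_subsets):
        sel = rng.choice(x.size, size=subset_size, replace=False)
        _, p = _perm_pvalue(x[sel], y[sel], n_perms, rng, two_sided)
        if p < alpha:
            n_sig += 1
    return CorrelationResult(
        pair=(param_x, param_y),
        R=r_obs,
        p_perm=p_pool,
        slope=float(lr.slope),
        slope_p=float(lr.pvalue),
        pct_significant=100.0 * n_sig / n_subsets if n_subsets else np.nan,
        n=x.size,
    )


def correlation_table(
    pop: pd.DataFrame,
    params=PARAM_NAMES,
    rng=None,
    n_subsets: int = 200,
    n_perms: int = 500,
    fdr_column: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """All pairwise correlations as a tidy table.

    ``fdr_column`` appends Benjamini-Hochberg adjusted permutation p-values
    (an extension beyond the raw p < 0.01 screen).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for i, a in enumerate(params):
        for b in params[i + 1 :]:
            r = pearson_permutation(pop, a, b, rng=rng, n_subsets=n_subsets, n_perms=n_perms, **kwargs)
            rows.append(
                {
                    "param_x": a,
                    "param_y": b,
                    "R": r.R,
                    "p_perm": r.p_perm,
                    "slope": r.slope,
                    "slope_p": r.slope_p,
                    "pct_significant": r.pct_significant,
                }
            )
    out = pd.DataFrame(rows)
    if fdr_column:
        p = out["p_perm"].to_numpy(dtype=float)
        out["p_perm_bh"] = stats.false_discovery_control(np.clip(p, 0, 1), method="bh")
    return out


def partition_gca(pop: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Label each model 'low' (g_Ca < threshold) or 'high' (g_Ca >= threshold).

    Models exactly at the threshold go to 'high' (documented tie rule).  The
    partition is exhaustive and disjoint; an empty group warns.
    """
    out = pop.copy()
    out["gca_group"] = np.where(out["g_Ca"] < threshold, "low", "high")
    for g in ("low", "high"):
        if not (out["gca_group"] == g).any():
            warnings.warn(f"empty {g} g_Ca group at threshold {threshold}", RuntimeWarning)
    return out


def group_pvalue_table(
    pop: pd.DataFrame,
    params=PARAM_NAMES,
    threshold: float = 0.05,
    rng=None,
    n_perms: int = 2000,
) -> pd.DataFrame:
    """Triangular per-group permutation p-value matrix.

    Lower triangle: low g_Ca group; upper triangle: high g_Ca group
    (pooled-group permutation p-values, no subset resampling).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lab = partition_gca(pop, threshold)
    lo = lab[lab["gca_group"] == "low"]
    hi = lab[lab["gca_group"] == "high"]
    k = len(params)
    M = pd.DataFrame(np.full((k, k), np.nan), index=params, columns=params)
    for i, a in enumerate(params):
        for j, b in enumerate(params):
            if i == j:
                continue
            grp = lo if i > j else hi
            if len(grp) < 3:
                continue
            x = grp[a].to_numpy(dtype=float)
            y = grp[b].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            _, p = _perm_pvalue(x, y, n_perms, rng)
            M.iloc[i, j] = p
    return M


# ---------------------------------------------------------------------------
# hyperpolarized-range (V_low) experiment


def vlow_shift(
    params: ModelParams,
    consts: FixedConstants | None = None,
    base_zap: ZapConfig | None = None,
    v_low: float = -70.0,
    evaluators: tuple[AttributeEvaluator, AttributeEvaluator] | None = None,
) -> dict:
    """Shift of f_res and Z_max when the lower clamp bound moves to ``v_low``.

    Profiles the model over the base range and over (v_low, v_high); deltas
    are value(shifted) - value(base).  Models that lose resonance at either
    range are flagged (``ok`` False) and should be excluded from group means.
    """
    if evaluators is None:
        base_zap = base_zap or ZapConfig()
        shifted = shifted_range_config(base_zap, v_low, base_zap.v_high)
        # target irrelevant here; the evaluator is used only for attributes
        from .impedance import reference_target

        evaluators = (
            AttributeEvaluator(reference_target(), consts=consts, zap=base_zap),
            AttributeEvaluator(reference_target(), consts=consts, zap=shifted),
        )
    ev0, ev1 = evaluators
    x = params.to_array()
    try:
        a0 = ev0.attributes_of(x)
        a1 = ev1.attributes_of(x)
    except (FloatingPointError, ValueError):
        return {"ok": False, "d_fres": np.nan, "d_zmax": np.nan}
    ok = a0.has_resonance and a1.has_resonance
    return {
        "ok": bool(ok),
        "f_res_base": a0.f_res,
        "Z_max_base": a0.Z_max,
        "f_res_shifted": a1.f_res,
        "Z_max_shifted": a1.Z_max,
        "d_fres": a1.f_res - a0.f_res,
        "d_zmax": a1.Z_max - a0.Z_max,
    }


def vlow_shift_population(
    pop: pd.DataFrame,
    consts: FixedConstants | None = None,
    base_zap: ZapConfig | None = None,
    v_low: float = -70.0,
) -> pd.DataFrame:
    """Per-model V_low shifts for a population table (adds d_fres/d_zmax)."""
    from .impedance import reference_target

    base_zap = base_zap or ZapConfig()
    shifted = shifted_range_config(base_zap, v_low, base_zap.v_high)
    evs = (
        AttributeEvaluator(reference_target(), consts=consts, zap=base_zap),
        AttributeEvaluator(reference_target(), consts=consts, zap=shifted),
    )
    rows = []
    for _, row in pop.iterrows():
        p = ModelParams.from_array(row[list(PARAM_NAMES)].to_numpy(dtype=float))
        rows.append(vlow_shift(p, evaluators=evs))
    out = pop.reset_index(drop=True).join(pd.DataFrame(rows))
    return out


def intermediate_filter(
    pop: pd.DataFrame,
    shifted_target_fres: float,
    shifted_target_zmax: float,
    consts: FixedConstants | None = None,
    base_zap: ZapConfig | None = None,
    v_low: float = -70.0,
    tol: float = 0.05,
) -> pd.DataFrame:
    """Subset of accepted models reproducing the biological V_low response.

    Keeps models whose shifted-range f_res and Z_max are each within ``tol``
    of the stated shifted targets (f_res reduced, Z_max unchanged).  The
    returned frame carries the shifted-range attributes; an empty subset
    warns rather than raises.  A table that already carries the shift
    columns (from :func:`vlow_shift_population`) is reused as is.
    """
    if "f_res_shifted" in pop.columns:
        shifted = pop.reset_index(drop=True)
    else:
        shifted = vlow_shift_population(pop, consts=consts, base_zap=base_zap, v_low=v_low)
    ok = shifted["ok"].fillna(False).astype(bool)
    e_f = np.abs(shifted["f_res_shifted"] - shifted_target_fres) / abs(shifted_target_fres)
    e_z = np.abs(shifted["Z_max_shifted"] - shifted_target_zmax) / abs(shifted_target_zmax)
    keep = ok & (e_f <= tol) & (e_z <= tol)
    out = shifted[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("no models passed the V_low intermediate filter", RuntimeWarning, stacklevel=2)
    return out


def normalized_cov(x: np.ndarray) -> float:
    """Coefficient of variation with median normalization: std(x / median)."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    if med == 0:
        return np.nan
    return float(np.std(x / med, ddof=1))
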