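"""Model/Results interface over the fitting pipeline.

:class:`PDResonanceModel` bundles everything that defines one fitting
problem — the target attribute set, the fixed biophysical constants, the
ZAP protocol and the search configuration — and ``fit()`` runs the pooled
evolutionary search, returning a :class:`ResonanceFitResult` that carries
the accepted model population together with the downstream analyses
(parameter dispersion, pairwise correlations, the hyperpolarized-range
experiment and sensitivity along correlation lines).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis as an
from . import moea
from . import sensitivity as sens
from .evaluator import AttributeEvaluator
from .impedance import AttributeSet, reference_target
from .params import FixedConstants, ModelParams, PARAM_NAMES
from .stimulus import ZapConfig

__all__ = ["PDResonanceModel", "ResonanceFitResult"]


class PDResonanceModel:
    """A resonance-fitting problem for the PD neuron model.

    Parameters
    ----------
    target : AttributeSet, optional
        Impedance attributes to fit; defaults to the biological reference
        target.
    consts : FixedConstants, optional
        Fixed constants; pass ``FixedConstants(V_half_mH=-96.0)`` for the
        shifted I_H midpoint variant.
    zap : ZapConfig, optional
        The clamp protocol.
    config : moea.MoeaConfig, optional
        Search settings (population size, generations, operator indices).

    Examples
    --------
    >>> model = PDResonanceModel()                        # doctest: +SKIP
    >>> result = model.fit(seeds=[1, 2, 3])               # doctest: +SKIP
    >>> print(result.summary())                           # doctest: +SKIP
    """

    def __init__(
        self,
        target: AttributeSet | None = None,
        consts: FixedConstants | None = None,
        zap: ZapConfig | None = None,
        config: moea.MoeaConfig | None = None,
    ):
        self.target = target or reference_target()
        self.consts = consts or FixedConstants()
        self.config = config or moea.MoeaConfig()
        self.zap = (zap or ZapConfig()).replace(dt=self.config.dt)
        self._evaluator: AttributeEvaluator | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_target_json(cls, path, **kwargs) -> "PDResonanceModel":
        """Build from a target attribute file (the AttributeSet JSON schema)."""
        with open(path) as fh:
            target = AttributeSet.from_dict(json.load(fh))
        return cls(target=target, **kwargs)

    @classmethod
    def from_synthetic(cls, truth: ModelParams, noise_level: float = 0.0, rng=None, **kwargs):
        """Build a fitting problem whose target comes from a known truth."""
        from .synthetic import make_target

        zap = kwargs.get("zap") or ZapConfig()
        consts = kwargs.get("consts")
        st = make_target(truth, zap=zap, consts=consts, noise_level=noise_level, rng=rng)
        model = cls(target=st.target, **kwargs)
        model.truth = truth
        return model

    # -- infrastructure -----------------------------------------------------

    @property
    def evaluator(self) -> AttributeEvaluator:
        if self._evaluator is None:
            self._evaluator = AttributeEvaluator(self.target, consts=self.consts, zap=self.zap)
        return self._evaluator

    def attributes_of(self, params: ModelParams) -> AttributeSet:
        """Measured attributes of one parameter set under this protocol."""
        return self.evaluator.attributes_of(params.to_array())

    # -- fitting ------------------------------------------------------------

    def fit(self, seeds=(1, 2, 3), progress: bool = False) -> "ResonanceFitResult":
        """Run the pooled evolutionary search (one run per seed)."""
        pooled, runs = moea.run_pooled(
            self.target, self.config, seeds=list(seeds), consts=self.consts, zap=self.zap, progress=progress
        )
        return ResonanceFitResult(model=self, accepted=pooled, runs=runs)


@dataclass
class ResonanceFitResult:
    """Accepted model population and the analyses computed from it."""

    model: PDResonanceModel
    accepted: pd.DataFrame
    runs: list[moea.EvolutionResult] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    @property
    def params_frame(self) -> pd.DataFrame:
        return self.accepted[list(PARAM_NAMES)]

    def best_individual(self) -> tuple[ModelParams, float]:
        """The run individual with the smallest acceptance score."""
        best = (np.inf, None)
        for run in self.runs:
            pop = run.population
            for _, row in pop.iterrows():
                x = row[list(PARAM_NAMES)].to_numpy(dtype=float)
                try:
                    err = self.model.evaluator.errors_of(x)
                except (FloatingPointError, ValueError):
                    continue
                score = max(err.values())
                if score < best[0]:
                    best = (score, x)
        if best[1] is None:
            raise ValueError("no evaluable individual found")
        return ModelParams.from_array(best[1]), float(best[0])

    # -- analyses -----------------------------------------------------------

    def dispersion(self) -> pd.DataFrame:
        """Per-parameter median, range and median-normalized CoV."""
        rows = []
        for name in PARAM_NAMES:
            v = self.accepted[name].to_numpy(dtype=float)
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(v)),
                    "low": float(v.min()),
                    "high": float(v.max()),
                    "cov": an.normalized_cov(v),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def correlations(self, rng=None, **kwargs) -> pd.DataFrame:
        return an.correlation_table(self.accepted, rng=rng, **kwargs)

    def partition(self, threshold: float = 0.05) -> pd.DataFrame:
        return an.partition_gca(self.accepted, threshold)

    def vlow_experiment(self, v_low: float = -70.0) -> pd.DataFrame:
        return an.vlow_shift_population(
            self.accepted, consts=self.model.consts, base_zap=self.model.zap, v_low=v_low
        )

    def sensitivity_along_pair(
        self,
        pair: tuple[str, str],
        attribute: str = "f_res",
        group: pd.DataFrame | None = None,
        n_models: int = 20,
        rng=None,
    ) -> pd.DataFrame:
        """Parallel vs perpendicular 2-d sensitivities for a correlated pair."""
        group = self.accepted if group is None else group
        line, sample = sens.correlation_line_family(group, pair, n_models=n_models, rng=rng)
        ev = self.model.evaluator

        def attr_fn(x):
            try:
                a = ev.attributes_of(x)
            except (FloatingPointError, ValueError):
                return np.nan
            return getattr(a, attribute) if attribute != "Q_Z" else a.Q_Z

        rows = []
        for _, row in sample.iterrows():
            x = row[list(PARAM_NAMES)].to_numpy(dtype=float)
            rec = {"model": tuple(np.round(x, 6))}
            for perp in (False, True):
                try:
                    r = sens.sensitivity_2d(
                        attr_fn, x, pair, line, attribute=attribute, perpendicular=perp,
                        bounds=self.model.config.bounds,
                    )
                    rec["perpendicular" if perp else "parallel"] = r.slope
                except ValueError:
                    rec["perpendicular" if perp else "parallel"] = np.nan
            rows.append(rec)
        return pd.DataFrame(rows)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary."""
        t = self.model.target
        lines = [
            "PD neuron resonance fit",
            "=" * 60,
            f"target: f_res={t.f_res:g} Hz, Z_max={t.Z_max:g} MOhm, Q_Z={t.Q_Z:g} MOhm",
            f"runs: {len(self.runs)}  pop={self.model.config.pop_size}"
            f"  generations={self.model.config.generations}  dt={self.model.config.dt} ms",
            f"accepted models (every attribute within {100*self.model.config.tolerance:g}%): {self.n_accepted}",
        ]
        if self.n_accepted:
            disp = self.dispersion()
            lines.append("")
            lines.append(f"{'parameter':>12} {'median':>10} {'low':>10} {'high':>10} {'CoV':>8}")
            for name, row in disp.iterrows():
                lines.append(
                    f"{name:>12} {row['median']:>10.4g} {row['low']:>10.4g} {row['high']:>10.4g} {row['cov']:>8.3f}"
                )
            d = (self.accepted["f_res"] - self.accepted["f_phi0"]).abs().median()
            lines.append("")
            lines.append(f"median |f_res - f_phi0|: {d:.4f} Hz")
        else:
            best = min((r.log["best_score"].iloc[-1] for r in self.runs if len(r.log)), default=np.nan)
            lines.append(f"(no accepted models; best attribute error reached {100*best:.2f}%)")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.accepted.to_csv(path, index=False)
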