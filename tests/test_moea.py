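"""Evolutionary machinery: sorting, crowding, variation operators, evolution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mprfit.moea import (
    MoeaConfig,
    _survivor_select,
    crowding_distance,
    evolve,
    filter_optimal,
    non_dominated_sort,
    polynomial_mutation,
    sbx_crossover,
)
from mprfit.params import DEFAULT_BOUNDS, PARAM_NAMES, ParameterBounds


def brute_force_fronts(F):
    """Independent oracle: repeatedly peel the set of maximal elements found
    by exhaustive pairwise dominance checks."""
    F = np.asarray(F, dtype=float)
    remaining = list(range(F.shape[0]))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = False
            for j in remaining:
                if i == j:
                    continue
                if (F[j] <= F[i]).all() and (F[j] < F[i]).any():
                    dominated = True
                    break
            if not dominated:
                front.append(i)
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestNonDominatedSort:
    def test_hand_checked_chain(self):
        F = np.array([[1.0, 1.0], [1.0, 2.0], [2.0, 2.0]])
        fronts = [sorted(f.tolist()) for f in non_dominated_sort(F)]
        assert fronts == [[0], [1], [2]]

    def test_identical_vectors_share_one_front(self):
        F = np.ones((5, 3))
        fronts = non_dominated_sort(F)
        assert len(fronts) == 1 and len(fronts[0]) == 5

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.random((50, 10))
        got = [sorted(f.tolist()) for f in non_dominated_sort(F)]
        assert got == brute_force_fronts(F)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20)
    def test_partition_is_exhaustive_and_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.integers(0, 4, size=(20, 3)).astype(float)  # many ties
        fronts = non_dominated_sort(F)
        flat = np.concatenate(fronts)
        assert sorted(flat.tolist()) == list(range(20))


class TestCrowding:
    def test_two_individuals_both_boundary(self):
        d = crowding_distance(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.isinf(d).all()

    def test_evenly_spaced_collinear_middle_distance(self):
        F = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        d = crowding_distance(F)
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)  # one full normalized span per objective

    def test_duplicate_values_stay_finite(self):
        F = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        d = crowding_distance(F)
        assert np.isfinite(d[1]) and (d >= 0).all()


class TestSBX:
    def test_identical_parents_fixed_point(self):
        rng = np.random.default_rng(0)
        p = DEFAULT_BOUNDS.low + 0.3 * DEFAULT_BOUNDS.span
        c1, c2 = sbx_crossover(p, p, 20.0, DEFAULT_BOUNDS, rng)
        np.testing.assert_allclose(c1, p)
        np.testing.assert_allclose(c2, p)

    def test_large_eta_concentrates_on_parents(self):
        rng = np.random.default_rng(1)
        p1 = DEFAULT_BOUNDS.low + 0.25 * DEFAULT_BOUNDS.span
        p2 = DEFAULT_BOUNDS.low + 0.75 * DEFAULT_BOUNDS.span
        c1, c2 = sbx_crossover(p1, p2, 1e9, DEFAULT_BOUNDS, rng, gene_prob=1.0)
        got = np.sort(np.stack([c1, c2]), axis=0)
        want = np.sort(np.stack([p1, p2]), axis=0)
        np.testing.assert_allclose(got, want, rtol=1e-4)

    def test_child_mean_unbiased(self):
        rng = np.random.default_rng(2)
        p1 = DEFAULT_BOUNDS.low + 0.35 * DEFAULT_BOUNDS.span
        p2 = DEFAULT_BOUNDS.low + 0.65 * DEFAULT_BOUNDS.span
        acc = np.zeros_like(p1)
        n = 10_000
        for _ in range(n):
            c1, c2 = sbx_crossover(p1, p2, 20.0, DEFAULT_BOUNDS, rng)
            acc += 0.5 * (c1 + c2)
        mean = acc / n
        # clipping is rare for interior parents; 3 SE tolerance on each gene
        se = DEFAULT_BOUNDS.span * 0.3 / np.sqrt(n)
        assert (np.abs(mean - 0.5 * (p1 + p2)) < 3 * se + 1e-12).all()

    def test_children_respect_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p1 = rng.uniform(DEFAULT_BOUNDS.low, DEFAULT_BOUNDS.high)
            p2 = rng.uniform(DEFAULT_BOUNDS.low, DEFAULT_BOUNDS.high)
            for c in sbx_crossover(p1, p2, 20.0, DEFAULT_BOUNDS, rng):
                assert DEFAULT_BOUNDS.contains(c)


class TestMutation:
    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        x = DEFAULT_BOUNDS.low + 0.4 * DEFAULT_BOUNDS.span
        np.testing.assert_array_equal(polynomial_mutation(x, 20.0, 0.0, DEFAULT_BOUNDS, rng), x)

    def test_gene_at_bound_moves_inward(self):
        rng = np.random.default_rng(1)
        x = DEFAULT_BOUNDS.low.copy()
        for _ in range(500):
            y = polynomial_mutation(x, 20.0, 1.0, DEFAULT_BOUNDS, rng)
            assert (y >= DEFAULT_BOUNDS.low).all()

    def test_centered_gene_perturbation_symmetric(self):
        rng = np.random.default_rng(2)
        x = DEFAULT_BOUNDS.low + 0.5 * DEFAULT_BOUNDS.span
        deltas = np.stack(
            [polynomial_mutation(x, 20.0, 1.0, DEFAULT_BOUNDS, rng) - x for _ in range(10_000)]
        )
        sd = deltas.std(axis=0)
        assert (np.abs(deltas.mean(axis=0)) < 3 * sd / np.sqrt(10_000) + 1e-15).all()


class _QuadraticStub:
    """Cheap evaluator stand-in: objectives are |x - c| per objective, no
    attributes (exercises the machinery without simulations)."""

    def __init__(self, centers):
        self.centers = centers  # (n_obj, 8)

    def evaluate(self, X):
        X = np.atleast_2d(X)
        span = DEFAULT_BOUNDS.span
        F = np.stack(
            [np.abs((X - c) / span).mean(axis=1) for c in self.centers], axis=1
        )
        return F, [None] * X.shape[0]


def _stub_evaluator(seed=0, n_obj=10):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(DEFAULT_BOUNDS.low, DEFAULT_BOUNDS.high, size=(n_obj, 8))
    return _QuadraticStub(centers)


class TestEvolve:
    def test_zero_generations_returns_evaluated_initial_population(self, target):
        cfg = MoeaConfig(pop_size=20, generations=0, seed=5)
        res = evolve(target, cfg, evaluator=_stub_evaluator())
        assert len(res.population) == 20
        assert {f"obj_{i}" for i in range(10)} <= set(res.population.columns)
        assert res.log.empty

    def test_same_seed_bitwise_identical(self, target):
        cfg = MoeaConfig(pop_size=20, generations=5, seed=7)
        a = evolve(target, cfg, evaluator=_stub_evaluator())
        b = evolve(target, cfg, evaluator=_stub_evaluator())
        pd.testing.assert_frame_equal(a.population, b.population)

    def test_per_objective_best_non_increasing(self, target):
        """Elitist survival never loses the best value of any single objective
        (guaranteed while the truncated front's boundary solutions fit in the
        crowding slots, so 3 objectives with population 24)."""
        cfg = MoeaConfig(pop_size=24, generations=15, seed=3)
        res = evolve(target, cfg, evaluator=_stub_evaluator(n_obj=3))
        hist = np.array(res.log["per_objective_best"].tolist())
        assert (np.diff(hist, axis=0) <= 1e-12).all()

    def test_front_hypervolume_non_decreasing_under_survival(self):
        """The dominated hypervolume of the surviving first front (Monte
        Carlo estimate against a fixed reference box) never shrinks as new
        random candidates arrive and (mu+lambda) selection is applied."""
        rng = np.random.default_rng(4)
        probe = rng.random((4000, 3))  # fixed MC points in the unit box
        P = rng.random((30, 3))

        def hv(F):
            front = non_dominated_sort(F)[0]
            dominated = (F[front][:, None, :] <= probe[None, :, :]).all(axis=2).any(axis=0)
            return dominated.mean()

        last = hv(P)
        for _ in range(15):
            children = rng.random((30, 3))
            allF = np.vstack([P, children])
            P = allF[_survivor_select(allF, 30, score=allF.sum(axis=1))]
            now = hv(P)
            assert now >= last - 1e-12
            last = now

    def test_survivor_selection_keeps_objective_minima(self):
        rng = np.random.default_rng(0)
        F = rng.random((40, 4))
        keep = _survivor_select(F, 20, score=rng.random(40))
        for j in range(4):
            assert F[keep, j].min() == pytest.approx(F[:, j].min())


@pytest.fixture(scope="module")
def scaled_bio_run(target):
    """One scaled-down run against the biological target (variant baseline)."""
    from mprfit.moea import run_pooled

    cfg = MoeaConfig(pop_size=48, generations=60, dt=0.5)
    _, runs = run_pooled(target, cfg, seeds=[7])
    return cfg, runs[0]


def _best_front(run, k=12):
    pop = run.population
    score = pop[[f"obj_{i}" for i in range(10)]].max(axis=1)
    return pop.loc[score.sort_values().index[:k]]


class TestVariantConfigs:
    def test_shifted_h_midpoint_rescales_gh_only(self, target, scaled_bio_run):
        """Moving the I_H activation midpoint from -70 to -96 mV starves the
        gate over the clamp range, so fits compensate with a much larger g_H
        while the other parameters stay in their usual range (the g_H bound
        is widened so the rescaling can be expressed)."""
        from mprfit.moea import run_pooled
        from mprfit.params import DEFAULT_BOUNDS, FixedConstants

        cfg, base_run = scaled_bio_run
        wide = DEFAULT_BOUNDS.replace_param("g_H", 0.0, 14.0)
        _, runs = run_pooled(
            target, cfg.replace(bounds=wide), seeds=[7], consts=FixedConstants(V_half_mH=-96.0)
        )
        top_base = _best_front(base_run)
        top_var = _best_front(runs[0])
        assert top_var["g_H"].median() > 3.0 * top_base["g_H"].median()
        # the leak conductance is unaffected by the I_H midpoint
        assert top_var["g_L"].median() == pytest.approx(top_base["g_L"].median(), rel=0.5)

    def test_removing_ih_pushes_fits_to_high_gca_low_inactivation_midpoint(self, target, scaled_bio_run):
        """With g_H forced to zero, the calcium current must carry the
        resonance alone: good fits move to higher g_Ca and a more negative
        inactivation midpoint."""
        from mprfit.moea import run_pooled
        from mprfit.params import DEFAULT_BOUNDS

        cfg, base_run = scaled_bio_run
        no_h = DEFAULT_BOUNDS.replace_param("g_H", 0.0, 0.0)
        _, runs = run_pooled(target, cfg.replace(bounds=no_h), seeds=[7])
        top_base = _best_front(base_run)
        top_var = _best_front(runs[0])
        assert top_var["g_Ca"].median() > top_base["g_Ca"].median()
        assert top_var["V_half_hCa"].median() < top_base["V_half_hCa"].median()


class TestFilterOptimal:
    def _pop_from_attrs(self, attrs_list, params_list):
        from mprfit.evaluator import attrs_to_row

        rows = []
        for a, p in zip(attrs_list, params_list):
            row = dict(zip(PARAM_NAMES, p))
            row.update(attrs_to_row(a))
            rows.append(row)
        return pd.DataFrame(rows)

    def test_exact_target_kept_and_six_percent_rejected(self, target):
        good = target
        bad = target.replace(Z_max=target.Z_max * 1.06)
        p = DEFAULT_BOUNDS.low + 0.5 * DEFAULT_BOUNDS.span
        pop = self._pop_from_attrs([good, bad], [p, p + 1e-3 * DEFAULT_BOUNDS.span])
        kept = filter_optimal(pop, target)
        assert len(kept) == 1

    def test_near_duplicates_removed(self, target):
        p = DEFAULT_BOUNDS.low + 0.5 * DEFAULT_BOUNDS.span
        pop = self._pop_from_attrs([target, target], [p, p * (1 + 1e-9)])
        kept = filter_optimal(pop, target)
        assert len(kept) == 1

    def test_empty_result_warns_not_raises(self, target):
        bad = target.replace(Z_max=target.Z_max * 1.5)
        p = DEFAULT_BOUNDS.low + 0.5 * DEFAULT_BOUNDS.span
        pop = self._pop_from_attrs([bad], [p])
        with pytest.warns(RuntimeWarning):
            kept = filter_optimal(pop, target)
        assert kept.empty
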