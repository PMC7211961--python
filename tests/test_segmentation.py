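import math

import numpy as np
import pytest

import treeseg as ts
from treeseg.segmentation import interval_bounds

from oracles import EnumerationOracle


def _planted_instance(seed, n=12, k=1):
    rng = np.random.default_rng(seed)
    tree = ts.simulate_tree(n, "yule", seed=rng)
    ordering = ts.standard_ordering(tree)
    if k == 0:
        y_pos = rng.binomial(1, 0.5, size=n).astype(float)
    else:
        design = ts.SimulationDesign(
            n_leaves=n, k_true=k,
            clade_fraction=tuple([0.3] * k),
            probs=tuple([0.15] + [0.9] * k),
            n_reps=1, seed=0, size_tol=0.6)
        try:
            _, y = ts.plant_signal(tree, ordering, design, rng)
        except Exception:
            y_pos = rng.binomial(1, 0.5, size=n).astype(float)
        else:
            y_pos = np.array([y[leaf - 1] for leaf in ordering.order])
    return tree, ordering, y_pos


class TestIntervalBounds:
    def test_all_ones_upper_bound_is_one(self):
        cons = interval_bounds(np.ones(6), q=1.0, min_segment=2)
        assert cons.hi_table[1, 6] == 1.0

    def test_single_observation_closed_form(self):
        q = 2.0
        n = 5
        cons = interval_bounds(np.array([1.0, 1, 1, 1, 1]), q=q, min_segment=1)
        c = 0.5 * (q + math.sqrt(ts.penalty(1, n))) ** 2
        # for one success the admissible lower bound solves -log(b) = c
        assert cons.lo_table[1, 1] == pytest.approx(math.exp(-c), abs=1e-9)

    def test_bounds_nest_as_q_shrinks(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 30).astype(float)
        wide = interval_bounds(y, q=2.0, min_segment=3)
        narrow = interval_bounds(y, q=0.5, min_segment=3)
        assert np.all(narrow.lo_table >= wide.lo_table - 1e-12)
        assert np.all(narrow.hi_table <= wide.hi_table + 1e-12)


class TestEndToEnd:
    def test_constant_responses_give_no_association(self, qtable_small):
        tree = ts.simulate_tree(24, "yule", seed=1)
        res = ts.treeseg(tree, np.zeros(24), alpha=0.1,
                         quantile_table=qtable_small)
        assert res.k_hat == 0
        assert res.node_confidence_set == []
        assert np.allclose(res.fitted, 0.0)
        assert np.all(res.band_lo <= res.band_hi)

    def test_perfect_half_split_recovers_the_root_split(self, qtable_small):
        tree = ts.simulate_tree(32, "perfect", seed=0)
        ordering = ts.standard_ordering(tree)
        y = np.empty(32)
        for pos, leaf in enumerate(ordering.order):
            y[leaf - 1] = 1.0 if pos < 16 else 0.0
        res = ts.treeseg(tree, y, alpha=0.1, ordering=ordering,
                         quantile_table=qtable_small, min_segment=2)
        assert res.k_hat == 1
        levels = sorted(set(res.fitted))
        assert levels == [0.0, 1.0]
        lo, hi = ordering.clade_interval[res.active_nodes[0]]
        assert (lo, hi) in [(1, 16), (17, 32)]

    def test_alpha_nestedness_on_identical_data(self, qtable_small):
        tree, ordering, y_pos = _planted_instance(seed=5, n=30, k=1)
        ks = []
        for alpha in (0.02, 0.1, 0.5):
            res = ts.treeseg(tree, np.array(
                [y_pos[ordering.position[leaf] - 1] for leaf in tree.leaves]),
                alpha=alpha, ordering=ordering, quantile_table=qtable_small,
                min_segment=2)
            ks.append(res.k_hat)
        assert ks == sorted(ks)

    def test_active_nodes_inside_confidence_set_and_band(self, qtable_small):
        for seed in range(6):
            tree, ordering, y_pos = _planted_instance(seed, n=20, k=1)
            y = np.array([y_pos[ordering.position[leaf] - 1]
                          for leaf in tree.leaves])
            res = ts.treeseg(tree, y, alpha=0.1, ordering=ordering,
                             quantile_table=qtable_small, min_segment=2)
            assert set(res.active_nodes) <= set(res.node_confidence_set)
            assert np.all(res.band_lo <= res.fitted + 1e-9)
            assert np.all(res.fitted <= res.band_hi + 1e-9)
            assert res.k_hat == len(res.active_nodes)
            assert len(set(np.round(res.fitted, 12))) <= res.k_hat + 1

    def test_missing_responses_are_tolerated(self, qtable_small):
        tree = ts.simulate_tree(30, "yule", seed=3)
        labels = list(tree.leaf_labels.values())
        responses = {lb: 1.0 for lb in labels[:20]}  # ten leaves missing
        res = ts.treeseg(tree, responses, alpha=0.1,
                         quantile_table=qtable_small)
        assert res.n_observed == 20
        assert res.k_hat == 0

    def test_input_validation(self, qtable_small):
        tree = ts.simulate_tree(10, "yule", seed=0)
        with pytest.raises(ValueError, match="alpha"):
            ts.treeseg(tree, np.zeros(10), alpha=1.5,
                       quantile_table=qtable_small)
        with pytest.raises(ValueError, match="observed"):
            ts.treeseg(tree, {}, alpha=0.1, quantile_table=qtable_small)
        with pytest.raises(ValueError, match="bernoulli"):
            ts.treeseg(tree, np.linspace(0, 2, 10), alpha=0.1,
                       quantile_table=qtable_small)

    def test_gaussian_family_segments_continuous_traits(self, qtable_small):
        tree = ts.simulate_tree(32, "perfect", seed=0)
        ordering = ts.standard_ordering(tree)
        rng = np.random.default_rng(9)
        y_pos = np.r_[rng.normal(3.0, 0.5, 16), rng.normal(0.0, 0.5, 16)]
        y = np.array([y_pos[ordering.position[leaf] - 1]
                      for leaf in tree.leaves])
        res = ts.treeseg(tree, y, alpha=0.1, family="gaussian",
                         ordering=ordering, quantile_table=qtable_small,
                         min_segment=2)
        assert res.k_hat == 1

    def test_random_ordering_majority_agrees_with_standard(self, qtable_small):
        tree = ts.simulate_tree(32, "perfect", seed=1)
        ordering = ts.standard_ordering(tree)
        y = np.empty(32)
        for pos, leaf in enumerate(ordering.order):
            y[leaf - 1] = 1.0 if pos < 16 else 0.0
        k_std = ts.treeseg(tree, y, alpha=0.1, ordering=ordering,
                           quantile_table=qtable_small, min_segment=2).k_hat
        ks = [ts.treeseg(tree, y, alpha=0.1, ordering="random",
                         ordering_seed=s, quantile_table=qtable_small,
                         min_segment=2).k_hat for s in range(5)]
        assert sorted(ks)[len(ks) // 2] == k_std


class TestAsymptoticBehaviour:
    def test_underestimation_decays_with_sample_size(self, qtable_512):
        """At a fixed signal (gap 0.5, clade a quarter of the tree) the rate
        of missing the active clade falls monotonically as n grows,
        vanishing by n = 200."""
        rates = []
        for n in (50, 100, 200):
            design = ts.SimulationDesign(
                n_leaves=n, k_true=1, clade_fraction=(0.25,),
                probs=(0.25, 0.75), n_reps=50, seed=31, alpha=0.1)
            study = ts.run_study(design, quantile_table=qtable_512)
            rates.append(study.aggregates["underestimation_rate"])
        se = math.sqrt(0.5 * 0.5 / 50)
        assert all(b <= a + 3 * se for a, b in zip(rates, rates[1:]))
        assert rates[-1] <= 0.05

    def test_localization_on_perfect_trees(self, qtable_512):
        """A single depth-2 active clade with a 0.9 probability gap on a
        256-leaf perfect tree is recovered as exactly the true node in at
        least 95% of replicates."""
        tree = ts.simulate_tree(256, "perfect", seed=0)
        ordering = ts.standard_ordering(tree)
        depth2 = [v for v in tree.inner_nodes
                  if len(tree.offspring_leaves(v)) == 64]
        rng = np.random.default_rng(17)
        hits = reps = 0
        for rep in range(40):
            v = depth2[rep % 4]
            p = np.full(256, 0.05)
            lo, hi = ordering.clade_interval[v]
            p[lo - 1: hi] = 0.95
            y_pos = rng.binomial(1, p).astype(float)
            y = np.empty(256)
            for pos, leaf in enumerate(ordering.order):
                y[leaf - 1] = y_pos[pos]
            res = ts.treeseg(tree, y, alpha=0.1, ordering=ordering,
                             quantile_table=qtable_512)
            reps += 1
            hits += (res.k_hat == 1 and res.active_nodes == [v])
        assert hits / reps >= 0.95


class TestOracleEquivalence:
    """Spot checks against exhaustive enumeration (bulk run in acceptance)."""

    @pytest.mark.parametrize("seed,k", [(0, 0), (1, 1), (2, 1), (3, 2)])
    def test_small_instances_match_enumeration(self, seed, k, qtable_small):
        tree, ordering, y_pos = _planted_instance(seed, n=11, k=k)
        q = ts.quantile(qtable_small, 0.1)
        oracle = EnumerationOracle(ordering, y_pos, q, min_segment=2)
        ok, feas, oll, onodes, (oblo, obhi) = oracle.solve(max_k=3)

        k_hat, _ = ts.estimate_k(y_pos, tree, ordering, q, min_segment=2)
        assert k_hat == ok
        _, ll, _ = ts.constrained_mle(y_pos, tree, ordering, q, k_hat,
                                      min_segment=2)
        assert ll == pytest.approx(oll, abs=1e-6)
        assert set(ts.node_confidence_set(y_pos, tree, ordering, q, k_hat,
                                          min_segment=2)) == onodes
        blo, bhi = ts.confidence_band(y_pos, tree, ordering, q, k_hat,
                                      min_segment=2)
        assert np.allclose(blo, oblo, atol=1e-6)
        assert np.allclose(bhi, obhi, atol=1e-6)
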