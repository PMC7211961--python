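import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import treeseg as ts
from treeseg.likelihood import BernoulliFamily, GaussianFamily

from oracles import brute_multiscale


class TestPenalty:
    def test_full_length_is_two(self):
        assert ts.penalty(100, 100) == pytest.approx(2.0)

    def test_scale_n_over_e(self):
        assert ts.penalty(100 / math.e, 100) == pytest.approx(4.0)

    def test_single_leaf(self):
        assert ts.penalty(1, 100) == pytest.approx(2 * math.log(100 * math.e))

    def test_monotone_decreasing(self):
        vals = ts.penalty(np.arange(1, 51), 50)
        assert np.all(np.diff(vals) < 0)

    def test_rejects_zero_length(self):
        with pytest.raises(ValueError):
            ts.penalty(0, 10)


class TestLocalLR:
    def test_all_ones_against_half(self):
        assert ts.local_lr([1, 1, 1, 1], 0.5) == pytest.approx(4 * math.log(2))

    def test_zero_at_the_mle(self):
        y = [1, 0, 1, 1, 0]
        assert ts.local_lr(y, np.mean(y)) == pytest.approx(0.0, abs=1e-12)

    def test_balanced_pair_against_half(self):
        assert ts.local_lr([1, 0], 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_discordant_boundary_is_infinite(self):
        assert ts.local_lr([1, 0], 0.0) == math.inf
        assert ts.local_lr([1, 0], 1.0) == math.inf

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            ts.local_lr([], 0.5)
        with pytest.raises(ValueError):
            ts.local_lr([np.nan], 0.5)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, size=rng.integers(2, 30)).astype(float)
            p = rng.uniform(0.05, 0.95)
            assert ts.local_lr(y, p) == pytest.approx(
                ts.local_lr(1 - y, 1 - p), rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=25),
           st.floats(0.01, 0.99))
    def test_nonnegative(self, y, p):
        assert ts.local_lr(y, p) >= 0.0

    def test_gaussian_closed_form(self):
        fam = GaussianFamily(sigma=2.0)
        y = np.array([1.0, 3.0, 2.0, 2.0])
        expected = 4 * (y.mean() - 0.5) ** 2 / (2 * 4.0)
        assert ts.local_lr(y, 0.5, fam) == pytest.approx(expected)

    def test_gaussian_sigma_estimate_on_pure_noise(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1.7, size=4000)
        assert GaussianFamily.estimate_sigma(y) == pytest.approx(1.7, rel=0.06)


class TestMeanBounds:
    def test_bounds_bracket_the_mle(self):
        fam = BernoulliFamily()
        rng = np.random.default_rng(1)
        m = rng.integers(1, 40, size=50).astype(float)
        s = np.floor(rng.uniform(0, m + 1)).clip(0, m)
        lo, hi = fam.mean_bounds(m, s, np.full(50, 1.5))
        assert np.all(lo <= s / m + 1e-12)
        assert np.all(hi >= s / m - 1e-12)
        # at the bound the LR equals the threshold (interior bounds only)
        interior = (lo > 1e-9) & (hi < 1 - 1e-9)
        assert np.allclose(fam.lr(m, s, lo)[interior], 1.5, atol=1e-8)
        assert np.allclose(fam.lr(m, s, hi)[interior], 1.5, atol=1e-8)

    def test_negative_threshold_poisons(self):
        fam = BernoulliFamily()
        lo, hi = fam.mean_bounds(np.array([5.0]), np.array([2.0]),
                                 np.array([-1.0]))
        assert lo[0] > hi[0]


class TestMultiscaleStatistic:
    def test_constant_fit_on_constant_data_is_negative(self):
        y = np.ones(20)
        stat = ts.multiscale_statistic(y, np.ones(20), min_segment=2)
        assert stat == pytest.approx(-math.sqrt(ts.penalty(20, 20)))

    def test_matches_bruteforce_on_four_leaves(self):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        p = np.full(4, 0.5)
        stat = ts.multiscale_statistic(y, p, min_segment=1)
        assert stat == pytest.approx(brute_multiscale(y, p, 1), abs=1e-12)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 2, size=n).astype(float)
            k = int(rng.integers(0, 3))
            cuts = sorted(rng.choice(np.arange(1, n), size=k, replace=False))
            p = np.empty(n)
            levels = rng.uniform(0.1, 0.9, size=k + 1)
            for seg, (a, b) in enumerate(zip([0, *cuts], [*cuts, n])):
                p[a:b] = levels[seg]
            ms = int(rng.integers(1, 4))
            assert ts.multiscale_statistic(y, p, min_segment=ms) == \
                pytest.approx(brute_multiscale(y, p, ms), abs=1e-12)

    def test_signal_resolution_through_ordering(self):
        tree = ts.read_newick("((A,B),(C,D));")
        o = ts.standard_ordering(tree)
        cherry = [v for v in tree.inner_nodes
                  if o.clade_interval[v] == (1, 2)][0]
        sig = ts.CladeSignal(baseline=0.5, active=[(cherry, 0.4)])
        y = np.array([1.0, 1.0, 0.0, 1.0])
        direct = ts.multiscale_statistic(y, sig.implied_vector(o),
                                         min_segment=2)
        assert ts.multiscale_statistic(y, sig, o, min_segment=2) == direct

    def test_missing_values_reindex_observed(self):
        y = np.array([1.0, np.nan, 1.0, 0.0, np.nan, 0.0])
        p = np.full(6, 0.5)
        stat = ts.multiscale_statistic(y, p, min_segment=2)
        expected = brute_multiscale([1, 1, 0, 0], [0.5] * 4, 2)
        assert stat == pytest.approx(expected, abs=1e-12)

    def test_true_signal_rarely_exceeds_null_quantile(self, qtable_512):
        # coverage transfer at modest size: the statistic of the true signal
        # exceeds q_{0.9} in at most ~10% of draws
        q = ts.quantile(qtable_512, 0.1)
        rng = np.random.default_rng(8)
        n, reps = 100, 200
        ms = ts.default_min_segment(n)
        exceed = sum(
            ts.multiscale_statistic(rng.binomial(1, 0.5, n).astype(float),
                                    np.full(n, 0.5), min_segment=ms) > q
            for _ in range(reps))
        se = math.sqrt(0.1 * 0.9 / reps)
        assert exceed / reps <= 0.1 + 3 * se
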