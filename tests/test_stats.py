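"""Bootstrap tests, Holm correction, effect sizes, percentile CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reachloss as rl


class TestBootstrapTest:
    def test_identical_constant_samples_give_p_one(self):
        res = rl.bootstrap_test(np.ones(8), np.ones(8), kind="two_sample",
                                n_resamples=2000, seed=0)
        assert res.p_value == 1.0

    def test_displaced_constant_samples_give_p_zero(self):
        res = rl.bootstrap_test(np.ones(8), np.zeros(8), kind="two_sample",
                                n_resamples=2000, seed=0)
        assert res.p_value == 0.0

    def test_one_sample_type_i_error_near_nominal(self):
        # binomial envelope around 0.05 for the simulation size used here
        rng = np.random.default_rng(55)
        n_sims = 1000
        rejections = 0
        for i in range(n_sims):
            a = rng.normal(size=20)
            res = rl.bootstrap_test(a, kind="one_sample", null_value=0.0,
                                    tails="two", n_resamples=2000, seed=i)
            rejections += res.p_value < 0.05
        rate = rejections / n_sims
        half_width = 3 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < half_width

    def test_two_sample_power_on_separated_groups(self):
        rng = np.random.default_rng(66)
        hits = 0
        for i in range(25):
            a = rng.normal(1.0, 1.0, 30)
            b = rng.normal(0.0, 1.0, 30)
            res = rl.bootstrap_test(a, b, kind="two_sample", tails="two",
                                    n_resamples=4000, seed=i)
            hits += res.p_value < 0.05
        assert hits >= 20  # >= 80% of seeded repeats

    def test_invariant_to_common_location_shift(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=15), rng.normal(0.5, 1, 15)
        r1 = rl.bootstrap_test(a, b, kind="two_sample", n_resamples=5000,
                               seed=3)
        r2 = rl.bootstrap_test(a + 100, b + 100, kind="two_sample",
                               n_resamples=5000, seed=3)
        assert r1.p_value == r2.p_value

    def test_invariant_to_sample_order_within_mc_error(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(0.7, 1, 20)
        r1 = rl.bootstrap_test(a, b, kind="two_sample", n_resamples=40_000,
                               seed=5)
        r2 = rl.bootstrap_test(a[::-1], b[::-1], kind="two_sample",
                               n_resamples=40_000, seed=5)
        assert abs(r1.p_value - r2.p_value) < 0.02

    def test_paired_equals_one_sample_on_differences(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.5, 1, 25)
        b = rng.normal(0.0, 1, 25)
        paired = rl.bootstrap_test(a, b, kind="paired", n_resamples=5000,
                                   seed=9)
        one = rl.bootstrap_test(a - b, kind="one_sample", n_resamples=5000,
                                seed=9)
        assert paired.p_value == one.p_value
        assert paired.kind == "paired"

    def test_permutation_variant_agrees_with_recentering(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.6, 1, 25)
        b = rng.normal(0.0, 1, 25)
        pr = rl.bootstrap_test(a, b, kind="two_sample",
                               method="permutation", n_resamples=20_000,
                               seed=4).p_value
        rc = rl.bootstrap_test(a, b, kind="two_sample", n_resamples=20_000,
                               seed=4).p_value
        assert abs(pr - rc) < 0.05

    def test_one_tailed_p_is_half_of_two_tailed_roughly(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.4, 1, 30)
        two = rl.bootstrap_test(a, kind="one_sample", tails="two",
                                n_resamples=50_000, seed=1).p_value
        one = rl.bootstrap_test(a, kind="one_sample", tails="greater",
                                n_resamples=50_000, seed=1).p_value
        assert one == pytest.approx(two / 2, abs=0.02)

    def test_low_resample_count_warns(self):
        with pytest.warns(UserWarning):
            rl.bootstrap_test(np.arange(5.0), kind="one_sample",
                              n_resamples=100, seed=0)

    def test_determinism(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=12)
        r1 = rl.bootstrap_test(a, kind="one_sample", n_resamples=3000,
                               seed=8)
        r2 = rl.bootstrap_test(a, kind="one_sample", n_resamples=3000,
                               seed=8)
        assert r1.p_value == r2.p_value and r1.ci_95 == r2.ci_95


class TestHolmBonferroni:
    def test_two_element_analytic_example(self):
        assert np.allclose(rl.holm_bonferroni([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        assert rl.holm_bonferroni([0.2]) == pytest.approx([0.2])

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_dominance_and_cap(self, ps):
        adj = rl.holm_bonferroni(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rl.holm_bonferroni([0.5, 1.2])


class TestCommonLanguageEffect:
    def test_identical_samples_give_50(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert rl.common_language_effect(x, x) == pytest.approx(50.0)

    def test_fully_separated_samples_give_100(self):
        assert rl.common_language_effect([5, 6, 7], [1, 2, 3]) == 100.0

    def test_exhaustive_nine_pair_enumeration(self):
        # pairs of a=(1,2,3) vs b=(2,3,4): one win (3>2) plus two ties
        # counted half -> 2/9
        theta = rl.common_language_effect([1, 2, 3], [2, 3, 4])
        assert theta == pytest.approx(100 * 2 / 9)

    def test_complement_identity_for_tie_free_samples(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=40), rng.normal(size=35)
        assert rl.common_language_effect(a, b) + rl.common_language_effect(
            b, a
        ) == pytest.approx(100.0)

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(1, 1, 200), rng.normal(0, 1, 200)
        exact = rl.common_language_effect(a, b)
        mc = rl.common_language_effect(a, b, seed=1, max_exact=10_000)
        assert mc == pytest.approx(exact, abs=2.0)


class TestPercentileCI:
    def test_constant_sample_zero_width(self):
        lo, hi = rl.percentile_ci(np.full(10, 3.0), seed=0)
        assert lo == hi == 3.0

    def test_coverage_near_95(self):
        rng = np.random.default_rng(19)
        cover = 0
        n_rep = 600
        for i in range(n_rep):
            x = rng.normal(size=100)
            lo, hi = rl.percentile_ci(x, n_boot=1000, seed=i)
            cover += lo <= 0.0 <= hi
        assert 0.92 <= cover / n_rep <= 0.98

    def test_interval_ordered_and_nested_in_wider_level(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=50)
        lo95, hi95 = rl.percentile_ci(x, level=95, seed=2)
        lo99, hi99 = rl.percentile_ci(x, level=99, seed=2)
        assert lo95 <= hi95
        assert lo99 <= lo95 and hi95 <= hi99

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rl.percentile_ci([1.0])
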