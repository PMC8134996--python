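"""Exactness and conventions of the statistical battery."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps

from woundmetrics.errors import DegenerateSampleError, ValidationError
from woundmetrics.stats import (
    chi_square_gof,
    fisher_exact_2x2,
    format_p,
    paired_t,
    wilcoxon_signed_rank,
)


def brute_wilcoxon_p(d):
    """Two-sided exact signed-rank p by literal enumeration of 2^n sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    lower = upper = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        lower += w <= w_obs + 1e-9
        upper += w >= w_obs - 1e-9
    total = 2**n
    return min(1.0, 2 * min(lower / total, upper / total))


class TestWilcoxon:
    def test_all_positive_small_sample_exact(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.25)  # 2 * 1/8
        assert res.exact

    def test_tied_magnitudes_get_midranks(self):
        res = wilcoxon_signed_rank(np.array([1.0, -1.0]))
        assert res.statistic == 1.5
        assert res.p_value == 1.0

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_zero_differences_discarded_before_ranking(self):
        # zeros removed: effective n is 3, matching the pure-difference call
        a = wilcoxon_signed_rank([1.0, 2.0, 3.0, 5.0], [1.0, 0.0, 0.0, 0.0])
        b = wilcoxon_signed_rank([2.0, 3.0, 5.0])
        assert a.n == b.n == 3 and a.p_value == b.p_value

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_path_matches_literal_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        d = np.round(rng.normal(size=n) * 4) / 2
        d = np.where(d == 0, 0.5, d)
        res = wilcoxon_signed_rank(d)
        assert res.exact
        assert res.p_value == pytest.approx(brute_wilcoxon_p(d), abs=1e-12)

    def test_exact_matches_scipy_exact_mode(self):
        rng = np.random.default_rng(7)
        d = rng.normal(size=15)  # continuous: no ties, scipy exact applies
        ours = wilcoxon_signed_rank(d)
        theirs = sps.wilcoxon(d, mode="exact")
        assert ours.p_value == pytest.approx(theirs.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = rng.normal(size=25)
            exact = wilcoxon_signed_rank(d, method="exact")
            approx = wilcoxon_signed_rank(d, method="approx")
            assert exact.exact and not approx.exact
            assert abs(exact.p_value - approx.p_value) <= 0.02


class TestFisher:
    def test_strong_association_two_sided(self):
        res = fisher_exact_2x2([[1, 9], [9, 1]])
        assert res.p_value == pytest.approx(0.0011, abs=2e-4)
        assert res.exact

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == 1.0

    def test_reviewer_agreement_example_rounds_to_01(self):
        res = fisher_exact_2x2([[42, 58], [116, 84]])
        assert round(res.p_value, 2) == 0.01

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_two_sided(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 30, size=(2, 2))
        ours = fisher_exact_2x2(t)
        theirs = sps.fisher_exact(t, alternative="two-sided")
        assert ours.p_value == pytest.approx(theirs.pvalue, rel=1e-7)

    def test_transpose_invariance(self, rng):
        for _ in range(20):
            t = rng.integers(0, 25, size=(2, 2))
            assert fisher_exact_2x2(t).p_value == pytest.approx(
                fisher_exact_2x2(t.T).p_value, rel=1e-9
            )

    def test_negative_or_fractional_entries_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1, -2], [3, 4]])
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])


class TestChiSquare:
    def test_uniform_counts_give_zero_statistic(self):
        res = chi_square_gof([10, 10, 10])
        assert res.statistic == 0 and res.p_value == 1.0

    def test_selection_bias_example(self):
        res = chi_square_gof([3, 36, 50])
        assert res.statistic == pytest.approx(39.26, abs=0.01)
        assert res.p_value < 0.001

    def test_moderate_bias_statistic(self):
        res = chi_square_gof([37, 39, 29])
        assert res.statistic == pytest.approx(1.6, abs=0.02)
        assert res.details["df"] == 2

    def test_all_one_category(self):
        res = chi_square_gof([12, 0, 0])
        assert res.statistic == pytest.approx(24.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_gof([0, 0, 0])


class TestPairedT:
    def test_zero_mean_differences(self):
        res = paired_t(np.array([1.0, -1.0, 1.0, -1.0]))
        assert res.statistic == 0 and res.p_value == 1.0

    def test_constant_differences_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            paired_t(np.array([2.0, 2.0, 2.0]))

    def test_hand_computed_example(self):
        res = paired_t(np.array([1.0, 2.0, 3.0]))
        assert res.statistic == pytest.approx(3.464, abs=1e-3)
        assert res.details["df"] == 2
        assert res.p_value == pytest.approx(0.0742, abs=1e-3)

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=(2, 20))
        ours = paired_t(x, y)
        theirs = sps.ttest_rel(x, y)
        assert ours.p_value == pytest.approx(theirs.pvalue, rel=1e-10)


class TestTypeIError:
    """Each test's rejection rate under its own null stays near alpha=.05.

    Smaller replicate counts than the dedicated acceptance check; these are
    fast smoke versions.
    """

    def test_paired_t_and_chi_square_sizes(self, rng):
        reps = 2000
        d = rng.normal(size=(reps, 20))
        rej_t = np.mean([paired_t(row).p_value < 0.05 for row in d])
        counts = rng.multinomial(90, [1 / 3] * 3, size=reps)
        rej_c = np.mean([chi_square_gof(c).p_value < 0.05 for c in counts])
        assert 0.03 <= rej_t <= 0.07
        assert 0.03 <= rej_c <= 0.07


class TestFormatting:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0005, "<.001"), (0.010094, ".0101"), (0.47, ".47"), (1.0, "1.0")],
    )
    def test_journal_style_p_formatting(self, p, expected):
        assert format_p(p) == expected

    def test_p_values_always_in_unit_interval(self, rng):
        for _ in range(50):
            d = rng.normal(size=int(rng.integers(2, 30)))
            if np.all(d == d[0]):
                continue
            assert 0 <= wilcoxon_signed_rank(d).p_value <= 1
            assert 0 <= paired_t(d).p_value <= 1
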