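import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata

from skeletochron.errors import AlignmentError, DegenerateSampleError
from skeletochron.stats import (
    PairedDiffSet,
    column_summary,
    mean_absolute_difference,
    paired_differences,
    round_half_away,
    standard_error,
    wilcoxon_signed_rank,
)

# printed difference column of the validation table (measured - estimated)
TABLE1_DIFFS = (0.0, -0.2, -0.4, 0.6, 0.4, -0.8, 0.0, -0.3, -1.5, 0.0)
TABLE1_MEASURED = [55.1, 69.4, 55.9, 70.6, 44.7, 83.8, 54.8, 57.4, 45.5, 51.0]
TABLE1_ESTIMATED = [55.1, 69.6, 56.3, 70.0, 44.3, 84.6, 54.8, 57.7, 47.0, 51.0]
TABLE2_DIFFS = (-0.8, 0.0, -0.2, -0.3, 0.0)


def brute_force_wilcoxon(diffs):
    """Literal enumeration of all 2^N sign assignments (independent oracle)."""
    d = np.asarray([x for x in diffs if x != 0.0])
    n = d.size
    ranks = rankdata(np.abs(d))
    t_plus = ranks[d > 0].sum()
    t = min(t_plus, ranks.sum() - t_plus)
    total = ranks.sum()
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= t + 1e-9 or w >= total - t - 1e-9:
            hits += 1
    return float(t), n, min(1.0, hits / 2.0**n)


def test_rounding_is_half_away_from_zero():
    assert round_half_away(-0.15) == -0.2
    assert round_half_away(0.15) == 0.2
    assert round_half_away(-0.197) == -0.2
    assert round_half_away(0.04) == 0.0


class TestPairedDifferences:
    def test_printed_columns_give_printed_differences(self):
        out = paired_differences(TABLE1_MEASURED, TABLE1_ESTIMATED)
        assert out.differences == TABLE1_DIFFS

    def test_single_pair(self):
        assert paired_differences([83.8], [84.6]).differences == (-0.8,)

    def test_identical_pair_gives_zero(self):
        assert paired_differences([50.0], [50.0]).differences == (0.0,)

    def test_length_mismatch_is_alignment_error(self):
        with pytest.raises(AlignmentError):
            paired_differences([1.0, 2.0], [1.0])


class TestWilcoxonSignedRank:
    def test_printed_difference_vector(self):
        t, n, p = wilcoxon_signed_rank(TABLE1_DIFFS)
        assert t == 8.5
        assert n == 7
        assert p > 0.20

    def test_all_positive_small_sample(self):
        # all 8 sign assignments enumerated by hand: only the all-negative
        # and all-positive assignments reach T = 0, p = 2/8
        t, n, p = wilcoxon_signed_rank((1.0, 2.0, 3.0))
        assert (t, n) == (0.0, 3)
        assert p == pytest.approx(0.25)

    def test_all_zero_differences_are_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            wilcoxon_signed_rank((0.0, 0.0))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        # one-decimal rounding induces ties and occasional zeros
        d = np.round(rng.normal(0, 1, size=n), 1)
        if np.all(d == 0):
            return
        t_b, n_b, p_b = brute_force_wilcoxon(d)
        t, n_eff, p = wilcoxon_signed_rank(tuple(d))
        assert t == pytest.approx(t_b)
        assert n_eff == n_b
        assert p == pytest.approx(p_b, abs=1e-12)

    @given(st.lists(st.floats(-5, 5).map(lambda x: round(x, 1)), min_size=1, max_size=20))
    def test_rank_sums_are_conserved(self, diffs):
        d = np.asarray([x for x in diffs if x != 0.0])
        if d.size == 0:
            return
        ranks = rankdata(np.abs(d))
        t_plus = ranks[d > 0].sum()
        t_minus = ranks[d < 0].sum()
        assert t_plus + t_minus == pytest.approx(d.size * (d.size + 1) / 2)
        t, n, _ = wilcoxon_signed_rank(tuple(d))
        assert t == pytest.approx(min(t_plus, t_minus))
        assert t <= n * (n + 1) / 4  # min of two halves never exceeds the midpoint


class TestMeanAbsoluteDifference:
    def test_printed_vector_gives_printed_mean(self):
        diffs = paired_differences(TABLE1_MEASURED, TABLE1_ESTIMATED,
                                   ids=[f"T{i}" for i in range(10)])
        assert mean_absolute_difference(diffs) == 0.4

    def test_excluding_the_fallback_turtle(self):
        ids = ["CM-1", "CM-4", "CM-6", "CM-8", "CM-9",
               "CM-10", "CM-11", "CM-12", "CM-13", "CM-14"]
        diffs = PairedDiffSet(tuple(ids), TABLE1_DIFFS)
        assert mean_absolute_difference(diffs, exclude_ids=["CM-13"]) == 0.3

    def test_all_zero_gives_zero(self):
        assert mean_absolute_difference(PairedDiffSet(("a", "b"), (0.0, 0.0))) == 0.0

    def test_sign_flip_invariance(self):
        flipped = tuple(-d for d in TABLE1_DIFFS)
        assert mean_absolute_difference(
            PairedDiffSet(tuple("abcdefghij"), flipped)
        ) == 0.4

    def test_empty_after_exclusion_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            mean_absolute_difference(PairedDiffSet(("a",), (1.0,)), exclude_ids=["a"])


class TestStandardError:
    def test_printed_otc_differences(self):
        assert round_half_away(standard_error(TABLE2_DIFFS), 1) == 0.1

    def test_constant_vector_gives_zero(self):
        assert standard_error((0.3, 0.3, 0.3)) == 0.0

    def test_two_point_closed_form(self):
        # |0|, |1|: sd = sqrt(0.5), SE = sqrt(0.5)/sqrt(2) = 0.5
        assert standard_error((0.0, 1.0)) == pytest.approx(0.5)

    def test_short_sample_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            standard_error((1.0,))


class TestColumnSummary:
    def test_measured_column(self):
        assert column_summary(TABLE1_MEASURED) == (58.8, 12.3, 44.7, 83.8)

    def test_estimated_column(self):
        assert column_summary(TABLE1_ESTIMATED) == (59.0, 12.3, 44.3, 84.6)

    def test_identical_values(self):
        mean, sd, lo, hi = column_summary((50.0, 50.0, 50.0))
        assert (mean, sd) == (50.0, 0.0) and lo == hi == 50.0


def test_exact_test_is_conservative_under_symmetric_null():
    """Type-I error of the exact test at nominal alpha = 0.05, N = 7.

    The discrete null distribution makes the achievable size 6/128 ~ 0.047;
    the Monte-Carlo rejection rate must not exceed nominal + 3 binomial SE.
    """
    rng = np.random.default_rng(20260930)
    n_rep, alpha, n = 2000, 0.05, 7
    rejections = sum(
        wilcoxon_signed_rank(tuple(rng.normal(0, 1, size=n))).p <= alpha
        for _ in range(n_rep)
    )
    rate = rejections / n_rep
    margin = 3 * math.sqrt(alpha * (1 - alpha) / n_rep)
    assert rate <= alpha + margin
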