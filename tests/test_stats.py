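import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from selacq import BehaviorDataset
from selacq.stats import (
    InsufficientDataError,
    compare_groups,
    dot_product_surrogate_test,
    filter_by_confidence,
    letter_reassignment_surrogate_test,
    normalize_lengths,
    probability_of_superiority,
)
from conftest import make_subject


class TestNormalizeLengths:
    def test_division_by_subject_total(self):
        out = normalize_lengths([100, 300, 0, 600])
        assert np.allclose(out, [0.1, 0.3, 0.0, 0.6])
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_nonzero_essay(self):
        assert np.allclose(normalize_lengths([0, 250, 0]), [0, 1.0, 0])

    def test_all_zero_subject_rejected(self):
        with pytest.raises(InsufficientDataError):
            normalize_lengths([0, 0, 0])


class TestConfidenceBands:
    def test_boundary_75_in_lower_band_only(self):
        c = np.array([75.0])
        assert filter_by_confidence(c, "lower")[0]
        assert not filter_by_confidence(c, "upper")[0]

    def test_49_excluded_from_analyzed(self):
        assert not filter_by_confidence([49.0], "analyzed")[0]
        assert filter_by_confidence([50.0], "analyzed")[0]

    def test_100_in_upper_and_certain(self):
        assert filter_by_confidence([100.0], "upper")[0]
        assert filter_by_confidence([100.0], "certain")[0]
        assert not filter_by_confidence([99.0], "certain")[0]

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError):
            filter_by_confidence([50.0], "middle")


class TestProbabilityOfSuperiority:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((3, 5), (1, 2), 1.0),
            ((1, 3), (2, 4), 0.25),
            ((2, 2), (2, 2), 0.5),  # all ties, half credit
        ],
    )
    def test_examples(self, a, b, expected):
        assert probability_of_superiority(a, b) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            probability_of_superiority([], [1.0])

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=8),
        st.lists(st.integers(0, 5), min_size=1, max_size=8),
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_exhaustive_pair_enumeration(self, a, b):
        wins = sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x, y in itertools.product(a, b)
        )
        assert probability_of_superiority(a, b) == pytest.approx(
            wins / (len(a) * len(b))
        )

    @given(
        st.lists(st.integers(0, 4), min_size=2, max_size=8),
        st.lists(st.integers(0, 4), min_size=2, max_size=8),
    )
    @settings(deadline=None, max_examples=100)
    def test_consistent_with_mann_whitney_u(self, a, b):
        """PS = U_a / (n_a n_b) under the midrank/half-tie convention."""
        u = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
        assert probability_of_superiority(a, b) == pytest.approx(
            u / (len(a) * len(b))
        )


class TestCompareGroups:
    def test_identical_groups_one_sided_p_at_least_half(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        for test in ("mann-whitney", "t-independent"):
            res = compare_groups(x, x, test=test, n_boot=200, seed=0)
            assert res.p_value >= 0.5

    def test_paired_constant_shift_flagged_degenerate(self):
        b = np.array([1.0, 2.0, 3.0])
        res = compare_groups(b + 10, b, test="t-paired", n_boot=100, seed=0)
        assert res.degenerate
        assert np.isnan(res.effect_size)

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1, 2, 3], [1, 2], test="t-paired")

    def test_bootstrap_ci_brackets_location(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 1, 200)
        res = compare_groups(a, a - 5, test="t-independent", n_boot=2000, seed=2)
        assert res.ci_a[0] < 10 < res.ci_a[1]
        assert res.ci_b[0] < 5 < res.ci_b[1]
        assert res.effect_size == pytest.approx(5.0, rel=0.2)

    def test_mann_whitney_power_on_planted_shift(self):
        """One-sd location shift at n=30/30 is detected in >= 90% of replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(1.0, 1.0, 30)
            b = rng.normal(0.0, 1.0, 30)
            res = compare_groups(a, b, test="mann-whitney", n_boot=10, seed=0)
            hits += res.p_value < 0.05
        assert hits / n_rep >= 0.9


class TestDotProductSurrogate:
    def test_hand_computed_single_subject_statistic(self):
        # conf (80, 60) -> unit (0.8, 0.6); lengths (80, 20) -> unit ~(0.9701, 0.2425)
        ds = BehaviorDataset([make_subject("s0", [80, 60], [80, 20])])
        res = dot_product_surrogate_test(ds, n_surrogate=50, seed=0)
        expected = 0.8 * (80 / np.hypot(80, 20)) + 0.6 * (20 / np.hypot(80, 20))
        assert res.observed_stat == pytest.approx(expected, abs=1e-12)
        assert res.observed_stat == pytest.approx(0.9215, abs=1e-3)

    def test_parallel_vectors_reach_theoretical_max(self):
        subs = [
            make_subject(f"s{k}", [90, 80, 60, 50], [9, 8, 6, 5]) for k in range(4)
        ]
        res = dot_product_surrogate_test(BehaviorDataset(subs), n_surrogate=200, seed=0)
        assert res.observed_stat == pytest.approx(4.0)
        assert res.theoretical_max == 4.0
        # minimal attainable p with the +1 correction
        assert res.p_value <= (1 + np.count_nonzero(res.null_samples >= 4.0 - 1e-12)) / 201

    def test_invariant_to_positive_rescaling_of_lengths(self):
        s1 = make_subject("a", [90, 70, 55], [100, 40, 10])
        s2 = make_subject("a", [90, 70, 55], [300, 120, 30])  # x3
        r1 = dot_product_surrogate_test(BehaviorDataset([s1]), 100, seed=5)
        r2 = dot_product_surrogate_test(BehaviorDataset([s2]), 100, seed=5)
        assert r1.observed_stat == pytest.approx(r2.observed_stat)
        assert np.allclose(r1.null_samples, r2.null_samples)

    def test_subjects_below_confidence_50_excluded(self):
        subs = [
            make_subject("keep", [80, 60, 55], [10, 20, 5]),
            make_subject("drop", [40, 30, 10], [10, 20, 5]),  # nothing analyzed
        ]
        res = dot_product_surrogate_test(BehaviorDataset(subs), 50, seed=0)
        assert res.n_subjects == 1
        assert res.n_excluded == 1

    def test_no_qualifying_subjects_rejected(self):
        ds = BehaviorDataset([make_subject("s", [20, 30], [5, 5])])
        with pytest.raises(InsufficientDataError):
            dot_product_surrogate_test(ds, 50, seed=0)


class TestLetterReassignmentSurrogate:
    def test_hand_computed_contribution_and_null_mean(self):
        # one spontaneous 30-letter and one forced 10-letter certain word:
        # observed share 0.75; multinomial(40, uniform over 2) mean share 0.5
        s = make_subject(
            "s0", [100, 100], [30, 10], condition=["spontaneous", "forced"]
        )
        res = letter_reassignment_surrogate_test(
            BehaviorDataset([s]), n_surrogate=4000, seed=0
        )
        assert res.observed_stat == pytest.approx(0.75)
        assert np.mean(res.null_samples) == pytest.approx(0.5, abs=0.01)

    def test_only_spontaneous_certain_words_contribute_one_everywhere(self):
        s = make_subject("s0", [100, 100, 80], [30, 10, 5])
        res = letter_reassignment_surrogate_test(
            BehaviorDataset([s]), n_surrogate=100, seed=1
        )
        assert res.observed_stat == 1.0
        assert np.all(res.null_samples == 1.0)

    def test_invariant_to_rescaling_up_to_multinomial_granularity(self):
        """Scaling all lengths x10 leaves the observed statistic unchanged."""
        s1 = make_subject("a", [100, 100], [30, 10], ["spontaneous", "forced"])
        s2 = make_subject("a", [100, 100], [300, 100], ["spontaneous", "forced"])
        r1 = letter_reassignment_surrogate_test(BehaviorDataset([s1]), 100, seed=2)
        r2 = letter_reassignment_surrogate_test(BehaviorDataset([s2]), 100, seed=2)
        assert r1.observed_stat == pytest.approx(r2.observed_stat)

    def test_no_certain_words_rejected(self):
        ds = BehaviorDataset([make_subject("s", [90, 80], [10, 10])])
        with pytest.raises(InsufficientDataError):
            letter_reassignment_surrogate_test(ds, 50, seed=0)


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=60)
def test_surrogate_statistics_within_theoretical_bounds(seed):
    """Observed and null statistics live in [0, n_subjects] for both tests."""
    rng = np.random.default_rng(seed)
    subs = []
    for k in range(rng.integers(2, 6)):
        n = int(rng.integers(3, 10))
        subs.append(
            make_subject(
                f"s{k}",
                rng.integers(0, 101, n),
                rng.integers(0, 200, n),
                condition=list(rng.choice(["spontaneous", "forced"], n)),
            )
        )
    ds = BehaviorDataset(subs)
    for fn in (dot_product_surrogate_test, letter_reassignment_surrogate_test):
        try:
            res = fn(ds, n_surrogate=50, seed=seed)
        except InsufficientDataError:
            continue
        assert 0.0 <= res.observed_stat <= res.theoretical_max + 1e-9
        assert np.all(res.null_samples >= -1e-9)
        assert np.all(res.null_samples <= res.theoretical_max + 1e-9)
        assert 0.0 < res.p_value <= 1.0
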