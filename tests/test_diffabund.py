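"""Mann-Whitney test, fold-change ratio, and up/down classification."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dkdprot.diffabund import (
    RatioSentinel,
    Thresholds,
    classify,
    differential_abundance,
    exact_null_size,
    group_ratio,
    mann_whitney,
)
from dkdprot.io import GroupDesign, MasterTable


def permutation_pvalue(xs, ys):
    """Independent oracle: exact two-sided Mann-Whitney p by enumerating all
    C(n1+n2, n1) assignments of the pooled ranks (tie-free data only)."""
    pooled = sorted(xs + ys)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in xs)
    n = len(pooled)
    dist = [sum(c) for c in combinations(range(1, n + 1), len(xs))]
    total = len(dist)
    lower = sum(w <= w_obs for w in dist)
    upper = sum(w >= w_obs for w in dist)
    return min(1.0, 2.0 * min(lower, upper) / total)


class TestMannWhitney:
    def test_most_extreme_two_vs_two(self):
        assert mann_whitney([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_interleaved_two_vs_two(self):
        assert mann_whitney([1, 3], [2, 4]) == pytest.approx(2 / 3)

    def test_identical_samples_give_one(self):
        assert mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0
        assert mann_whitney([5.0, 5.0], [5.0, 5.0]) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 5), (3, 3), (3, 6), (4, 5), (6, 6)])
    def test_matches_enumeration_oracle_without_ties(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            xs = list(rng.normal(0, 1, n1))
            ys = list(rng.normal(0.5, 1, n2))
            assert mann_whitney(xs, ys) == pytest.approx(
                permutation_pvalue(xs, ys), abs=1e-12
            )

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=9),
        st.lists(st.floats(-50, 50), min_size=1, max_size=9),
    )
    def test_symmetry_in_arguments(self, xs, ys):
        assert mann_whitney(xs, ys) == pytest.approx(mann_whitney(ys, xs))

    def test_smallest_attainable_p_matches_group_sizes(self):
        # 8 vs 7 tie-free samples: most extreme arrangement has p = 2/C(15,7)
        xs = list(range(8))
        ys = [x + 100 for x in range(7)]
        assert mann_whitney(xs, ys) == pytest.approx(2 / math.comb(15, 7))

    def test_exact_null_size_eight_vs_seven(self):
        # achievable size is below the nominal 0.05 because p is discrete
        size = exact_null_size(8, 7, 0.05)
        assert 0 < size <= 0.05
        assert size == pytest.approx(0.0400932400932, abs=1e-10)


class TestGroupRatio:
    def test_ratio_of_detected_means(self):
        assert group_ratio([2, 4], [1, 2]) == pytest.approx(2.0)

    def test_only_in_control_sentinel(self):
        assert group_ratio([np.nan, np.nan], [5, 6]) is RatioSentinel.ONLY_IN_CONTROL

    def test_only_in_case_sentinel(self):
        assert group_ratio([5.0], [np.nan]) is RatioSentinel.ONLY_IN_CASE

    def test_identity(self):
        assert group_ratio([3.0], [3.0]) == pytest.approx(1.0)

    def test_both_missing_is_hard_error(self):
        with pytest.raises(ValueError, match="both groups"):
            group_ratio([np.nan], [np.nan, np.nan])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0.01, 1e6), min_size=1, max_size=8),
        st.lists(st.floats(0.01, 1e6), min_size=1, max_size=8),
    )
    def test_reciprocal_symmetry(self, case, control):
        r = group_ratio(case, control)
        assert group_ratio(control, case) == pytest.approx(1.0 / r)


class TestClassification:
    @pytest.mark.parametrize(
        "p,ratio,expected",
        [
            (0.000311, 2.94, "up"),  # glutaminase, early stage
            (0.000622, 0.2499, "down"),  # NUDT19, early stage
            (0.5, 3.0, "unchanged"),  # fails alpha regardless of ratio
            (0.04, 1.2, "unchanged"),  # significant but ratio in dead zone
            (0.05, 1.5, "up"),  # boundaries are inclusive
            (0.05, 0.67, "down"),
            (0.00215, RatioSentinel.ONLY_IN_CONTROL, "down"),  # "only in wt"
            (0.01, RatioSentinel.ONLY_IN_CASE, "up"),
            (0.5, RatioSentinel.ONLY_IN_CONTROL, "unchanged"),
        ],
    )
    def test_threshold_rules(self, p, ratio, expected):
        assert classify(p, ratio) == expected

    @settings(deadline=None, max_examples=100)
    @given(
        st.floats(0, 1),
        st.one_of(
            st.floats(0, 1000),
            st.sampled_from([RatioSentinel.ONLY_IN_CASE, RatioSentinel.ONLY_IN_CONTROL]),
        ),
    )
    def test_trichotomy(self, p, ratio):
        assert classify(p, ratio) in {"up", "down", "unchanged"}

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(alpha=0.05, up_cut=0.9, down_cut=0.67)


class TestDifferentialAbundance:
    @pytest.fixture
    def comparison(self):
        # 4 vs 4 samples: the smallest exact two-sided p is 2/C(8,4) < 0.05
        design = GroupDesign(
            groups={"case": ("c1", "c2", "c3", "c4"), "ctrl": ("w1", "w2", "w3", "w4")}
        )
        data = pd.DataFrame(
            {
                "c1": [400.0, 100.0, np.nan],
                "c2": [410.0, 105.0, np.nan],
                "c3": [420.0, 95.0, np.nan],
                "c4": [415.0, 101.0, np.nan],
                "w1": [100.0, 100.0, 50.0],
                "w2": [105.0, 103.0, 55.0],
                "w3": [95.0, 99.0, 60.0],
                "w4": [110.0, 97.0, 52.0],
            },
            index=["UP", "FLAT", "ONLYWT"],
        )
        return MasterTable(data=data, normalized=True), design

    def test_classifications_and_counts(self, comparison):
        table, design = comparison
        recs = {r.accession: r for r in differential_abundance(table, "case", "ctrl", design)}
        assert recs["UP"].classification == "up"
        assert recs["UP"].ratio == pytest.approx(411.25 / 102.5)
        assert recs["FLAT"].classification == "unchanged"
        assert recs["ONLYWT"].ratio is RatioSentinel.ONLY_IN_CONTROL
        assert recs["ONLYWT"].n_detected_case == 0
        assert recs["ONLYWT"].n_detected_control == 4
        # zeros entered in the rank test give absences a p-value
        assert recs["ONLYWT"].p_value < 0.2

    def test_case_equals_control_rejected(self, comparison):
        table, design = comparison
        with pytest.raises(ValueError, match="must differ"):
            differential_abundance(table, "case", "case", design)

    def test_unnormalized_table_rejected(self, comparison):
        table, design = comparison
        raw = MasterTable(data=table.data, normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            differential_abundance(raw, "case", "ctrl", design)
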