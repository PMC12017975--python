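"""Categorization cut-offs, relevance thresholds, and group comparisons."""

import numpy as np
import pytest

from contour_iov import (
    GroupSummary,
    MetricRecord,
    SubtypeDefinition,
    categorize,
    consistency_assessment,
    group_summary,
    mann_whitney_u,
    median_difference,
    pooled_comparison,
    subtype_comparison,
)
from contour_iov.stats import (
    DETERIORATION,
    IMPROVEMENT,
    NO_DIFFERENCE,
    large_radiologist_variation_cases,
)

from conftest import exact_mwu_p


def summary_with_median(value, n=5):
    return GroupSummary(n=n, median=value, iqr=(value, value), range=(value, value))


def record(case_id, group, dsc=0.8, sdsc=0.8, hd98=5.0, observer_id="o"):
    return MetricRecord(
        case_id=case_id,
        observer_id=observer_id,
        group=group,
        dsc=dsc,
        sdsc=sdsc,
        hd98=hd98,
        mda_mean=1.0,
        mda_sd=0.5,
        observer_volume=100.0,
        reference_volume=100.0,
    )


class TestCategorize:
    @pytest.mark.parametrize(
        "metric,value,expected",
        [
            ("SDSC", 0.84, "little"),
            ("SDSC", 0.58, "large"),
            ("DSC", 0.599999, "large"),
            ("DSC", 0.6, "average"),  # lower boundary is inclusive upward
            ("DSC", 0.8, "little"),
            ("SDSC", 0.7999, "average"),
            ("HD98", 9.99, "little"),
            ("HD98", 10.0, "average"),  # 10 mm <= HD98 < 20 mm
            ("HD98", 19.99, "average"),
            ("HD98", 20.0, "large"),
            ("HD98", 35.0, "large"),
        ],
    )
    def test_boundary_semantics(self, metric, value, expected):
        assert categorize(metric, value) == expected

    def test_unknown_metric_raises(self):
        with pytest.raises(ValueError):
            categorize("MDA", 1.0)


class TestMedianDifference:
    def test_hd98_decrease_is_an_improvement(self):
        d = median_difference(summary_with_median(22.0), summary_with_median(5.0), "HD98")
        assert d.absolute_difference == pytest.approx(-17.0)
        assert d.category == IMPROVEMENT

    def test_zero_difference_is_no_relevant_difference(self):
        d = median_difference(summary_with_median(0.75), summary_with_median(0.75), "SDSC")
        assert d.category == NO_DIFFERENCE

    def test_dsc_increase_beyond_threshold_is_improvement(self):
        d = median_difference(summary_with_median(0.60), summary_with_median(0.75), "DSC")
        assert d.absolute_difference == pytest.approx(0.15)
        assert d.category == IMPROVEMENT

    @pytest.mark.parametrize(
        "metric,minus,plus,expected",
        [
            ("DSC", 0.6, 0.7, NO_DIFFERENCE),  # exactly at threshold: not relevant
            ("HD98", 10.0, 7.0, NO_DIFFERENCE),
            ("HD98", 10.0, 14.0, DETERIORATION),
            ("SDSC", 0.9, 0.75, DETERIORATION),
        ],
    )
    def test_thresholds_are_exclusive_and_signed(self, metric, minus, plus, expected):
        d = median_difference(summary_with_median(minus), summary_with_median(plus), metric)
        assert d.category == expected


class TestConsistency:
    def _diffs(self, cats):
        return [
            median_difference(summary_with_median(a), summary_with_median(b), m)
            for m, (a, b) in zip(("SDSC", "DSC", "HD98"), cats)
        ]

    def test_all_improved_all_worse_and_mixed(self):
        improved = self._diffs([(0.5, 0.7), (0.5, 0.7), (20.0, 5.0)])
        assert consistency_assessment(improved) == "consistent improvement"
        worse = self._diffs([(0.7, 0.5), (0.7, 0.5), (5.0, 20.0)])
        assert consistency_assessment(worse) == "consistent deterioration"
        mixed = self._diffs([(0.5, 0.7), (0.7, 0.7), (20.0, 5.0)])
        assert consistency_assessment(mixed) == "mixed/none"

    def test_missing_metric_raises(self):
        with pytest.raises(ValueError):
            consistency_assessment(self._diffs([(0.5, 0.7), (0.5, 0.7), (20.0, 5.0)])[:2])


class TestGroupSummary:
    def test_odd_even_and_ordering(self):
        s = group_summary([3, 1, 2])
        assert s.median == 2 and s.range == (1, 3)
        assert group_summary([1, 2, 3, 4]).median == 2.5
        assert s.range[0] <= s.iqr[0] <= s.median <= s.iqr[1] <= s.range[1]

    def test_uniform_sample_median_near_half(self):
        rng = np.random.default_rng(0)
        assert group_summary(rng.random(100)).median == pytest.approx(0.5, abs=0.1)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            group_summary([])


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_small_separated_samples_exact(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_for_small_tie_free_samples(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, min(9, 11 - n1)))
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1.0))
        x, y = vals[:n1], vals[n1:]
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(exact_mwu_p(x, y), abs=1e-9)

    def test_detects_two_sigma_shift(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0.0, 1.0, 20)
        y = rng.normal(2.0, 1.0, 20)
        _, p = mann_whitney_u(x, y)
        assert p <= 0.05

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPooledAndSubtype:
    def _records(self):
        recs = []
        for case in ("c1", "c2"):
            for i in range(4):
                recs.append(record(case, "GTV-", dsc=0.6 + 0.01 * i, sdsc=0.6 + 0.01 * i, hd98=15 - i, observer_id=f"m{i}"))
                recs.append(record(case, "GTV+", dsc=0.8 + 0.01 * i, sdsc=0.8 + 0.01 * i, hd98=6 - i, observer_id=f"p{i}"))
        return recs

    def test_identical_groups_give_p_one(self):
        recs = [record("c1", g, observer_id=f"{g}{i}") for g in ("GTV-", "GTV+") for i in range(3)]
        pooled = pooled_comparison(recs)
        for m in ("SDSC", "DSC", "HD98"):
            assert pooled[m]["p"] == pytest.approx(1.0, abs=1e-9)

    def test_excluding_all_cases_raises(self):
        with pytest.raises(ValueError):
            pooled_comparison(self._records(), exclude_cases=["c1", "c2"])

    def test_subtype_of_all_cases_equals_pooled(self):
        recs = self._records()
        pooled = pooled_comparison(recs)
        sub = subtype_comparison(recs, [SubtypeDefinition("everything", ("c1", "c2"))])
        for m in ("SDSC", "DSC", "HD98"):
            assert sub["everything"][m]["p"] == pooled[m]["p"]
            assert sub["everything"][m]["gtv_minus"] == pooled[m]["gtv_minus"]

    def test_disjoint_subtypes_conserve_record_counts(self):
        recs = self._records()
        sub = subtype_comparison(
            recs, [SubtypeDefinition("a", ("c1",)), SubtypeDefinition("b", ("c2",))]
        )
        total = sum(sub[s]["DSC"]["gtv_minus"].n + sub[s]["DSC"]["gtv_plus"].n for s in ("a", "b"))
        assert total == len(recs)

    def test_unknown_case_id_raises(self):
        with pytest.raises(ValueError):
            subtype_comparison(self._records(), [SubtypeDefinition("x", ("nope",))])

    def test_large_radiologist_variation_flags_all_metric_rule(self):
        bad = [record("c1", "RAD", dsc=0.4, sdsc=0.4, hd98=30.0, observer_id=f"r{i}") for i in range(3)]
        good = [record("c2", "RAD", dsc=0.9, sdsc=0.9, hd98=4.0, observer_id=f"r{i}") for i in range(3)]
        mixed = [record("c3", "RAD", dsc=0.4, sdsc=0.9, hd98=30.0, observer_id=f"r{i}") for i in range(3)]
        assert large_radiologist_variation_cases(bad + good + mixed, rule="all") == ["c1"]
        assert large_radiologist_variation_cases(bad + good + mixed, rule="any") == ["c1", "c3"]
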