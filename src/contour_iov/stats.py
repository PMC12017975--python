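"""Categorization, relevance thresholds, and group comparison of agreement metrics.

Implements the interpretation layer of the interobserver-variation analysis:

* per-metric variation categories (little / average / large) from gross
  cut-offs — DSC/SDSC at 0.6 and 0.8, HD98 at 10 and 20 mm;
* relevant-difference assessment of GTV+ minus GTV− medians at ±0.1
  (DSC/SDSC) and ±3 mm (HD98);
* pooled, subtype-restricted, and exclusion comparisons of the two
  radiation-oncologist arms with the Mann-Whitney U test (α ≤ 0.05).

The improvement direction of each metric is encoded once, centrally: higher
DSC/SDSC is better, lower HD98 is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .metrics import MetricRecord, ToleranceConfig, compute_case_metrics
from .study import GROUP_GTV_MINUS, GROUP_GTV_PLUS, GROUP_RAD, CaseStudy

__all__ = [
    "METRICS",
    "HIGHER_IS_BETTER",
    "RELEVANCE_THRESHOLD",
    "ALPHA",
    "GroupSummary",
    "DifferenceAssessment",
    "SubtypeDefinition",
    "categorize",
    "median_difference",
    "consistency_assessment",
    "group_summary",
    "mann_whitney_u",
    "pooled_comparison",
    "subtype_comparison",
    "case_report",
    "large_radiologist_variation_cases",
]

METRICS = ("SDSC", "DSC", "HD98")

#: improvement direction, encoded once to prevent sign errors for HD98
HIGHER_IS_BETTER = {"DSC": True, "SDSC": True, "HD98": False}

#: minimum |median difference| for a relevant change (exclusive thresholds)
RELEVANCE_THRESHOLD = {"DSC": 0.1, "SDSC": 0.1, "HD98": 3.0}

ALPHA = 0.05

LITTLE, AVERAGE, LARGE = "little", "average", "large"
IMPROVEMENT = "relevant improvement"
NO_DIFFERENCE = "no relevant difference"
DETERIORATION = "relevant deterioration"


def categorize(metric: str, value: float) -> str:
    """Variation category of a metric value.

    DSC/SDSC: ``< 0.6`` large, ``0.6 <= v < 0.8`` average, ``>= 0.8`` little.
    HD98 (mm): ``< 10`` little, ``10 <= v < 20`` average, ``>= 20`` large.
    """
    if metric in ("DSC", "SDSC"):
        if value < 0.6:
            return LARGE
        if value < 0.8:
            return AVERAGE
        return LITTLE
    if metric == "HD98":
        if value < 10.0:
            return LITTLE
        if value < 20.0:
            return AVERAGE
        return LARGE
    raise ValueError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class GroupSummary:
    """Median with IQR (25th/75th percentile, linear interpolation) and range."""

    n: int
    median: float
    iqr: tuple[float, float]
    range: tuple[float, float]


@dataclass(frozen=True)
class DifferenceAssessment:
    """Signed GTV+ − GTV− median difference and its relevance category."""

    metric: str
    absolute_difference: float
    category: str


@dataclass(frozen=True)
class SubtypeDefinition:
    """A recurrence subtype and its member cases (membership may overlap)."""

    subtype: str
    case_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.case_ids:
            raise ValueError(f"subtype {self.subtype!r} has no cases")


def group_summary(values) -> GroupSummary:
    """Summarize a sample as median, IQR and range."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return GroupSummary(
        n=int(v.size),
        median=float(q50),
        iqr=(float(q25), float(q75)),
        range=(float(v.min()), float(v.max())),
    )


def median_difference(
    gtv_minus: GroupSummary, gtv_plus: GroupSummary, metric: str
) -> DifferenceAssessment:
    """Assess the GTV+ − GTV− median difference against the relevance threshold.

    A change is relevant only when its magnitude strictly exceeds the
    threshold (±0.1 for DSC/SDSC, ±3 mm for HD98); the improvement direction
    is positive for DSC/SDSC and negative for HD98.
    """
    if metric not in HIGHER_IS_BETTER:
        raise ValueError(f"unknown metric {metric!r}")
    diff = gtv_plus.median - gtv_minus.median
    thr = RELEVANCE_THRESHOLD[metric]
    if abs(diff) <= thr:
        category = NO_DIFFERENCE
    else:
        improved = diff > 0 if HIGHER_IS_BETTER[metric] else diff < 0
        category = IMPROVEMENT if improved else DETERIORATION
    return DifferenceAssessment(metric=metric, absolute_difference=float(diff), category=category)


def consistency_assessment(case_differences: list[DifferenceAssessment]) -> str:
    """Overall case verdict: change consistent along all three metrics, or mixed.

    ``consistent improvement`` iff SDSC, DSC and HD98 all show a relevant
    improvement; analogously for deterioration; anything else is
    ``mixed/none``.
    """
    by_metric = {d.metric: d.category for d in case_differences}
    missing = [m for m in METRICS if m not in by_metric]
    if missing:
        raise ValueError(f"missing difference assessment for metrics: {missing}")
    cats = [by_metric[m] for m in METRICS]
    if all(c == IMPROVEMENT for c in cats):
        return "consistent improvement"
    if all(c == DETERIORATION for c in cats):
        return "consistent deterioration"
    return "mixed/none"


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (midranks for ties).

    Exact p by enumeration for small tie-free samples (pooled n ≤ 20, which
    covers both samples at n ≤ 8 and any tie-free split of up to 20
    observations); otherwise the normal approximation with tie correction
    and continuity correction. Returns ``(U, p)`` with U counted for ``x``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence of separation
        return float(x.size * y.size / 2.0), 1.0
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _metric_value(r: MetricRecord, metric: str) -> float:
    return {"DSC": r.dsc, "SDSC": r.sdsc, "HD98": r.hd98}[metric]


def _records_by_group(records: list[MetricRecord], group: str, case_ids=None) -> list[MetricRecord]:
    return [
        r
        for r in records
        if r.group == group and (case_ids is None or r.case_id in case_ids)
    ]


def pooled_comparison(
    records: list[MetricRecord],
    exclude_cases: list[str] | None = None,
    case_ids: list[str] | None = None,
) -> dict[str, dict]:
    """Compare all GTV− against all GTV+ contours, per metric.

    Pooling is per-contour across all non-excluded cases: every returned
    contour contributes one value per metric. Returns, per metric, the two
    group summaries, the Mann-Whitney U and two-sided p, and a significance
    flag at α ≤ 0.05.
    """
    excluded = set(exclude_cases or [])
    keep = None if case_ids is None else set(case_ids)
    if keep is not None:
        keep -= excluded
    else:
        all_ids = {r.case_id for r in records}
        keep = all_ids - excluded
    minus = _records_by_group(records, GROUP_GTV_MINUS, keep)
    plus = _records_by_group(records, GROUP_GTV_PLUS, keep)
    if not minus or not plus:
        raise ValueError(
            "a comparison arm is empty after case exclusion "
            f"(GTV-: {len(minus)}, GTV+: {len(plus)} contours)"
        )
    out: dict[str, dict] = {}
    for metric in METRICS:
        vm = [_metric_value(r, metric) for r in minus]
        vp = [_metric_value(r, metric) for r in plus]
        sm, sp_ = group_summary(vm), group_summary(vp)
        u, p = mann_whitney_u(vm, vp)
        out[metric] = {
            "gtv_minus": sm,
            "gtv_plus": sp_,
            "difference": median_difference(sm, sp_, metric),
            "u": u,
            "p": p,
            "significant": p <= ALPHA,
        }
    return out


def subtype_comparison(
    records: list[MetricRecord], subtypes: list[SubtypeDefinition]
) -> dict[str, dict[str, dict]]:
    """Pooled GTV− vs GTV+ comparison restricted to each subtype's cases.

    A case may belong to several subtypes and then contributes to each.
    """
    known = {r.case_id for r in records}
    out: dict[str, dict[str, dict]] = {}
    for sd in subtypes:
        unknown = [c for c in sd.case_ids if c not in known]
        if unknown:
            raise ValueError(f"subtype {sd.subtype!r} references unknown cases: {unknown}")
        out[sd.subtype] = pooled_comparison(records, case_ids=list(sd.case_ids))
    return out


def case_report(
    case: CaseStudy,
    cfg: ToleranceConfig = ToleranceConfig(),
    records: list[MetricRecord] | None = None,
) -> dict:
    """Per-case report row: group medians, categories, and difference verdicts.

    Requires the case to have all three groups (RAD, GTV−, GTV+). Metric
    records are computed against each group's own median contour unless
    precomputed records for this case are passed in.
    """
    missing = [g for g in (GROUP_RAD, GROUP_GTV_MINUS, GROUP_GTV_PLUS) if g not in case.groups]
    if missing:
        raise ValueError(f"case {case.case_id!r} is missing groups: {missing}")
    if records is None:
        records = compute_case_metrics(case, cfg)
    report: dict = {"case_id": case.case_id, "subtypes": list(case.subtypes), "groups": {}}
    summaries: dict[str, dict[str, GroupSummary]] = {}
    for group in (GROUP_RAD, GROUP_GTV_MINUS, GROUP_GTV_PLUS):
        grp_records = _records_by_group(records, group, {case.case_id})
        summaries[group] = {}
        report["groups"][group] = {}
        for metric in METRICS:
            s = group_summary([_metric_value(r, metric) for r in grp_records])
            summaries[group][metric] = s
            report["groups"][group][metric] = {
                "n": s.n,
                "median": s.median,
                "iqr": s.iqr,
                "range": s.range,
                "category": categorize(metric, s.median),
            }
    diffs = [
        median_difference(summaries[GROUP_GTV_MINUS][m], summaries[GROUP_GTV_PLUS][m], m)
        for m in METRICS
    ]
    report["differences"] = {
        d.metric: {"difference": d.absolute_difference, "category": d.category} for d in diffs
    }
    report["consistency"] = consistency_assessment(diffs)
    return report


def large_radiologist_variation_cases(
    records: list[MetricRecord], rule: str = "all"
) -> list[str]:
    """Cases whose radiologist group shows large variation — exclusion candidates.

    A case qualifies when its RAD per-case medians are categorized ``large``
    on all three metrics (``rule='all'``, the default) or on any metric
    (``rule='any'``).
    """
    if rule not in ("all", "any"):
        raise ValueError(f"unknown exclusion rule {rule!r}")
    combine = all if rule == "all" else any
    flagged = []
    for case_id in sorted({r.case_id for r in records}):
        rad = _records_by_group(records, GROUP_RAD, {case_id})
        if not rad:
            continue
        cats = [
            categorize(m, group_summary([_metric_value(r, m) for r in rad]).median)
            for m in METRICS
        ]
        if combine(c == LARGE for c in cats):
            flagged.append(case_id)
    return flagged
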