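"""End-to-end orchestration: consensus → metrics → reports → group comparisons.

``run_pipeline`` takes the per-case observer sets (from a manifest or from
the synthetic generator), evaluates every contour against its own group's
median contour, and produces:

* per-contour metric records (one row per returned delineation);
* a per-case report table (group medians, variation categories, and the
  GTV+ − GTV− difference verdicts);
* the pooled GTV− vs GTV+ comparison over all contours;
* the same comparison excluding cases with large radiologist variation;
* per-subtype comparisons (cases may belong to several subtypes).

The output is a pure function of the inputs and the tolerance config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .metrics import MetricRecord, ToleranceConfig, compute_case_metrics
from .stats import (
    SubtypeDefinition,
    case_report,
    large_radiologist_variation_cases,
    pooled_comparison,
    subtype_comparison,
)
from .study import GROUP_GTV_MINUS, GROUP_GTV_PLUS, GROUP_RAD, CaseStudy

__all__ = [
    "StudyReport",
    "run_pipeline",
    "subtypes_from_cases",
    "comparison_rows",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass
class StudyReport:
    """The full report bundle of one study run."""

    records: list[MetricRecord]
    case_reports: list[dict]
    pooled: dict
    excluded_cases: list[str]
    pooled_after_exclusion: dict | None
    subtypes: dict
    config: dict

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])


def subtypes_from_cases(cases: list[CaseStudy]) -> list[SubtypeDefinition]:
    """Collect overlapping subtype definitions from the cases' tags."""
    membership: dict[str, list[str]] = {}
    for c in cases:
        for s in c.subtypes:
            membership.setdefault(s, []).append(c.case_id)
    return [SubtypeDefinition(subtype=s, case_ids=tuple(ids)) for s, ids in sorted(membership.items())]


def run_pipeline(
    cases: list[CaseStudy],
    cfg: ToleranceConfig = ToleranceConfig(),
    exclusion_rule: str = "all",
) -> StudyReport:
    """Run the complete agreement analysis over a list of cases."""
    if not cases:
        raise ValueError("no cases to analyze")
    records: list[MetricRecord] = []
    reports: list[dict] = []
    for case in cases:
        counts = {g: len(s) for g, s in case.groups.items()}
        logger.info("case %s: observers %s", case.case_id, counts)
        case_records = compute_case_metrics(case, cfg)
        records.extend(case_records)
        missing = {GROUP_RAD, GROUP_GTV_MINUS, GROUP_GTV_PLUS} - set(case.groups)
        if missing:
            raise ValueError(f"case {case.case_id!r} is missing groups: {sorted(missing)}")
        reports.append(case_report(case, cfg, records=case_records))

    pooled = pooled_comparison(records)
    excluded = large_radiologist_variation_cases(records, rule=exclusion_rule)
    logger.info("cases with large radiologist variation (%s rule): %s", exclusion_rule, excluded)
    pooled_after = None
    if excluded and len(excluded) < len(cases):
        pooled_after = pooled_comparison(records, exclude_cases=excluded)
    subtype_defs = subtypes_from_cases(cases)
    subtypes = subtype_comparison(records, subtype_defs) if subtype_defs else {}
    config = {
        "sdsc_tolerance_mm": cfg.sdsc_tolerance,
        "hd_percentile": cfg.hd_percentile,
        "iqr_convention": "25th/75th percentile, linear interpolation",
        "hd_direction": "directed observer->reference",
        "mda_sd": "population (divisor n)",
        "consensus": "strict >50% majority, leave-one-in",
        "exclusion_rule": exclusion_rule,
    }
    return StudyReport(
        records=records,
        case_reports=reports,
        pooled=pooled,
        excluded_cases=excluded,
        pooled_after_exclusion=pooled_after,
        subtypes=subtypes,
        config=config,
    )


def comparison_rows(tag: str, comparison: dict) -> list[dict]:
    """Flatten one per-metric comparison dict into table rows."""
    rows = []
    for metric, c in comparison.items():
        rows.append(
            {
                "analysis": tag,
                "metric": metric,
                "n_gtv_minus": c["gtv_minus"].n,
                "median_gtv_minus": c["gtv_minus"].median,
                "iqr_lo_gtv_minus": c["gtv_minus"].iqr[0],
                "iqr_hi_gtv_minus": c["gtv_minus"].iqr[1],
                "n_gtv_plus": c["gtv_plus"].n,
                "median_gtv_plus": c["gtv_plus"].median,
                "iqr_lo_gtv_plus": c["gtv_plus"].iqr[0],
                "iqr_hi_gtv_plus": c["gtv_plus"].iqr[1],
                "median_difference": c["difference"].absolute_difference,
                "difference_category": c["difference"].category,
                "U": c["u"],
                "p": c["p"],
                "significant": c["significant"],
            }
        )
    return rows


def write_report(report: StudyReport, out_dir) -> Path:
    """Write the report bundle as CSV tables plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report.records_frame().to_csv(out / "metric_records.csv", index=False)

    case_rows = []
    for r in report.case_reports:
        row: dict = {"case_id": r["case_id"], "subtypes": ";".join(r["subtypes"])}
        for group, metrics in r["groups"].items():
            for metric, v in metrics.items():
                row[f"{group}_{metric}_median"] = v["median"]
                row[f"{group}_{metric}_category"] = v["category"]
        for metric, d in r["differences"].items():
            row[f"diff_{metric}"] = d["difference"]
            row[f"diff_{metric}_category"] = d["category"]
        row["consistency"] = r["consistency"]
        case_rows.append(row)
    pd.DataFrame(case_rows).to_csv(out / "per_case_summary.csv", index=False)

    pd.DataFrame(comparison_rows("pooled", report.pooled)).to_csv(
        out / "pooled_comparison.csv", index=False
    )
    if report.pooled_after_exclusion is not None:
        pd.DataFrame(
            comparison_rows("pooled_excluding_large_rad_iov", report.pooled_after_exclusion)
        ).to_csv(out / "pooled_comparison_after_exclusion.csv", index=False)
    if report.subtypes:
        rows = []
        for subtype, comp in report.subtypes.items():
            rows.extend(comparison_rows(subtype, comp))
        pd.DataFrame(rows).to_csv(out / "subtype_comparison.csv", index=False)

    summary = {
        "config": report.config,
        "n_cases": len(report.case_reports),
        "n_records": len(report.records),
        "excluded_cases": report.excluded_cases,
        "consistency_by_case": {
            r["case_id"]: r["consistency"] for r in report.case_reports
        },
        "pooled": {
            m: {
                "median_gtv_minus": c["gtv_minus"].median,
                "median_gtv_plus": c["gtv_plus"].median,
                "p": c["p"],
                "significant": c["significant"],
            }
            for m, c in report.pooled.items()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out
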