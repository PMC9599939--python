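"""Tumor/normal fold-change analysis of the gene's target miRNAs.

Assays come from a paired tumor/normal low-density miRNA card.  A fold
change exists only when the miR was detected in both tissues; assays with a
signal in only one tissue are dropped (detection filter).  A miR (or a
case's average over its retained miRs) is dysregulated when FC >= 2 or
FC <= 0.5.

Two cohort-level "abnormal miR" summaries coexist and are reported
separately: abnormality by per-miR *average* FC (the subset selector used
for correlation analyses) and abnormality by per-miR *median* FC (used for
descriptive naming of dysregulated miRs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .qpcr import classify_expression

__all__ = [
    "filter_detected",
    "classify_mir",
    "mir_cohort_summary",
    "abnormal_mir_subset",
]


def filter_detected(assays: pd.DataFrame) -> pd.DataFrame:
    """Keep assays detected in both tumor and normal tissue.

    ``assays`` is long format with boolean columns tumor_detected and
    normal_detected.  Idempotent; never increases the row count.
    """
    if assays.empty:
        return assays
    missing = {"tumor_detected", "normal_detected"} - set(assays.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    keep = assays["tumor_detected"].astype(bool) & assays["normal_detected"].astype(bool)
    return assays.loc[keep].reset_index(drop=True)


def classify_mir(fc: float) -> str:
    """Dysregulation category of a miR fold change: over (>=2), under (<=0.5)."""
    return classify_expression(fc)


def mir_cohort_summary(
    assays: pd.DataFrame, min_cases: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-miR and per-case summaries of retained (both-detected) assays.

    Returns ``(per_mir, per_case)``:

    per_mir
        One row per miR with >= ``min_cases`` retained cases: n, mean and
        median FC, and two abnormality flags — ``abnormal_by_average``
        (mean FC >= 2 or <= 0.5; the correlation-subset rule) and
        ``abnormal_by_median``.
    per_case
        One row per case: number of retained miRs, arithmetic-mean FC over
        them, and its category.
    """
    retained = filter_detected(assays) if {"tumor_detected", "normal_detected"} <= set(assays.columns) else assays
    if retained.empty:
        raise ValueError("no retained assays")
    missing = {"case_id", "mir_id", "fc"} - set(retained.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    retained = retained.dropna(subset=["fc"])
    per_mir_rows = []
    for mir, grp in retained.groupby("mir_id", sort=True):
        if len(grp) < min_cases:
            continue
        mean_fc = float(grp["fc"].mean())
        median_fc = float(grp["fc"].median())
        per_mir_rows.append(
            {
                "mir_id": mir,
                "n_cases": len(grp),
                "mean_fc": mean_fc,
                "median_fc": median_fc,
                "abnormal_by_average": classify_mir(mean_fc) != "normal",
                "abnormal_by_median": classify_mir(median_fc) != "normal",
            }
        )
    per_mir = pd.DataFrame(per_mir_rows)
    retained_mirs = set(per_mir["mir_id"]) if not per_mir.empty else set()
    per_case_rows = []
    for case, grp in retained.groupby("case_id", sort=True):
        grp = grp[grp["mir_id"].isin(retained_mirs)]
        if grp.empty:
            continue
        avg = float(grp["fc"].mean())
        per_case_rows.append(
            {
                "case_id": case,
                "n_mirs": len(grp),
                "avg_fc": avg,
                "category": classify_mir(avg),
            }
        )
    per_case = pd.DataFrame(per_case_rows)
    return per_mir, per_case


def abnormal_mir_subset(per_mir: pd.DataFrame) -> list[str]:
    """miR ids abnormal by average FC — the subset correlated against SNPs."""
    if per_mir.empty:
        return []
    return sorted(per_mir.loc[per_mir["abnormal_by_average"], "mir_id"])
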