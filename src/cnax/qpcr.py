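"""Relative mRNA quantification by the comparative-Ct (2^-ddCt) method.

Each assay is a triplicate of threshold-cycle (Ct) values for a target probe
and for a single reference gene, measured in tumor and matched normal tissue
of the same case.  Per tissue, dCt = mean(target Ct) - mean(reference Ct);
ddCt = dCt_tumor - dCt_normal; the fold change is FC = 2^-ddCt.  Fold
changes are categorized as overexpressed (FC >= 2.0), underexpressed
(FC <= 0.5), or normal (the open interval between).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "QpcrAssay",
    "FoldChange",
    "compute_fold_change",
    "classify_expression",
    "case_average_expression",
    "probe_frequency_distribution",
    "DdctFoldChange",
]

logger = logging.getLogger(__name__)

#: Replicate spread (cycles) above which a QC warning is logged.
REPLICATE_SD_WARN = 0.5


@dataclass(frozen=True)
class QpcrAssay:
    """Triplicate Ct measurement of one probe in one tissue of one case.

    Missing replicates are allowed (NaN), but at least one finite value is
    required per triplicate; Ct values must be positive.
    """

    case_id: str
    probe_id: str
    tissue: str  # "tumor" | "normal"
    target_ct: tuple[float, ...]
    reference_ct: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "normal"):
            raise ValueError("tissue must be 'tumor' or 'normal'")
        for name, trip in (("target", self.target_ct), ("reference", self.reference_ct)):
            vals = np.asarray(trip, dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size == 0:
                raise ValueError(f"{name} triplicate has no usable Ct value")
            if np.any(finite <= 0):
                raise ValueError(f"{name} Ct values must be positive")
            if finite.size >= 2 and float(np.std(finite, ddof=1)) > REPLICATE_SD_WARN:
                logger.warning(
                    "replicate spread > %.1f cycles for %s/%s/%s (%s)",
                    REPLICATE_SD_WARN, self.case_id, self.probe_id, self.tissue, name,
                )

    @property
    def delta_ct(self) -> float:
        """Mean target Ct minus mean reference Ct (cycles)."""
        return float(np.nanmean(np.asarray(self.target_ct, dtype=float))) - float(
            np.nanmean(np.asarray(self.reference_ct, dtype=float))
        )


@dataclass(frozen=True)
class FoldChange:
    """ddCt pipeline result for one (case, probe) pair."""

    case_id: str
    probe_id: str
    delta_ct_tumor: float
    delta_ct_normal: float
    delta_delta_ct: float
    fc: float
    category: str


def compute_fold_change(tumor: QpcrAssay, normal: QpcrAssay) -> FoldChange:
    """Tumor/normal fold change of one probe by the 2^-ddCt formula."""
    if tumor.tissue != "tumor" or normal.tissue != "normal":
        raise ValueError("expected one tumor and one normal assay")
    if (tumor.case_id, tumor.probe_id) != (normal.case_id, normal.probe_id):
        raise ValueError("tumor and normal assays must share case and probe")
    dct_t = tumor.delta_ct
    dct_n = normal.delta_ct
    ddct = dct_t - dct_n
    fc = float(2.0 ** (-ddct))
    return FoldChange(
        case_id=tumor.case_id,
        probe_id=tumor.probe_id,
        delta_ct_tumor=dct_t,
        delta_ct_normal=dct_n,
        delta_delta_ct=ddct,
        fc=fc,
        category=classify_expression(fc),
    )


def classify_expression(fc: float, over_min: float = 2.0, under_max: float = 0.5) -> str:
    """Expression category of a fold change: over (>=2), under (<=0.5), normal."""
    if not np.isfinite(fc) or fc <= 0:
        raise ValueError("fold change must be a positive finite number")
    if fc >= over_min:
        return "over"
    if fc <= under_max:
        return "under"
    return "normal"


def case_average_expression(fold_changes: Iterable[float | FoldChange]) -> tuple[float, str]:
    """Arithmetic mean of a case's per-probe fold changes, with its category."""
    fcs = [f.fc if isinstance(f, FoldChange) else float(f) for f in fold_changes]
    if not fcs:
        raise ValueError("no probe fold changes supplied")
    mean_fc = float(np.mean(fcs))
    return mean_fc, classify_expression(mean_fc)


def probe_frequency_distribution(
    fold_changes: pd.DataFrame, min_cases: int = 5
) -> pd.DataFrame:
    """Per-probe category frequencies and FC summaries over the cohort.

    ``fold_changes`` is long format with columns case_id, probe_id, fc.
    Probes observed in fewer than ``min_cases`` cases are excluded.  The
    over/normal/under frequencies sum to 1 for every retained probe.
    """
    required = {"case_id", "probe_id", "fc"}
    if fold_changes.empty:
        raise ValueError("empty cohort")
    missing = required - set(fold_changes.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for probe, grp in fold_changes.groupby("probe_id", sort=True):
        fcs = grp["fc"].dropna()
        if len(fcs) < min_cases:
            continue
        cats = fcs.map(classify_expression)
        n = len(fcs)
        rows.append(
            {
                "probe_id": probe,
                "n_cases": n,
                "freq_over": float((cats == "over").sum()) / n,
                "freq_normal": float((cats == "normal").sum()) / n,
                "freq_under": float((cats == "under").sum()) / n,
                "median_fc": float(fcs.median()),
                "mean_fc": float(fcs.mean()),
                "min_fc": float(fcs.min()),
                "max_fc": float(fcs.max()),
            }
        )
    return pd.DataFrame(rows)


def _triplicate(row) -> tuple[float, ...]:
    vals = (getattr(row, c) for c in ("rep1", "rep2", "rep3"))
    return tuple(float(v) if pd.notna(v) else float("nan") for v in vals)


class DdctFoldChange(TransformerMixin, BaseEstimator):
    """ddCt fold-change transformer over a long-format Ct table.

    Input rows carry case_id, probe_id, tissue, target (gene name), rep1-3.
    Reference-gene rows are matched to target rows by (case, tissue, probe),
    falling back to a case/tissue-level reference when the reference was run
    once per sample rather than per probe.  ``transform`` returns one row per
    (case, probe) with dCt per tissue, ddCt, FC and category.
    """

    def __init__(
        self,
        target_gene: str = "CSMD1",
        reference_gene: str = "GAPDH",
        over_min: float = 2.0,
        under_max: float = 0.5,
    ):
        self.target_gene = target_gene
        self.reference_gene = reference_gene
        self.over_min = over_min
        self.under_max = under_max

    def fit(self, X: pd.DataFrame, y=None) -> "DdctFoldChange":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        required = {"case_id", "probe_id", "tissue", "target", "rep1", "rep2", "rep3"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        targets = X[X["target"] == self.target_gene]
        refs = X[X["target"] == self.reference_gene]
        if targets.empty or refs.empty:
            raise ValueError("Ct table must contain both target and reference rows")
        ref_by_probe = {
            (r.case_id, r.tissue, r.probe_id): _triplicate(r)
            for r in refs.itertuples()
        }
        ref_by_case = {
            (case, tissue): _triplicate(grp.iloc[0])
            for (case, tissue), grp in refs.groupby(["case_id", "tissue"])
        }
        assays: dict[tuple[str, str, str], QpcrAssay] = {}
        for r in targets.itertuples():
            key = (r.case_id, r.tissue, r.probe_id)
            ref = ref_by_probe.get(key, ref_by_case.get((r.case_id, r.tissue)))
            if ref is None:
                raise ValueError(
                    f"no reference-gene Ct for case {r.case_id} ({r.tissue})"
                )
            assays[key] = QpcrAssay(r.case_id, r.probe_id, r.tissue, _triplicate(r), ref)
        rows = []
        pairs = sorted({(c, p) for c, _, p in assays})
        for case, probe in pairs:
            tum = assays.get((case, "tumor", probe))
            nor = assays.get((case, "normal", probe))
            if tum is None or nor is None:
                raise ValueError(
                    f"case {case} probe {probe} lacks a paired tumor/normal assay"
                )
            fc = compute_fold_change(tum, nor)
            rows.append(
                {
                    "case_id": case,
                    "probe_id": probe,
                    "dct_tumor": fc.delta_ct_tumor,
                    "dct_normal": fc.delta_ct_normal,
                    "ddct": fc.delta_delta_ct,
                    "fc": fc.fc,
                    "category": classify_expression(fc.fc, self.over_min, self.under_max),
                }
            )
        return pd.DataFrame(rows)
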