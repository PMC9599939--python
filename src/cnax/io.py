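"""File formats, packaged fixtures, and the declarative pipeline config.

Dialects: UTF-8 throughout; tab-separated for genomic tables, comma-
separated for assay/clinical tables; one header row.  Genomic positions are
1-based inclusive in files and 0-based half-open in memory.  Readers
validate schemas (missing required columns raise :class:`SchemaError`
naming the column) and key integrity (duplicated (case, marker) rows raise
:class:`IntegrityError`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .cna import CaseAlterationCategory, SnpProfile, summarize_cohort_alterations
from .qpcr import classify_expression

__all__ = [
    "SchemaError",
    "IntegrityError",
    "PipelineConfig",
    "read_snp_map", "write_snp_map",
    "read_lrr_baf", "write_lrr_baf",
    "read_segments", "write_segments",
    "read_ct_table", "write_ct_table",
    "read_mir_table", "write_mir_table",
    "read_clinical", "write_clinical",
    "read_results", "write_results",
    "load_table1", "load_target_mirs", "reproduce_table1",
]


class SchemaError(ValueError):
    """A table is missing required columns or has malformed rows."""


class IntegrityError(ValueError):
    """A table violates a uniqueness or fixture invariant."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _no_duplicates(df: pd.DataFrame, keys: Sequence[str], what: str) -> None:
    dup = df.duplicated(subset=list(keys))
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]  # +2: header + 1-based
        raise IntegrityError(f"{what}: duplicated {tuple(keys)} keys at file line(s) {rows}")


# ---------------------------------------------------------------------------
# SNP annotation map

_SNP_MAP_COLS = ["snp_id", "chrom", "pos", "intron", "allele_a", "allele_b"]


def write_snp_map(snp_map: pd.DataFrame, path: str | Path) -> None:
    _require_columns(snp_map, _SNP_MAP_COLS, "snp map")
    snp_map[_SNP_MAP_COLS].to_csv(path, sep="\t", index=False)


def read_snp_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, _SNP_MAP_COLS, str(path))
    _no_duplicates(df, ["snp_id"], str(path))
    return df


# ---------------------------------------------------------------------------
# LRR/BAF long table

_LRR_BAF_COLS = ["case_id", "snp_id", "chrom", "pos", "genotype", "lrr", "baf"]


def write_lrr_baf(profiles: Iterable[SnpProfile], path: str | Path) -> None:
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "case_id": p.case_id,
                    "snp_id": p.snp_ids,
                    "chrom": p.chrom,
                    "pos": p.positions,
                    "genotype": p.genotype,
                    "lrr": p.lrr,
                    "baf": p.baf,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_lrr_baf(path: str | Path) -> dict[str, SnpProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, _LRR_BAF_COLS, str(path))
    _no_duplicates(df, ["case_id", "snp_id"], str(path))
    profiles: dict[str, SnpProfile] = {}
    for case, grp in df.groupby("case_id", sort=True):
        grp = grp.sort_values("pos")
        profiles[str(case)] = SnpProfile(
            snp_ids=grp["snp_id"].to_numpy(),
            positions=grp["pos"].to_numpy(),
            lrr=grp["lrr"].to_numpy(),
            baf=grp["baf"].to_numpy(),
            genotype=grp["genotype"].to_numpy(),
            case_id=str(case),
            chrom=str(grp["chrom"].iloc[0]),
        )
    return profiles


# ---------------------------------------------------------------------------
# BED-like segment table (file coordinates 1-based inclusive)

_SEGMENT_COLS = [
    "chrom", "start", "end", "n_probes", "mean_lrr", "cn_state",
    "allelic_state", "case_id",
]


def write_segments(segments: pd.DataFrame, path: str | Path) -> None:
    """Write annotated segments; start/end are genomic base-pair bounds."""
    df = segments.rename(columns={"start_pos": "start", "end_pos": "end"})
    _require_columns(df, _SEGMENT_COLS, "segments")
    df[_SEGMENT_COLS].to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, _SEGMENT_COLS, str(path))
    if (df["end"] < df["start"]).any():
        raise SchemaError(f"{path}: segment end precedes start")
    return df


# ---------------------------------------------------------------------------
# assay / clinical CSVs

_CT_COLS = ["case_id", "probe_id", "tissue", "target", "rep1", "rep2", "rep3"]
_MIR_COLS = ["case_id", "mir_id", "tumor_detected", "normal_detected", "fc"]
_CLINICAL_COLS = ["case_id", "months", "event"]
_RESULT_COLS = ["analysis", "id1", "id2", "n", "rho", "p", "nominal", "bonferroni", "direction"]


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, _CT_COLS, "Ct table")
    df[_CT_COLS].to_csv(path, index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, _CT_COLS, str(path))
    _no_duplicates(df, ["case_id", "probe_id", "tissue", "target"], str(path))
    return df


def write_mir_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, _MIR_COLS, "miR table")
    df[_MIR_COLS].to_csv(path, index=False)


def read_mir_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, _MIR_COLS, str(path))
    _no_duplicates(df, ["case_id", "mir_id"], str(path))
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, _CLINICAL_COLS, "clinical table")
    df.to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, _CLINICAL_COLS, str(path))
    _no_duplicates(df, ["case_id"], str(path))
    return df


def write_results(
    df: pd.DataFrame,
    analysis: str,
    path: str | Path,
    id_cols: tuple[str, str] = ("id1", "id2"),
    mode: str = "w",
) -> None:
    """Write a correlation-screen result in the long results dialect.

    ``id_cols`` names the two identifier columns of ``df`` (e.g.
    ``("snp_id", "probe_id")``); they are written as id1/id2.  ``mode="a"``
    appends without a header so several analyses share one file.
    """
    out = df.rename(columns={id_cols[0]: "id1", id_cols[1]: "id2"}).copy()
    out.insert(0, "analysis", analysis)
    _require_columns(out, _RESULT_COLS, "results")
    out[_RESULT_COLS].to_csv(path, sep="\t", index=False, mode=mode, header=(mode == "w"))


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _RESULT_COLS, str(path))
    return df


# ---------------------------------------------------------------------------
# packaged fixtures

_CATEGORY_VOCAB = {"Allelic Imbalance", "CN Gain", "CN Loss", "LOH"}


def load_table1() -> pd.DataFrame:
    """The packaged 56-case alteration/expression summary fixture.

    Columns: case_id, alteration_category (canonical comma-joined label or
    "not observed"), gene_fc (case-average mRNA fold change, may be
    missing), mir_fc (case-average target-miR fold change).
    """
    with resources.files("cnax.data").joinpath("table1.csv").open("r") as fh:
        df = pd.read_csv(fh)
    _require_columns(df, ["case_id", "alteration_category", "gene_fc", "mir_fc"], "table1 fixture")
    if len(df) != 56:
        raise IntegrityError(f"table1 fixture must have 56 rows, found {len(df)}")
    _no_duplicates(df, ["case_id"], "table1 fixture")
    for label in df["alteration_category"]:
        CaseAlterationCategory.from_label(label)  # raises on unknown vocabulary
    for col in ("gene_fc", "mir_fc"):
        vals = df[col].dropna()
        if (vals <= 0).any():
            raise IntegrityError(f"table1 fixture: non-positive {col}")
    return df


def load_target_mirs() -> list[str]:
    """The packaged 22-entry target-miR list."""
    with resources.files("cnax.data").joinpath("target_mirs.txt").open("r") as fh:
        mirs = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(mirs) != 22:
        raise IntegrityError(f"target miR list must have 22 entries, found {len(mirs)}")
    return mirs


def reproduce_table1(table: pd.DataFrame | None = None) -> dict[str, float]:
    """All cohort counts derivable from the packaged summary fixture.

    Computes, from the fixture columns alone: the altered-case count and
    percentage; alteration-group counts (loss/LOH without gain and its AI
    subcount, gain without loss/LOH and its AI subcount, AI only, mixed
    gain with loss/LOH); gene-expression category counts over cases with a
    fold change, split by alteration status; and target-miR abnormal-case
    counts.
    """
    df = table if table is not None else load_table1()
    cats = [CaseAlterationCategory.from_label(l) for l in df["alteration_category"]]
    out = summarize_cohort_alterations(cats)
    altered = np.array([c.altered for c in cats])

    gene = df["gene_fc"]
    has_gene = gene.notna().to_numpy()
    gene_cat = gene[has_gene].map(classify_expression)
    out["gene_fc_cases"] = int(has_gene.sum())
    out["gene_under"] = int((gene_cat == "under").sum())
    out["gene_over"] = int((gene_cat == "over").sum())
    out["gene_abnormal"] = out["gene_under"] + out["gene_over"]
    abnormal = np.zeros(len(df), dtype=bool)
    abnormal[np.flatnonzero(has_gene)] = (gene_cat != "normal").to_numpy()
    n_alt = int((altered & has_gene).sum())
    n_not = int((~altered & has_gene).sum())
    out["gene_abnormal_altered"] = int((abnormal & altered).sum())
    out["gene_fc_cases_altered"] = n_alt
    out["pct_abnormal_among_altered"] = 100.0 * out["gene_abnormal_altered"] / n_alt
    out["gene_abnormal_unaltered"] = int((abnormal & ~altered).sum())
    out["gene_fc_cases_unaltered"] = n_not
    out["pct_abnormal_among_unaltered"] = 100.0 * out["gene_abnormal_unaltered"] / n_not

    mir_cat = df["mir_fc"].map(classify_expression)
    out["mir_over_cases"] = int((mir_cat == "over").sum())
    out["mir_under_cases"] = int((mir_cat == "under").sum())
    out["mir_abnormal_cases"] = out["mir_over_cases"] + out["mir_under_cases"]
    return out


# ---------------------------------------------------------------------------
# declarative pipeline configuration


@dataclass
class PipelineConfig:
    """Every tunable pipeline parameter in one declarative document.

    Defaults equal the calling criteria and cutoffs used throughout the
    package.  Unknown keys in a YAML document are rejected.
    """

    seed: int = 0
    n_cases: int = 56
    n_snps: int = 888
    noise_sd_lrr: float = 0.15
    baf_sd: float = 0.05
    het_fraction: float = 0.27
    significance_threshold: float = 5.0e-6
    max_probe_spacing: int = 1_000_000
    min_probes: int = 3
    n_permutations: int = 10_000
    min_het_fraction: float = 0.5
    over_min: float = 2.0
    under_max: float = 0.5
    min_cases: int = 5
    alpha: float = 0.05
    min_cases_with_cna: int = 1
    fc_cutoff: float = 1.0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise SchemaError("config document must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
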