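"""Synthetic cohort generator with planted ground truth.

Emulates the data a paired tumor/normal single-gene study produces, so every
downstream stage is testable without any external download:

* a SNP annotation map over a two-megabase gene region,
* per-case tumor LRR/BAF profiles with planted copy-number and allelic
  segments (piecewise-constant LRR plus Gaussian noise; BAF mixtures around
  the heterozygous and homozygous cluster centers, shifted by planted AI/LOH),
* triplicate qPCR Ct tables for 11 exon-boundary probes and a reference
  gene, with planted tumor/normal log2 expression shifts,
* target-miR fold-change tables with a detection filter,
* planted monotone SNP-to-expression couplings, and
* exponential survival times with group-dependent hazards.

Every planted effect is recorded in :class:`PlantedTruth` so recovery can be
scored.  All randomness flows from ``SyntheticConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cna import SnpProfile

__all__ = [
    "SyntheticConfig",
    "PlantedSegment",
    "Coupling",
    "PlantedTruth",
    "ScenarioError",
    "DEFAULT_STATE_MEANS",
    "PROBE_IDS",
    "generate_snp_map",
    "generate_case_profile",
    "generate_expression_assays",
    "generate_survival",
    "simulate_cohort",
    "CohortBundle",
]

#: Default per-state LRR means, each sitting centrally inside its calling
#: window (gain ~= log2(3/2), loss ~ single-copy loss with tumor admixture).
DEFAULT_STATE_MEANS = {
    "neutral": 0.0,
    "gain": 0.58,
    "high_gain": 1.3,
    "loss": -0.7,
    "big_loss": -1.5,
}

#: The 11 exon-boundary expression probes assayed per case.
PROBE_IDS = (
    "exon 4-5", "exon 5-6", "exon 6-7", "exon 7-8", "exon 8-9", "exon 9-10",
    "exon 10-11", "exon 24-25", "exon 39-40", "exon 55-56", "exon 69-70",
)


class ScenarioError(ValueError):
    """Raised for inconsistent planted-segment scenarios."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic cohort.

    The defaults are the study conditions the cohort emulates: 56 cases,
    888 intronic SNPs over a ~2.06 Mb gene span, 70 exons, array
    heterozygosity ~0.27, qPCR triplicate noise of 0.1 cycles.
    """

    n_cases: int = 56
    n_snps: int = 888
    gene_span: tuple[int, int] = (2_935_353, 4_994_806)
    chrom: str = "8"
    n_exons: int = 70
    noise_sd_lrr: float = 0.15
    baf_sd: float = 0.05
    het_fraction: float = 0.27
    noise_sd_ct: float = 0.1
    noise_sd_mir_log2: float = 0.25
    mir_dropout: float = 0.05
    survival_hr: float = 2.5
    censor_rate: float = 0.05
    baseline_median_months: float = 24.0
    state_means: dict = field(default_factory=lambda: dict(DEFAULT_STATE_MEANS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 3:
            raise ValueError("n_snps must be >= 3")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.noise_sd_lrr <= 0:
            raise ValueError("noise_sd_lrr must be positive")
        if not 0 < self.het_fraction < 1:
            raise ValueError("het_fraction must be in (0, 1)")
        lo, hi = self.gene_span
        if lo >= hi:
            raise ValueError("gene_span start must precede end")
        if hi - lo < self.n_snps:
            raise ValueError("gene_span too narrow for n_snps distinct positions")


@dataclass(frozen=True)
class PlantedSegment:
    """Ground-truth segment over [start, end) SNP indices (0-based)."""

    start: int
    end: int
    cn_state: str = "neutral"
    allelic_state: str = "normal"  # "normal" | "AI" | "LOH"

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ScenarioError("planted segment must satisfy 0 <= start < end")
        if self.cn_state not in DEFAULT_STATE_MEANS:
            raise ScenarioError(f"unknown CN state {self.cn_state!r}")
        if self.allelic_state not in ("normal", "AI", "LOH"):
            raise ScenarioError(f"unknown allelic state {self.allelic_state!r}")


@dataclass(frozen=True)
class Coupling:
    """Planted monotone link from a SNP's LRR to a probe/miR log2-FC."""

    snp_id: str
    target_id: str
    target_kind: str  # "probe" | "mir"
    slope: float  # log2-FC units per LRR unit; sign is the coupling sign

    @property
    def sign(self) -> int:
        return 1 if self.slope > 0 else -1


@dataclass
class PlantedTruth:
    """Bookkeeping of everything planted in one synthetic cohort."""

    segments: dict[str, list[PlantedSegment]] = field(default_factory=dict)
    probe_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    mir_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    couplings: list[Coupling] = field(default_factory=list)
    hazard_ratio: float | None = None
    survival_groups: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format serializable view (tab-separated sidecar)."""
        rows = []
        for case, segs in self.segments.items():
            for s in segs:
                rows.append({"kind": "segment", "case_id": case, "start": s.start,
                             "end": s.end, "cn_state": s.cn_state,
                             "allelic_state": s.allelic_state,
                             "target_id": "", "value": np.nan, "snp_id": ""})
        for case, shifts in self.probe_shifts.items():
            for probe, s in shifts.items():
                rows.append({"kind": "probe_shift", "case_id": case, "start": -1,
                             "end": -1, "cn_state": "", "allelic_state": "",
                             "target_id": probe, "value": s, "snp_id": ""})
        for case, shifts in self.mir_shifts.items():
            for mir, s in shifts.items():
                rows.append({"kind": "mir_shift", "case_id": case, "start": -1,
                             "end": -1, "cn_state": "", "allelic_state": "",
                             "target_id": mir, "value": s, "snp_id": ""})
        for c in self.couplings:
            rows.append({"kind": "coupling", "case_id": "", "start": -1, "end": -1,
                         "cn_state": c.target_kind, "allelic_state": "",
                         "target_id": c.target_id, "value": c.slope,
                         "snp_id": c.snp_id})
        if self.hazard_ratio is not None:
            rows.append({"kind": "hazard_ratio", "case_id": "", "start": -1,
                         "end": -1, "cn_state": "", "allelic_state": "",
                         "target_id": "", "value": self.hazard_ratio, "snp_id": ""})
        return pd.DataFrame(rows)


def _rng(config: SyntheticConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def generate_snp_map(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Annotation table of n_snps intronic markers over the gene span.

    Positions are distinct, strictly increasing, 1-based coordinates inside
    the span; each SNP gets an intron index in [1, n_exons - 1] proportional
    to its position, and A/B alleles drawn from the four bases.
    """
    rng = _rng(config, rng)
    lo, hi = config.gene_span
    positions = np.sort(
        rng.choice(np.arange(lo, hi + 1), size=config.n_snps, replace=False)
    )
    span = hi - lo
    intron = 1 + ((positions - lo) * (config.n_exons - 1) // (span + 1))
    intron = np.clip(intron, 1, config.n_exons - 1)
    bases = np.array(list("ACGT"))
    allele_a = rng.choice(bases, size=config.n_snps)
    # B allele differs from A at every marker.
    shift = rng.integers(1, 4, size=config.n_snps)
    allele_b = bases[(np.searchsorted(bases, allele_a) + shift) % 4]
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i:05d}" for i in range(config.n_snps)],
            "chrom": config.chrom,
            "pos": positions.astype(np.int64),
            "intron": intron.astype(int),
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )


def _validate_scenario(scenario: Sequence[PlantedSegment], n_snps: int) -> None:
    segs = sorted(scenario, key=lambda s: s.start)
    for s in segs:
        if s.end > n_snps:
            raise ScenarioError("planted segment exceeds the SNP range")
    for a, b in zip(segs[:-1], segs[1:]):
        if b.start < a.end:
            raise ScenarioError("planted segments overlap")


def generate_case_profile(
    snp_map: pd.DataFrame,
    scenario: Sequence[PlantedSegment],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    case_id: str = "",
) -> SnpProfile:
    """Tumor LRR/BAF profile with the scenario's segments planted.

    LRR is the per-state mean plus N(0, noise_sd_lrr).  Germline genotypes
    are heterozygous with probability het_fraction.  Heterozygous tumor BAF
    sits near 0.5 (balanced), splits symmetrically into the two AI bands
    (one band offset per segment, side chosen per SNP), or collapses toward
    0/1 under LOH; homozygous SNPs sit near 0 or 1 regardless of state.
    """
    rng = _rng(config, rng)
    n = len(snp_map)
    _validate_scenario(scenario, n)
    state = np.full(n, "neutral", dtype=object)
    allelic = np.full(n, "normal", dtype=object)
    seg_delta = {}
    for k, seg in enumerate(scenario):
        state[seg.start : seg.end] = seg.cn_state
        allelic[seg.start : seg.end] = seg.allelic_state
        # One AI band offset per segment keeps the band structure coherent.
        seg_delta[k] = rng.uniform(0.10, 0.25)
    means = np.array([config.state_means[s] for s in state], dtype=float)
    lrr = means + rng.normal(0.0, config.noise_sd_lrr, size=n)
    het = rng.random(n) < config.het_fraction
    hom_b = rng.random(n) < 0.5
    genotype = np.where(het, "AB", np.where(hom_b, "BB", "AA")).astype(object)
    baf = np.empty(n)
    hom_center = np.where(hom_b, 1.0, 0.0)
    baf = hom_center + rng.normal(0.0, config.baf_sd, size=n)
    het_center = np.full(n, 0.5)
    for k, seg in enumerate(scenario):
        sl = slice(seg.start, seg.end)
        m = seg.end - seg.start
        side = np.where(rng.random(m) < 0.5, 1.0, -1.0)
        if seg.allelic_state == "AI":
            het_center[sl] = 0.5 + side * seg_delta[k]
        elif seg.allelic_state == "LOH":
            het_center[sl] = 0.5 + side * 0.47
    baf[het] = het_center[het] + rng.normal(0.0, config.baf_sd, size=int(het.sum()))
    baf = np.clip(baf, 0.0, 1.0)
    return SnpProfile(
        snp_ids=snp_map["snp_id"].to_numpy(),
        positions=snp_map["pos"].to_numpy(),
        lrr=lrr,
        baf=baf,
        genotype=genotype,
        case_id=case_id,
        chrom=config.chrom,
    )


def generate_expression_assays(
    case_id: str,
    probe_log2_shifts: dict[str, float],
    mir_log2_shifts: dict[str, float],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triplicate Ct rows and a miR FC table for one case.

    A planted log2 shift ``s`` lowers the tumor target Ct by ``s`` cycles,
    so the ddCt pipeline recovers FC = 2^s up to triplicate noise.  miR fold
    changes are 2^(s + N(0, noise_sd_mir_log2)); each tissue independently
    drops out with probability ``mir_dropout`` (no FC when either did).
    """
    rng = _rng(config, rng)
    for s in list(probe_log2_shifts.values()) + list(mir_log2_shifts.values()):
        if not np.isfinite(s):
            raise ValueError("planted shifts must be finite")
    base_target, base_ref = 26.0, 20.0
    ct_rows = []
    for tissue in ("tumor", "normal"):
        ref_reps = base_ref + rng.normal(0.0, config.noise_sd_ct, size=3)
        ct_rows.append(
            {"case_id": case_id, "probe_id": "*", "tissue": tissue,
             "target": "GAPDH",
             "rep1": ref_reps[0], "rep2": ref_reps[1], "rep3": ref_reps[2]}
        )
    for probe, shift in probe_log2_shifts.items():
        for tissue in ("tumor", "normal"):
            mean_ct = base_target - (shift if tissue == "tumor" else 0.0)
            reps = mean_ct + rng.normal(0.0, config.noise_sd_ct, size=3)
            ct_rows.append(
                {"case_id": case_id, "probe_id": probe, "tissue": tissue,
                 "target": "CSMD1",
                 "rep1": reps[0], "rep2": reps[1], "rep3": reps[2]}
            )
    mir_rows = []
    for mir, shift in mir_log2_shifts.items():
        t_det = rng.random() >= config.mir_dropout
        n_det = rng.random() >= config.mir_dropout
        fc = (
            float(2.0 ** (shift + rng.normal(0.0, config.noise_sd_mir_log2)))
            if (t_det and n_det)
            else np.nan
        )
        mir_rows.append(
            {"case_id": case_id, "mir_id": mir, "tumor_detected": t_det,
             "normal_detected": n_det, "fc": fc}
        )
    return pd.DataFrame(ct_rows), pd.DataFrame(mir_rows)


def generate_survival(
    group_labels: Sequence[str],
    hazard_ratio_by_group: dict[str, float],
    censor_rate: float,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival times (months) with group-dependent hazards.

    The baseline hazard is ln(2)/baseline_median_months; a group with
    hazard multiplier HR has stochastically shorter survival.  Censoring is
    by an independent exponential whose rate is chosen so that each case is
    censored with probability ``censor_rate``.
    """
    for g, hr in hazard_ratio_by_group.items():
        if hr <= 0:
            raise ValueError(f"hazard ratio for group {g!r} must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = _rng(config, rng)
    h0 = np.log(2.0) / config.baseline_median_months
    rows = []
    for i, g in enumerate(group_labels):
        h = h0 * hazard_ratio_by_group[g]
        t_event = rng.exponential(1.0 / h)
        if censor_rate > 0:
            hc = h * censor_rate / (1.0 - censor_rate)
            t_cens = rng.exponential(1.0 / hc)
        else:
            t_cens = np.inf
        t = min(t_event, t_cens)
        rows.append({"group": g, "time": max(t, 1e-6), "event": int(t_event <= t_cens)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort assembly

# Composite-category mixture matching the observed cohort distribution
# (17 unaltered, 6 AI-only, 7 gain+AI, 2 gain, 15 loss+AI, 3 loss,
#  1 loss+LOH, 1 LOH-only, 3 gain+loss+AI, 1 gain+LOH+AI of 56).
_CATEGORY_MIX = (
    ("none", 17), ("ai_only", 6), ("gain_ai", 7), ("gain", 2), ("loss_ai", 15),
    ("loss", 3), ("loss_loh", 1), ("loh_only", 1), ("gain_loss_ai", 3),
    ("gain_loh_ai", 1),
)


def _plant_for_category(cat: str, n_snps: int, rng: np.random.Generator) -> list[PlantedSegment]:
    """Planted segments realizing one composite category."""
    third = n_snps // 3
    lo_len = max(10, n_snps // 6)

    def seg_bounds(region: int) -> tuple[int, int]:
        start = int(rng.integers(region * third, region * third + third - lo_len))
        length = int(rng.integers(lo_len, third))
        return start, min(start + length, (region + 1) * third)

    if cat == "none":
        return []
    if cat == "ai_only":
        # Allelic events on a copy-neutral background are planted gene-wide:
        # boundaries come from LRR segmentation alone, so a sub-segment
        # allelic shift with neutral copy number is not localizable.
        return [PlantedSegment(0, n_snps, "neutral", "AI")]
    if cat == "gain":
        s, e = seg_bounds(int(rng.integers(0, 3)))
        return [PlantedSegment(s, e, "gain", "normal")]
    if cat == "gain_ai":
        s, e = seg_bounds(int(rng.integers(0, 3)))
        return [PlantedSegment(s, e, "gain", "AI")]
    if cat == "loss":
        s, e = seg_bounds(int(rng.integers(0, 3)))
        return [PlantedSegment(s, e, "loss", "normal")]
    if cat == "loss_ai":
        s, e = seg_bounds(int(rng.integers(0, 3)))
        return [PlantedSegment(s, e, "loss", "AI")]
    if cat == "loss_loh":
        s, e = seg_bounds(int(rng.integers(0, 3)))
        return [PlantedSegment(s, e, "loss", "LOH")]
    if cat == "loh_only":
        return [PlantedSegment(0, n_snps, "neutral", "LOH")]
    if cat == "gain_loss_ai":
        s1, e1 = seg_bounds(0)
        s2, e2 = seg_bounds(2)
        return [PlantedSegment(s1, e1, "gain", "AI"), PlantedSegment(s2, e2, "loss", "normal")]
    if cat == "gain_loh_ai":
        s1, e1 = seg_bounds(0)
        # LOH fills the copy-neutral remainder after the gain segment, so the
        # LRR-derived boundary at e1 also delimits the allelic event.
        return [PlantedSegment(s1, e1, "gain", "AI"),
                PlantedSegment(e1, n_snps, "neutral", "LOH")]
    raise ScenarioError(f"unknown category {cat!r}")


@dataclass
class CohortBundle:
    """Everything one synthetic cohort comprises."""

    config: SyntheticConfig
    snp_map: pd.DataFrame
    profiles: list[SnpProfile]
    ct_table: pd.DataFrame
    mir_table: pd.DataFrame
    clinical: pd.DataFrame
    truth: PlantedTruth

    @property
    def case_ids(self) -> list[str]:
        return [p.case_id for p in self.profiles]


def _load_target_mirs() -> list[str]:
    from .io import load_target_mirs

    return load_target_mirs()


def simulate_cohort(
    config: SyntheticConfig | None = None,
    n_couplings_probe: int = 3,
    n_couplings_mir: int = 2,
) -> CohortBundle:
    """Full synthetic cohort: DNA profiles, Ct tables, miR FCs, clinical.

    Case categories are drawn from the cohort mixture; expression shifts
    follow the case's copy-number direction plus per-probe heterogeneity;
    coupled probes/miRs additionally track the LRR state mean at their
    coupled SNP; survival groups split on the case-level planted gene
    shift with hazard ratio ``config.survival_hr``.
    """
    config = config or SyntheticConfig()
    root = np.random.SeedSequence(config.seed)
    keys = root.spawn(6)
    rng_map, rng_cat, rng_dna, rng_expr, rng_surv, rng_cpl = (
        np.random.default_rng(k) for k in keys
    )
    snp_map = generate_snp_map(config, rng_map)
    mirs = _load_target_mirs()
    cats = np.array([c for c, _ in _CATEGORY_MIX], dtype=object)
    weights = np.array([w for _, w in _CATEGORY_MIX], dtype=float)
    weights /= weights.sum()
    case_cats = rng_cat.choice(cats, size=config.n_cases, p=weights)

    truth = PlantedTruth(hazard_ratio=config.survival_hr)
    profiles: list[SnpProfile] = []
    case_ids = [f"S{i + 1:04d}" for i in range(config.n_cases)]
    state_mean_at = {}
    for case, cat in zip(case_ids, case_cats):
        scenario = _plant_for_category(str(cat), config.n_snps, rng_dna)
        truth.segments[case] = scenario
        profiles.append(
            generate_case_profile(snp_map, scenario, config, rng_dna, case_id=case)
        )
        means = np.zeros(config.n_snps)
        for seg in scenario:
            means[seg.start : seg.end] = config.state_means[seg.cn_state]
        state_mean_at[case] = means

    # Couplings: SNPs drawn from the middle of the gene (frequently altered);
    # slope 1.5 log2-FC per LRR unit with random sign.
    snp_ids = snp_map["snp_id"].to_numpy()
    n = config.n_snps
    candidates = rng_cpl.choice(
        np.arange(n // 4, 3 * n // 4), size=n_couplings_probe + n_couplings_mir,
        replace=False,
    )
    couplings = []
    for idx, probe in zip(candidates[:n_couplings_probe], PROBE_IDS):
        couplings.append(Coupling(str(snp_ids[idx]), probe, "probe",
                                  float(1.5 * rng_cpl.choice([-1.0, 1.0]))))
    for idx, mir in zip(candidates[n_couplings_probe:], mirs):
        couplings.append(Coupling(str(snp_ids[idx]), mir, "mir",
                                  float(1.5 * rng_cpl.choice([-1.0, 1.0]))))
    truth.couplings = couplings
    snp_pos = {sid: i for i, sid in enumerate(snp_ids)}

    ct_frames, mir_frames = [], []
    case_gene_shift = {}
    for case, cat in zip(case_ids, case_cats):
        direction = 1.0 if "gain" in str(cat) else (-1.0 if "loss" in str(cat) else 0.0)
        base_shift = rng_expr.normal(1.2 * direction, 0.8)
        probe_shifts = {
            p: base_shift + rng_expr.normal(0.0, 0.4) for p in PROBE_IDS
        }
        mir_shifts = {m: rng_expr.normal(0.8, 0.8) for m in mirs}
        for c in couplings:
            contrib = c.slope * state_mean_at[case][snp_pos[c.snp_id]]
            if c.target_kind == "probe":
                probe_shifts[c.target_id] += contrib
            else:
                mir_shifts[c.target_id] += contrib
        truth.probe_shifts[case] = probe_shifts
        truth.mir_shifts[case] = mir_shifts
        case_gene_shift[case] = float(np.mean(list(probe_shifts.values())))
        ct_df, mir_df = generate_expression_assays(
            case, probe_shifts, mir_shifts, config, rng_expr
        )
        ct_frames.append(ct_df)
        mir_frames.append(mir_df)

    groups = ["high" if case_gene_shift[c] >= 0 else "low" for c in case_ids]
    truth.survival_groups = dict(zip(case_ids, groups))
    surv = generate_survival(
        groups, {"low": 1.0, "high": config.survival_hr}, config.censor_rate,
        config, rng_surv,
    )
    clinical = pd.DataFrame(
        {
            "case_id": case_ids,
            "months": surv["time"].round(1).clip(lower=0.1).to_numpy(),
            "event": surv["event"].to_numpy(),
            "family_history": (rng_surv.random(config.n_cases) < 0.30).astype(int),
            "lymph_node": (rng_surv.random(config.n_cases) < 0.55).astype(int),
        }
    )
    return CohortBundle(
        config=config,
        snp_map=snp_map,
        profiles=profiles,
        ct_table=pd.concat(ct_frames, ignore_index=True),
        mir_table=pd.concat(mir_frames, ignore_index=True),
        clinical=clinical,
        truth=truth,
    )
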