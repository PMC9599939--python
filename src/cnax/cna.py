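"""Somatic copy-number and allelic-state calling from paired SNP-array signals.

The DNA entry point of the pipeline is a per-SNP table of tumor Log R ratio
(LRR, a log-scale proxy for total copy number), tumor B-allele frequency
(BAF), and the germline genotype of each SNP.  This module

* partitions a tumor LRR profile into constant-mean segments by recursive
  binary segmentation with a permutation significance test,
* classifies each segment into a copy-number state from its mean LRR
  (high gain >= 1.0, gain > 0.2, neutral, loss < -0.2, big loss <= -1.0),
* classifies each germline-heterozygous SNP into an allelic state from its
  tumor BAF (allelic imbalance in [0.20, 0.45] or [0.55, 0.80]; loss of
  heterozygosity below 0.20 or above 0.80), and
* rolls SNP- and segment-level calls up into a per-case composite alteration
  category ("Allelic Imbalance, CN Gain, CN Loss, LOH" vocabulary).

Homozygous SNPs sit near BAF 0 or 1 regardless of the somatic state, so
allelic-state calling is restricted to germline-heterozygous markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "CN_STATES",
    "ALLELIC_STATES",
    "InsufficientDataError",
    "SegmentationParams",
    "CnThresholds",
    "BafWindows",
    "SnpProfile",
    "Segment",
    "CaseAlterationCategory",
    "LrrSegmenter",
    "CnaCaller",
    "segment_lrr",
    "classify_segment_cn",
    "classify_snp_baf",
    "call_case_alterations",
    "snp_cna_mask",
    "summarize_cohort_alterations",
]

#: Copy-number states ordered from fewest to most copies.
CN_STATES = ("big_loss", "loss", "neutral", "gain", "high_gain")

#: Allelic states a segment (or informative SNP) can take.
ALLELIC_STATES = ("AI", "LOH", "normal", "indeterminate")

_FLAG_LABELS = (
    ("ai", "Allelic Imbalance"),
    ("cn_gain", "CN Gain"),
    ("cn_loss", "CN Loss"),
    ("loh", "LOH"),
)


class InsufficientDataError(ValueError):
    """Raised when a profile has too few finite markers to segment."""


@dataclass(frozen=True)
class SegmentationParams:
    """Criteria for accepting a candidate change-point.

    significance_threshold
        Family-wise p-value a split must beat (default 5.0e-6).
    max_probe_spacing
        Base-pair gap between adjacent SNPs above which a segment boundary is
        forced (default 1 Mb).
    min_probes
        Minimum markers per segment (default 3).
    n_permutations
        Permutations used to screen the max-|t| split statistic.
    """

    significance_threshold: float = 5.0e-6
    max_probe_spacing: int = 1_000_000
    min_probes: int = 3
    n_permutations: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.significance_threshold < 1.0:
            raise ValueError("significance_threshold must be in (0, 1)")
        if self.min_probes < 2:
            raise ValueError("min_probes must be >= 2")
        if self.max_probe_spacing <= 0 or self.n_permutations <= 0:
            raise ValueError("max_probe_spacing and n_permutations must be positive")


@dataclass(frozen=True)
class CnThresholds:
    """Mean-LRR cut points for copy-number states.

    Boundary semantics follow the calling rules exactly: high gain is
    inclusive (>= 1.0), gain and loss are strict (> 0.2, < -0.2), big loss is
    inclusive (<= -1.0); a mean LRR of exactly +/-0.2 is neutral.
    """

    high_gain_min: float = 1.0
    gain_min: float = 0.2
    loss_max: float = -0.2
    big_loss_max: float = -1.0

    def __post_init__(self) -> None:
        if not self.big_loss_max < self.loss_max < 0 < self.gain_min < self.high_gain_min:
            raise ValueError("thresholds must satisfy big_loss < loss < 0 < gain < high_gain")


@dataclass(frozen=True)
class BafWindows:
    """Tumor-BAF windows for allelic states of heterozygous SNPs.

    AI bands are closed intervals; LOH is strict (< loh_low or > loh_high).
    The remaining band around 0.5 is balanced/normal.
    """

    ai_low: tuple[float, float] = (0.20, 0.45)
    ai_high: tuple[float, float] = (0.55, 0.80)
    loh_low: float = 0.20
    loh_high: float = 0.80

    def __post_init__(self) -> None:
        lo, hi = self.ai_low
        lo2, hi2 = self.ai_high
        if not (0 <= lo < hi < lo2 < hi2 <= 1):
            raise ValueError("AI bands must be ordered within [0, 1]")
        if self.loh_low > lo or self.loh_high < hi2:
            raise ValueError("LOH cut points must lie outside the AI bands")


@dataclass
class SnpProfile:
    """Per-case tumor profile over the SNPs of one gene region.

    Positions are 1-based base-pair coordinates on a single chromosome and
    must be strictly increasing.  ``genotype`` holds germline calls from the
    matched normal ("AA", "AB", "BB", or "NC" for missing).  BAF may be NaN
    (undetected); LRR must be finite.
    """

    snp_ids: np.ndarray
    positions: np.ndarray
    lrr: np.ndarray
    baf: np.ndarray
    genotype: np.ndarray
    case_id: str = ""
    chrom: str = "8"

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        self.genotype = np.asarray(self.genotype, dtype=object)
        n = len(self.snp_ids)
        if not all(len(a) == n for a in (self.positions, self.lrr, self.baf, self.genotype)):
            raise ValueError("profile vectors must have equal length")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        finite_baf = self.baf[np.isfinite(self.baf)]
        if finite_baf.size and (finite_baf.min() < 0 or finite_baf.max() > 1):
            raise ValueError("BAF must lie in [0, 1] where present")
        if not np.all(np.isfinite(self.lrr)):
            raise ValueError("LRR must be finite")

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.snp_ids)


@dataclass
class Segment:
    """Contiguous SNP run (0-based, half-open indices) with its calls."""

    start: int
    end: int
    start_pos: int
    end_pos: int
    n_probes: int
    mean_lrr: float
    cn_state: str | None = None
    allelic_state: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.n_probes != self.end - self.start:
            raise ValueError("n_probes inconsistent with index range")


@dataclass(frozen=True)
class CaseAlterationCategory:
    """Composite per-case alteration flags with the canonical label."""

    ai: bool = False
    cn_gain: bool = False
    cn_loss: bool = False
    loh: bool = False

    @property
    def altered(self) -> bool:
        return self.ai or self.cn_gain or self.cn_loss or self.loh

    @property
    def label(self) -> str:
        parts = [text for attr, text in _FLAG_LABELS if getattr(self, attr)]
        return ", ".join(parts) if parts else "not observed"

    @classmethod
    def from_label(cls, label: str) -> "CaseAlterationCategory":
        label = label.strip()
        if label == "not observed":
            return cls()
        parts = {p.strip() for p in label.split(",")}
        known = {text for _, text in _FLAG_LABELS}
        unknown = parts - known
        if unknown:
            raise ValueError(f"unknown alteration terms: {sorted(unknown)}")
        return cls(
            ai="Allelic Imbalance" in parts,
            cn_gain="CN Gain" in parts,
            cn_loss="CN Loss" in parts,
            loh="LOH" in parts,
        )


# ---------------------------------------------------------------------------
# segmentation


def _split_t_stats(x: np.ndarray, min_probes: int) -> tuple[np.ndarray, np.ndarray]:
    """|t| of the two-sample split at every admissible split index.

    Split index k partitions ``x`` into x[:k] and x[k:]; admissible k keep at
    least ``min_probes`` markers on each side.  Uses pooled-variance t.
    """
    n = len(x)
    ks = np.arange(min_probes, n - min_probes + 1)
    if ks.size == 0:
        return ks, np.empty(0)
    cs = np.cumsum(x)
    cq = np.cumsum(x * x)
    n1 = ks.astype(float)
    n2 = n - n1
    s1 = cs[ks - 1]
    q1 = cq[ks - 1]
    m1 = s1 / n1
    m2 = (cs[-1] - s1) / n2
    ss = np.maximum((q1 - n1 * m1**2) + ((cq[-1] - q1) - n2 * m2**2), 0.0)
    sp2 = ss / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    degenerate = sp2 <= 0
    if np.any(degenerate):
        t = np.where(degenerate, np.where(m1 != m2, np.inf, 0.0), t)
    return ks, t


def _max_abs_t_rows(xs: np.ndarray, min_probes: int) -> np.ndarray:
    """Row-wise max |t| over admissible splits for a matrix of profiles."""
    c, n = xs.shape
    ks = np.arange(min_probes, n - min_probes + 1)
    cs = np.cumsum(xs, axis=1)
    cq = np.cumsum(xs * xs, axis=1)
    n1 = ks.astype(float)
    n2 = n - n1
    s1 = cs[:, ks - 1]
    q1 = cq[:, ks - 1]
    m1 = s1 / n1
    m2 = (cs[:, -1:] - s1) / n2
    ss = np.maximum((q1 - n1 * m1**2) + ((cq[:, -1:] - q1) - n2 * m2**2), 0.0)
    sp2 = ss / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = np.where(sp2 <= 0, np.where(m1 != m2, np.inf, 0.0), t)
    return t.max(axis=1)


def _split_pvalue(
    x: np.ndarray, t_obs: float, params: SegmentationParams, rng: np.random.Generator
) -> float:
    """Family-wise p-value of the best split of ``x``.

    Hybrid of a permutation screen and an analytic tail bound: the reported p
    is the permutation estimate as soon as any permuted max-|t| reaches the
    observed value; if none of ``n_permutations`` does, the Bonferroni-
    corrected two-sided t tail over admissible splits is reported, which can
    resolve below the permutation granularity of 1/n_permutations.
    """
    n = len(x)
    n_splits = max(n - 2 * params.min_probes + 1, 1)
    if np.isinf(t_obs):
        p_tail = 0.0
    else:
        p_tail = min(1.0, n_splits * 2.0 * stats.t.sf(t_obs, n - 2))
    if p_tail >= params.significance_threshold:
        # Permutations can only report a larger p than the analytic bound at
        # this resolution; the split is rejected either way.
        return max(p_tail, 1.0 / params.n_permutations)
    done = 0
    exceed = 0
    while done < params.n_permutations:
        chunk = min(1000, params.n_permutations - done)
        perms = rng.permuted(np.broadcast_to(x, (chunk, n)).copy(), axis=1)
        tmax = _max_abs_t_rows(perms, params.min_probes)
        exceed += int(np.count_nonzero(tmax >= t_obs - 1e-12))
        done += chunk
        if exceed:
            return exceed / done
    return p_tail


def _segment_block(
    x: np.ndarray,
    offset: int,
    params: SegmentationParams,
    rng: np.random.Generator,
    out: list[tuple[int, int]],
) -> None:
    n = len(x)
    if n < 2 * params.min_probes:
        out.append((offset, offset + n))
        return
    ks, ts = _split_t_stats(x, params.min_probes)
    best = int(np.argmax(ts))
    k, t_obs = int(ks[best]), float(ts[best])
    p = _split_pvalue(x, t_obs, params, rng)
    if p < params.significance_threshold:
        _segment_block(x[:k], offset, params, rng, out)
        _segment_block(x[k:], offset + k, params, rng, out)
    else:
        out.append((offset, offset + n))


def segment_lrr(
    profile: SnpProfile,
    params: SegmentationParams | None = None,
    random_state: int | np.random.Generator = 0,
) -> list[Segment]:
    """Partition a tumor LRR profile into constant-mean segments.

    Recursive binary segmentation: at each step the split maximizing the
    two-sample t statistic is tested against ``significance_threshold`` (see
    :func:`_split_pvalue`); accepted splits recurse into both children, each
    of which keeps at least ``min_probes`` markers.  Inter-SNP gaps larger
    than ``max_probe_spacing`` force segment boundaries.  The returned
    segments tile ``[0, len(profile))`` exactly.
    """
    params = params or SegmentationParams()
    rng = (
        random_state
        if isinstance(random_state, np.random.Generator)
        else np.random.default_rng(random_state)
    )
    lrr = profile.lrr
    if np.count_nonzero(np.isfinite(lrr)) < params.min_probes:
        raise InsufficientDataError(
            f"need at least {params.min_probes} finite LRR values, "
            f"got {int(np.count_nonzero(np.isfinite(lrr)))}"
        )
    gaps = np.diff(profile.positions)
    forced = np.flatnonzero(gaps > params.max_probe_spacing) + 1
    blocks = np.concatenate([[0], forced, [len(lrr)]])
    bounds: list[tuple[int, int]] = []
    for b0, b1 in zip(blocks[:-1], blocks[1:]):
        _segment_block(lrr[b0:b1], int(b0), params, rng, bounds)
    segments = []
    for s, e in bounds:
        segments.append(
            Segment(
                start=s,
                end=e,
                start_pos=int(profile.positions[s]),
                end_pos=int(profile.positions[e - 1]),
                n_probes=e - s,
                mean_lrr=float(np.mean(lrr[s:e])),
            )
        )
    return segments


# ---------------------------------------------------------------------------
# state classification


def classify_segment_cn(mean_lrr: float, thresholds: CnThresholds | None = None) -> str:
    """Copy-number state of a segment from its mean LRR."""
    thresholds = thresholds or CnThresholds()
    if not np.isfinite(mean_lrr):
        raise ValueError("mean LRR must be finite")
    if mean_lrr >= thresholds.high_gain_min:
        return "high_gain"
    if mean_lrr > thresholds.gain_min:
        return "gain"
    if mean_lrr <= thresholds.big_loss_max:
        return "big_loss"
    if mean_lrr < thresholds.loss_max:
        return "loss"
    return "neutral"


def classify_snp_baf(
    baf: float, germline_genotype: str, windows: BafWindows | None = None
) -> str:
    """Allelic call of one SNP from its tumor BAF and germline genotype.

    Only germline-heterozygous SNPs are informative; homozygous or missing
    genotypes (or missing BAF) return ``"not_informative"``.
    """
    windows = windows or BafWindows()
    if germline_genotype != "AB" or baf is None or not np.isfinite(baf):
        return "not_informative"
    if baf < 0 or baf > 1:
        raise ValueError("BAF must lie in [0, 1]")
    if baf < windows.loh_low or baf > windows.loh_high:
        return "LOH"
    if windows.ai_low[0] <= baf <= windows.ai_low[1] or windows.ai_high[0] <= baf <= windows.ai_high[1]:
        return "AI"
    return "normal"


def _segment_allelic_state(
    calls: np.ndarray, start: int, end: int, min_het_fraction: float
) -> str:
    seg_calls = calls[start:end]
    informative = seg_calls[seg_calls != "not_informative"]
    if informative.size == 0:
        return "indeterminate"
    frac_loh = float(np.mean(informative == "LOH"))
    frac_ai = float(np.mean(informative == "AI"))
    if frac_loh >= min_het_fraction:  # LOH takes precedence over AI
        return "LOH"
    if frac_ai >= min_het_fraction:
        return "AI"
    return "normal"


def call_case_alterations(
    profile: SnpProfile,
    seg_params: SegmentationParams | None = None,
    thresholds: CnThresholds | None = None,
    windows: BafWindows | None = None,
    min_het_fraction: float = 0.5,
    random_state: int | np.random.Generator = 0,
) -> tuple[list[Segment], np.ndarray, CaseAlterationCategory]:
    """Full per-case calling: segments, per-SNP allelic calls, and category.

    A segment is called AI (resp. LOH) when at least ``min_het_fraction`` of
    its informative germline-het SNPs fall in the AI (resp. LOH) windows,
    with LOH taking precedence when both qualify.  Case flags aggregate over
    segments: CN Gain from any gain/high-gain segment, CN Loss from any
    loss/big-loss segment, AI/LOH from any segment with that allelic state.
    """
    thresholds = thresholds or CnThresholds()
    windows = windows or BafWindows()
    segments = segment_lrr(profile, seg_params, random_state)
    snp_calls = np.array(
        [classify_snp_baf(b, g, windows) for b, g in zip(profile.baf, profile.genotype)],
        dtype=object,
    )
    for seg in segments:
        seg.cn_state = classify_segment_cn(seg.mean_lrr, thresholds)
        seg.allelic_state = _segment_allelic_state(
            snp_calls, seg.start, seg.end, min_het_fraction
        )
    category = CaseAlterationCategory(
        ai=any(s.allelic_state == "AI" for s in segments),
        cn_gain=any(s.cn_state in ("gain", "high_gain") for s in segments),
        cn_loss=any(s.cn_state in ("loss", "big_loss") for s in segments),
        loh=any(s.allelic_state == "LOH" for s in segments),
    )
    return segments, snp_calls, category


def snp_cna_mask(segments: Sequence[Segment], n_snps: int) -> np.ndarray:
    """Boolean per-SNP flag: SNP lies in a segment carrying an alteration.

    A SNP "shows a CNA" when its segment is copy-number non-neutral or has an
    AI/LOH allelic state; this is the subset selector used downstream for
    copy-number/expression correlations.
    """
    mask = np.zeros(n_snps, dtype=bool)
    for seg in segments:
        if seg.cn_state not in (None, "neutral") or seg.allelic_state in ("AI", "LOH"):
            mask[seg.start : seg.end] = True
    return mask


def summarize_cohort_alterations(
    categories: Iterable[CaseAlterationCategory],
) -> dict[str, float]:
    """Cohort frequency table over composite alteration categories.

    Groups mirror the cohort-level reporting: cases with loss/LOH but no
    gain (AI subcount within), gain without loss/LOH (AI subcount within),
    AI only, and mixed gain with loss/LOH.
    """
    cats = list(categories)
    if not cats:
        raise ValueError("no cases supplied")
    n = len(cats)
    altered = [c for c in cats if c.altered]
    loss_loh = [c for c in cats if (c.cn_loss or c.loh) and not c.cn_gain]
    gain_only = [c for c in cats if c.cn_gain and not (c.cn_loss or c.loh)]
    ai_only = [c for c in cats if c.ai and not (c.cn_gain or c.cn_loss or c.loh)]
    mixed = [c for c in cats if c.cn_gain and (c.cn_loss or c.loh)]
    return {
        "n_cases": n,
        "n_altered": len(altered),
        "pct_altered": 100.0 * len(altered) / n,
        "loss_loh_without_gain": len(loss_loh),
        "loss_loh_with_ai": sum(c.ai for c in loss_loh),
        "gain_without_loss_loh": len(gain_only),
        "gain_with_ai": sum(c.ai for c in gain_only),
        "ai_only": len(ai_only),
        "mixed_gain_loss": len(mixed),
        "n_ai": sum(c.ai for c in cats),
        "n_cn_gain": sum(c.cn_gain for c in cats),
        "n_cn_loss": sum(c.cn_loss for c in cats),
        "n_loh": sum(c.loh for c in cats),
    }


# ---------------------------------------------------------------------------
# estimators


class LrrSegmenter(BaseEstimator):
    """Change-point segmentation of one LRR profile (sklearn-style).

    Parameters mirror :class:`SegmentationParams`.  After :meth:`fit`,
    ``segments_`` holds the fitted :class:`Segment` list and ``labels_`` the
    per-SNP segment index (a piecewise-constant labelling, clustering-like).
    """

    def __init__(
        self,
        significance_threshold: float = 5.0e-6,
        max_probe_spacing: int = 1_000_000,
        min_probes: int = 3,
        n_permutations: int = 10_000,
        random_state: int = 0,
    ):
        self.significance_threshold = significance_threshold
        self.max_probe_spacing = max_probe_spacing
        self.min_probes = min_probes
        self.n_permutations = n_permutations
        self.random_state = random_state

    def _params(self) -> SegmentationParams:
        return SegmentationParams(
            significance_threshold=self.significance_threshold,
            max_probe_spacing=self.max_probe_spacing,
            min_probes=self.min_probes,
            n_permutations=self.n_permutations,
        )

    def fit(self, X: SnpProfile, y=None) -> "LrrSegmenter":
        self.segments_ = segment_lrr(X, self._params(), self.random_state)
        labels = np.empty(len(X), dtype=int)
        for i, seg in enumerate(self.segments_):
            labels[seg.start : seg.end] = i
        self.labels_ = labels
        return self

    def fit_predict(self, X: SnpProfile, y=None) -> np.ndarray:
        return self.fit(X).labels_


class CnaCaller(BaseEstimator):
    """Cohort-level somatic alteration caller (sklearn-style estimator).

    ``fit`` takes a sequence of :class:`SnpProfile` (one per case) and
    exposes fitted attributes:

    segments_
        Long-format DataFrame of annotated segments across cases.
    snp_calls_
        DataFrame (cases x SNPs) of per-SNP allelic calls.
    cna_matrix_
        Boolean DataFrame (cases x SNPs): SNP lies in an altered segment.
    lrr_matrix_
        DataFrame (cases x SNPs) of tumor LRR, the signal correlated with
        expression downstream.
    categories_
        Per-case composite category flags and canonical label.
    summary_
        Cohort frequency table from :func:`summarize_cohort_alterations`.
    """

    def __init__(
        self,
        significance_threshold: float = 5.0e-6,
        max_probe_spacing: int = 1_000_000,
        min_probes: int = 3,
        n_permutations: int = 10_000,
        min_het_fraction: float = 0.5,
        random_state: int = 0,
    ):
        self.significance_threshold = significance_threshold
        self.max_probe_spacing = max_probe_spacing
        self.min_probes = min_probes
        self.n_permutations = n_permutations
        self.min_het_fraction = min_het_fraction
        self.random_state = random_state

    def fit(self, X: Sequence[SnpProfile], y=None) -> "CnaCaller":
        profiles = [X] if isinstance(X, SnpProfile) else list(X)
        if not profiles:
            raise ValueError("no profiles supplied")
        params = SegmentationParams(
            significance_threshold=self.significance_threshold,
            max_probe_spacing=self.max_probe_spacing,
            min_probes=self.min_probes,
            n_permutations=self.n_permutations,
        )
        rng = np.random.default_rng(self.random_state)
        seg_rows, call_rows, cna_rows, lrr_rows, cat_rows = [], {}, {}, {}, []
        snp_index = None
        for prof in profiles:
            case = prof.case_id or f"case{len(cat_rows)}"
            if snp_index is None:
                snp_index = pd.Index(prof.snp_ids, name="snp_id")
            segments, snp_calls, category = call_case_alterations(
                prof, params, min_het_fraction=self.min_het_fraction, random_state=rng
            )
            for seg in segments:
                seg_rows.append(
                    {
                        "case_id": case,
                        "chrom": prof.chrom,
                        "start": seg.start,
                        "end": seg.end,
                        "start_pos": seg.start_pos,
                        "end_pos": seg.end_pos,
                        "n_probes": seg.n_probes,
                        "mean_lrr": seg.mean_lrr,
                        "cn_state": seg.cn_state,
                        "allelic_state": seg.allelic_state,
                    }
                )
            call_rows[case] = snp_calls
            cna_rows[case] = snp_cna_mask(segments, len(prof))
            lrr_rows[case] = prof.lrr
            cat_rows.append(
                {
                    "case_id": case,
                    "ai": category.ai,
                    "cn_gain": category.cn_gain,
                    "cn_loss": category.cn_loss,
                    "loh": category.loh,
                    "label": category.label,
                }
            )
        self.segments_ = pd.DataFrame(seg_rows)
        self.snp_calls_ = pd.DataFrame.from_dict(
            call_rows, orient="index", columns=snp_index
        )
        self.cna_matrix_ = pd.DataFrame.from_dict(
            cna_rows, orient="index", columns=snp_index
        )
        self.lrr_matrix_ = pd.DataFrame.from_dict(
            lrr_rows, orient="index", columns=snp_index
        )
        self.categories_ = pd.DataFrame(cat_rows).set_index("case_id")
        self.summary_ = summarize_cohort_alterations(
            [
                CaseAlterationCategory(r.ai, r.cn_gain, r.cn_loss, r.loh)
                for r in self.categories_.itertuples()
            ]
        )
        return self
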