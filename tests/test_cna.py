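"""Unit and property tests for segmentation and CN/allelic classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnax.cna import (
    BafWindows,
    CaseAlterationCategory,
    CnaCaller,
    CnThresholds,
    InsufficientDataError,
    LrrSegmenter,
    SegmentationParams,
    SnpProfile,
    call_case_alterations,
    classify_segment_cn,
    classify_snp_baf,
    segment_lrr,
    snp_cna_mask,
    summarize_cohort_alterations,
)
from cnax.cna import _split_t_stats


def _profile(lrr, positions=None, baf=None, genotype=None, case_id="c"):
    n = len(lrr)
    return SnpProfile(
        snp_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        positions=np.asarray(positions if positions is not None else np.arange(1, n + 1) * 1000),
        lrr=np.asarray(lrr, dtype=float),
        baf=np.asarray(baf if baf is not None else np.full(n, 0.5)),
        genotype=np.asarray(genotype if genotype is not None else ["AB"] * n, dtype=object),
        case_id=case_id,
    )


class TestClassifySegmentCn:
    @pytest.mark.parametrize(
        "mean_lrr,state",
        [
            (1.0, "high_gain"),   # boundary inclusive
            (1.5, "high_gain"),
            (0.2, "neutral"),     # gain cut is strict
            (0.21, "gain"),
            (0.0, "neutral"),
            (-0.2, "neutral"),    # loss cut is strict
            (-0.5, "loss"),
            (-1.0, "big_loss"),   # boundary inclusive
            (-2.0, "big_loss"),
        ],
    )
    def test_boundaries(self, mean_lrr, state):
        assert classify_segment_cn(mean_lrr) == state

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_segment_cn(float("nan"))

    @given(st.floats(min_value=-3, max_value=3, allow_nan=False))
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_mean_lrr(self, x):
        """Higher mean LRR never maps to a lower-copy state."""
        order = {s: i for i, s in enumerate(("big_loss", "loss", "neutral", "gain", "high_gain"))}
        a, b = classify_segment_cn(x), classify_segment_cn(x + 0.3)
        assert order[b] >= order[a]

    def test_threshold_ordering_validated(self):
        with pytest.raises(ValueError):
            CnThresholds(gain_min=1.5)


class TestClassifySnpBaf:
    @pytest.mark.parametrize(
        "baf,genotype,call",
        [
            (0.30, "AB", "AI"),
            (0.20, "AB", "AI"),    # AI band endpoints included
            (0.45, "AB", "AI"),
            (0.55, "AB", "AI"),
            (0.80, "AB", "AI"),
            (0.50, "AB", "normal"),
            (0.90, "AB", "LOH"),
            (0.10, "AB", "LOH"),
            (0.95, "AA", "not_informative"),
            (0.30, "BB", "not_informative"),
            (0.30, "NC", "not_informative"),
            (float("nan"), "AB", "not_informative"),
        ],
    )
    def test_calls(self, baf, genotype, call):
        assert classify_snp_baf(baf, genotype) == call

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_snp_baf(1.2, "AB")


class TestSegmentLrr:
    def test_constant_profile_single_segment(self):
        segs = segment_lrr(_profile(np.zeros(30)))
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 30)

    def test_step_profile_boundary_recovered(self, rng):
        lrr = np.concatenate([rng.normal(0, 0.05, 50), rng.normal(1.3, 0.05, 50)])
        segs = segment_lrr(_profile(lrr), random_state=1)
        assert len(segs) == 2
        assert abs(segs[0].end - 50) <= 2

    def test_segments_tile_profile(self, rng):
        """Coverage and disjointness over random multi-step profiles."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            lrr = np.concatenate(
                [r.normal(mu, 0.1, 25) for mu in (0.0, -0.7, 0.0, 1.3)]
            )
            segs = segment_lrr(_profile(lrr), random_state=seed)
            bounds = [(s.start, s.end) for s in segs]
            assert bounds[0][0] == 0 and bounds[-1][1] == len(lrr)
            for (a, b), (c, d) in zip(bounds[:-1], bounds[1:]):
                assert b == c

    def test_best_split_matches_exhaustive_search(self, rng):
        """Vectorized max-t split equals a brute-force loop on <=20 SNPs."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = int(r.integers(7, 21))
            x = r.normal(0, 1, n)
            ks, ts = _split_t_stats(x, min_probes=3)
            # independent oracle: direct two-sample t at every split
            best_k, best_t = None, -np.inf
            for k in range(3, n - 3 + 1):
                a, b = x[:k], x[k:]
                sp2 = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)) / (n - 2)
                t = abs(a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
                if t > best_t:
                    best_k, best_t = k, t
            assert ks[np.argmax(ts)] == best_k
            assert np.isclose(ts.max(), best_t)

    def test_large_gap_forces_boundary(self):
        positions = np.concatenate([np.arange(1, 11) * 1000, 5_000_000 + np.arange(10) * 1000])
        segs = segment_lrr(_profile(np.zeros(20), positions=positions))
        assert len(segs) == 2
        assert segs[0].end == 10

    def test_too_few_probes_raises(self):
        with pytest.raises(InsufficientDataError):
            segment_lrr(_profile([0.0, 0.1]))

    def test_deterministic_for_fixed_state(self, rng):
        lrr = rng.normal(0, 0.3, 60)
        a = segment_lrr(_profile(lrr), random_state=5)
        b = segment_lrr(_profile(lrr), random_state=5)
        assert [(s.start, s.end) for s in a] == [(s.start, s.end) for s in b]

    def test_segmenter_estimator_labels(self, rng):
        lrr = np.concatenate([np.zeros(40), np.full(40, 1.3)]) + rng.normal(0, 0.05, 80)
        seg = LrrSegmenter(random_state=0)
        labels = seg.fit_predict(_profile(lrr))
        assert len(np.unique(labels)) == len(seg.segments_)
        assert seg.get_params()["min_probes"] == 3


class TestCaseCalls:
    def test_all_neutral_not_observed(self):
        _, _, cat = call_case_alterations(_profile(np.zeros(30), genotype=["AA"] * 30))
        assert cat.label == "not observed"

    def test_gain_with_ai(self, rng):
        lrr = np.concatenate([rng.normal(0, 0.05, 40), rng.normal(0.58, 0.05, 40)])
        baf = np.concatenate([rng.normal(0.5, 0.02, 40), 0.3 + rng.normal(0, 0.02, 40)])
        prof = _profile(lrr, baf=np.clip(baf, 0, 1))
        _, _, cat = call_case_alterations(prof, random_state=2)
        assert cat.label == "Allelic Imbalance, CN Gain"

    def test_loss_with_loh(self, rng):
        lrr = np.concatenate([rng.normal(0, 0.05, 40), rng.normal(-0.7, 0.05, 40)])
        baf = np.concatenate([rng.normal(0.5, 0.02, 40), np.full(40, 0.95)])
        prof = _profile(lrr, baf=np.clip(baf, 0, 1))
        _, _, cat = call_case_alterations(prof, random_state=2)
        assert cat.label == "CN Loss, LOH"

    def test_loh_precedence_over_ai(self):
        """A segment qualifying for both AI and LOH fractions is called LOH."""
        baf = np.array([0.95] * 6 + [0.3] * 4)
        prof = _profile(np.zeros(10), baf=baf)
        segs, _, cat = call_case_alterations(prof, min_het_fraction=0.3)
        assert segs[0].allelic_state == "LOH"
        assert cat.loh and not cat.ai

    def test_homozygous_only_indeterminate(self):
        prof = _profile(np.zeros(10), baf=np.full(10, 0.95), genotype=["AA"] * 10)
        segs, _, _ = call_case_alterations(prof)
        assert segs[0].allelic_state == "indeterminate"

    def test_snp_cna_mask_marks_altered_segments(self, rng):
        lrr = np.concatenate([rng.normal(0, 0.05, 40), rng.normal(-0.7, 0.05, 40)])
        prof = _profile(lrr, genotype=["AA"] * 80)
        segs, _, _ = call_case_alterations(prof, random_state=0)
        mask = snp_cna_mask(segs, 80)
        assert not mask[:38].any() and mask[42:].all()


class TestCategoryAndSummary:
    def test_label_round_trip(self):
        for label in ("not observed", "Allelic Imbalance", "CN Loss, LOH",
                      "Allelic Imbalance, CN Gain, CN Loss"):
            assert CaseAlterationCategory.from_label(label).label == label

    def test_unknown_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            CaseAlterationCategory.from_label("Copy Gain")

    def test_all_not_observed_zero_percent(self):
        out = summarize_cohort_alterations([CaseAlterationCategory()] * 4)
        assert out["pct_altered"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort_alterations([])


def test_cna_caller_cohort_shapes(small_config, small_map):
    from cnax.synthetic import PlantedSegment, generate_case_profile

    rng = np.random.default_rng(1)
    profiles = [
        generate_case_profile(small_map, [PlantedSegment(50, 100, "gain", "AI")],
                              small_config, rng, case_id=f"c{i}")
        for i in range(3)
    ]
    caller = CnaCaller(random_state=0).fit(profiles)
    assert caller.lrr_matrix_.shape == (3, 100)
    assert caller.cna_matrix_.dtypes.map(lambda d: d == bool).all()
    assert set(caller.categories_.index) == {"c0", "c1", "c2"}
    assert caller.summary_["n_cases"] == 3
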