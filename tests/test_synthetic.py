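"""Tests for the synthetic cohort generator and its planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnax.synthetic import (
    CohortBundle,
    PlantedSegment,
    ScenarioError,
    SyntheticConfig,
    generate_case_profile,
    generate_expression_assays,
    generate_snp_map,
    generate_survival,
    simulate_cohort,
)


class TestConfig:
    def test_defaults_are_study_scale(self):
        cfg = SyntheticConfig()
        assert cfg.n_snps == 888 and cfg.n_cases == 56
        assert cfg.gene_span == (2_935_353, 4_994_806)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_snps=2), dict(noise_sd_lrr=0.0), dict(het_fraction=0.0),
         dict(het_fraction=1.0), dict(gene_span=(10, 5))],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestSnpMap:
    def test_positions_inside_span_and_increasing(self):
        cfg = SyntheticConfig(seed=4)
        m = generate_snp_map(cfg)
        assert len(m) == 888
        assert m["pos"].between(2_935_353, 4_994_806).all()
        assert (m["pos"].diff().dropna() > 0).all()
        assert m["intron"].between(1, 69).all()
        assert (m["allele_a"] != m["allele_b"]).all()

    def test_minimal_size(self):
        m = generate_snp_map(SyntheticConfig(n_snps=3, seed=0))
        assert len(m) == 3 and (m["pos"].diff().dropna() > 0).all()

    def test_same_seed_byte_identical(self):
        cfg = SyntheticConfig(seed=9)
        a = generate_snp_map(cfg).to_csv()
        b = generate_snp_map(cfg).to_csv()
        assert a == b


class TestCaseProfile:
    def test_no_planted_signal_stays_near_zero(self, small_map, small_config):
        cfg = SyntheticConfig(n_snps=100, noise_sd_lrr=0.01, seed=1)
        prof = generate_case_profile(small_map, [], cfg, np.random.default_rng(0))
        assert np.abs(prof.lrr).max() < 0.05

    def test_overlapping_segments_rejected(self, small_map, small_config):
        with pytest.raises(ScenarioError):
            generate_case_profile(
                small_map,
                [PlantedSegment(0, 30, "gain"), PlantedSegment(20, 50, "loss")],
                small_config,
            )

    def test_out_of_range_segment_rejected(self, small_map, small_config):
        with pytest.raises(ScenarioError):
            generate_case_profile(small_map, [PlantedSegment(50, 200, "gain")], small_config)

    def test_gain_segment_mean_in_window(self, small_map):
        """Monte-Carlo separability: the 20-SNP gain-segment mean LRR falls in
        (0.2, 1.0) in at least 99% of draws at the default noise level."""
        cfg = SyntheticConfig(n_snps=100, noise_sd_lrr=0.15, seed=0)
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            prof = generate_case_profile(
                small_map, [PlantedSegment(40, 60, "gain")], cfg, rng
            )
            hits += 0.2 < prof.lrr[40:60].mean() < 1.0
        assert hits / n_rep >= 0.99

    def test_loh_baf_outside_het_band(self, small_map):
        """Planted LOH pushes >=90% of het-SNP BAFs outside [0.2, 0.8]."""
        cfg = SyntheticConfig(n_snps=100, baf_sd=0.05, seed=0)
        rng = np.random.default_rng(7)
        fracs = []
        for _ in range(200):
            prof = generate_case_profile(
                small_map, [PlantedSegment(0, 100, "neutral", "LOH")], cfg, rng
            )
            het = prof.genotype == "AB"
            baf = prof.baf[het]
            fracs.append(np.mean((baf < 0.2) | (baf > 0.8)))
        assert np.mean(fracs) >= 0.9

    def test_het_fraction_near_target(self, small_map):
        cfg = SyntheticConfig(n_snps=100, het_fraction=0.27, seed=0)
        rng = np.random.default_rng(5)
        het = [
            (generate_case_profile(small_map, [], cfg, rng).genotype == "AB").mean()
            for _ in range(50)
        ]
        assert np.mean(het) == pytest.approx(0.27, abs=0.03)


class TestExpressionAssays:
    def test_null_shift_unit_fc(self):
        cfg = SyntheticConfig(noise_sd_ct=1e-9, seed=0)
        ct, _ = generate_expression_assays("c", {"e1": 0.0}, {}, cfg, np.random.default_rng(0))
        from cnax.qpcr import DdctFoldChange

        out = DdctFoldChange().transform(ct)
        assert out["fc"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_shift_one_doubles_fc(self):
        """A planted shift of +1 log2 (= -1 ddCt cycle) yields FC = 2."""
        cfg = SyntheticConfig(noise_sd_ct=1e-9, seed=0)
        ct, _ = generate_expression_assays("c", {"e1": 1.0}, {}, cfg, np.random.default_rng(0))
        from cnax.qpcr import DdctFoldChange

        assert DdctFoldChange().transform(ct)["fc"].iloc[0] == pytest.approx(2.0, abs=1e-5)

    def test_nonfinite_shift_rejected(self):
        cfg = SyntheticConfig(seed=0)
        with pytest.raises(ValueError):
            generate_expression_assays("c", {"e1": float("inf")}, {}, cfg)

    def test_mir_dropout_removes_fc(self):
        cfg = SyntheticConfig(mir_dropout=1.0, seed=0)
        _, mir = generate_expression_assays("c", {}, {"m1": 0.5}, cfg, np.random.default_rng(0))
        assert mir["fc"].isna().all()


class TestSurvivalGenerator:
    def test_no_censoring_all_events(self):
        cfg = SyntheticConfig(seed=0)
        df = generate_survival(["A"] * 50, {"A": 1.0}, 0.0, cfg, np.random.default_rng(0))
        assert (df["event"] == 1).all()

    def test_invalid_hr_rejected(self):
        with pytest.raises(ValueError):
            generate_survival(["A"], {"A": -1.0}, 0.0, SyntheticConfig(seed=0))

    def test_censor_rate_matches_target(self):
        cfg = SyntheticConfig(seed=0)
        df = generate_survival(["A"] * 4000, {"A": 1.0}, 0.3, cfg, np.random.default_rng(1))
        assert (1 - df["event"]).mean() == pytest.approx(0.3, abs=0.03)

    def test_null_hr_logrank_p_uniform(self):
        """Under HR=1 the log-rank p-value is uniform (KS over 500 cohorts)."""
        from cnax.survival import km_logrank

        cfg = SyntheticConfig(seed=0)
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(500):
            df = generate_survival(["A"] * 25 + ["B"] * 25, {"A": 1.0, "B": 1.0},
                                   0.0, cfg, rng)
            pvals.append(km_logrank(df).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def bundle():
    return simulate_cohort(SyntheticConfig(n_cases=12, n_snps=120, seed=21))


class TestCohortBundle:
    def test_shapes_and_keys(self, bundle):
        assert len(bundle.profiles) == 12
        assert len(bundle.snp_map) == 120
        assert set(bundle.clinical["case_id"]) == set(bundle.case_ids)
        assert bundle.mir_table.groupby("case_id").size().eq(22).all()

    def test_truth_bookkeeping_complete(self, bundle):
        """Every planted segment, shift and coupling is retrievable once."""
        t = bundle.truth
        assert set(t.segments) == set(bundle.case_ids)
        assert set(t.probe_shifts) == set(bundle.case_ids)
        assert all(len(v) == 11 for v in t.probe_shifts.values())
        assert all(len(v) == 22 for v in t.mir_shifts.values())
        snp_ids = set(bundle.snp_map["snp_id"])
        probe_or_mir = set(bundle.mir_table["mir_id"]) | {
            p for shifts in t.probe_shifts.values() for p in shifts
        }
        for c in t.couplings:
            assert c.snp_id in snp_ids and c.target_id in probe_or_mir
        frame = t.to_frame()
        assert (frame["kind"] == "coupling").sum() == len(t.couplings)

    def test_planted_segments_within_range_and_disjoint(self, bundle):
        for segs in bundle.truth.segments.values():
            ordered = sorted(segs, key=lambda s: s.start)
            for s in ordered:
                assert 0 <= s.start < s.end <= 120
            for a, b in zip(ordered[:-1], ordered[1:]):
                assert a.end <= b.start

    def test_bitwise_determinism(self):
        cfg = SyntheticConfig(n_cases=5, n_snps=60, seed=33)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.ct_table.to_csv() == b.ct_table.to_csv()
        assert a.mir_table.to_csv() == b.mir_table.to_csv()
        assert a.clinical.to_csv() == b.clinical.to_csv()
        for pa, pb in zip(a.profiles, b.profiles):
            assert np.array_equal(pa.lrr, pb.lrr) and np.array_equal(pa.baf, pb.baf)
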