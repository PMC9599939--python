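# cnax

Integrated analysis of somatic DNA alterations and expression for a single
tumor-suppressor gene region, built for paired tumor/normal study designs of
the kind used in esophageal squamous cell carcinoma (ESCC) cohorts: SNP-array
copy-number signals, exon-boundary qRT-PCR, and target-miRNA cards from the
same patients.

The package is aimed at cancer-genomics analysts who have per-SNP LRR/BAF
tables (array normalization already done), triplicate Ct tables, and a
clinical follow-up table, and want reproducible calls, correlations, and
survival comparisons — plus a synthetic-cohort generator with planted ground
truth so the whole pipeline can be validated without any external data.

## What it computes

**Somatic CNA / AI / LOH calling.** Tumor Log R ratio (LRR) profiles are
segmented by recursive binary segmentation (two-sample max-t splits,
family-wise significance threshold 5.0×10⁻⁶, minimum 3 probes per segment,
boundaries forced at inter-SNP gaps > 1 Mb). Segment mean LRR maps to a
copy-number state:

    high gain:  LRR >= 1.0        gain:  LRR > 0.2
    big loss:   LRR <= -1.0       loss:  LRR < -0.2      neutral otherwise

Tumor B-allele frequency (BAF) of germline-heterozygous SNPs classifies the
allelic state: allelic imbalance (AI) for BAF in [0.20, 0.45] ∪ [0.55, 0.80],
loss of heterozygosity (LOH) for BAF < 0.20 or > 0.80. Each case receives a
composite category ("Allelic Imbalance, CN Gain, CN Loss, LOH" vocabulary).

**Expression fold changes.** Relative expression by the comparative-Ct
method: ΔCt = mean target Ct − mean reference Ct per tissue,
ΔΔCt = ΔCt_tumor − ΔCt_normal, FC = 2^−ΔΔCt; overexpressed at FC ≥ 2,
underexpressed at FC ≤ 0.5. miR fold changes use the same cutoffs after a
both-tissues detection filter.

**Integration.** Spearman correlation screens (exact permutation p for
n ≤ 9, t approximation otherwise) between CNA-SNP LRR and probe/miR fold
changes, with nominal (p < 0.05) and Bonferroni (p < 0.05/m) flags, a
≥ 5-complete-cases rule per pair, and dual-correlated-SNP reporting.

**Survival.** Kaplan–Meier curves, log-rank test, and a Cox
proportional-hazards hazard ratio for fold-change-dichotomized groups
(FC < 1 vs FC ≥ 1), plus Fisher exact comparisons of alteration frequency
across clinical covariates.

Core algorithmic components are exposed as sklearn-style estimators
(`CnaCaller`, `LrrSegmenter`, `DdctFoldChange`, `SpearmanScreen`,
`FcSurvival`) with plain functions as thin wrappers.

## Worked example

```python
from cnax import (SyntheticConfig, simulate_cohort, CnaCaller, DdctFoldChange,
                  correlate_snp_vs_expression, default_snp_subset)

cohort = simulate_cohort(SyntheticConfig(n_cases=20, n_snps=200, seed=42))
caller = CnaCaller(random_state=0).fit(cohort.profiles)
print(caller.summary_)

fc = DdctFoldChange().fit(cohort.ct_table).transform(cohort.ct_table)
probe_fc = fc.pivot(index="case_id", columns="probe_id", values="fc")
subset = default_snp_subset(caller.cna_matrix_, min_cases_with_cna=3)
res, plan = correlate_snp_vs_expression(caller.lrr_matrix_, probe_fc, subset)
```

This prints (abridged):

```
summary: {'n_cases': 20, 'n_altered': 13, 'pct_altered': 65.0,
          'loss_loh_without_gain': 6, 'gain_without_loss_loh': 3, ...}
case_id  start  end  n_probes  mean_lrr cn_state allelic_state
  S0001      0  134       134 -0.006205  neutral        normal
  S0001    134  192        58  0.558867     gain            AI
  S0001    192  200         8 -0.006969  neutral        normal
subset size: 200 | m = 2200 | bonferroni threshold = 2.27e-05
nominal-significant pairs: 284
  snp_id  probe_id  n      rho        p
snp00177 exon 9-10 20 0.786466 0.000039
```

Reading: 13 of the 20 synthetic cases carry somatic alterations; case S0001
was segmented into a copy-neutral background and a 58-SNP gain segment
(mean LRR 0.56, inside the gain window) that also shows allelic imbalance.
The correlation screen tests 200 CNA SNPs against 11 probes (m = 2200
comparisons, Bonferroni threshold 0.05/2200 ≈ 2.3×10⁻⁵); the strongest hit
is a planted SNP→expression coupling recovered at rho 0.79.

The same pipeline runs from a shell:

```
cnax simulate --out sim --seed 7
cnax call-cna --lrr-baf sim/lrr_baf.tsv --out cna --seed 7
cnax expression --ct-table sim/ct.csv --out expr
cnax mirna --table sim/mirna.csv --out mir
cnax integrate --cna cna --expr expr --mirna mir --out int
cnax survive --clinical sim/clinical.csv --fc-table mir/retained.csv \
             --item hsa-miR-130b --out surv
cnax reproduce-table1
```

`cnax reproduce-table1` recomputes all cohort counts from the packaged
56-case summary fixture (alteration categories, gene and miR fold-change
categories): 39/56 cases altered (70%), 20 loss/LOH-without-gain cases of
which 15 with AI, 9 gain-without-loss of which 7 with AI, 6 AI-only, 4
mixed; 13 under- and 24 over-expressed of 54 cases with a gene fold change;
37/56 cases with abnormal average miR fold change (36 over, 1 under).

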