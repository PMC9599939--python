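# Methods

`cnax` implements an integrated single-gene tumor analysis: somatic
copy-number and allelic-state calling from paired tumor/normal SNP-array
signals, relative expression quantification by the comparative-Ct method,
copy-number/expression correlation screens, and survival comparisons of
expression-defined groups. This note records the models, the numerical
choices, and what the synthetic cohorts do and do not establish.

## DNA calling model

The DNA entry point is a per-SNP table of tumor Log R ratio (LRR, a
log-scale proxy for total copy number), tumor B-allele frequency (BAF), and
the matched germline genotype, over the intronic SNPs of one gene region
(by default 888 markers across ~2.06 Mb of chromosome 8p23.2).

**Segmentation.** Tumor LRR is partitioned by recursive binary
segmentation: at each step the candidate split maximizing the pooled
two-sample t statistic of mean LRR is tested, and accepted when its
family-wise p-value beats the significance threshold (default 5.0e-6) and
both children retain at least `min_probes` markers (default 3). Inter-SNP
gaps above `max_probe_spacing` (default 1 Mb) force boundaries. Segments
tile the profile exactly.

*Split p-value.* A permutation test with 10,000 permutations cannot resolve
p-values below 1e-4, while the acceptance threshold is 5.0e-6. The split
test is therefore a hybrid: the observed max-|t| is screened against
permutations of the segment (early-stopping as soon as one permuted value
reaches it, since the split is then rejected at any threshold below the
permutation resolution), and when no permutation reaches it the reported
p-value is the Bonferroni-corrected two-sided t tail over the admissible
split positions, which can resolve arbitrarily small values. Degenerate
(zero-variance) splits map to |t| = inf when the means differ and 0
otherwise.

**Copy-number states.** Segment mean LRR is classified as high gain
(>= 1.0), gain (> 0.2), neutral ([-0.2, 0.2]), loss (< -0.2), or big loss
(<= -1.0). The boundary semantics are exactly these inequalities: a mean of
+-0.2 is neutral. The map is total and monotone in mean LRR.

**Allelic states.** Only germline-heterozygous SNPs are informative: a
homozygous SNP sits near BAF 0 or 1 under every somatic state, and applying
the BAF windows to it would call LOH everywhere. For a heterozygous SNP,
tumor BAF in [0.20, 0.45] or [0.55, 0.80] (closed bands) is allelic
imbalance (AI); BAF < 0.20 or > 0.80 (strict) is LOH; the band around 0.5
is balanced. A segment is called AI (or LOH) when at least
`min_het_fraction` (default 0.5) of its informative SNPs carry that call,
with LOH taking precedence when both qualify — LOH is the stronger state.
Segments without informative SNPs are `indeterminate`.

**Case category.** Case-level flags aggregate over segments (CN Gain from
any gain/high-gain segment, CN Loss from any loss/big-loss segment, AI/LOH
from any segment with that allelic state) and compose the canonical label
("Allelic Imbalance, CN Gain, CN Loss, LOH" order, or "not observed"). A
SNP "carries a CNA" when its segment is copy-number non-neutral or AI/LOH;
that per-SNP flag defines the subset correlated with expression.

## Expression quantification

Each exon-boundary probe is measured as triplicate threshold cycles (Ct) in
tumor and matched normal, alongside a single reference gene. Per tissue,
dCt = mean(target Ct) − mean(reference Ct); ddCt = dCt_tumor − dCt_normal;
fold change FC = 2^−ddCt. Missing replicates are averaged over the
available values; a replicate spread above 0.5 cycles logs a QC warning but
is not fatal (no QC exclusion rule is imposed). No amplification-efficiency
correction or multi-reference normalization is applied.

FC >= 2.0 is overexpressed, FC <= 0.5 underexpressed, the open interval
between is normal. A case's gene-level FC is the arithmetic mean of its
per-probe FCs (geometric averaging was considered and rejected: the
published per-case averages are consistent with arithmetic means).

miR fold changes follow the same cutoffs. Assays detected in only one
tissue are dropped before any summary (detection filter). Two cohort-level
abnormality summaries coexist deliberately: per-miR *average* FC (the
selector for the correlation subset) and per-miR *median* FC (descriptive);
they are reported under distinct names to avoid conflation.

## Correlation screens

Each screen correlates two case-aligned matrices pair-by-pair with Spearman
rank correlation over pairwise-complete observations; pairs with fewer than
five complete cases are excluded and recorded as skipped. The SNP signal
correlated is tumor LRR; BAF is not used here. rho is the Pearson
correlation of mid-ranks (ties averaged). The p-value is the exhaustive
permutation distribution for n <= 9 without ties, and the two-sided
t approximation `t = rho * sqrt((n-2)/(1-rho^2))` on n − 2 df otherwise;
|rho| = 1 maps to the smallest positive float rather than 0 so p stays in
(0, 1].

Significance is flagged twice: nominal (p < 0.05) and Bonferroni
(p < 0.05/m), where m is the full planned family — subset size times number
of probes/miRs, counting skipped pairs. No FDR procedure is layered on top.
The SNP subset for the mRNA screen is an explicit input; the default rule
is "SNPs with a CNA call in >= k cases" (k configurable, default 1) —
no fixed subset size is hard-coded. Positive rho means copy number and
expression move together (gain with overexpression or loss with
underexpression); negative is the inverse. Dual-correlated SNPs are the
intersection, on SNP id, of the nominal-significant sets of the mRNA and
miR screens.

## Survival

Cases are dichotomized at a fold-change cutoff (default: FC < 1 low,
FC >= 1 high; the boundary belongs to the high group, and the rule is
configurable). Groups are compared by Kaplan-Meier product-limit curves
(median = first time the estimate reaches 0.5; reported as not reached when
it never does), the log-rank chi-square test, and a single-covariate Cox
proportional-hazards fit (Efron tie handling, Newton-Raphson partial
likelihood, via lifelines). Non-convergence or separation is flagged in the
result rather than raised. Alteration frequencies across binary clinical
covariates are compared by a two-sided Fisher exact test — the test choice
is this package's, made because small strata make asymptotic chi-square
unreliable.

## Synthetic cohorts

The generator emulates the study conditions: 56 cases, 888 SNPs over
chr8:2,935,353-4,994,806, 70 exons, 11 exon-boundary probes, 22 target
miRs, and the observed composite-category mixture (17 unaltered, 6 AI-only,
9 gain without loss, 20 loss/LOH without gain, 4 mixed).

Signal model and defaults, with rationale:

- LRR = per-state mean + Gaussian noise. State means (gain +0.58 ~
  log2(3/2), high gain +1.3, loss −0.7, big loss −1.5) sit centrally inside
  the calling windows; `noise_sd_lrr` defaults to 0.15, a typical per-probe
  spread for Affymetrix-class arrays after normalization. With these
  defaults a 10-SNP segment mean lands in its window with probability
  >= 0.99.
- Heterozygosity 0.27, matching the mean heterozygosity of the array
  generation emulated. Het BAF: N(0.5, `baf_sd`=0.05) when balanced;
  under AI the center shifts by a per-segment offset drawn in [0.10, 0.25]
  (both bands used with equal probability per SNP — the windows are
  symmetric); under LOH the center moves to 0.03/0.97. Homozygous SNPs sit
  near 0/1 regardless of state, clipped to [0, 1].
- Allelic events on a copy-neutral background are planted gene-wide (or
  over the full copy-neutral remainder): segment boundaries come from LRR
  only, so a sub-segment allelic shift with neutral copy number is not
  localizable by this pipeline. This mirrors the biology (allelic imbalance
  at this locus is typically arm-scale) and keeps recovery well-posed; it
  is also the pipeline's main known blind spot on real data.
- Ct triplicates: planted log2 shift s lowers the tumor target Ct by s
  cycles; replicate noise 0.1 cycles (typical qPCR spread). The ddCt
  pipeline then recovers 2^s within 2^(±3·sd/√3·√4) bounds.
- Couplings: a coupled probe/miR adds `slope x state-mean LRR at the
  coupled SNP` to its log2 shift, making log2 FC an exactly monotone
  function of the SNP's copy-number state.
- Survival: exponential event times, baseline median 24 months (the
  cohort's observed median follow-up), group hazard multiplied by the
  planted HR (default 2.5), independent exponential censoring calibrated to
  the target censor fraction (default 0.05, ~3/56 lost to follow-up).

What passing synthetic tests does **not** show: the generator has no probe-
level intensity artifacts, no wave/GC bias in LRR, no genotype-calling
error, no tumor purity/subclonality continuum, no platform batch structure,
and its expression noise is homoscedastic on the log scale. Recovery rates
on these cohorts are therefore upper bounds on real-data performance.

## Problem sizes used in checks

Monte-Carlo checks run at: segmentation boundary recovery on 200 (tests) /
100 (acceptance script) step profiles of 100 SNPs; type-I calibration on
500 / 200 replicates of a 10x10 screen at n=30; coupling recovery on 100 /
50 cohorts of 56 cases; Cox recovery on 100 / 20 runs at n=200 per group.
In the coupling check, two latent copy-number signals each drive a block of
the 11 probes, so planted and null pairs each form half the tested family;
this keeps the family-wise error of the null half comfortably inside the
5% Bonferroni budget that the zero-false-positive assertion relies on.

## Known limitations

- AI/LOH localization is bounded by LRR segmentation (above).
- The permutation/t hybrid split test assumes approximately Gaussian LRR
  noise for its analytic tail; heavy-tailed noise would make the accepted
  splits anticonservative.
- Exact Spearman p-values are only computed for n <= 9 without ties; the
  t approximation at moderate n is slightly approximate in the extreme
  tail.
- Survival modelling is univariate by design; no covariate adjustment.
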