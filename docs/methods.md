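# Methods

This note documents the models and procedures implemented in `epitype`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Purity adjustment

**Model.** A bulk sample with tumor cell fraction *p* observes, at each CpG,
approximately `β_obs = p·β_tumor + (1 − p)·β_normal + ε`. Because distinct
tumor methylation states can coexist at one CpG across a cohort (e.g. a
subtype-specific hypermethylation event), samples are first partitioned into
1–3 *methylation populations* per CpG before fitting.

**Population discovery.** 1-D k-means on the beta values with k ∈ {1, 2, 3}.
Candidate multi-population splits require every population to hold ≥ 3
samples and a mean silhouette ≥ 0.6; otherwise k = 1. Initialization uses
per-probe quantiles, which makes the fit deterministic; a `seed` parameter is
retained on the interface for compatibility. Because a single population
spread along the purity axis can also clear the silhouette bar (its k-means
split is a cut through a continuum), fitted populations whose lines differ by
less than `merge_gap = 0.2` beta at both purity 0 and purity 1 are merged
back and refitted. Genuinely distinct populations — planted effects are
≥ 0.3 beta apart at purity 1 — are unaffected.

**Line fit and adjustment.** Each population gets a least-squares line
β ~ purity with the slope clipped to [−1, 1] (beta is a fraction of a
two-component mixture, so no population can change faster than one unit per
unit purity). Adjustment extrapolates the sample's population line to purity
1 *preserving the sample's residual*:

    β_adj = (a + b) + (β_obs − (a + b·p)) = β_obs + b·(1 − p)

clamped to [0, 1]. Residual preservation keeps inter-tumor heterogeneity in
the adjusted data instead of collapsing each population onto its line. At
p = 1 the adjustment is the identity by construction. The intercept *a*
(the line at purity 0), clamped to [0, 1], is the inferred in-silico normal.
Probes with fewer than 10 usable samples are flagged unfit and passed
through unchanged, with a missing normal estimate.

## Context annotation

Probe positions and gene coordinates are 1-based; BED-derived intervals are
0-based half-open, converted at ingest. Consensus gene models collapse all
transcript/exon records of a gene: the 5′-most base is the consensus TSS,
the 3′-most the TES; conflicting strands within a gene are an error.

Genic context uses the signed distance *d* to the nearest consensus TSS on
the probe's chromosome (positive downstream by gene strand): promoter when
|d| ≤ 500, proximal when 500 < |d| ≤ 5000, distal beyond. Both boundaries
are inclusive; nearest-TSS ties break by lexical gene id for determinism.
CGI context is island inside a (merged) CpG island, shore within 2000 bp of
an island edge, ocean beyond — the conventional shore width.

CpG density is computed over a 1001-bp window centered on the probe:
`O/E = (#CpG · L)/(#C · #G)` (0 when either count is 0) and GC fraction.
The two-class split calls HCG at O/E ≥ 0.48. The three-class promoter
scheme slides 500-bp subwindows (5-bp step): HCP when some subwindow has
O/E ≥ 0.75 and GC ≥ 0.55, LCP when every subwindow has O/E < 0.48, ICP
otherwise. These thresholds follow the cited density classifications; the
window mechanics are the package's own, fixed here.

TFBS enrichment per CpG cluster is a one-sided (greater) Fisher exact test
on the 2×2 cluster-membership × TF-overlap table, Benjamini-Hochberg
adjusted across TFs.

## Epityping

Feature selection ranks probes passing a context predicate (genic, CGI,
ATAC-overlap) by sample SD, ties broken by probe id; probes with any missing
beta are excluded. NMF uses multiplicative updates with the KL objective
(scikit-learn's `mu` solver), tolerance 1e-6, max 2000 iterations, and
`nrun` restarts seeded `seed + run`; the restart with the lowest objective
is kept. Samples take the factor with the largest mixture coefficient — the
factor-to-cluster rule is dominant-coefficient assignment. Two-group
concordance against a binary label is the best accuracy over the two
cluster↔label mappings. CpG row clustering for heatmap structure is
agglomerative with Euclidean distance and Ward linkage.

## Differential methylation

Two-sided Wilcoxon rank-sum for two groups, Kruskal-Wallis for more. A probe
whose pooled values are constant gets p = 1 ("SD = 0 in a comparison" is
read as pooled SD; group-wise zero SDs with unequal means stay testable).
When every group has ≤ 6 samples and the arrangement count is ≤ 2·10⁵,
p-values come from exact enumeration of group assignments (two-sided by
deviation of the rank sum from its null mean; upper tail of H for
Kruskal-Wallis); otherwise the tie-corrected normal approximation with
continuity correction (or chi-square) is used, vectorized across probes.
Significance combines the adjusted p (Bonferroni or FDR; the p filter can be
disabled) with the maximum pairwise absolute difference of group mean betas
(max-pairwise in >2-group mode). Probes under 80% sample coverage are
skipped and flagged. Contrast against the inferred normal adds the
tumor-minus-normal shift and the hypo/hyper state (mean beta ≤ 0.5 is hypo).

## Methylation-expression linkage

CpGs map to every gene whose consensus TSS lies within ±250 kb (inclusive).
Eligibility: probe beta range > 0.25; gene FPKM range > 1 and cohort mean
FPKM ≥ 0.5; expression is then log2(FPKM + 0.1). The jackknife Pearson
statistic is the signed value of smallest magnitude among the full-data r
and all n leave-one-out r's — the most conservative member of the jackknife
family, chosen to damp single-outlier correlations; pairs with a constant
full or leave-one-out subsample are dropped and flagged. (The bias-corrected
jackknife mean is not the default because it does not bound |r| by any
subsample's value.) Null cutoffs are the 2.5/97.5 percentiles (linear
interpolation) of the same statistic over uniformly sampled probes and their
own windows, one pooled null per cohort, pooling all window genes per
sampled probe; calls are strict inequalities outside the band. Candidate
epigenetically regulated genes require ≥ 3 significant negative pairs
within 7 kb of the TSS, membership in the differentially expressed set, a
group-median FPKM difference > 5, and optionally a fold change > 10 — all
exposed as parameters.

## Expression

Rank tests run on log2(FPKM + 0.1); effect sizes on raw FPKM. Overall
significance: FDR-adjusted p < 0.05 and group-median span > 1 FPKM. The
three-group group-specific scheme restricts to overall-significant genes,
FDR-adjusts each pairwise Wilcoxon family separately over that restricted
set, and calls a gene specific to group g iff both pairwise tests involving
g are significant and the remaining pair is not, with direction from g's
median against the others. Metagene rank scores are the mean within-sample
ascending rank of the member genes divided by the total gene count (ties
averaged) — invariant under any monotone transform of a sample's profile.
Networks are connected components (≥ 8 genes) of the graph with edges at
Spearman r ≥ 0.7 (positive only, computed on raw FPKM — Spearman is
rank-based so the choice only affects ties); each network's per-sample score
is the median raw FPKM over members, and edges are exported as SIF.

## Synthetic cohorts

The generator builds one chromosome with genes every 50 kb (so a 500-kb
window holds ~10 TSSs), CpG islands at promoters, and four probe strata
populating the promoter-island, proximal-shore, distal-ocean and distal-ATAC
contexts. True tumor and normal betas sit near 0.05/0.95 (Beta draws);
~10% of probes carry a somatic tumor-vs-normal switch, and 15% carry
epitype-independent inter-tumor heterogeneity (per-sample tumor betas
scattered around a probe-level center, SD 0.15) — these populate the
empirical-null universe of variable-but-unlinked CpGs, without which purity
adjustment would leave almost no eligible null pairs. Planted DMC blocks
shift the tumor beta of one epitype (or subgroup) by Δβ inside a chosen
stratum. Observed betas are the purity mixture plus truncated-normal noise
(bounds keep the sum in [0, 1]); expectation therefore matches the mixture
up to a small boundary truncation bias. Expression is log-normal
(log2 means ~N(3, 1.5), residual SD 0.8); planted pairs set a gene's
log-expression to `c` times the standardized observed beta of a planted
probe plus √(1−c²) residual (sign configurable), so the sample correlation
concentrates at the configured coupling; network blocks share a per-sample
latent factor with loading 0.9. One TF's binding sites are enriched on
planted probes for enrichment tests. Everything is deterministic given the
seed (default 221027, also the default clustering seed).

Defaults follow the study conditions the workflow targets: 120 samples,
20,000 probes, 200 planted distal-ATAC DMCs at Δβ 0.4, purity ~ U(0.3, 0.9),
noise SD 0.03, 50 planted pairs at coupling 0.7, one 10-gene network block.

**What passing tests show — and don't.** Recovery on these cohorts
demonstrates that each algorithm inverts its own generative assumptions at
realistic effect sizes and noise. The simulation does not emulate Infinium
I/II chemistry effects, probe cross-reactivity, copy-number-driven beta
shifts, batch structure, correlated probe blocks within regions, or
realistic linkage disequilibrium of methylation; performance on real arrays
depends on upstream normalization handling those.

## Problem sizes and numerics

Validation runs use desk-scale cohorts: purity recovery on 100 samples ×
4,000 probes; epityping on 120 samples with 6,000 probes (500 NMF features,
30 restarts, plus five no-signal controls at 5 restarts — a single control
cohort has a chance-concordance SD of ~0.036, so the control is averaged);
error rates on 50 null and 100 planted cohorts of 10,000 probes; the
empirical null at 5,000 sampled probes of an 8,000-probe universe; the
end-to-end chain on the full default cohort with 1,000 NMF features. These
sizes are the package's validation defaults; all scale parameters are
arguments. Numerical conventions: percentiles use linear interpolation;
exact-test tail comparisons use an epsilon of 1e-9 on discrete statistics;
batch jackknife uses sufficient-statistic downdates with a relative 1e-12
constancy guard; NMF determinism holds for fixed (matrix, k, nrun, seed).

## Known limitations

The population-discovery scheme for purity models is a concrete, documented
stand-in for the cited approach's unspecified mechanics (silhouette-gated
1-D k-means with coincident-line merging); other reasonable schemes would
differ at CpGs with weakly separated populations. The jackknife definition
is the conservative minimum-|r| rule; cohorts with two or more co-located
outliers can still inflate it. The empirical null pools all window genes per
probe, so pairs sharing a probe are correlated; calibration statements are
therefore made at probe granularity. Region-level (DMR) merging,
reference-based deconvolution, and rank-selection diagnostics for NMF (e.g.
cophenetic correlation) are out of scope.
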