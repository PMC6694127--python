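# Methods

This note documents the statistical model behind each stage, the
defaults and why they hold, what the synthetic generator does and does
not emulate, and the numerical conventions that make runs reproducible.

## Differential expression

Each cohort is a gene × sample matrix with case/control labels and a
`scale` flag (`linear` or `log2`). Fold change is
FC = mean(case)/mean(control) on linear data and
log₂FC = mean(case) − mean(control) on log₂ data; the per-dataset flag
exists because public microarray matrices are deposited in both forms
and the two conventions give different fold changes if conflated.
Genes with a non-positive control mean on linear scale cannot have a
ratio and are excluded from calling (and logged).

Significance is the two-sided Wilcoxon rank-sum test. For pooled
sample size ≤ 16 without ties the exact null distribution of the rank
sum is built by dynamic programming and the two-sided p is twice the
smaller tail (the distribution is symmetric when tie-free); otherwise a
normal approximation with midranks, the standard tie correction of the
variance, and a 0.5 continuity correction is used. Exact mode refuses
ties and falls back to the normal path with a log record, since
exactness under ties would require full permutation enumeration. The
two p-value paths agree within 0.02 wherever p < 0.2; at the centre of
the discrete null the residual point mass allows discrepancies up to
about 0.03 at the smallest sample sizes, which never affects a call at
the 0.05 threshold.

Direction calls use strict inequalities — up iff FC > 1.5 and
p < 0.05, down iff FC < 1/1.5 and p < 0.05 — so a gene exactly on a
boundary is not significant. No multiple-testing correction is applied
by default; `fdr: bh` switches the thresholding to Benjamini–Hochberg
adjusted p-values (stored as `p_adj`) in both the DE and enrichment
stages.

The cross-dataset direction matrix keeps genes called (non-ns) in at
least `min_datasets` cohorts (default 3) and stores the signed log₂FC,
which is how tissue-dependent sign flips (up in brain, down in blood)
become visible.

## Cross-dataset similarity

Fold changes of *all* genes (not only significant ones) feed the
similarity stage. For each cohort pair, Spearman ρ is computed over the
intersection of the two gene universes; pairs sharing fewer than
`min_common_genes` (default 100) are a hard error because a rank
correlation over a handful of genes is noise. Two distance dialects are
provided, since "Euclidean distance from correlation coefficients" is
genuinely ambiguous:

* `corr_rows` (default) — Euclidean distance between rows of the
  correlation matrix, i.e. two cohorts are close when they relate to
  *all other cohorts* similarly; the common practice when a distance
  matrix is derived from a correlation matrix in R workflows.
* `direct` — d = √(2(1 − ρ)), the chordal distance of the correlation
  itself.

Classical (Torgerson) MDS double-centres the squared distances,
B = −½ J D² J, takes the top-k eigenpairs, and scales eigenvectors by
√λ. Axes are ordered by eigenvalue and each axis's sign is fixed so its
largest-magnitude loading is positive, making the embedding
deterministic bit-for-bit. Fewer than k positive eigenvalues zero-fill
the remaining axes with a warning. Distance matrices that arise from
true 2-D configurations are reconstructed to ≈ 1e−15.

The tissue test asks whether same-tissue cohorts sit closer than
different-tissue ones. The statistic is
T = mean(between-tissue pairwise distance) − mean(within-tissue
pairwise distance), measured by default in the 2-D embedding (the map
on which the claim is made; the input-distance option exists). The null
permutes tissue labels across cohorts; p = (#{T_null ≥ T_obs}+1)/(N+1)
(add-one rule, never zero). Tissues with a single cohort contribute
between-tissue pairs but no within-tissue mean. The choice of a
label-permutation test is a design decision — the original significance
procedure behind this kind of comparison is typically unstated — and
the output labels it as such. Note the null is coarse when cohort
counts are small: with 4+4 cohorts only 35 distinct label partitions
exist, so p has a granularity floor near 0.03 and at least ~1000
permutations are needed to resolve it stably.

## Enrichment

Over-representation uses the hypergeometric upper tail
P(X ≥ k | N, K, n) with the *dataset's own measured gene universe* as
background — platforms measure different genes, so a genome-wide
background would inflate enrichment for platform-specific sets. Up and
down lists are tested separately; records with p < 0.05 are retained.
This deliberately replaces service-specific scores (e.g. EASE-adjusted
ones) with the standard hypergeometric test: downstream logic depends
only on p < 0.05 membership. Because the statistic is discrete, the
attained level of the p < 0.05 rule sits at or below 0.05; calibration
tests compare against the exact attained level rather than the nominal
one.

The term-overlap matrix keys rows by (term, direction) — a term
significant both up and down in one cohort yields two rows — and keeps
rows significant in ≥ `min_overlap` cohorts (default 2). Cells are
+(−log₁₀ p) for up-list and −(−log₁₀ p) for down-list enrichment,
ready for heat-mapping.

Drug-set enrichment is the identical machinery with drugs in place of
genes and the full catalogue as universe.

## Connectivity drug prediction

A query signature per cohort: valid genes are those present in the
catalogue universe; the up list (descending FC, ties broken by symbol)
is truncated at 150, cohorts with fewer than 10 valid up genes are
excluded from the query; down genes are optional and truncated
likewise. The per-drug statistic is the bidirectional KS enrichment of
a gene set in a ranked profile of N genes: with sorted ranks
r₁ < … < r_t,

    a = max_j (j/t − r_j/N),   b = max_j (r_j/N − (j−1)/t),
    es = a if a > b else −b.

Positive es means the set concentrates at the profile top. The a/b
convention is the classic one and is mildly asymmetric: a bottom-t set
scores −(1 − (t−1)/N) while a top-t set scores +(1 − t/N), and profile
reversal negates es only up to 1/N (bimodal sets with a ≈ b may not
flip sign at all). The combined score is 0 when es_up and es_down share
a sign, otherwise 100·(es_up − es_down)/2 (or 100·es_up when the down
list is empty); a perfect reverser with t = 50 up + 50 down genes in
N = 1000 scores −95.05 (continuous limit −95).

Reversers are drugs with score in the closed window [−100, −80].
Cohort candidate lists with fewer than two compounds are dropped (a
single compound carries no overlap information), and drugs present in
≥ 4 lists (human group) or ≥ 5 lists (animal group) — "more than
three/four" read as ≥ 4/≥ 5 — become the interested list. This score
is an implemented emulation of proprietary connectivity services; the
window and overlap rules operate on top of it unchanged.

## Permutation validation of cross-group overlaps

Two statistics compare the cohort groups: the number of significant
terms shared (a term counts for a group when significant, either
direction, in ≥ 2 of its cohorts — the same recurrence convention the
term-overlap matrix uses) and the number of shared interested drugs.
Each null replicate redraws the randomness at the level of the inputs:
uniform random gene lists of the observed per-dataset sizes from each
dataset's *own* universe (the stricter, platform-aware null) for the
term statistic, and uniform random candidate-drug subsets of the
observed sizes from the catalogue for the drug statistic, then reapplies
the full group-level criteria. p = (exceedances + 1)/(N + 1) with
"≥ observed" exceedance — conservative, never zero, floor 1/(N+1).
Validity: when the observed statistic itself comes from the null, the
resulting p-values are superuniform (no anti-conservative excess of
small p), which the suite checks with a one-sided KS bound because the
overlap statistic is heavily discrete.

## Synthetic data generator

The generator emulates a multi-cohort microarray compendium, not
sequencing counts: log₂-scale Gaussian intensities
value(g, s) = baseline_g + case(s)·δ(g, tissue) + N(0, σ), with gene
baselines N(8, 2²) drawn once and shared across cohorts so that
fold-change vectors, not absolute levels, carry the cross-dataset
signal. Defaults describe the emulated study: 4 brain + 4 blood human
cohorts of 10 cases vs 10 controls over 1000 genes; a 60-gene immune
set with δ = +2 in brain and −2 in blood; a 40-gene
oxidative-phosphorylation set with δ = −2 everywhere (planted pathway
sizes in the 40–60 gene range match typical curated pathways); noise
σ = 0.5; 10% per-cohort gene dropout standing in for platform-universe
differences. Planted genes are exempt from dropout so every cohort
carries the full planted structure; dropout therefore exercises the
pairwise-common-gene logic without eroding ground truth. Animal-model
groups reuse the same planted sets in brain-only cohorts under a
non-human organism label (which activates the ≥ 5 samples/group rule).

Planted reverser drugs place the planted signature's down genes in the
top profile ranks and its up genes at the bottom; all other drugs are
uniform permutations. With δ = 2, σ = 0.5 and 10v10 cohorts the
signature contains roughly 4–5 false-positive genes per direction next
to the planted 60/40, which dilutes reverser scores to about −89 ± 4 —
comfortably inside the [−100, −80] window. Smaller cohorts (6v6–8v8)
roughly double the false-positive load and push scores toward the −80
boundary; that regime is deliberately not the default.

What the generator does **not** model: probe-level artifacts, batch
effects, correlated gene-gene noise, RNA-seq count distributions, or
cross-species ortholog mapping (callers must supply harmonised
symbols). Passing tests therefore demonstrate the machinery recovers
planted structure under idealised independent Gaussian noise; they do
not certify performance on real cohorts with correlated expression and
batch structure.

## Problem sizes and determinism

Validation experiments run at deliberately modest sizes chosen to make
the checked properties sharp: oracle equivalences are exhaustive where
enumeration is feasible (rank assignments to pooled n = 12, gene-set
subsets to N = 12 with exact combinatorics to N = 20, KS profiles
exhaustively to N = 9 and sampled to N = 50); recovery and calibration
experiments use 100 seeds (tissue test), 20 seeds (enrichment), 50–100
seeds (drug prediction), and 999–1000 permutation replicates, against
the 10,000 a full-scale analysis would use — the add-one p floor scales
accordingly.

Every stochastic stage takes its generator from the run seed; the
pipeline writes the resolved configuration and SHA-256 hashes of every
output, and two runs with identical inputs, config and seed are
byte-identical. Degenerate inputs fail loudly: empty designs,
all-singleton tissue layouts, sub-minimum group sizes, non-permutation
drug profiles, and pairs with too few shared genes are all hard errors
rather than silent adjustments.
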