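# Methods

`pcsig` re-implements, as a reusable and testable pipeline, the analysis of
human in-vivo plasma-cell (PC) transcriptomes: naive B cells (BC) compared
with three functionally distinct PC subsets — tonsil PC (TPC, mostly early
PC), blood PC after booster immunization (BPC, mostly cycling
plasmablasts), and bone-marrow CD138+ PC (BMPC, including the long-lived
compartment). This note records the models, the defaults and why they were
chosen, and what the synthetic-data tests do and do not establish.

## Preprocessing

**Normexp background correction.** Observed linear-scale intensity is
modeled as X = S + B with true signal S ~ Exponential(mean α) and optical
background B ~ Normal(μ, σ²). Parameters are estimated per sample by moment
matching (E X = μ + α, Var X = σ² + α², third central moment = 2α³); the
corrected value is the posterior mean E[S | X = x], a truncated-normal
expectation computed in log space for stability, then log2-transformed with
an offset (default 10 intensity units) that bounds the variance of
low-intensity probes. Per-sample estimation keeps samples exchangeable, as
is standard for one-color arrays. When a sample shows no positive variance
or right skew the convolution is unidentifiable and the correction falls
back to mean-background subtraction floored at zero (logged). The moment
estimator's σ is poorly identified when α ≫ σ; the conditional mean is
insensitive to σ in that regime, so corrected values remain accurate (the
test suite checks them against numeric integration).

**Quantile normalization.** Every sample is mapped onto the mean empirical
distribution (row-wise mean of sorted columns); ties receive the mean of
their assigned quantile values. The operation is idempotent and preserves
ranks within a sample.

**Probeset filtering.** Two categories are removed as uninformative:
immunoglobulin-assigned probesets (constitutively saturated in
antibody-secreting cells) and probesets without a gene symbol. Counts and
fractions per category are reported. Filtering happens after normalization
so quantiles are computed on the full array.

**Gene collapse.** Redundant probesets collapse to one representative per
gene: highest mean expression (`max_mean`, default for expression-rank
analyses) or smallest differential-expression p (`min_p`, for rank-by-t
analyses). Ties break on the lexicographically smallest probeset id so
results are deterministic.

## Differential expression

Each contrast is a two-group comparison of log2 expression. Per-gene pooled
variances s²_g (d_g = n_A + n_B − 2 df) are shrunk toward a prior through
the scaled-F hierarchical model: the prior df d0 and prior variance s0² are
estimated by matching the mean and variance of log s²_g via
digamma/trigamma identities (trigamma inverted by Newton iteration). The
posterior variance is (d0·s0² + d_g·s²_g)/(d0 + d_g) and the moderated t
has d0 + d_g df. When the observed spread of log-variances is no larger
than expected under a common variance, d0 = ∞ and all genes share s0².
The implementation reproduces the reference empirical-Bayes implementation
to ~1e-13 on a frozen fixture (checked in the tests). Multiple testing uses
Benjamini–Hochberg within each contrast; the default significance call is
adjusted p < 0.1 with no fold-change filter, both configurable.

Gene-level significance uses the `any` rule by default: a gene is
significant if at least one of its probesets is and all its significant
probesets agree in direction; conflicting genes are dropped and logged. A
`collapse-first` mode (minimum-p probeset represents the gene) is provided
because either convention is defensible; the choice affects only genes with
discordant redundant probes.

## Signatures

**Core signatures.** PC-down / PC-up are the genes significantly down/up in
ALL THREE subset-vs-BC contrasts — a directional intersection, so relaxing
the threshold can only grow a signature, and the two directions are
disjoint by construction.

**Subtype signatures.** From the three PC-vs-PC contrasts: `X-specific` =
up in X against both other subsets; `X/Y-common` = up in X and in Y against
the third, excluding genes already specific to X or Y so the labels
partition. The common sets require the same direction in both contrasts,
treating them as shared up-regulated markers.

**Over-representation.** An EASE-style test: one-sided hypergeometric tail
with the overlap decremented by one (singleton overlaps never score),
which is conservative relative to Fisher's exact test. Fold enrichment is
(k/n)/(K/N).

**External-profile concordance.** Relative-expression tables per cell type
are compared across signatures after making magnitudes direction-free
(values below 1 inverted; non-change stays 1). Signed-log inputs are
auto-detected (any value ≤ 0) and converted via 2^x, with an explicit
override. Welch t-tests are used between gene sets because their variances
differ; a pooled-variance mode exists for strict replication. Box-plot
whiskers are 1.5·IQR and outliers are excluded from display only, never
from tests.

## Rank-bin conservation statistic

A ranked transcriptome (by moderated t, or by group-average expression) is
cut into consecutive bins of equal gene count — 551 genes by default, which
yields 42 bins (d.f. 41) on a ~23k-gene universe. Genes beyond the last
complete bin are truncated by default (the bin size and universe sizes used
in the original analysis imply trimming to a multiple); an unequal-last-bin
mode with length-proportional expected counts is available. Set-member
counts per bin are tested against uniformity with the chi-square
goodness-of-fit statistic; replicate comparisons are averaged (mean ± SEM)
before a single test per comparison. The statistic's null calibration was
verified by simulation (rejection rate 0.03–0.07 at α = 0.05 with a
260-member set, slightly conservative because member ranks are sampled
without replacement). Percentile summaries report the fraction of a set
above a high-expression quantile (default 90th percentile).

## Cross-species comparison

Mouse antibody-secreting-cell genes enter the human universe only through
unequivocal ortholog pairs — one-to-one and present in the expression
universe; ambiguity is resolved by exclusion, never by arbitrary choice.
Conservation is quantified by the overlap of the mapped set with the top-N
(default 2000) of each ranked contrast and the intersection across
contrasts. Knockout tables are classified per gene as concordant or
discordant with a signature given the regulator mode: for an activator, an
up-signature gene that falls upon knockout is concordant; repressor mode
inverts the pairing; dual-mode regulators are reported once per mode.

## Motif enrichment

Motifs are position weight matrices regularized with a pseudocount (0.5 by
default) against the background base composition (uniform by default,
matching the i.i.d. promoter null of the generator). Each promoter is
scored by the best log-likelihood-ratio site over both strands and all
offsets, min-max normalized by the matrix's attainable range; windows with
ambiguous bases are skipped. Enrichment of a promoter set uses the
set-mean Z statistic z = (mean_fg − mean_bg)/(sd_bg/√n_fg) with the full
supplied promoter universe as background (not genome-wide), and a one-tailed
normal p. Motifs are ranked by Z; two rankings are compared by per-motif
absolute rank difference Δ (strong Δ > 150, moderate 50 < Δ ≤ 150, weak
Δ ≤ 50 — boundary values fall in the weaker class), the overlap fraction of
significant motifs, and Spearman correlation over all motifs by default
(a significant-only flag exists because either universe is defensible).
Motifs significant in both lists can be filtered from the divergence table.

## Gammopathy meta-analysis

Studies of monoclonal gammopathies (MGUS, SMM, MM; subtypes pooled) must
include healthy bone-marrow PC as the reference; the gene universe is the
intersection across studies after collapse. Per study and stage the top
k = 1000 genes with adjusted p < 0.1 (ranked by p) carry their direction
into the consistency rule: same direction in ≥ 2 studies, conflicts
dropped. Signature imbalance reports, per stage × signature × direction,
the overlap count, the percentage of the signature, and per-study mean ±
SD with the number of contributing studies (recorded explicitly since
stages need not be balanced across studies).

The GEP70-style risk score defaults to the arithmetic mean of the listed
probesets' log2 expression (`mean_all`); the up-minus-down form of the
original risk-score definition is also provided. The risk screen computes
per-dataset Pearson r with p from the exact transform
t = r√((n−2)/(1−r²)); a gene is consistent only when significant with the
same sign in all datasets (sign consistency is enforced because a
risk-gene call with discordant signs is uninterpretable), classed high- or
low-risk by that sign.

## Synthetic data

The cohort generator emulates the study design: groups BC = 3, TPC = 7,
BPC = 6, BMPC = 7 samples; log2 intensities Normal(baseline_g + effect,
noise_sd) with baseline_g ~ Normal(8, 1.5) and noise_sd 0.5 log2 units
(typical between-replicate array variability); redundant probesets share
the gene mean plus a fixed Normal(0, 0.2) offset, making collapse rules
consequential; immunoglobulin probes are constitutively high; unannotated
probes are background-like. Planted directional sets record their genes in
a JSON truth object. Promoters are i.i.d. sequences with motif sites
sampled from the PWM and placed at recorded offsets. Gammopathy studies
share baselines, differ by a per-study Normal(0, platform_shift) gene
shift, and receive stage-graded planted shifts (multipliers ordered
MGUS ≤ SMM ≤ MM when monotone progression is requested). Knockout tables
plant an exact rounded concordant fraction.

What the generator does not emulate: probe-level thermodynamics and
sequence-specific hybridization bias, spatial array artifacts, correlated
gene modules, heavy-tailed noise, and real promoter composition
(CpG islands, repeats). Passing recovery tests therefore demonstrates the
correctness of the statistical machinery under its stated model, not
performance on real arrays.

## Problem sizes and numerics

Tests and the pipeline default to cohorts of 500–2000 genes, 2–3 studies,
and 20-seed replications — sizes at which every planted effect is
identifiable yet a full run completes in seconds. The conservation
statistic is exercised at the original scale (23142-gene universe, 42 bins
of 551) because its calibration depends on the universe-to-set ratio. All
randomness descends from one root seed split per module; reruns are
byte-identical. Degenerate inputs fail loudly (empty signatures, missing
probesets, groups with fewer than two samples) rather than silently
propagating.

## Known limitations

- The normexp moment estimator can be unstable for samples with weak skew;
  the fallback is plain background subtraction.
- The set-mean motif Z assumes approximate normality of mean best-site
  scores; very small foregrounds (< 5 promoters) are rejected.
- The chi-square uniformity test is slightly conservative for sets drawn
  without replacement and anti-conservative for bins with expected counts
  well below ~5; the default configuration keeps expected counts ≈ 6.
- The meta-analysis assumes a shared gene-symbol universe; no
  cross-platform batch correction beyond universe intersection is applied.
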