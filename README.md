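# pcsig

Plasma cells (PC) are the terminally differentiating, antibody-secreting
end stage of the B-cell lineage. `pcsig` is a Python package for deriving
and stress-testing transcriptional signatures of that transition from bulk
expression arrays: naive B cells (BC) compared against tonsil PC (TPC),
blood plasmablasts (BPC) and bone-marrow CD138+ PC (BMPC), and the fate of
those signatures in monoclonal gammopathies (MGUS, SMM, multiple myeloma).
It is aimed at computational biologists who want the full analysis chain —
from probe-level matrices to signature imbalance reports — as tested,
scriptable functions rather than a one-off collection of scripts.

## What it computes

- **Preprocessing** — normexp background correction (posterior mean of the
  normal + exponential convolution, offset 10), quantile normalization,
  removal of immunoglobulin and unannotated probesets, gene-level collapse,
  and a 2^−ΔΔCt qPCR utility.
- **Differential expression** — empirical-Bayes moderated t per pairwise
  contrast: per-gene variances s²_g shrunk toward a prior (d0, s0²)
  estimated from the distribution of log s²_g, t = log2FC / (s̃_g·√(1/n_A +
  1/n_B)) with d0 + d_g df, Benjamini–Hochberg per contrast, significance
  at adjusted p < 0.1 with no fold-change filter.
- **Signatures** — PC-down / PC-up as directional intersections of all
  three PC-vs-BC contrasts; subtype-specific and pairwise-common sets from
  the PC-vs-PC contrasts; EASE-style over-representation; concordance with
  external per-cell-type profiles.
- **Rank-bin conservation statistic** — a ranked transcriptome cut into
  bins of 551 genes; chi-square goodness of fit (d.f. = bins − 1) of a gene
  set's bin counts against uniformity; expression-percentile summaries.
- **Cross-species and knockout checks** — unequivocal (one-to-one)
  ortholog mapping, top-N overlap across ranked contrasts, concordant /
  discordant classification of knockout responses.
- **Promoter motif enrichment** — PWM best-site scanning on both strands,
  Pscan-style set-mean Z = (mean_fg − mean_bg)/(sd_bg/√n_fg), motif
  ranking, and cross-list rank tracking (Δ classes, significant-motif
  overlap, Spearman correlation).
- **Gammopathy meta-analysis** — per-study top-1000 dysregulated genes vs
  healthy PC, cross-study consistency (same direction in ≥ 2 studies),
  signature imbalance per stage, GEP70-style risk scores and a
  sign-consistent Pearson correlation risk screen.
- **Synthetic data** — generators for all of the above with planted ground
  truth, so every stage is testable without external data.

## Worked example

```python
from pcsig.synth import CohortSpec, PlantedSet, generate_cohort
from pcsig.diffexpr import Contrast, pairwise_de, collapse_de_to_genes
from pcsig.signatures import core_signature
from pcsig.rankdist import rank_by_statistic, bin_counts, chi2_uniform

spec = CohortSpec(
    n_genes=2000,
    planted=(PlantedSet("PC-down", 300, ("TPC", "BPC", "BMPC"), -1.5),
             PlantedSet("PC-up", 200, ("TPC", "BPC", "BMPC"), 1.5)),
    seed=1)
matrix, annotation, design, truth = generate_cohort(spec)

contrasts = [Contrast.of(g, "BC") for g in ("TPC", "BPC", "BMPC")]
de = {name: collapse_de_to_genes(d, annotation)
      for name, d in pairwise_de(matrix, design, contrasts).items()}
for direction in ("down", "up"):
    sig = core_signature(de, direction)
    planted = set(truth.signatures[f"PC-{direction}"]["genes"])
    j = len(sig.genes & planted) / len(sig.genes | planted)
    print(f"PC-{direction}: {len(sig)} genes (Jaccard vs truth {j:.2f})")

sig_up = core_signature(de, "up")
ranked = rank_by_statistic(de["BMPC_vs_BC"], key="t", direction="up")
res = chi2_uniform(bin_counts(ranked, set(sig_up.genes), bin_size=50))
print(f"rank-bin test: chi2 = {res.chi2:.1f}, d.f. = {res.df}, p = {res.p:.3g}")
```

Output:

```
PC-down: 294 genes (Jaccard vs truth 0.96)
PC-up: 201 genes (Jaccard vs truth 0.97)
rank-bin test: chi2 = 1717.6, d.f. = 39, p = 0
```

The 23-sample cohort (BC = 3, TPC = 7, BPC = 6, BMPC = 7) carries 300
planted down-regulated and 200 up-regulated genes at ±1.5 log2 units. The
directional intersection of the three reference contrasts recovers both
signatures nearly exactly (Jaccard 0.96–0.97 against the planted truth),
and the recovered up-signature concentrates at the top of the t-ranked
transcriptome, which the bin-count chi-square test rejects as non-uniform
at floating-point zero.

The same flow is available from the shell:

```sh
pcsig synth cohort --seed 1 --out cohort/
pcsig de --expression cohort/expression.tsv --design cohort/design.tsv \
      --annotation cohort/annotation.tsv --out de/
pcsig signatures --de-dir de/ --out signatures.gmt
pcsig run --seed 1 --out report/    # full pipeline, deterministic per seed
```

## Layout

```
src/pcsig/
  synth.py         synthetic cohorts, promoters, studies, KO tables
  preprocess.py    normexp, quantile normalization, filtering, collapse
  diffexpr.py      moderated t, BH adjustment, pairwise contrasts
  signatures.py    core/subtype signatures, EASE test, concordance
  rankdist.py      rank binning, chi-square uniformity, percentiles
  crossspecies.py  ortholog mapping, top-N overlap, KO concordance
  tfbs.py          PWM scanning, motif Z-scores, rank tracking
  meta_mm.py       multi-study meta-analysis, GEP70 score, risk screen
  pipeline.py      end-to-end orchestration
  cli.py           `pcsig` command-line entry point
```

See `docs/methods.md` for the statistical models, defaults and known
limitations.
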