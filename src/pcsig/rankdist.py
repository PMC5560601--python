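"""Ranked-transcriptome binning and chi-square uniformity statistics.

A transcriptome is ordered (by moderated t or by expression), cut into
consecutive bins of equal gene count (551 genes by default), and the
members of a query gene set are counted per bin. Departure of the counts
from uniformity is measured with a chi-square goodness-of-fit test with
n_bins - 1 degrees of freedom; a gene set concentrated at one end of the
ranking produces a large statistic, a randomly scattered set does not.
Percentile summaries report the fraction of a set above a high-expression
quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 551


@dataclass(frozen=True)
class RankedList:
    """Ordered gene ids with the statistic that produced the order."""
    genes: tuple[str, ...]
    statistic: tuple[float, ...]
    key: str

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate gene ids")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class BinProfile:
    """Per-bin member counts of a gene set over a ranked universe."""
    counts: tuple[float, ...]
    bin_size: int
    universe_size: int
    set_size_in_universe: int
    bin_lengths: tuple[int, ...]  # genes per bin (last may differ)

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def rank_by_statistic(de: DEResult, key: str = "t",
                      direction: str = "up") -> RankedList:
    """Order genes by the signed contrast statistic.

    direction="up" puts the largest statistic first (most up-regulated),
    "down" the smallest. Ties break lexicographically on gene id so the
    order is reproducible.
    """
    col = {"t": "t", "logFC": "log2FC"}.get(key)
    if col is None or col not in de.table.columns:
        raise KeyError(f"unknown ranking key {key!r}")
    stat = de.table[col]
    if stat.isna().any():
        raise ValueError("ranking statistic contains missing values")
    ascending = direction == "down"
    frame = pd.DataFrame({"stat": stat, "gene": de.table.index})
    frame = frame.sort_values(["stat", "gene"], ascending=[ascending, True],
                              kind="mergesort")
    return RankedList(tuple(frame["gene"]), tuple(frame["stat"]),
                      key=f"{key}:{direction}:{de.contrast.name}")


def rank_by_expression(matrix: pd.DataFrame, samples: list[str] | None = None,
                       label: str = "expression") -> RankedList:
    """Order genes by average expression over the given samples, descending."""
    sub = matrix[samples] if samples is not None else matrix
    means = sub.mean(axis=1)
    frame = pd.DataFrame({"stat": means, "gene": matrix.index})
    frame = frame.sort_values(["stat", "gene"], ascending=[False, True],
                              kind="mergesort")
    return RankedList(tuple(frame["gene"]), tuple(frame["stat"]), key=label)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_counts(ranked: RankedList, geneset: set[str],
               bin_size: int = DEFAULT_BIN_SIZE,
               remainder: str = "truncate") -> BinProfile:
    """Count gene-set members in consecutive rank bins of ``bin_size`` genes.

    remainder="truncate" (default) drops trailing genes beyond the last
    complete bin; remainder="last-bin" keeps them as a shorter final bin
    whose expected count is scaled by its length.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if remainder not in ("truncate", "last-bin"):
        raise ValueError(f"unknown remainder policy {remainder!r}")
    universe = np.asarray(ranked.genes)
    member = np.isin(universe, sorted(geneset))
    n_full = len(universe) // bin_size
    if n_full == 0:
        raise ValueError("universe smaller than one bin")
    tail = len(universe) - n_full * bin_size
    if remainder == "truncate":
        if tail:
            logger.info("bin_counts: truncating %d trailing genes", tail)
        member = member[: n_full * bin_size]
        lengths = [bin_size] * n_full
    else:
        lengths = [bin_size] * n_full + ([tail] if tail else [])
    if not member.any():
        logger.warning("gene set has no members in the ranked universe")
    counts, edges = [], np.cumsum([0] + lengths)
    for lo, hi in zip(edges[:-1], edges[1:]):
        counts.append(int(member[lo:hi].sum()))
    return BinProfile(tuple(float(c) for c in counts), bin_size,
                      universe_size=int(sum(lengths)),
                      set_size_in_universe=int(member.sum()),
                      bin_lengths=tuple(lengths))


def average_bin_profiles(profiles: list[BinProfile]) -> tuple[BinProfile, np.ndarray]:
    """Element-wise mean profile and SEM across replicate profiles."""
    if not profiles:
        raise ValueError("no profiles given")
    first = profiles[0]
    for p in profiles[1:]:
        if p.bin_lengths != first.bin_lengths:
            raise ValueError("profiles have mismatched bin structure")
    counts = np.array([p.counts for p in profiles], dtype=float)
    mean = counts.mean(axis=0)
    sem = (counts.std(axis=0, ddof=1) / np.sqrt(len(profiles))
           if len(profiles) > 1 else np.zeros(first.n_bins))
    mean_profile = BinProfile(tuple(mean), first.bin_size, first.universe_size,
                              set_size_in_universe=int(round(mean.sum())),
                              bin_lengths=first.bin_lengths)
    return mean_profile, sem


# ---------------------------------------------------------------------------
# chi-square uniformity
# ---------------------------------------------------------------------------

def chi2_uniform(profile: BinProfile) -> ChiSquareResult:
    """Chi-square goodness of fit of the bin counts against uniformity.

    Expected counts are proportional to bin lengths (equal for complete
    bins); df = n_bins - 1; the p-value is the upper tail.
    """
    if profile.n_bins < 2:
        raise ValueError("need at least 2 bins")
    counts = np.asarray(profile.counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("gene set has no members in the universe")
    lengths = np.asarray(profile.bin_lengths, dtype=float)
    expected = total * lengths / lengths.sum()
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = profile.n_bins - 1
    return ChiSquareResult(chi2, df, float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# expression-rank profiles and percentile summaries
# ---------------------------------------------------------------------------

def expression_rank_profile(matrix: pd.DataFrame, design: pd.DataFrame,
                            geneset: set[str], n_bins: int = 50
                            ) -> dict[str, BinProfile]:
    """Per-group bin profile of a gene set over the expression ranking.

    For each sample group, genes are ranked by group-average expression
    (descending) and cut into ``n_bins`` equal bins; set members are counted
    per bin. The fraction of the set present in the universe is logged.
    """
    if not geneset:
        raise ValueError("empty gene set")
    out: dict[str, BinProfile] = {}
    bin_size = len(matrix) // n_bins
    if bin_size < 1:
        raise ValueError("more bins than genes")
    for group in dict.fromkeys(design["group"]):
        samples = [s for s in design.index[design["group"] == group]
                   if s in matrix.columns]
        if not samples:
            continue
        ranked = rank_by_expression(matrix, samples, label=f"expr:{group}")
        out[group] = bin_counts(ranked, geneset, bin_size=bin_size)
        frac = out[group].set_size_in_universe / len(geneset)
        logger.info("expression_rank_profile[%s]: %.1f%% of set represented",
                    group, 100 * frac)
    return out


def merge_profiles_across_studies(per_study: list[dict[str, BinProfile]]
                                  ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Mean and SD of per-group profiles over studies sharing bin structure."""
    groups = set.intersection(*(set(d) for d in per_study))
    merged = {}
    for g in sorted(groups):
        counts = np.array([d[g].counts for d in per_study], dtype=float)
        merged[g] = (counts.mean(axis=0),
                     counts.std(axis=0, ddof=1) if len(per_study) > 1
                     else np.zeros(counts.shape[1]))
    return merged


def percentile_fraction(matrix: pd.DataFrame, geneset: set[str],
                        q: float = 0.90,
                        samples: list[str] | None = None) -> float:
    """Fraction of set members whose average expression exceeds the
    q-quantile of all genes."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    sub = matrix[samples] if samples is not None else matrix
    means = sub.mean(axis=1)
    cutoff = means.quantile(q)
    members = means.index.intersection(sorted(geneset))
    if len(members) == 0:
        return 0.0
    return float((means.loc[members] > cutoff).mean())
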