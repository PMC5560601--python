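"""Derivation of plasma-cell signatures and their downstream summaries.

The core signatures (PC-down, PC-up) are directional intersections over the
three contrasts of each plasma-cell subset against the naive B-cell
reference: a gene belongs to the signature only if it is significantly
changed in the same direction in all three comparisons. Subtype signatures
come from the three PC-vs-PC contrasts (subtype-specific and pairwise-common
up-regulated sets). An EASE-style over-representation test and a
relative-expression concordance summary against external per-cell-type
profiles complete the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureSet:
    """A named, directional gene set with the contrasts it came from."""
    name: str
    direction: str  # "up" | "down"
    genes: frozenset[str]
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# core PC signatures
# ---------------------------------------------------------------------------

def core_signature(de_map: dict[str, DEResult], direction: str,
                   reference: str = "BC") -> SignatureSet:
    """Directional intersection of the three subset-vs-reference contrasts.

    Every supplied contrast must have ``reference`` as its B group (so a
    positive fold change means up in the plasma-cell subset); exactly three
    contrasts with distinct subsets are required. A gene enters the
    signature only if significant with the requested direction in ALL three.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(de_map) != 3:
        raise ValueError(f"expected exactly 3 reference contrasts, got {len(de_map)}")
    subsets = []
    for de in de_map.values():
        if de.contrast.group_b != reference:
            raise ValueError(f"contrast {de.contrast.name} is not referenced "
                             f"against {reference}")
        subsets.append(de.contrast.group_a)
    if len(set(subsets)) != 3:
        raise ValueError(f"contrast subsets must be distinct, got {subsets}")
    sets = [de.significant_up if direction == "up" else de.significant_down
            for de in de_map.values()]
    genes = frozenset(set.intersection(*sets))
    name = f"PC-{direction}"
    return SignatureSet(name, direction, genes,
                        tuple(sorted(de.contrast.name for de in de_map.values())))


# ---------------------------------------------------------------------------
# subtype signatures
# ---------------------------------------------------------------------------

def _up_in(de_map: dict[str, DEResult], a: str, b: str) -> set[str]:
    """Genes significantly up in subtype a relative to subtype b."""
    for de in de_map.values():
        if (de.contrast.group_a, de.contrast.group_b) == (a, b):
            return de.significant_up
        if (de.contrast.group_a, de.contrast.group_b) == (b, a):
            return de.significant_down
    raise KeyError(f"no contrast between {a} and {b} supplied")


def subtype_signatures(de_map: dict[str, DEResult]) -> dict[str, SignatureSet]:
    """Subtype-specific and pairwise-common up-regulated sets.

    From the three PC-vs-PC contrasts: ``X-specific`` holds genes up in X
    against BOTH other subtypes; ``X/Y-common`` holds genes up in X and in Y
    each against the third subtype, excluding genes already specific to X or
    Y so the labels partition cleanly.
    """
    groups = sorted({g for de in de_map.values()
                     for g in (de.contrast.group_a, de.contrast.group_b)})
    if len(groups) != 3:
        raise ValueError(f"need contrasts among exactly 3 subtypes, got {groups}")
    provenance = tuple(sorted(de.contrast.name for de in de_map.values()))
    specific: dict[str, set[str]] = {}
    for x in groups:
        others = [g for g in groups if g != x]
        specific[x] = _up_in(de_map, x, others[0]) & _up_in(de_map, x, others[1])
    out: dict[str, SignatureSet] = {}
    for x in groups:
        out[f"{x}-specific"] = SignatureSet(f"{x}-specific", "up",
                                            frozenset(specific[x]), provenance)
    for i, x in enumerate(groups):
        for y in groups[i + 1:]:
            third = next(g for g in groups if g not in (x, y))
            common = (_up_in(de_map, x, third) & _up_in(de_map, y, third)) \
                - specific[x] - specific[y]
            name = f"{x}/{y}-common"
            out[name] = SignatureSet(name, "up", frozenset(common), provenance)
    return out


# ---------------------------------------------------------------------------
# EASE over-representation
# ---------------------------------------------------------------------------

def ease_p(k: int, n: int, K: int, N: int) -> float:
    """One-sided Fisher p with the EASE correction (overlap decremented by 1).

    k: overlap, n: query size, K: term size, N: universe size. The
    decremented overlap is floored at 0, so singleton overlaps never score.
    """
    k_adj = max(k - 1, 0)
    if k_adj == 0:
        return 1.0
    # P(X >= k_adj) for X ~ Hypergeometric(N, K, n)
    return float(stats.hypergeom.sf(k_adj - 1, N, K, n))


def overrepresentation_ease(signature: SignatureSet,
                            annotation_sets: dict[str, set[str]],
                            universe: set[str],
                            alpha: float = 0.05) -> pd.DataFrame:
    """EASE-adjusted over-representation of functional terms in a signature.

    Returns terms with p < alpha sorted by p, with fold enrichment
    (k/n)/(K/N) and the overlapping genes. The signature must lie inside the
    universe.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(signature.genes)
    if not query <= universe:
        raise ValueError("signature contains genes outside the universe: "
                         + ", ".join(sorted(query - universe)[:5]))
    N, n = len(universe), len(query)
    rows = []
    for term, members in annotation_sets.items():
        members = set(members) & universe
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(query & members)
        k = len(overlap)
        p = ease_p(k, n, K, N)
        fold = (k / n) / (K / N) if n else 0.0
        rows.append((term, p, fold, k, K, ",".join(overlap)))
    table = pd.DataFrame(rows, columns=["term", "p", "fold_enrichment",
                                        "overlap", "term_size", "genes"])
    table = table[table["p"] < alpha]
    return table.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# external-profile concordance
# ---------------------------------------------------------------------------

def fold_magnitude(values: np.ndarray) -> np.ndarray:
    """Map ratio-scale values below 1 to their inverse (non-change stays 1)."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    low = (values < 1) & (values > 0)
    out[low] = 1.0 / values[low]
    return out


def detect_convention(table: pd.DataFrame) -> str:
    """'log' if any value is <= 0 (signed log-ratio scale), else 'ratio'."""
    return "log" if (table.to_numpy() <= 0).any() else "ratio"


def external_profile_concordance(signatures: dict[str, SignatureSet],
                                 external: pd.DataFrame,
                                 reference: str | None = None,
                                 convention: str | None = None,
                                 welch: bool = True) -> dict[str, pd.DataFrame]:
    """Compare signature genes' relative expression across external cell types.

    ``external`` is a gene-by-cell-type table of relative expression, either
    on a ratio-to-mean scale centered at 1 or a signed log scale
    (auto-detected unless ``convention`` is given; log values are mapped to
    ratios via 2**x before the inverse transform). Magnitudes are made
    direction-free by inverting values below 1, then summarized per
    signature x cell type (quartiles and 1.5*IQR whiskers; outliers flagged
    for display only) and tested with two-sample t-tests between signatures
    within each cell type and, when ``reference`` is given, between each
    cell type and the reference within each signature. Tests always use all
    values; degenerate (zero-variance) comparisons report NaN.
    """
    conv = convention or detect_convention(external)
    if conv not in ("ratio", "log"):
        raise ValueError(f"unknown convention {conv!r}")
    if conv == "log":
        logger.info("external profile detected as signed log scale; "
                    "converting to ratios")
        external = 2.0 ** external

    values: dict[tuple[str, str], np.ndarray] = {}
    for sig_name, sig in signatures.items():
        overlap = sorted(set(sig.genes) & set(external.index))
        if len(overlap) < 3:
            raise ValueError(f"signature {sig_name}: fewer than 3 genes overlap "
                             "the external table")
        for cell in external.columns:
            values[(sig_name, cell)] = fold_magnitude(
                external.loc[overlap, cell].to_numpy())

    summary_rows = []
    for (sig_name, cell), v in values.items():
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo) & (v <= hi)]
        summary_rows.append((sig_name, cell, len(v), q1, med, q3,
                             inside.min() if len(inside) else np.nan,
                             inside.max() if len(inside) else np.nan,
                             int(((v < lo) | (v > hi)).sum())))
    summary = pd.DataFrame(summary_rows, columns=[
        "signature", "cell_type", "n_genes", "q1", "median", "q3",
        "whisker_low", "whisker_high", "n_outliers"])

    def _t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return float("nan"), float("nan")
        res = stats.ttest_ind(a, b, equal_var=not welch)
        return float(res.statistic), float(res.pvalue)

    test_rows = []
    sig_names = list(signatures)
    for cell in external.columns:
        for i, s1 in enumerate(sig_names):
            for s2 in sig_names[i + 1:]:
                t, p = _t(values[(s1, cell)], values[(s2, cell)])
                test_rows.append(("between_signatures", cell, s1, s2, t, p))
    if reference is not None:
        if reference not in external.columns:
            raise KeyError(f"reference cell type {reference!r} not in table")
        for sig_name in sig_names:
            for cell in external.columns:
                if cell == reference:
                    continue
                t, p = _t(values[(sig_name, cell)], values[(sig_name, reference)])
                test_rows.append(("vs_reference", sig_name, cell, reference, t, p))
    tests = pd.DataFrame(test_rows, columns=["comparison", "within", "a", "b",
                                             "t", "p"])
    return {"summary": summary, "tests": tests}
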