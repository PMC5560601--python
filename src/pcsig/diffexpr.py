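"""Pairwise differential expression with empirical-Bayes variance moderation.

Each contrast is a two-group comparison on log2 expression. Per-gene pooled
variances are shrunk toward a prior (d0, s0^2) estimated by moment-matching
the distribution of log sample variances (the digamma/trigamma equations of
the scaled-F hierarchical model), giving a moderated t-statistic with
d0 + d_g degrees of freedom. P-values are adjusted per contrast with the
Benjamini-Hochberg step-up procedure; the default significance call is
adjusted p < 0.1 with no fold-change filter.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_ADJ_P = 0.1


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; log2FC and t are oriented as A minus B."""
    name: str
    group_a: str
    group_b: str

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")

    @classmethod
    def of(cls, group_a: str, group_b: str) -> "Contrast":
        return cls(f"{group_a}_vs_{group_b}", group_a, group_b)


@dataclass
class DEResult:
    """Per-feature statistics for one contrast.

    ``table`` is indexed by feature id with columns log2FC, s2, t, p, adj_p,
    direction, significant. Hyperparameters of the variance prior are kept
    for diagnostics.
    """
    contrast: Contrast
    table: pd.DataFrame
    d0: float
    s0_2: float
    residual_df: float
    threshold: float = DEFAULT_ADJ_P

    @property
    def significant_up(self) -> set[str]:
        t = self.table
        return set(t.index[t["significant"] & (t["direction"] == "up")])

    @property
    def significant_down(self) -> set[str]:
        t = self.table
        return set(t.index[t["significant"] & (t["direction"] == "down")])

    def flipped(self) -> "DEResult":
        """Same contrast with orientation reversed (signs of log2FC and t flip)."""
        t = self.table.copy()
        t["log2FC"] = -t["log2FC"]
        t["t"] = -t["t"]
        t["direction"] = np.where(t["log2FC"] >= 0, "up", "down")
        c = Contrast(f"{self.contrast.group_b}_vs_{self.contrast.group_a}",
                     self.contrast.group_b, self.contrast.group_a)
        return DEResult(c, t, self.d0, self.s0_2, self.residual_df, self.threshold)


# ---------------------------------------------------------------------------
# variance-prior estimation (moment matching on log s^2)
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic starting value 1/y + 0.5 and the monotone update on
    1/x; converges in a handful of steps for all positive y.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 from sample variances.

    Under the hierarchical model s2 ~ s0^2 * F(df, d0); moment-match the
    mean and variance of log s2 using digamma/trigamma identities. When the
    trigamma equation has no finite solution (observed spread no larger than
    expected under a common variance) d0 is infinite and s0^2 = exp(mean).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive sample variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = e.mean()
    n = len(e)
    e_var = ((e - e_mean) ** 2).sum() / (n - 1)
    target = e_var - special.polygamma(1, df / 2.0)
    if target <= 0:
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(target)
    s0_2 = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return float(d0), float(s0_2)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def moderated_t(matrix: pd.DataFrame, design: pd.DataFrame, contrast: Contrast,
                threshold: float = DEFAULT_ADJ_P,
                d0_override: float | None = None) -> DEResult:
    """Empirical-Bayes two-sample t-test for one contrast.

    ``design`` maps sample_id -> group; both groups need >= 2 samples.
    ``d0_override`` forces the prior df (0 recovers the ordinary pooled t,
    inf ranks genes purely by fold change).
    """
    a_samples = design.index[design["group"] == contrast.group_a]
    b_samples = design.index[design["group"] == contrast.group_b]
    a_samples = [s for s in a_samples if s in matrix.columns]
    b_samples = [s for s in b_samples if s in matrix.columns]
    n_a, n_b = len(a_samples), len(b_samples)
    if n_a < 2 or n_b < 2:
        raise ValueError(f"contrast {contrast.name}: both groups need >=2 samples "
                         f"(got {n_a}, {n_b})")
    xa = matrix[a_samples].to_numpy(dtype=float)
    xb = matrix[b_samples].to_numpy(dtype=float)
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    log2fc = mean_a - mean_b
    df_resid = n_a + n_b - 2
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if d0_override is not None:
        d0 = float(d0_override)
        if math.isinf(d0):
            _, s0_2 = fit_f_dist(s2, df_resid)
        elif d0 == 0:
            s0_2 = float("nan")
        else:
            _, s0_2 = fit_f_dist(s2, df_resid)
    else:
        d0, s0_2 = fit_f_dist(s2, df_resid)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = math.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj_p = bh_adjust(p)
    table = pd.DataFrame({
        "log2FC": log2fc,
        "s2": s2,
        "t": t,
        "p": p,
        "adj_p": adj_p,
        "direction": np.where(log2fc >= 0, "up", "down"),
        "significant": adj_p < threshold,
    }, index=matrix.index)
    return DEResult(contrast, table, d0=d0, s0_2=s0_2,
                    residual_df=float(df_resid), threshold=threshold)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_de(matrix: pd.DataFrame, design: pd.DataFrame,
                contrasts: list[Contrast] | str = "all-pairs",
                threshold: float = DEFAULT_ADJ_P) -> dict[str, DEResult]:
    """Run moderated-t tests for a list of contrasts (or every group pair).

    BH adjustment is applied within each contrast separately. For
    "all-pairs", groups are taken in design order and each pair (A, B) with
    A before B yields contrast A_vs_B.
    """
    if contrasts == "all-pairs":
        groups = list(dict.fromkeys(design["group"]))
        contrasts = [Contrast.of(a, b) for a, b in itertools.combinations(groups, 2)]
    known = set(design["group"])
    for c in contrasts:
        missing = {c.group_a, c.group_b} - known
        if missing:
            raise KeyError(f"contrast {c.name}: groups absent from design: {missing}")
    return {c.name: moderated_t(matrix, design, c, threshold=threshold)
            for c in contrasts}


# ---------------------------------------------------------------------------
# probeset -> gene significance collapse
# ---------------------------------------------------------------------------

def collapse_de_to_genes(de: DEResult, annotation: pd.DataFrame,
                         rule: str = "any") -> DEResult:
    """Summarize probeset-level tests at gene level.

    rule="any": a gene is significant if at least one of its probesets is
    significant and all its significant probesets agree in direction; genes
    whose significant probesets conflict are dropped (logged). The reported
    statistics come from the minimum-p probeset (lexicographic tie-break).

    rule="collapse-first": the minimum-p probeset simply represents the gene
    (no conflict handling), mirroring collapse-then-test workflows.
    """
    if rule not in ("any", "collapse-first"):
        raise ValueError(f"unknown gene rule {rule!r}")
    t = de.table
    common = t.index.intersection(annotation.index)
    sym = annotation.loc[common, "gene_symbol"]
    frame = t.loc[common].copy()
    frame["gene"] = sym.to_numpy()
    frame = frame[frame["gene"].notna()]
    frame["probeset"] = frame.index

    rep = (frame.sort_values(["gene", "p", "probeset"], kind="mergesort")
                .drop_duplicates("gene", keep="first")
                .set_index("gene"))

    if rule == "any":
        sig = frame[frame["significant"]]
        dirs = sig.groupby("gene")["direction"].agg(set)
        conflicted = set(dirs.index[dirs.apply(len) > 1])
        if conflicted:
            logger.info("collapse_de_to_genes: %d genes with conflicting "
                        "significant directions dropped", len(conflicted))
        sig_genes = set(dirs.index) - conflicted
        rep = rep.drop(index=[g for g in conflicted if g in rep.index])
        rep["significant"] = rep.index.isin(sig_genes)
        # direction of the significant call, not of the representative probeset
        agreed = {g: next(iter(d)) for g, d in dirs.items() if g in sig_genes}
        rep.loc[rep["significant"], "direction"] = [
            agreed[g] for g in rep.index[rep["significant"]]]

    table = rep[["log2FC", "s2", "t", "p", "adj_p", "direction", "significant"]]
    table.index.name = "gene_symbol"
    return DEResult(de.contrast, table, de.d0, de.s0_2, de.residual_df, de.threshold)
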