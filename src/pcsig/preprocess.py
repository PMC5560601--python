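"""Background correction, normalization, probeset filtering and gene collapse.

The preprocessing chain for one-color array intensities is
normexp background correction (on the linear scale, then log2 with an
offset), quantile normalization across samples, removal of non-informative
probesets (immunoglobulin-assigned and symbol-less), and — for stages that
need gene-level data — collapse of redundant probesets to one row per gene.
A small 2^-ddCt utility supports relative qPCR quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normexp background correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormexpParams:
    """Normal+exponential convolution parameters for one sample.

    Observed intensity X = S + B with signal S ~ Exponential(mean alpha)
    and background B ~ Normal(mu, sigma^2).
    """
    mu: float
    sigma: float
    alpha: float


def fit_normexp_moments(x: np.ndarray) -> NormexpParams:
    """Moment-matching estimator of (mu, sigma, alpha) for one sample.

    Matches mean, variance and third central moment of the convolution:
    E X = mu + alpha, Var X = sigma^2 + alpha^2, mu3 = 2 alpha^3.
    Degenerate samples (no right skew or variance) raise ValueError so the
    caller can fall back to plain background subtraction.
    """
    x = np.asarray(x, dtype=float)
    m1 = x.mean()
    v = x.var(ddof=1)
    m3 = np.mean((x - m1) ** 3)
    if v <= 0 or m3 <= 0:
        raise ValueError("sample has no positive variance/skewness; "
                         "normexp moments undefined")
    alpha = (m3 / 2.0) ** (1.0 / 3.0)
    sigma2 = v - alpha ** 2
    if sigma2 <= 0:
        # skew dominates: shrink alpha so a positive background variance remains
        alpha = np.sqrt(v * 0.95)
        sigma2 = v - alpha ** 2
    return NormexpParams(mu=m1 - alpha, sigma=float(np.sqrt(sigma2)), alpha=float(alpha))


def normexp_conditional_signal(x: np.ndarray, params: NormexpParams) -> np.ndarray:
    """E[S | X = x] under the normal+exponential model (always > 0).

    Closed form: with mu_sf = x - mu - sigma^2/alpha,
    E[S|X=x] = mu_sf + sigma * phi(mu_sf/sigma) / Phi(mu_sf/sigma),
    computed on the log scale for numerical stability far in the left tail.
    """
    x = np.asarray(x, dtype=float)
    mu_sf = x - params.mu - params.sigma ** 2 / params.alpha
    z = mu_sf / params.sigma
    # sigma * phi(z)/Phi(z) via log-space Mills ratio
    log_ratio = stats.norm.logpdf(z) - stats.norm.logcdf(z)
    signal = mu_sf + params.sigma * np.exp(log_ratio)
    return np.maximum(signal, np.finfo(float).tiny)


def normexp_correct(raw: pd.DataFrame, offset: float = 10.0) -> pd.DataFrame:
    """Background-correct a linear-scale matrix per sample, return log2 values.

    Each sample's parameters are estimated independently by moment matching;
    the corrected value is log2(E[signal | observed] + offset). Samples on
    which the convolution fit is degenerate fall back to subtracting the
    sample mean background with a floor at zero (logged).
    """
    if (raw.values < 0).any():
        raise ValueError("normexp_correct expects non-negative linear intensities")
    out = {}
    for sample in raw.columns:
        x = raw[sample].to_numpy(dtype=float)
        try:
            params = fit_normexp_moments(x)
            signal = normexp_conditional_signal(x, params)
        except ValueError:
            logger.warning("normexp fit degenerate for sample %s; "
                           "subtracting mean background", sample)
            signal = np.maximum(x - x.mean(), 0.0)
        out[sample] = np.log2(signal + offset)
    return pd.DataFrame(out, index=raw.index)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the mean empirical distribution.

    The reference distribution is the row-wise mean of the sorted columns;
    each value is replaced by the reference value at its rank, ties within a
    column receiving the mean of their assigned quantile values.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two samples")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, len(reference) + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# probeset filtering and gene collapse
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_immunoglobulin: int
    n_unassigned: int
    n_retained: int

    @property
    def fraction_immunoglobulin(self) -> float:
        return self.n_immunoglobulin / self.n_input if self.n_input else 0.0

    @property
    def fraction_unassigned(self) -> float:
        return self.n_unassigned / self.n_input if self.n_input else 0.0


def filter_probesets(matrix: pd.DataFrame,
                     annotation: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop immunoglobulin-assigned and gene-symbol-less probesets.

    Both categories are uninformative for the differentiation signatures:
    immunoglobulin probes saturate in antibody-secreting cells, and probes
    without a gene assignment cannot enter gene-level analyses.
    """
    unknown = matrix.index.difference(annotation.index)
    if len(unknown):
        raise KeyError("probesets absent from annotation: "
                       + ", ".join(map(str, unknown[:10])))
    ann = annotation.loc[matrix.index]
    is_ig = ann["is_ig"].to_numpy(dtype=bool)
    no_symbol = ann["gene_symbol"].isna().to_numpy() & ~is_ig
    keep = ~(is_ig | no_symbol)
    report = FilterReport(
        n_input=len(matrix),
        n_immunoglobulin=int(is_ig.sum()),
        n_unassigned=int(no_symbol.sum()),
        n_retained=int(keep.sum()),
    )
    logger.info("filter_probesets: %d input, %d immunoglobulin removed, "
                "%d unassigned removed, %d retained", report.n_input,
                report.n_immunoglobulin, report.n_unassigned, report.n_retained)
    if report.n_retained == 0:
        logger.warning("filter_probesets removed every probeset")
    return matrix.loc[keep], report


def collapse_to_genes(matrix: pd.DataFrame, annotation: pd.DataFrame,
                      rule: str = "max_mean",
                      de: pd.DataFrame | None = None) -> pd.DataFrame:
    """Keep one representative probeset per gene symbol.

    rule="max_mean" keeps the probeset with the highest mean expression
    (standard for expression-rank analyses); rule="min_p" keeps the probeset
    with the smallest differential-expression p-value and requires `de`
    indexed by probeset with a 'p' column. Ties break on the
    lexicographically smallest probeset id, so the result is deterministic.
    The returned matrix is indexed by gene symbol and records the chosen
    probeset in the column attribute ``attrs['representative']``.
    """
    if rule not in ("max_mean", "min_p"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    if rule == "min_p" and de is None:
        raise ValueError("rule='min_p' requires a differential-expression table")
    ann = annotation.loc[matrix.index]
    symbols = ann["gene_symbol"]
    usable = symbols.notna()
    if rule == "max_mean":
        score = matrix.mean(axis=1)
    else:
        score = -de.loc[matrix.index, "p"]
    frame = pd.DataFrame({
        "gene": symbols[usable],
        "score": score[usable],
        "probeset": matrix.index[usable],
    })
    # sort: best score first, then lexicographic probeset id for ties
    frame = frame.sort_values(["gene", "score", "probeset"],
                              ascending=[True, False, True], kind="mergesort")
    chosen = frame.drop_duplicates("gene", keep="first")
    collapsed = matrix.loc[chosen["probeset"]].copy()
    collapsed.index = pd.Index(chosen["gene"].to_numpy(), name="gene_symbol")
    collapsed.attrs["representative"] = dict(zip(chosen["gene"], chosen["probeset"]))
    return collapsed


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

def ddct_fold_change(ct_target_test: float, ct_ref_test: float,
                     ct_target_calib: float, ct_ref_calib: float) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference gene) within each sample; the fold
    change of the test sample relative to the calibrator is
    2^-(dCt_test - dCt_calibrator).
    """
    for v in (ct_target_test, ct_ref_test, ct_target_calib, ct_ref_calib):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_calib - ct_ref_calib)
    return float(2.0 ** (-ddct))
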