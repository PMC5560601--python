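"""Promoter motif scanning and set-vs-background enrichment ranking.

Transcription-factor binding motifs are position weight matrices scored as
pseudocount-regularized log-likelihood ratios against an i.i.d. background.
Each promoter gets the best-site score over both strands and every offset,
min-max normalized to [0, 1] by the matrix's attainable score range. A
motif's enrichment in a promoter set is the Pscan-style Z statistic: the
foreground mean best-site score against the mean and SD of the full
promoter universe. Motifs are ranked by Z, and two rankings (e.g. the
down- and up-signature promoter sets) are compared by per-motif rank
differences, significant-motif overlap and Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}

STRONG_DELTA = 150
WEAK_DELTA = 50


@dataclass(frozen=True)
class PWM:
    """A position weight matrix with its scoring log-odds.

    ``probs`` is 4 x L (rows A, C, G, T), columns summing to 1 after
    pseudocount regularization against the background composition.
    """
    motif_id: str
    probs: np.ndarray
    background: np.ndarray
    log_odds: np.ndarray = field(init=False, repr=False)
    score_min: float = field(init=False)
    score_max: float = field(init=False)

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape[0] != 4 or probs.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        bg = np.asarray(self.background, dtype=float)
        lo = np.log2(probs / bg[:, None])
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "log_odds", lo)
        object.__setattr__(self, "score_min", float(lo.min(axis=0).sum()))
        object.__setattr__(self, "score_max", float(lo.max(axis=0).sum()))

    def __len__(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    @classmethod
    def from_counts(cls, motif_id: str, counts: pd.DataFrame | np.ndarray,
                    pseudocount: float = 0.5,
                    background: np.ndarray | None = None) -> "PWM":
        """Build from a 4 x L count matrix (rows A, C, G, T).

        Probabilities are (count + pseudocount * bg) / (column total +
        pseudocount), so zero counts never produce infinite log-odds.
        """
        if isinstance(counts, pd.DataFrame):
            counts = counts.loc[list(BASES)].to_numpy(dtype=float)
        counts = np.asarray(counts, dtype=float)
        bg = (np.full(4, 0.25) if background is None
              else np.asarray(background, dtype=float))
        totals = counts.sum(axis=0)
        probs = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
        return cls(motif_id, probs, bg)

    def reverse_complement(self) -> "PWM":
        rc = self.probs[::-1, ::-1]
        return PWM(self.motif_id, rc, self.background)


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and anything else (N) to -1."""
    return np.array([_CODE.get(b, -1) for b in seq.upper()], dtype=np.int64)


def _strand_scores(log_odds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Raw window scores for one strand; windows containing N are NaN."""
    L = log_odds.shape[1]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n_win, np.nan)
    if valid.any():
        w = windows[valid]
        scores[valid] = log_odds[w, np.arange(L)].sum(axis=1)
    return scores


def scan_best_site(pwm: PWM, seq: str) -> float:
    """Best normalized match score of a motif anywhere on either strand.

    The raw log-odds score is computed at every offset on the forward and
    reverse-complement strands; windows containing ambiguous bases are
    skipped. The best raw score is min-max normalized by the matrix's
    attainable range. Returns NaN when no window is scoreable.
    """
    codes = encode_sequence(seq)
    if len(codes) < len(pwm):
        raise ValueError(f"sequence shorter than motif {pwm.motif_id}")
    fwd = _strand_scores(pwm.log_odds, codes)
    rev = _strand_scores(pwm.reverse_complement().log_odds, codes)
    both = np.concatenate([fwd, rev])
    if np.isnan(both).all():
        return float("nan")
    best = np.nanmax(both)
    return float((best - pwm.score_min) / (pwm.score_max - pwm.score_min))


def best_site_scores(pwm: PWM, promoters: dict[str, str]) -> pd.Series:
    """Best-site score per promoter (indexed by promoter/gene id)."""
    return pd.Series({name: scan_best_site(pwm, seq)
                      for name, seq in promoters.items()}, name=pwm.motif_id)


# ---------------------------------------------------------------------------
# enrichment Z and ranking
# ---------------------------------------------------------------------------

def motif_z(scores: pd.Series, foreground: set[str]) -> tuple[float, float]:
    """Set-mean Z statistic of a motif in a foreground promoter set.

    ``scores`` holds the best-site score for every promoter in the universe
    (the background); z = (mean_fg - mean_bg) / (sd_bg / sqrt(n_fg)), with a
    one-tailed upper p from the normal approximation. Requires at least 5
    scoreable foreground promoters; a zero-variance background yields NaN.
    """
    fg_names = [n for n in foreground if n in scores.index]
    if len(set(foreground) - set(scores.index)):
        raise KeyError("foreground promoters missing from the universe: "
                       + ", ".join(sorted(set(foreground) - set(scores.index))[:5]))
    bg = scores.dropna()
    fg = scores.loc[fg_names].dropna()
    if len(fg) < 5:
        raise ValueError("need at least 5 scoreable foreground promoters")
    sd_bg = bg.std(ddof=1)
    if sd_bg == 0 or np.isnan(sd_bg):
        return float("nan"), float("nan")
    z = (fg.mean() - bg.mean()) / (sd_bg / np.sqrt(len(fg)))
    return float(z), float(stats.norm.sf(z))


def enrich_motifs(pwms: dict[str, PWM], promoters: dict[str, str],
                  foreground: set[str], alpha: float = 0.05) -> pd.DataFrame:
    """Z-score enrichment of every motif in a foreground promoter set.

    Returns one row per motif (mean_fg, mean_bg, sd_bg, z, p, rank,
    significant), ranked from most to least enriched. Rank ties break on
    motif id.
    """
    rows = []
    for motif_id, pwm in pwms.items():
        scores = best_site_scores(pwm, promoters)
        z, p = motif_z(scores, foreground)
        fg = scores.loc[[n for n in foreground if n in scores.index]].dropna()
        bg = scores.dropna()
        rows.append((motif_id, fg.mean(), bg.mean(), bg.std(ddof=1), z, p))
    table = pd.DataFrame(rows, columns=["motif", "mean_fg", "mean_bg",
                                        "sd_bg", "z", "p"]).set_index("motif")
    return rank_motifs(table, alpha=alpha)


def rank_motifs(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Assign ranks 1..n by descending Z (NaN last, ties by motif id)."""
    order = table.assign(_id=table.index).sort_values(
        ["z", "_id"], ascending=[False, True], kind="mergesort",
        na_position="last").index
    ranked = table.loc[order].drop(columns="_id", errors="ignore").copy()
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranked["significant"] = ranked["p"] < alpha
    return ranked


def delta_class(delta: float) -> str:
    if delta > STRONG_DELTA:
        return "strong"
    if delta > WEAK_DELTA:
        return "moderate"
    return "weak"


def rank_tracking(rank_a: pd.DataFrame, rank_b: pd.DataFrame,
                  filter_common: bool = False,
                  significant_only_corr: bool = False) -> dict:
    """Track motif ranks between two enrichment lists.

    Per motif: ranks in both lists, the absolute rank difference Δ and its
    class (strong Δ>150, moderate 50<Δ<=150, weak Δ<=50), and the
    significance flags. Summary: overlap fraction = significant in both /
    significant in either, divergent motifs (significant in exactly one
    list), and Spearman rank correlation (over all motifs unless
    ``significant_only_corr``). ``filter_common`` removes motifs significant
    in both lists from the per-motif table after the summary is computed.
    """
    if set(rank_a.index) != set(rank_b.index):
        raise ValueError("motif universes differ between the two rankings")
    motifs = rank_a.index.sort_values()
    table = pd.DataFrame({
        "z_a": rank_a.loc[motifs, "z"],
        "z_b": rank_b.loc[motifs, "z"],
        "rank_a": rank_a.loc[motifs, "rank"],
        "rank_b": rank_b.loc[motifs, "rank"],
        "sig_a": rank_a.loc[motifs, "significant"],
        "sig_b": rank_b.loc[motifs, "significant"],
    }, index=motifs)
    table["delta"] = (table["rank_a"] - table["rank_b"]).abs()
    table["class"] = table["delta"].map(delta_class)

    sig_a, sig_b = set(motifs[table["sig_a"]]), set(motifs[table["sig_b"]])
    either = sig_a | sig_b
    overlap = len(sig_a & sig_b) / len(either) if either else float("nan")
    corr_table = table[table["sig_a"] | table["sig_b"]] if significant_only_corr else table
    if len(corr_table) >= 2 and corr_table["rank_a"].nunique() > 1:
        rho = float(stats.spearmanr(corr_table["rank_a"],
                                    corr_table["rank_b"]).statistic)
    else:
        rho = float("nan")
    if filter_common:
        table = table[~(table["sig_a"] & table["sig_b"])]
    return {
        "table": table,
        "overlap_fraction": overlap,
        "divergent": sorted(either - (sig_a & sig_b)),
        "spearman": rho,
    }
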