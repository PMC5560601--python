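"""Multi-study meta-analysis of monoclonal gammopathies.

Each study contributes gene-level expression for healthy bone-marrow plasma
cells plus one or more disease stages (MGUS, SMM, MM). Per study and stage,
genes are tested against the healthy reference with the moderated t, and
the top-k significant genes (adjusted p < 0.1, ranked by p) carry their
direction into a cross-study consistency rule: a gene is consistently
dysregulated when it appears with the same direction in at least
``min_studies`` studies. The overlap of consistent genes with the PC
signatures, split by direction, quantifies the imbalance of the normal
plasma-cell program in disease. A GEP70-style per-sample score (mean log2
expression of a 70-probeset list) supports a correlation screen for
risk-associated signature genes across independent datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import Contrast, DEResult, moderated_t
from .signatures import SignatureSet

logger = logging.getLogger(__name__)

STAGES = ("healthy", "MGUS", "SMM", "MM")


@dataclass(frozen=True)
class Study:
    study_id: str
    matrix: pd.DataFrame  # gene-level, log2
    design: pd.DataFrame  # sample_id -> group (stage labels)

    def stages(self) -> list[str]:
        return [s for s in dict.fromkeys(self.design["group"])]


def shared_universe(studies: list[Study]) -> pd.Index:
    """Genes represented in every study (the meta-analysis universe)."""
    universe = studies[0].matrix.index
    for s in studies[1:]:
        universe = universe.intersection(s.matrix.index)
    return universe.sort_values()


# ---------------------------------------------------------------------------
# per-study top differential genes
# ---------------------------------------------------------------------------

def per_study_top_de(study: Study, stage: str, reference: str = "healthy",
                     k: int = 1000, threshold: float = 0.1,
                     universe: pd.Index | None = None) -> pd.DataFrame:
    """Top-k significant genes of stage vs healthy reference in one study.

    Returns a frame (gene index; columns log2FC, p, adj_p, direction)
    holding at most k genes with adjusted p below the threshold, ordered by
    p. A warning is logged when fewer than k genes reach significance.
    """
    if stage not in set(study.design["group"]):
        raise KeyError(f"stage {stage!r} absent from study {study.study_id}")
    if reference not in set(study.design["group"]):
        raise KeyError(f"reference {reference!r} absent from study {study.study_id}")
    matrix = study.matrix if universe is None else study.matrix.loc[universe]
    de = moderated_t(matrix, study.design, Contrast.of(stage, reference),
                     threshold=threshold)
    sig = de.table[de.table["significant"]].sort_values(
        ["p", "log2FC"], kind="mergesort")
    if len(sig) < k:
        logger.warning("study %s stage %s: only %d significant genes (< k=%d)",
                       study.study_id, stage, len(sig), k)
    return sig.head(k)[["log2FC", "p", "adj_p", "direction"]]


def consistent_dysregulated(top_lists: list[pd.DataFrame],
                            min_studies: int = 2) -> pd.DataFrame:
    """Genes present with the same direction in at least ``min_studies`` lists.

    Direction conflicts (a gene up in one study's top list and down in
    another's) are dropped and logged. Returns a frame indexed by gene with
    columns direction and n_studies.
    """
    if len(top_lists) < min_studies:
        raise ValueError(f"need at least min_studies={min_studies} lists")
    votes: dict[str, dict[str, int]] = {}
    for top in top_lists:
        for gene, direction in top["direction"].items():
            votes.setdefault(gene, {}).setdefault(direction, 0)
            votes[gene][direction] += 1
    rows, conflicts = [], 0
    for gene, dirs in votes.items():
        if len(dirs) > 1:
            conflicts += 1
            continue
        direction, count = next(iter(dirs.items()))
        if count >= min_studies:
            rows.append((gene, direction, count))
    if conflicts:
        logger.info("consistent_dysregulated: %d direction conflicts dropped",
                    conflicts)
    frame = pd.DataFrame(rows, columns=["gene", "direction", "n_studies"])
    return frame.sort_values("gene", kind="mergesort").set_index("gene")


# ---------------------------------------------------------------------------
# signature imbalance
# ---------------------------------------------------------------------------

def signature_imbalance(consistent_per_stage: dict[str, pd.DataFrame],
                        signatures: dict[str, SignatureSet],
                        per_study_per_stage: dict[str, list[pd.DataFrame]] | None = None
                        ) -> pd.DataFrame:
    """Overlap of consistent dysregulated genes with each signature.

    One row per (stage, signature, dysregulation direction): gene count,
    percentage of the signature, and — when per-study top lists are
    supplied — the mean and SD of the per-study overlap counts and the
    number of studies contributing to the stage.
    """
    rows = []
    for stage, consistent in consistent_per_stage.items():
        by_dir = {d: set(consistent.index[consistent["direction"] == d])
                  for d in ("up", "down")}
        for sig_name, sig in signatures.items():
            for direction in ("up", "down"):
                overlap = by_dir[direction] & sig.genes
                row = {
                    "stage": stage,
                    "signature": sig_name,
                    "dysregulation": direction,
                    "count": len(overlap),
                    "pct_of_signature": 100.0 * len(overlap) / len(sig) if len(sig) else 0.0,
                }
                if per_study_per_stage is not None:
                    tops = per_study_per_stage.get(stage, [])
                    per_study = [
                        len(set(t.index[t["direction"] == direction]) & sig.genes)
                        for t in tops]
                    row["per_study_mean"] = float(np.mean(per_study)) if per_study else np.nan
                    row["per_study_sd"] = (float(np.std(per_study, ddof=1))
                                           if len(per_study) > 1 else np.nan)
                    row["n_studies"] = len(per_study)
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GEP70-style score and risk screen
# ---------------------------------------------------------------------------

def gep70_score(matrix: pd.DataFrame, up_probes: list[str],
                down_probes: list[str] | None = None,
                mode: str = "mean_all") -> pd.Series:
    """Per-sample risk score from a 70-probeset expression list.

    mode="mean_all" (default): the arithmetic mean of the log2 expression of
    every listed probeset. mode="up_minus_down": mean of the up list minus
    mean of the down list, the form of the original risk-score publication.
    Missing probesets raise (no silent dropping).
    """
    down_probes = down_probes or []
    if mode not in ("mean_all", "up_minus_down"):
        raise ValueError(f"unknown score mode {mode!r}")
    if not up_probes and not down_probes:
        raise ValueError("probeset lists are empty")
    wanted = list(up_probes) + list(down_probes)
    missing = [p for p in wanted if p not in matrix.index]
    if missing:
        raise KeyError("probesets absent from matrix: " + ", ".join(missing[:10]))
    if mode == "mean_all":
        score = matrix.loc[wanted].mean(axis=0)
    else:
        if not up_probes or not down_probes:
            raise ValueError("up_minus_down needs both lists")
        score = matrix.loc[list(up_probes)].mean(axis=0) \
            - matrix.loc[list(down_probes)].mean(axis=0)
    return score.rename("score")


def risk_screen(datasets: list[tuple[pd.DataFrame, pd.Series]],
                geneset: set[str], alpha: float = 0.05) -> pd.DataFrame:
    """Correlate each gene's expression with a risk score across datasets.

    For every gene and dataset: Pearson r and the two-sided p from the exact
    t transform t = r * sqrt((n-2)/(1-r^2)). A gene is ``consistent`` when
    its correlation is significant with the same sign in ALL datasets, and
    is then classed low-risk (all r < 0) or high-risk (all r > 0).
    Zero-variance genes yield NaN r for that dataset and cannot be
    consistent.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    for matrix, score in datasets:
        if matrix.shape[1] < 10:
            raise ValueError("each dataset needs at least 10 samples")
        if not matrix.columns.equals(score.index):
            raise ValueError("score index must match dataset samples")
    genes = sorted(geneset)
    rows = []
    for gene in genes:
        rs, ps = [], []
        for matrix, score in datasets:
            if gene not in matrix.index:
                rs.append(np.nan)
                ps.append(np.nan)
                continue
            x = matrix.loc[gene].to_numpy(dtype=float)
            y = score.to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rs.append(np.nan)
                ps.append(np.nan)
                continue
            n = len(x)
            r = float(np.corrcoef(x, y)[0, 1])
            t = r * np.sqrt((n - 2) / max(1.0 - r * r, 1e-12))
            p = 2.0 * stats.t.sf(abs(t), n - 2)
            rs.append(r)
            ps.append(float(p))
        rs_arr, ps_arr = np.array(rs), np.array(ps)
        ok = np.isfinite(rs_arr).all() and np.isfinite(ps_arr).all()
        all_sig = ok and bool((ps_arr < alpha).all())
        same_sign = ok and (bool((rs_arr > 0).all()) or bool((rs_arr < 0).all()))
        consistent = all_sig and same_sign
        risk_class = ""
        if consistent:
            risk_class = "high" if rs_arr[0] > 0 else "low"
        row = {"gene": gene, "consistent": consistent, "risk_class": risk_class}
        for i, (r, p) in enumerate(zip(rs, ps)):
            row[f"r_{i}"] = r
            row[f"p_{i}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
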