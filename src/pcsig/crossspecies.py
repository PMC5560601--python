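"""Cross-species comparison: ortholog mapping, top-N overlap, KO concordance.

A mouse antibody-secreting-cell gene set is carried into the human
expression universe through an ortholog table, keeping only unequivocal
(one-to-one, both present) pairs; its concentration among the most
up-regulated human genes is then assessed by top-N overlap across ranked
lists. Knockout tables from conditional regulator inactivation are
classified as concordant or discordant with a signature given the
regulator's assumed mode (activator or repressor).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .rankdist import RankedList
from .signatures import SignatureSet


@dataclass(frozen=True)
class OrthologReport:
    n_input: int
    n_mapped: int
    n_unmapped: int
    n_ambiguous: int
    n_absent_from_universe: int


def map_orthologs(geneset: set[str], ortholog_map: pd.DataFrame,
                  universe: set[str]) -> tuple[set[str], OrthologReport]:
    """Map a source-species gene set into a target universe, one-to-one only.

    ``ortholog_map`` has columns (source, target). A source gene maps only
    if it pairs with exactly one target that lies in the universe, and that
    target is not claimed by any other source gene in the set of candidate
    pairs ("unequivocally comparable"). Dropped genes are counted by reason.
    """
    if ortholog_map.empty:
        raise ValueError("empty ortholog map")
    pairs = ortholog_map.iloc[:, :2].drop_duplicates()
    pairs.columns = ["source", "target"]
    # restrict to pairs whose target exists in the universe
    in_universe = pairs[pairs["target"].isin(universe)]
    src_counts = Counter(in_universe["source"])
    tgt_counts = Counter(in_universe["target"])

    mapped: set[str] = set()
    n_unmapped = n_ambiguous = n_absent = 0
    by_source = in_universe.groupby("source")["target"].agg(list)
    all_sources = set(pairs["source"])
    for gene in geneset:
        if gene not in all_sources:
            n_unmapped += 1
            continue
        if gene not in by_source.index:
            n_absent += 1
            continue
        targets = by_source[gene]
        if len(targets) != 1 or src_counts[gene] != 1 or tgt_counts[targets[0]] != 1:
            n_ambiguous += 1
            continue
        mapped.add(targets[0])
    report = OrthologReport(n_input=len(geneset), n_mapped=len(mapped),
                            n_unmapped=n_unmapped, n_ambiguous=n_ambiguous,
                            n_absent_from_universe=n_absent)
    return mapped, report


def topn_overlap(ranked_lists: list[RankedList], geneset: set[str],
                 n: int = 2000,
                 signature: SignatureSet | None = None,
                 significant: dict[str, set[str]] | None = None) -> dict:
    """Overlap of a gene set with the top-N of each ranked list.

    Returns per-list overlaps, the set common to all lists, and — when
    given — how many common genes are significant in any list and how many
    fall in a supplied signature.
    """
    if not ranked_lists:
        raise ValueError("no ranked lists supplied")
    for rl in ranked_lists:
        if n > len(rl):
            raise ValueError(f"N={n} exceeds universe size {len(rl)} of {rl.key}")
    per_list: dict[str, set[str]] = {}
    for rl in ranked_lists:
        per_list[rl.key] = set(rl.genes[:n]) & geneset
    common = set.intersection(*per_list.values())
    result = {
        "per_list": per_list,
        "common": common,
        "sizes": {k: len(v) for k, v in per_list.items()},
        "common_size": len(common),
    }
    if significant is not None:
        any_sig = set.union(*significant.values()) if significant else set()
        result["common_significant"] = len(common & any_sig)
    if signature is not None:
        result["common_in_signature"] = len(common & signature.genes)
    return result


def ko_concordance(signature: SignatureSet, ko_table: pd.DataFrame,
                   regulator_mode: str) -> dict:
    """Classify signature genes by their response to regulator knockout.

    ``ko_table`` has columns (gene, direction) with direction the change
    upon inactivation. For an activator, a target should fall when the
    regulator is lost: an up-signature gene down-in-KO (or a down-signature
    gene up-in-KO) is concordant. Repressor mode inverts the pairing.
    Signature genes absent from the table are not counted; the fraction is
    concordant over the full signature size.
    """
    if regulator_mode not in ("activator", "repressor"):
        raise ValueError(f"unknown regulator mode {regulator_mode!r}")
    if len(signature) == 0:
        raise ValueError("empty signature")
    ko = dict(zip(ko_table.iloc[:, 0], ko_table.iloc[:, 1]))
    expected_ko_dir = {"up": "down", "down": "up"}[signature.direction]
    if regulator_mode == "repressor":
        expected_ko_dir = {"down": "up", "up": "down"}[expected_ko_dir]
    concordant, discordant = set(), set()
    for gene in signature.genes:
        if gene not in ko:
            continue
        (concordant if ko[gene] == expected_ko_dir else discordant).add(gene)
    return {
        "concordant": concordant,
        "discordant": discordant,
        "fraction_of_signature": len(concordant) / len(signature),
        "mode": regulator_mode,
    }
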