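"""End-to-end orchestration of the synthetic study.

``run_pipeline`` generates a cohort, preprocesses it, derives the core and
subtype signatures, profiles their rank distribution, and (when enabled)
runs the motif-enrichment comparison and the gammopathy meta-analysis with
the risk screen. Every output lands in the report directory as plain text,
stamped with the configuration hash and root seed; reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, preprocess, diffexpr, signatures, rankdist, tfbs, meta_mm, synth
from .diffexpr import Contrast
from .synth import CohortSpec, PlantedSet, ImbalanceSpec, split_seed

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "adj_p": 0.1,
    "alpha": 0.05,
    "bin_size": 50,
    "top_n": 200,
    "top_k": 300,
    "min_studies": 2,
    "percentile": 0.90,
    "offset": 10,
    "reference_group": "BC",
    "cohort": {
        "groups": {"BC": 3, "TPC": 7, "BPC": 6, "BMPC": 7},
        "n_genes": 2000,
        "noise_sd": 0.5,
        "planted": [
            {"name": "PC-down", "n_genes": 300,
             "groups": ["TPC", "BPC", "BMPC"], "effect": -1.5},
            {"name": "PC-up", "n_genes": 200,
             "groups": ["TPC", "BPC", "BMPC"], "effect": 1.5},
        ],
    },
    "stages": {"tfbs": True, "meta": True},
    "tfbs": {"n_decoys": 20, "placement_prob": 0.8, "promoter_length": 300,
             "n_promoter_genes": 150, "foreground_size": 40},
    "meta": {"n_studies": 3, "n_genes": 1500,
             "groups": {"healthy": 8, "MGUS": 8, "MM": 8},
             "up_fraction_mm": 0.6, "down_fraction_mm": 0.2,
             "n_background": 150, "platform_shift": 0.3},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _cohort_spec(config: dict, seed: int) -> CohortSpec:
    c = config["cohort"]
    planted = tuple(
        PlantedSet(p["name"], p["n_genes"], tuple(p["groups"]), p["effect"])
        for p in c.get("planted", []))
    return CohortSpec(groups=dict(c["groups"]), n_genes=c["n_genes"],
                      planted=planted, noise_sd=c.get("noise_sd", 0.5),
                      seed=seed)


def run_pipeline(config: dict | None = None, out_dir: str | Path = "report") -> Path:
    """Run every enabled stage; returns the report directory."""
    config = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = split_seed(int(config["seed"]), 8)
    reference = config["reference_group"]
    counts: dict[str, object] = {}

    # --- synthetic cohort -------------------------------------------------
    spec = _cohort_spec(config, seeds[0])
    matrix, annotation, design, truth = synth.generate_cohort(spec)
    io.write_expression_tsv(matrix, out / "expression.tsv")
    io.write_annotation_tsv(annotation, out / "annotation.tsv")
    io.write_design_tsv(design, out / "design.tsv")
    truth.save(out / "truth.json")

    # --- preprocess -------------------------------------------------------
    filtered, report = preprocess.filter_probesets(matrix, annotation)
    counts["filter"] = {"input": report.n_input, "ig": report.n_immunoglobulin,
                        "unassigned": report.n_unassigned,
                        "retained": report.n_retained}

    # --- differential expression -----------------------------------------
    de_map = diffexpr.pairwise_de(filtered, design, "all-pairs",
                                  threshold=config["adj_p"])
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    gene_de = {}
    for name, de in de_map.items():
        gde = diffexpr.collapse_de_to_genes(de, annotation, rule="any")
        gene_de[name] = gde
        gde.table.to_csv(de_dir / f"{name}.tsv", sep="\t")
    counts["n_contrasts"] = len(de_map)

    # --- signatures -------------------------------------------------------
    pc_groups = [g for g in spec.groups if g != reference]
    ref_de = {}
    for g in pc_groups:
        name = f"{g}_vs_{reference}"
        ref_de[name] = (gene_de[name] if name in gene_de
                        else gene_de[f"{reference}_vs_{g}"].flipped())
    sig_down = signatures.core_signature(ref_de, "down", reference=reference)
    sig_up = signatures.core_signature(ref_de, "up", reference=reference)
    subtype_de = {n: d for n, d in gene_de.items()
                  if reference not in (d.contrast.group_a, d.contrast.group_b)}
    subtype = signatures.subtype_signatures(subtype_de)
    all_sigs = {s.name: s for s in [sig_down, sig_up]}
    all_sigs.update(subtype)
    gmt = {name: sorted(s.genes) for name, s in all_sigs.items() if s.genes}
    if gmt:
        io.write_gmt(gmt, out / "signatures.gmt")
    counts["signatures"] = {name: len(s) for name, s in all_sigs.items()}

    # --- rank distribution ------------------------------------------------
    collapsed = preprocess.collapse_to_genes(filtered, annotation, rule="max_mean")
    chi2_report = {}
    profiles = []
    for g in pc_groups if sig_up.genes else []:
        de = ref_de[f"{g}_vs_{reference}"]
        ranked = rankdist.rank_by_statistic(de, key="t", direction="up")
        profile = rankdist.bin_counts(ranked, set(sig_up.genes),
                                      bin_size=config["bin_size"])
        profiles.append(profile)
        res = rankdist.chi2_uniform(profile)
        chi2_report[f"{g}_vs_{reference}"] = {
            "chi2": res.chi2, "df": res.df, "p": res.p}
    if profiles:
        mean_profile, sem = rankdist.average_bin_profiles(profiles)
        pd.DataFrame({"bin": np.arange(1, mean_profile.n_bins + 1),
                      "mean_count": mean_profile.counts,
                      "sem": sem}).to_csv(out / "bin_profile.tsv", sep="\t",
                                          index=False)
        chi2_report["percentile_fraction_up"] = rankdist.percentile_fraction(
            collapsed, set(sig_up.genes), q=config["percentile"])
    else:
        (out / "bin_profile.tsv").write_text("bin\tmean_count\tsem\n")
    io.write_json(chi2_report, out / "rankdist.json")

    # --- motif enrichment -------------------------------------------------
    if config["stages"].get("tfbs"):
        t = config["tfbs"]
        pwms = synth.decoy_pwms(t["n_decoys"], seed=seeds[2])
        planted_pwm = tfbs.PWM.from_counts(
            "PLANTED", np.array([[8, 0, 0, 8, 0, 0, 8, 0],
                                 [0, 8, 0, 0, 8, 0, 0, 0],
                                 [0, 0, 8, 0, 0, 8, 0, 8],
                                 [0, 0, 0, 0, 0, 0, 0, 0]], dtype=float))
        pwms["PLANTED"] = planted_pwm
        gene_ids = [f"P{i:04d}" for i in range(1, t["n_promoter_genes"] + 1)]
        fg_a = set(gene_ids[: t["foreground_size"]])
        fg_b = set(gene_ids[t["foreground_size"]: 2 * t["foreground_size"]])
        promoters, _ = synth.generate_promoters(
            gene_ids, planted_pwm, fg_a, placement_prob=t["placement_prob"],
            length=t["promoter_length"], seed=seeds[3])
        rank_a = tfbs.enrich_motifs(pwms, promoters, fg_a, alpha=config["alpha"])
        rank_b = tfbs.enrich_motifs(pwms, promoters, fg_b, alpha=config["alpha"])
        track = tfbs.rank_tracking(rank_a, rank_b)
        track["table"].to_csv(out / "rank_track.tsv", sep="\t")
        io.write_json({"spearman": track["spearman"],
                       "overlap_fraction": track["overlap_fraction"],
                       "planted_rank": int(rank_a.loc["PLANTED", "rank"])},
                      out / "tfbs.json")

    # --- gammopathy meta-analysis ----------------------------------------
    if config["stages"].get("meta"):
        m = config["meta"]
        meta_genes = [f"G{i:05d}" for i in range(1, m["n_genes"] + 1)]
        sig_size = 150
        meta_sigs = {
            "PC-up": signatures.SignatureSet(
                "PC-up", "up", frozenset(meta_genes[:sig_size])),
            "PC-down": signatures.SignatureSet(
                "PC-down", "down", frozenset(meta_genes[sig_size:2 * sig_size])),
        }
        imbalance = [
            ImbalanceSpec("PC-up", "up", m["up_fraction_mm"],
                          {"MGUS": 0.5, "MM": 1.5}),
            ImbalanceSpec("PC-up", "down", m["down_fraction_mm"],
                          {"MGUS": 0.5, "MM": 1.5}),
        ]
        studies, meta_truth = synth.generate_gammopathy_studies(
            m["n_studies"], m["groups"], meta_sigs, imbalance,
            n_genes=m["n_genes"], n_background_dysregulated=m["n_background"],
            platform_shift=m["platform_shift"], seed=seeds[4])
        universe = meta_mm.shared_universe(studies)
        consistent_per_stage, tops_per_stage = {}, {}
        for stage in [s for s in m["groups"] if s != "healthy"]:
            tops = [meta_mm.per_study_top_de(s, stage, k=config["top_k"],
                                             threshold=config["adj_p"],
                                             universe=universe)
                    for s in studies]
            tops_per_stage[stage] = tops
            consistent_per_stage[stage] = meta_mm.consistent_dysregulated(
                tops, min_studies=config["min_studies"])
        imbalance_report = meta_mm.signature_imbalance(
            consistent_per_stage, meta_sigs, tops_per_stage)
        imbalance_report.to_csv(out / "imbalance.tsv", sep="\t", index=False)

        # risk screen on the first study's MM-correlated score
        rng = np.random.default_rng(seeds[5])
        score_probes = list(universe[:70])
        risk_datasets = []
        for study in studies:
            score = meta_mm.gep70_score(study.matrix, score_probes)
            risk_datasets.append((study.matrix, score))
        screen = meta_mm.risk_screen(risk_datasets,
                                     set(meta_sigs["PC-up"].genes),
                                     alpha=config["alpha"])
        screen.to_csv(out / "risk_screen.tsv", sep="\t")
        counts["n_consistent"] = {s: len(c) for s, c in
                                  consistent_per_stage.items()}

    io.write_json({"config_hash": config_hash(config),
                   "seed": config["seed"], "counts": counts},
                  out / "run_info.json")
    logger.info("pipeline complete: %s", out)
    return out
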