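"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study design the pipeline targets: a four-group
cohort (naive B cells and three plasma-cell subsets, 3/7/6/7 samples) on a
probeset-level array with redundant probesets, immunoglobulin probes and
unannotated probes; promoter sets with planted motif occurrences;
multi-study gammopathy cohorts with stage-graded planted dysregulation and
platform shifts; and knockout tables with a controlled concordant fraction.
Every generator is fully determined by its seed, and everything planted is
recorded in a serializable truth object so recovery can be scored exactly.

Expression is generated directly on the log2 scale as
Normal(baseline_g + planted effect, noise_sd); redundant probesets of a
gene share the gene mean plus a fixed probeset-specific offset. A linear
raw-intensity view (2**x plus additive Gaussian background) is available to
exercise background correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .meta_mm import Study
from .signatures import SignatureSet
from .tfbs import PWM, BASES

DEFAULT_GROUPS = {"BC": 3, "TPC": 7, "BPC": 6, "BMPC": 7}
PROBESET_OFFSET_SD = 0.2


def split_seed(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one root seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# truth record
# ---------------------------------------------------------------------------

@dataclass
class SynthTruth:
    """Everything planted by the generators, JSON-serializable."""
    signatures: dict = field(default_factory=dict)   # name -> {genes, direction, effect, groups}
    motif_placements: dict = field(default_factory=dict)  # promoter -> [{offset, site}]
    study_dysregulation: dict = field(default_factory=dict)  # name -> {genes, direction, stage_multipliers, fraction}
    ko: dict = field(default_factory=dict)           # {concordant, discordant, mode}
    risk_genes: dict = field(default_factory=dict)   # gene -> target r

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SynthTruth":
        return cls(**{k: data.get(k, {}) for k in
                      ("signatures", "motif_placements", "study_dysregulation",
                       "ko", "risk_genes")})

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "SynthTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def signature_set(self, name: str) -> SignatureSet:
        entry = self.signatures[name]
        return SignatureSet(name, entry["direction"], frozenset(entry["genes"]))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSet:
    """A planted directional effect: ``log2_effect`` is added to the listed
    groups for ``n_genes`` randomly chosen genes."""
    name: str
    n_genes: int
    affected_groups: tuple[str, ...]
    log2_effect: float

    @property
    def direction(self) -> str:
        return "up" if self.log2_effect >= 0 else "down"


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic cohort.

    ``probesets_per_gene`` maps a probeset count to its probability (e.g.
    {1: 0.7, 2: 0.3}); immunoglobulin and unannotated probesets are extra
    rows on top of the annotated genes.
    """
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    n_genes: int = 2000
    probesets_per_gene: dict = field(default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1})
    n_ig_probesets: int = 20
    n_unannotated: int = 100
    planted: tuple = ()
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if not self.groups or any(n < 1 for n in self.groups.values()):
            raise ValueError("every group needs at least one sample")
        if self.n_genes < 1 or self.n_ig_probesets < 0 or self.n_unannotated < 0:
            raise ValueError("counts must be positive")
        if any(k < 1 for k in self.probesets_per_gene):
            raise ValueError("probesets per gene must be >= 1")
        if not np.isclose(sum(self.probesets_per_gene.values()), 1.0):
            raise ValueError("probeset-count probabilities must sum to 1")
        for p in self.planted:
            if not np.isfinite(p.log2_effect):
                raise ValueError(f"planted set {p.name}: effect must be finite")
            unknown = set(p.affected_groups) - set(self.groups)
            if unknown:
                raise ValueError(f"planted set {p.name}: unknown groups {unknown}")
        if sum(p.n_genes for p in self.planted) > self.n_genes:
            raise ValueError("planted sets exceed the gene universe")


def generate_cohort(spec: CohortSpec
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Generate (expression matrix, probeset annotation, design, truth)."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(1, spec.n_genes + 1)]

    # assign disjoint planted gene sets
    truth = SynthTruth()
    pool = list(genes)
    effects = pd.DataFrame(0.0, index=genes, columns=list(spec.groups))
    for planted in spec.planted:
        chosen = sorted(rng.choice(pool, size=planted.n_genes, replace=False))
        pool = [g for g in pool if g not in set(chosen)]
        for g in chosen:
            effects.loc[g, list(planted.affected_groups)] = planted.log2_effect
        truth.signatures[planted.name] = {
            "genes": chosen,
            "direction": planted.direction,
            "effect": planted.log2_effect,
            "groups": list(planted.affected_groups),
        }

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)

    # probeset layout
    counts = np.array(sorted(spec.probesets_per_gene))
    probs = np.array([spec.probesets_per_gene[c] for c in counts], dtype=float)
    n_ps_per_gene = rng.choice(counts, size=spec.n_genes, p=probs)
    rows, row_gene_idx = [], []
    for gi, (gene, n_ps) in enumerate(zip(genes, n_ps_per_gene)):
        for k in range(int(n_ps)):
            rows.append((f"{gene}_at{k + 1}", gene, False))
            row_gene_idx.append(gi)
    offsets = rng.normal(0.0, PROBESET_OFFSET_SD, size=len(rows))

    # samples
    sample_ids, sample_groups = [], []
    for group, n in spec.groups.items():
        for i in range(1, n + 1):
            sample_ids.append(f"{group}_{i}")
            sample_groups.append(group)

    gene_idx = np.array(row_gene_idx)
    group_mean = baseline[:, None] + effects.to_numpy()  # genes x groups
    group_pos = {g: j for j, g in enumerate(spec.groups)}
    means = np.empty((len(rows), len(sample_ids)))
    for sj, group in enumerate(sample_groups):
        means[:, sj] = group_mean[gene_idx, group_pos[group]] + offsets
    values = means + rng.normal(0.0, spec.noise_sd, size=means.shape)

    # immunoglobulin probes: constitutively very high in every group
    ig_rows = []
    for i in range(1, spec.n_ig_probesets + 1):
        ig_rows.append((f"IG_{i:03d}_at", f"IGHV{i}", True))
    ig_values = rng.normal(spec.baseline_mean + 4.0, spec.noise_sd,
                           size=(spec.n_ig_probesets, len(sample_ids)))
    # unannotated probes: background-like, no gene symbol
    un_rows = [(f"UNK_{i:04d}_at", None, False)
               for i in range(1, spec.n_unannotated + 1)]
    un_values = rng.normal(spec.baseline_mean - 2.0, 1.0,
                           size=(spec.n_unannotated, len(sample_ids)))

    all_rows = rows + ig_rows + un_rows
    matrix = pd.DataFrame(
        np.vstack([values, ig_values, un_values]) if len(all_rows) > len(rows)
        else values,
        index=pd.Index([r[0] for r in all_rows], name="probeset_id"),
        columns=sample_ids)
    annotation = pd.DataFrame({
        "probeset_id": [r[0] for r in all_rows],
        "gene_symbol": [r[1] for r in all_rows],
        "is_ig": [r[2] for r in all_rows],
    }).set_index("probeset_id", drop=False)
    design = pd.DataFrame({
        "sample_id": sample_ids,
        "group": sample_groups,
        "study": "synth",
        "stage": "",
    }).set_index("sample_id", drop=False)
    return matrix, annotation, design, truth


def to_raw_intensities(log2_matrix: pd.DataFrame, seed: int,
                       bg_mean: float = 100.0, bg_sd: float = 10.0) -> pd.DataFrame:
    """Linear-scale view: 2**x plus additive Gaussian optical background."""
    rng = np.random.default_rng(seed)
    raw = 2.0 ** log2_matrix.to_numpy() + rng.normal(
        bg_mean, bg_sd, size=log2_matrix.shape)
    return pd.DataFrame(np.maximum(raw, 0.0), index=log2_matrix.index,
                        columns=log2_matrix.columns)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    """Draw one binding site from the motif's per-column base probabilities."""
    cols = [rng.choice(4, p=pwm.probs[:, j] / pwm.probs[:, j].sum())
            for j in range(len(pwm))]
    return "".join(BASES[c] for c in cols)


def generate_promoters(gene_ids: list[str], motif: PWM, foreground: set[str],
                       placement_prob: float = 1.0, length: int = 500,
                       seed: int = 0,
                       base_probs: np.ndarray | None = None
                       ) -> tuple[dict[str, str], SynthTruth]:
    """I.i.d.-background promoters with motif sites planted in the foreground.

    Each foreground promoter receives, with probability ``placement_prob``,
    one site sampled from the motif inserted at a random offset; placements
    (offset, site) are recorded in the truth. Background composition
    defaults to uniform.
    """
    if not 0 <= placement_prob <= 1:
        raise ValueError("placement_prob must be in [0, 1]")
    if length < len(motif):
        raise ValueError("promoter shorter than motif")
    rng = np.random.default_rng(seed)
    probs = (np.full(4, 0.25) if base_probs is None
             else np.asarray(base_probs, dtype=float))
    truth = SynthTruth()
    promoters: dict[str, str] = {}
    for gene in gene_ids:
        seq = "".join(BASES[c] for c in rng.choice(4, size=length, p=probs))
        placements = []
        if gene in foreground and rng.random() < placement_prob:
            site = sample_site(motif, rng)
            offset = int(rng.integers(0, length - len(site) + 1))
            seq = seq[:offset] + site + seq[offset + len(site):]
            placements.append({"offset": offset, "site": site})
        promoters[gene] = seq
        if placements:
            truth.motif_placements[gene] = placements
    return promoters, truth


def decoy_pwms(n: int, length: int = 8, seed: int = 0,
               concentration: float = 2.0) -> dict[str, PWM]:
    """Random Dirichlet-column decoy motifs for enrichment null panels."""
    rng = np.random.default_rng(seed)
    pwms = {}
    for i in range(1, n + 1):
        probs = rng.dirichlet(np.full(4, 1.0 / concentration), size=length).T
        pwms[f"DECOY{i:03d}"] = PWM(f"DECOY{i:03d}", probs, np.full(4, 0.25))
    return pwms


# ---------------------------------------------------------------------------
# gammopathy studies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImbalanceSpec:
    """Planted dysregulation of a signature across disease stages.

    A fraction of the signature's genes is dysregulated in the given
    direction; the planted shift in stage s is ``base_effect *
    stage_multipliers[s]``. Monotone multipliers (MGUS <= SMM <= MM) model
    progressive exacerbation.
    """
    signature_name: str
    direction: str  # direction of dysregulation: up | down
    fraction: float
    stage_multipliers: dict  # stage -> multiplier
    base_effect: float = 1.0
    require_monotone: bool = True

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be up/down")
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        unknown = set(self.stage_multipliers) - {"MGUS", "SMM", "MM"}
        if unknown:
            raise ValueError(f"unknown stage labels {unknown}")
        if self.require_monotone:
            order = [self.stage_multipliers.get(s) for s in ("MGUS", "SMM", "MM")]
            present = [m for m in order if m is not None]
            if any(a > b for a, b in zip(present, present[1:])):
                raise ValueError("stage multipliers must be ordered "
                                 "MGUS <= SMM <= MM")


def generate_gammopathy_studies(n_studies: int,
                                groups_per_study: dict,
                                signatures: dict[str, SignatureSet],
                                imbalance: list[ImbalanceSpec] = (),
                                n_genes: int = 3000,
                                n_background_dysregulated: int = 0,
                                background_effect: float = 1.5,
                                platform_shift: float = 0.0,
                                noise_sd: float = 0.5,
                                baseline_mean: float = 8.0,
                                baseline_sd: float = 1.5,
                                seed: int = 0) -> tuple[list[Study], SynthTruth]:
    """Multi-study cohorts sharing a gene universe, with planted imbalance.

    All studies share per-gene baselines; each study adds a per-gene
    platform shift ~ Normal(0, platform_shift). Signature genes selected by
    the imbalance specs are shifted stage-wise in the stated direction;
    optional background dysregulated genes (disease vs healthy, constant
    across stages, random direction) populate the top-k lists the
    meta-analysis consumes. Stage labels must come from
    {healthy, MGUS, SMM, MM}; each study must include healthy samples.
    """
    unknown = set(groups_per_study) - set(("healthy", "MGUS", "SMM", "MM"))
    if unknown:
        raise ValueError(f"unknown stage labels {unknown}")
    if "healthy" not in groups_per_study:
        raise ValueError("each study needs a healthy reference group")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    for name, sig in signatures.items():
        missing = set(sig.genes) - set(genes)
        if missing:
            raise ValueError(f"signature {name} has genes outside the universe")
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)

    truth = SynthTruth()
    stage_effect = {s: np.zeros(n_genes) for s in ("MGUS", "SMM", "MM")}
    claimed: set[str] = set()
    for spec in imbalance:
        sig = signatures[spec.signature_name]
        candidates = sorted(set(sig.genes) - claimed)
        n_dys = int(round(spec.fraction * len(sig.genes)))
        chosen = sorted(rng.choice(candidates, size=n_dys, replace=False))
        claimed.update(chosen)
        sign = 1.0 if spec.direction == "up" else -1.0
        for stage, mult in spec.stage_multipliers.items():
            idx = [gene_pos[g] for g in chosen]
            stage_effect[stage][idx] += sign * spec.base_effect * mult
        truth.study_dysregulation[f"{spec.signature_name}:{spec.direction}"] = {
            "genes": chosen,
            "direction": spec.direction,
            "fraction": spec.fraction,
            "stage_multipliers": dict(spec.stage_multipliers),
        }

    if n_background_dysregulated:
        free = sorted(set(genes) - claimed
                      - {g for s in signatures.values() for g in s.genes})
        bg_genes = sorted(rng.choice(free, size=n_background_dysregulated,
                                     replace=False))
        bg_dirs = rng.choice(["up", "down"], size=n_background_dysregulated)
        for g, d in zip(bg_genes, bg_dirs):
            shift = background_effect if d == "up" else -background_effect
            for stage in ("MGUS", "SMM", "MM"):
                stage_effect[stage][gene_pos[g]] += shift
        truth.study_dysregulation["background"] = {
            "genes": list(bg_genes),
            "direction": [str(d) for d in bg_dirs],
            "fraction": None,
            "stage_multipliers": {"MGUS": 1.0, "SMM": 1.0, "MM": 1.0},
        }

    studies = []
    for si in range(1, n_studies + 1):
        shift = (rng.normal(0.0, platform_shift, size=n_genes)
                 if platform_shift > 0 else np.zeros(n_genes))
        sample_ids, stages = [], []
        for stage, n in groups_per_study.items():
            for i in range(1, n + 1):
                sample_ids.append(f"S{si}_{stage}_{i}")
                stages.append(stage)
        means = np.empty((n_genes, len(sample_ids)))
        for sj, stage in enumerate(stages):
            eff = stage_effect.get(stage, np.zeros(n_genes))
            means[:, sj] = baseline + shift + eff
        values = means + rng.normal(0.0, noise_sd, size=means.shape)
        matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_symbol"),
                              columns=sample_ids)
        design = pd.DataFrame({
            "sample_id": sample_ids,
            "group": stages,
            "study": f"study{si}",
            "stage": stages,
        }).set_index("sample_id", drop=False)
        studies.append(Study(f"study{si}", matrix, design))
    return studies, truth


# ---------------------------------------------------------------------------
# knockout tables
# ---------------------------------------------------------------------------

def generate_ko_table(signature: SignatureSet, regulator_mode: str,
                      concordant_fraction: float, seed: int = 0
                      ) -> tuple[pd.DataFrame, SynthTruth]:
    """Knockout response table with a controlled concordant fraction.

    round(concordant_fraction * |signature|) genes respond in the direction
    expected for the stated regulator mode; the rest respond oppositely.
    ``mixed`` splits the concordant genes evenly between activator- and
    repressor-style pairings (recorded in truth).
    """
    if regulator_mode not in ("activator", "repressor", "mixed"):
        raise ValueError(f"unknown regulator mode {regulator_mode!r}")
    if not 0 <= concordant_fraction <= 1:
        raise ValueError("concordant_fraction must be in [0, 1]")
    if len(signature) == 0:
        raise ValueError("empty signature")
    rng = np.random.default_rng(seed)
    genes = sorted(signature.genes)
    n_conc = int(round(concordant_fraction * len(genes)))
    concordant = sorted(rng.choice(genes, size=n_conc, replace=False))
    conc_set = set(concordant)

    act_dir = {"up": "down", "down": "up"}[signature.direction]
    rep_dir = {"down": "up", "up": "down"}[act_dir]
    rows = []
    for i, gene in enumerate(genes):
        if regulator_mode == "activator":
            expected = act_dir
        elif regulator_mode == "repressor":
            expected = rep_dir
        else:
            expected = act_dir if i % 2 == 0 else rep_dir
        direction = expected if gene in conc_set else \
            {"up": "down", "down": "up"}[expected]
        rows.append((gene, direction))
    table = pd.DataFrame(rows, columns=["gene", "direction"])
    truth = SynthTruth(ko={
        "concordant": concordant,
        "discordant": sorted(set(genes) - conc_set),
        "mode": regulator_mode,
    })
    return table, truth
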