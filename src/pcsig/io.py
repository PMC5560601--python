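"""Readers and writers for the plain-text formats used across the pipeline.

Expression matrices, probeset annotations and sample designs travel as TSV;
gene sets as GMT; promoters as FASTA; position weight matrices in JASPAR
count format; configuration as YAML and ground-truth records as JSON.
All round-trips are lossless for the fields the pipeline consumes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ANNOTATION_COLUMNS = ["probeset_id", "gene_symbol", "is_ig"]
DESIGN_COLUMNS = ["sample_id", "group", "study", "stage"]


class FormatError(ValueError):
    """Raised when an input file violates its expected layout."""


# ---------------------------------------------------------------------------
# expression / annotation / design TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a probeset-by-sample matrix: first column row ids, header sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate row ids in {path}: {dup[:5]}")
    if df.columns.has_duplicates:
        raise FormatError(f"duplicate sample ids in {path}")
    return df.astype(float)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probeset_id")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"probeset_id": str, "gene_symbol": str})
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise FormatError(f"annotation {path} lacks columns {sorted(missing)}")
    ann = ann.set_index("probeset_id", drop=False)
    if ann.index.has_duplicates:
        raise FormatError(f"duplicate probeset ids in annotation {path}")
    ann["is_ig"] = ann["is_ig"].astype(bool)
    ann["gene_symbol"] = ann["gene_symbol"].where(ann["gene_symbol"].notna(), None)
    bad = ann[ann["is_ig"] & ann["gene_symbol"].isna()]
    if len(bad):
        raise FormatError("immunoglobulin probesets must carry a gene symbol: "
                          + ", ".join(bad.index[:5]))
    return ann


def write_annotation_tsv(ann: pd.DataFrame, path: str | Path) -> None:
    ann.loc[:, ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in design.columns or "group" not in design.columns:
        raise FormatError(f"design {path} needs sample_id and group columns")
    for col in DESIGN_COLUMNS:
        if col not in design.columns:
            design[col] = ""
    return design.set_index("sample_id", drop=False)


def write_design_tsv(design: pd.DataFrame, path: str | Path) -> None:
    design.loc[:, DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, "
                                  "description and at least one gene")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set '{name}'")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name '{name}'")
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            genes = sorted(genes)
            if not genes:
                raise FormatError(f"refusing to write empty gene set '{name}'")
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# FASTA promoters
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # Biopython wraps at 60; still plain text


# ---------------------------------------------------------------------------
# JASPAR-style PWM count files
# ---------------------------------------------------------------------------

def read_jaspar_pwms(path: str | Path) -> dict[str, "pd.DataFrame"]:
    """Parse JASPAR count format:

        >MOTIF_ID name
        A [ 3 10  0 ... ]
        C [ ... ]
        G [ ... ]
        T [ ... ]

    Returns motif id -> 4xL count DataFrame indexed by A,C,G,T.
    """
    pwms: dict[str, pd.DataFrame] = {}
    current: str | None = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    pwms[current] = _finish_pwm(current, rows, path)
                current = line[1:].split()[0]
                rows = {}
            else:
                base, _, values = line.partition("[")
                base = base.strip().upper()
                if base not in "ACGT" or len(base) != 1:
                    raise FormatError(f"{path}:{lineno}: expected base row, got '{line}'")
                rows[base] = [float(v) for v in values.rstrip("]").split()]
    if current is not None:
        pwms[current] = _finish_pwm(current, rows, path)
    if not pwms:
        raise FormatError(f"no motifs found in {path}")
    return pwms


def _finish_pwm(name: str, rows: dict[str, list[float]], path) -> pd.DataFrame:
    if set(rows) != set("ACGT"):
        raise FormatError(f"{path}: motif {name} missing base rows {set('ACGT') - set(rows)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: motif {name} has ragged rows")
    return pd.DataFrame([rows[b] for b in "ACGT"], index=list("ACGT"))


def write_jaspar_pwms(pwms: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, counts in pwms.items():
            fh.write(f">{name} {name}\n")
            for base in "ACGT":
                vals = " ".join(f"{v:g}" for v in counts.loc[base])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# YAML / JSON
# ---------------------------------------------------------------------------

def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_yaml(data: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=True)


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(data: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")
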