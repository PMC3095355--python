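"""Readers and writers for the pipeline's plain-text formats.

All stage outputs are TSV or JSON so any stage can be resumed from its
files or swapped for an external tool's output (e.g. user-supplied codeml
Ks values feed the mixture stage directly).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pairs import CodingGene

__all__ = [
    "read_cds_fasta",
    "write_fasta",
    "write_gene_fastas",
    "read_counts",
    "write_counts",
    "read_tissue_map",
    "write_tsv",
    "read_ks_table",
    "write_json",
]


def read_cds_fasta(path, counts: pd.DataFrame | None = None) -> list[CodingGene]:
    """Load coding genes from a CDS FASTA (proteins derived by translation)."""
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = CodingGene(id=rec.id, cds=str(rec.seq))
        if counts is not None and rec.id in counts.index:
            gene.est_counts = counts.loc[rec.id].to_numpy()
        genes.append(gene)
    return genes


def write_fasta(path, records: dict) -> None:
    """Write an id -> sequence mapping as FASTA."""
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_gene_fastas(genes, cds_path, protein_path) -> None:
    write_fasta(cds_path, {g.id: g.cds for g in genes})
    write_fasta(protein_path, {g.id: g.protein for g in genes})


def read_counts(path) -> pd.DataFrame:
    """Genes x libraries count matrix (TSV, header row = library ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(path, counts: pd.DataFrame, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        counts.to_csv(fh, sep="\t")


def read_tissue_map(path) -> dict:
    """Two-column TSV: library id -> tissue class."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["library", "tissue"])
    return dict(zip(frame["library"], frame["tissue"]))


def write_tsv(path, frame: pd.DataFrame, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_ks_table(path) -> dict:
    """Pair -> Ks from a Ks TSV, or row -> Ks for a one-column age list.

    Recognizes a Ks-like value column (``ks``, ``true_ks`` or ``age_ks``);
    keys are (gene_a, gene_b) pairs when those columns exist, else row
    numbers.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    value_col = next(
        (c for c in ("ks", "true_ks", "age_ks") if c in frame.columns),
        frame.columns[0],
    )
    if {"gene_a", "gene_b"} <= set(frame.columns):
        return {
            tuple(sorted((a, b))): float(v)
            for a, b, v in zip(frame["gene_a"], frame["gene_b"],
                               frame[value_col])
        }
    return {i: float(v) for i, v in enumerate(frame[value_col])}


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
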