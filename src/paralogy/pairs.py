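"""Paralog identification from protein similarity.

Candidate paralog pairs come either from an external all-against-all search
(BLAST-tabular hits) or from the built-in Smith-Waterman aligner, and are
filtered with the study's selection rules: a pair is paralogous when its best
HSP aligns >= 100 amino acids at > 30% identity, and eligible for Ks
estimation when identity is at least 60%.  Genes with no surviving pair are
single-copy (singlets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._codons import translate_cds

__all__ = [
    "CodingGene",
    "ParalogPair",
    "RawHit",
    "HitParseError",
    "load_hits",
    "align_all_vs_all",
    "call_paralogs",
    "dedupe_zero_ks",
    "apply_length_filter",
]

MIN_CDS_NT = 300


class HitParseError(ValueError):
    """A malformed row in a tabular hit file."""


@dataclass
class CodingGene:
    """A transcript-derived protein-coding gene."""

    id: str
    cds: str
    protein: str = ""
    est_counts: np.ndarray | None = None

    def __post_init__(self):
        self.cds = self.cds.upper().replace("U", "T")
        if len(self.cds) % 3:
            raise ValueError(f"{self.id}: CDS length not a multiple of 3")
        translated = translate_cds(self.cds).rstrip("*")
        if not self.protein:
            self.protein = translated
        else:
            self.protein = self.protein.upper().rstrip("*")
            for aa_t, aa_p in zip(translated, self.protein):
                if "X" in (aa_t, aa_p):
                    continue
                if aa_t != aa_p:
                    raise ValueError(
                        f"{self.id}: CDS does not translate to supplied protein"
                    )


class RawHit(NamedTuple):
    """One row of a 12-column BLAST-tabular-compatible hit table."""

    query: str
    subject: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class ParalogPair:
    """An unordered paralogous gene pair with its best-HSP statistics."""

    gene_a: str
    gene_b: str
    aligned_length: int
    percent_identity: float
    evalue: float
    ks_eligible: bool = False

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("a paralog pair needs two distinct genes")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def apply_length_filter(genes: Iterable[CodingGene],
                        min_cds_nt: int = MIN_CDS_NT) -> list[CodingGene]:
    """Discard transcripts whose open reading frame is shorter than 300 nt."""
    return [g for g in genes if len(g.cds) >= min_cds_nt]


# ---------------------------------------------------------------------------
# hit loading / generation
# ---------------------------------------------------------------------------

def load_hits(path) -> list[RawHit]:
    """Parse a 12-column BLAST-tabular file.

    Self-hits are dropped; reciprocal duplicates (A->B and B->A, or repeated
    HSPs for one pair) are collapsed keeping the lowest e-value, with the
    higher bitscore breaking ties.
    """
    best: dict[tuple[str, str], RawHit] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitParseError(
                    f"line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = RawHit(
                    fields[0], fields[1], float(fields[2]), int(fields[3]),
                    int(fields[4]), int(fields[5]), int(fields[6]),
                    int(fields[7]), int(fields[8]), int(fields[9]),
                    float(fields[10]), float(fields[11]),
                )
            except ValueError as exc:
                raise HitParseError(f"line {lineno}: {exc}") from None
            if hit.query == hit.subject:
                continue
            key = tuple(sorted((hit.query, hit.subject)))
            prev = best.get(key)
            if (prev is None or hit.evalue < prev.evalue
                    or (hit.evalue == prev.evalue
                        and hit.bitscore > prev.bitscore)):
                best[key] = hit
    return [best[k] for k in sorted(best)]


# gapped Karlin-Altschul parameters for BLOSUM62 (BLAST defaults), used to
# turn Smith-Waterman scores into a BLAST-like e-value surrogate
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _local_aligner(matrix: str, open_gap: float, extend_gap: float):
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = "local"
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def align_all_vs_all(genes: Iterable[CodingGene], matrix: str = "BLOSUM62",
                     open_gap: float = -11.0, extend_gap: float = -1.0,
                     max_evalue: float = 1e-10) -> list[RawHit]:
    """Built-in all-against-all local protein alignment.

    Smith-Waterman alignments are converted to the same record shape as
    tabular BLAST hits; the e-value field is a Karlin-Altschul surrogate
    derived from the raw score and the search-space size, so the downstream
    filters can be applied unchanged on small or synthetic datasets.
    """
    genes = list(genes)
    aligner = _local_aligner(matrix, open_gap, extend_gap)
    total_residues = sum(len(g.protein) for g in genes)
    hits: list[RawHit] = []
    for i, ga in enumerate(genes):
        pa = ga.protein.replace("*", "X")
        for gb in genes[i + 1 :]:
            pb = gb.protein.replace("*", "X")
            if not pa or not pb:
                continue
            score = aligner.score(pa, pb)
            evalue = _KA_K * len(pa) * total_residues * math.exp(
                -_KA_LAMBDA * score
            )
            if evalue > max_evalue:
                continue
            aln = aligner.align(pa, pb)[0]
            stats = _alignment_stats(aln)
            if stats is None:
                continue
            length, identical, qstart, qend, sstart, send = stats
            pct = 100.0 * identical / length if length else 0.0
            bitscore = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0)
            hits.append(RawHit(
                ga.id, gb.id, round(pct, 2), length, length - identical, 0,
                qstart + 1, qend, sstart + 1, send, evalue, round(bitscore, 1),
            ))
    return hits


def _alignment_stats(aln):
    """(aligned columns excl. gaps, identities, q/s spans) of one alignment."""
    blocks = aln.aligned
    if len(blocks[0]) == 0:
        return None
    qa, qb = aln.target, aln.query
    length = identical = 0
    for (qs, qe), (ss, se) in zip(*blocks):
        length += qe - qs
        identical += sum(
            1 for a, b in zip(qa[qs:qe], qb[ss:se]) if a == b
        )
    qstart = blocks[0][0][0]
    qend = blocks[0][-1][1]
    sstart = blocks[1][0][0]
    send = blocks[1][-1][1]
    return length, identical, qstart, qend, sstart, send


# ---------------------------------------------------------------------------
# paralog calling
# ---------------------------------------------------------------------------

def call_paralogs(hits: Iterable[RawHit], all_gene_ids: Iterable[str] | None = None,
                  min_aln_aa: int = 100, min_pct_id: float = 30.0,
                  ks_pct_id: float = 60.0):
    """Apply the paralogy filters to a hit list.

    A pair is accepted when its best HSP aligns at least ``min_aln_aa`` amino
    acids with identity strictly greater than ``min_pct_id``; it is eligible
    for Ks estimation when identity is at least ``ks_pct_id``.  Returns
    ``(pairs, singlets)`` where singlets are genes (of ``all_gene_ids`` when
    given, else genes seen in hits) with no surviving pair.
    """
    best: dict[tuple[str, str], RawHit] = {}
    seen_genes: set[str] = set()
    for hit in hits:
        if hit.query == hit.subject:
            continue
        seen_genes.update((hit.query, hit.subject))
        key = tuple(sorted((hit.query, hit.subject)))
        prev = best.get(key)
        if (prev is None or hit.evalue < prev.evalue
                or (hit.evalue == prev.evalue and hit.bitscore > prev.bitscore)):
            best[key] = hit

    pairs: list[ParalogPair] = []
    for (a, b), hit in sorted(best.items()):
        if hit.aln_length < min_aln_aa or hit.pct_identity <= min_pct_id:
            continue
        pairs.append(ParalogPair(
            a, b, hit.aln_length, hit.pct_identity, hit.evalue,
            ks_eligible=hit.pct_identity >= ks_pct_id,
        ))
    universe = set(all_gene_ids) if all_gene_ids is not None else seen_genes
    in_pairs = {g for p in pairs for g in p.key}
    singlets = sorted(universe - in_pairs)
    return pairs, singlets


def dedupe_zero_ks(zero_ks_pairs: Iterable[tuple[str, str]]) -> set[str]:
    """Genes to discard among pairs with no synonymous substitutions.

    Pairs with Ks = 0 are likely multiple entries of the same gene (e.g.
    splice variants): for each connected component of Ks = 0 edges exactly
    one representative — the lexicographically smallest id — is retained and
    the rest are returned for removal.  All pairs touching a removed gene
    should be dropped by the caller.
    """
    graph = nx.Graph()
    graph.add_edges_from(zero_ks_pairs)
    drop: set[str] = set()
    for component in nx.connected_components(graph):
        keep = min(component)
        drop.update(component - {keep})
    return drop
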