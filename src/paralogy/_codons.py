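"""Genetic-code tables and precomputed codon structures.

Everything here is derived once, at import time, from the standard (universal)
genetic code as distributed with Biopython, and shared by the GY94 likelihood
machinery, the NG86 counting oracle and the sequence simulators.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

STOP_CODONS = frozenset(_TABLE.stop_codons)
#: the 61 sense codons of the universal code, in a fixed canonical order
SENSE_CODONS = tuple(
    "".join(c)
    for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)
N_SENSE = len(SENSE_CODONS)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop."""
    if codon in STOP_CODONS:
        return "*"
    return AMINO_ACID[codon]


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def _build_single_diff_arrays():
    """Index arrays over ordered sense-codon pairs differing at one position."""
    src, dst, pos, ts, syn = [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            src.append(i)
            dst.append(j)
            pos.append(p)
            ts.append(is_transition(ci[p], cj[p]))
            syn.append(AMINO_ACID[ci] == AMINO_ACID[cj])
    return (
        np.asarray(src, dtype=np.intp),
        np.asarray(dst, dtype=np.intp),
        np.asarray(pos, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
    )


# ordered single-nucleotide-difference pairs (i -> j) among sense codons
DIFF_SRC, DIFF_DST, DIFF_POS, DIFF_IS_TS, DIFF_IS_SYN = _build_single_diff_arrays()

#: codon index -> nucleotide index (0..3 in TCAG order) at each position
CODON_NUC = np.array(
    [[NUCLEOTIDES.index(c[p]) for p in range(3)] for c in SENSE_CODONS],
    dtype=np.intp,
)


def codons_of(cds: str):
    """Split a CDS into codons; raises if length is not a multiple of 3."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def translate_cds(cds: str) -> str:
    """Translate a CDS; ambiguous codons become 'X', stops become '*'."""
    out = []
    for codon in codons_of(cds.upper()):
        if any(b not in "ACGT" for b in codon):
            out.append("X")
        else:
            out.append(translate_codon(codon))
    return "".join(out)


def f3x4_codon_frequencies(position_nuc_freqs: np.ndarray) -> np.ndarray:
    """F3x4 equilibrium frequencies over the 61 sense codons.

    ``position_nuc_freqs`` is a 3x4 array of nucleotide frequencies (TCAG
    order), one row per codon position.  Stop codons are excluded and the
    result renormalized to sum to one.
    """
    f = np.asarray(position_nuc_freqs, dtype=float)
    if f.shape != (3, 4):
        raise ValueError("position_nuc_freqs must be 3x4 (positions x TCAG)")
    if np.any(f < 0):
        raise ValueError("nucleotide frequencies must be non-negative")
    pi = f[0, CODON_NUC[:, 0]] * f[1, CODON_NUC[:, 1]] * f[2, CODON_NUC[:, 2]]
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate F3x4 frequencies: no sense codon has mass")
    return pi / total


def empirical_position_freqs(*cds_seqs: str, pseudocount: float = 0.0) -> np.ndarray:
    """Position-specific nucleotide frequencies pooled over CDS sequences."""
    counts = np.full((3, 4), pseudocount, dtype=float)
    for cds in cds_seqs:
        s = cds.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            for p in range(3):
                b = s[i + p]
                if b in "TCAG":
                    counts[p, NUCLEOTIDES.index(b)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("cannot estimate position frequencies from empty input")
    return counts / totals


UNIFORM_POSITION_FREQS = np.full((3, 4), 0.25)
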