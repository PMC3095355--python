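"""Digital expression divergence between paralogs from EST counts.

Expression of each gene is its EST representation across non-normalized
libraries.  Divergence between two paralogs is one minus the similarity of
their per-library relative-frequency profiles, measured by Pearson's r; the
significance threshold r* is the empirical 95th percentile of r over
randomly drawn non-paralogous gene pairs.  Shifts toward tissue-specific
expression are tested per tissue class with a 2x2 Fisher exact test
(gene x class-vs-rest), Holm-corrected across classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "expression_frequencies",
    "filter_min_ests",
    "pearson_divergence",
    "null_threshold",
    "divergent_fractions",
    "tissue_specificity",
    "TissueTest",
]

MIN_ESTS = 3
FREQ_SCALE = 10_000.0


def filter_min_ests(counts: pd.DataFrame, min_ests: int = MIN_ESTS) -> pd.DataFrame:
    """Keep genes represented by at least ``min_ests`` ESTs overall."""
    return counts.loc[counts.sum(axis=1) >= min_ests]


def expression_frequencies(counts: pd.DataFrame,
                           scale: float = FREQ_SCALE) -> pd.DataFrame:
    """Counts per ``scale`` library ESTs (per-library relative frequencies).

    Library sizes are the column sums of the full counts matrix; normalize
    before row-filtering so frequencies refer to true library depth.
    """
    totals = counts.sum(axis=0).astype(float)
    totals[totals == 0] = np.nan
    return counts / totals * scale


def pearson_divergence(pair, frequencies: pd.DataFrame) -> float:
    """Pearson r of two genes' expression profiles; NaN when undefined.

    A constant profile (no variance across libraries) leaves r undefined
    and the pair is flagged by the NaN return for symmetric exclusion.
    """
    a, b = pair
    va = frequencies.loc[a].to_numpy(dtype=float)
    vb = frequencies.loc[b].to_numpy(dtype=float)
    if np.std(va) == 0 or np.std(vb) == 0:
        return math.nan
    return float(np.corrcoef(va, vb)[0, 1])


def null_threshold(frequencies: pd.DataFrame, exclude_pairs=(),
                   n_random_pairs: int = 10_000, alpha: float = 0.05,
                   seed: int | None = None) -> float:
    """Co-regulation threshold r*: (1-alpha) quantile of the random-pair null.

    Unordered gene pairs are sampled uniformly, excluding known paralog
    pairs so the null represents unrelated genes; undefined correlations
    are excluded, mirroring their exclusion from the observed distribution.
    ``alpha=0`` returns the maximum of the null sample.
    """
    rng = np.random.default_rng(seed)
    genes = list(frequencies.index)
    if len(genes) < 2:
        raise ValueError("need at least two genes for a null distribution")
    excluded = {tuple(sorted(p)) for p in exclude_pairs}
    mat = frequencies.to_numpy(dtype=float)
    r_null = []
    attempts = 0
    while len(r_null) < n_random_pairs and attempts < 50 * n_random_pairs:
        attempts += 1
        i, j = rng.choice(len(genes), size=2, replace=False)
        if tuple(sorted((genes[i], genes[j]))) in excluded:
            continue
        va, vb = mat[i], mat[j]
        if va.std() == 0 or vb.std() == 0:
            continue
        r_null.append(np.corrcoef(va, vb)[0, 1])
    if not r_null:
        raise ValueError("could not sample any valid null pair")
    r_null = np.asarray(r_null)
    if alpha == 0:
        return float(r_null.max())
    return float(np.quantile(r_null, 1.0 - alpha))


def divergent_fractions(pair_r: dict, pair_ks: dict, r_star: float,
                        ks_cutoff: float = 0.4):
    """Fractions of pairs with divergent expression (r below r*).

    Returns a dict with the overall fraction, the fractions for young
    (Ks <= cutoff) and old (Ks > cutoff) strata (NaN when a stratum is
    empty), and the correlation between r and Ks over pairs with both.
    """
    rs = {p: r for p, r in pair_r.items() if not math.isnan(r)}

    def fraction(pairs):
        pairs = list(pairs)
        if not pairs:
            return math.nan
        return sum(1 for p in pairs if rs[p] < r_star) / len(pairs)

    overall = fraction(rs)
    young = fraction(p for p in rs if p in pair_ks and pair_ks[p] <= ks_cutoff)
    old = fraction(p for p in rs if p in pair_ks and pair_ks[p] > ks_cutoff)
    both = [p for p in rs if p in pair_ks]
    if len(both) >= 3:
        r_vs_ks = float(np.corrcoef(
            [rs[p] for p in both], [pair_ks[p] for p in both]
        )[0, 1])
    else:
        r_vs_ks = math.nan
    return {"overall": overall, "young": young, "old": old,
            "r_vs_ks": r_vs_ks, "n_pairs": len(rs)}


@dataclass(frozen=True)
class TissueTest:
    """One tissue class's 2x2 Fisher outcome for a paralog pair."""

    tissue: str
    table: tuple
    p_value: float
    p_holm: float
    direction: str  # which gene is relatively enriched in the class
    significant: bool


def tissue_specificity(pair, counts: pd.DataFrame, tissue_map: dict,
                       alpha: float = 0.05, holm: bool = True,
                       min_total: int = 5):
    """Per-tissue-class Fisher tests for a shift to tissue-specific expression.

    Library counts are aggregated into tissue classes; for each class the
    2x2 table has the two genes as rows and (class, all other classes) as
    columns.  P-values are Holm-corrected across the classes (disable with
    ``holm=False`` for the uncorrected any-class rule); the pair is
    tissue-shifted when any class stays significant.  Pairs where both
    genes have fewer than ``min_total`` ESTs are skipped (returns None).
    """
    a, b = pair
    classes = sorted(set(tissue_map.values()))
    lib_class = pd.Series({lib: tissue_map[lib] for lib in counts.columns})
    ca = counts.loc[a].groupby(lib_class).sum()
    cb = counts.loc[b].groupby(lib_class).sum()
    if ca.sum() < min_total and cb.sum() < min_total:
        return None

    raw = []
    for tissue in classes:
        a_in = int(ca.get(tissue, 0))
        b_in = int(cb.get(tissue, 0))
        a_out = int(ca.sum() - a_in)
        b_out = int(cb.sum() - b_in)
        _, p = stats.fisher_exact([[a_in, a_out], [b_in, b_out]],
                                  alternative="two-sided")
        direction = a if a_in * b_out > a_out * b_in else b
        raw.append((tissue, (a_in, a_out, b_in, b_out), float(p), direction))

    order = np.argsort([p for _, _, p, _ in raw])
    m = len(raw)
    p_holm = [1.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        adj = (m - rank) * raw[idx][2]
        running = max(running, adj)
        p_holm[idx] = min(1.0, running)

    results = []
    for k, (tissue, table, p, direction) in enumerate(raw):
        p_eff = p_holm[k] if holm else p
        results.append(TissueTest(
            tissue=tissue, table=table, p_value=p, p_holm=p_holm[k],
            direction=direction, significant=bool(p_eff < alpha),
        ))
    return results
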