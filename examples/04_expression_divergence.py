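"""Measure expression divergence between paralogs from EST counts.

Simulates libraries with a planted fraction of co-regulated pairs, then
recovers the co-regulation threshold r* from random non-paralog pairs and
classifies each paralog pair by its Pearson correlation.
"""

import math

from paralogy import simulate_expression
from paralogy.expression import (expression_frequencies, filter_min_ests,
                                 null_threshold, pearson_divergence)

genes = [f"g{i}" for i in range(400)]
pairs = [(genes[2 * i], genes[2 * i + 1]) for i in range(200)]
counts, truth = simulate_expression(
    genes, n_libraries=14, library_sizes=20_000,
    coregulated_fraction=0.2, seed=3, pairs=pairs,
    tissue_shift_fraction=0.25)

kept = filter_min_ests(counts)           # at least 3 ESTs per gene
freqs = expression_frequencies(counts).loc[kept.index]
usable = [p for p in pairs if p[0] in freqs.index and p[1] in freqs.index]

r_star = null_threshold(freqs, exclude_pairs=usable,
                        n_random_pairs=10_000, alpha=0.05, seed=3)
rs = {p: pearson_divergence(p, freqs) for p in usable}
rs = {p: r for p, r in rs.items() if not math.isnan(r)}
divergent = sum(1 for r in rs.values() if r < r_star) / len(rs)
planted = sum(1 for p in rs if truth[p] != "coregulated") / len(rs)

print(f"{len(rs)} paralog pairs profiled over 14 libraries")
print(f"co-regulation threshold r* = {r_star:.2f} "
      f"(95th percentile of {10_000} random pairs)")
print(f"divergent pairs (r < r*): {100 * divergent:.0f}% "
      f"(planted: {100 * planted:.0f}%)")
print("Pairs above r* share a tissue profile (co-regulated); pairs below "
      "have diverged in expression, the early signature of "
      "subfunctionalization.")
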