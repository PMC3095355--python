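"""Gene families: clustering, duplication-node dating, amplification,
family-size power law.

Families are connected components of the paralog graph (single-linkage
clustering).  Within a family, redundant pairwise Ks values describing one
duplication event are collapsed by average-linkage (UPGMA) agglomeration on
the Ks matrix: each of the n-1 merges emits one duplication node whose age
is the mean of the observed cross-cluster pairwise Ks values.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneFamily",
    "DuplicationNode",
    "AmplificationRecord",
    "PowerLawFit",
    "cluster_families",
    "date_duplications",
    "young_subset",
    "amplification_ratio",
    "fit_powerlaw",
    "compare_sizes",
    "load_amplified_family_table",
]


@dataclass(frozen=True)
class DuplicationNode:
    """One duplication event: the merge of two within-family clusters."""

    age_ks: float
    left: frozenset
    right: frozenset

    @property
    def members(self) -> frozenset:
        return self.left | self.right


@dataclass
class GeneFamily:
    """A single-linkage cluster of paralogous genes (size >= 2)."""

    family_id: str
    members: frozenset
    nodes: list | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class AmplificationRecord:
    """Post-duplication amplification of one family.

    ``ratio`` is the current copy number over the inferred copy number
    before the young duplications: n_total / (n_total - d_young).
    """

    family_id: str
    n_total: int
    d_young: int

    def __post_init__(self):
        if self.d_young >= self.n_total:
            raise ValueError(
                "young duplication count must be below the copy number"
            )
        if self.d_young < 0:
            raise ValueError("young duplication count cannot be negative")

    @property
    def n_ancestral(self) -> int:
        return self.n_total - self.d_young

    @property
    def ratio(self) -> float:
        return round(self.n_total / self.n_ancestral, 2)


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log least-squares fit f(x) = a * x^-b to family-size frequencies."""

    a: float
    b: float
    r_squared: float

    def halving_factor(self) -> float:
        """Factor by which family count drops when size doubles: 2^b."""
        return 2.0 ** self.b


# ---------------------------------------------------------------------------
# clustering and dating
# ---------------------------------------------------------------------------

def cluster_families(pairs) -> list[GeneFamily]:
    """Single-linkage families = connected components of the paralog graph.

    Accepts ParalogPair objects or plain (gene_a, gene_b) tuples; singleton
    genes are by construction excluded.  Family ids are assigned in order of
    the lexicographically smallest member for determinism.
    """
    graph = nx.Graph()
    for p in pairs:
        a, b = p.key if hasattr(p, "key") else tuple(p)
        graph.add_edge(a, b)
    components = sorted(nx.connected_components(graph), key=min)
    return [
        GeneFamily(family_id=f"FAM{i + 1:05d}", members=frozenset(c))
        for i, c in enumerate(components)
    ]


def date_duplications(family: GeneFamily, ks_values: dict) -> list[DuplicationNode]:
    """Date a family's n-1 duplication events by UPGMA on pairwise Ks.

    ``ks_values`` maps unordered pairs (tuples) to Ks.  Pairs without a Ks
    (identity below the estimation threshold, or Ks beyond the saturation
    cutoff) are imputed with the family's maximum observed Ks so the
    dendrogram stays connected, but only observed values enter a node's age
    mean; a merge whose cross-cluster pairs are all missing falls back to
    the imputed value.
    """
    members = sorted(family.members)
    n = len(members)
    if n < 2:
        raise ValueError("a family needs at least 2 members to date")

    def lookup(a, b):
        key = (a, b) if a <= b else (b, a)
        v = ks_values.get(key)
        if v is not None and np.isfinite(v):
            return float(v)
        return None

    observed = [v for a, b in itertools.combinations(members, 2)
                if (v := lookup(a, b)) is not None]
    impute = max(observed) if observed else 1.0

    clusters: list[frozenset] = [frozenset([m]) for m in members]
    nodes: list[DuplicationNode] = []

    def cross_stats(ca, cb):
        obs, total, count = [], 0.0, 0
        for a in ca:
            for b in cb:
                v = lookup(a, b)
                if v is None:
                    total += impute
                else:
                    obs.append(v)
                    total += v
                count += 1
        linkage_dist = total / count  # imputed values steer the topology
        age = float(np.mean(obs)) if obs else impute
        return linkage_dist, age

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist, age = cross_stats(clusters[i], clusters[j])
                key = (dist, min(clusters[i]), min(clusters[j]))
                if best is None or key < best[0]:
                    best = (key, i, j, age)
        (_, i, j, age) = best
        cb = clusters.pop(j)
        ca = clusters.pop(i)
        nodes.append(DuplicationNode(age_ks=age, left=ca, right=cb))
        clusters.append(ca | cb)
    return nodes


def young_subset(pairs_with_ks: dict, cutoff: float = 0.4):
    """Recluster the young paralogs (Ks strictly below ``cutoff``).

    ``pairs_with_ks`` maps unordered gene pairs to Ks.  Returns the list of
    young GeneFamily clusters built from pairs with Ks < cutoff only,
    following the same single-linkage approach as the whole dataset.
    """
    young_pairs = [pair for pair, ks in pairs_with_ks.items() if ks < cutoff]
    return cluster_families(young_pairs)


def count_young_nodes(nodes, cutoff: float = 0.4) -> int:
    """Number of duplication nodes dated younger than the cutoff."""
    return sum(1 for node in nodes if node.age_ks < cutoff)


def amplification_ratio(n_total: int, d_young: int,
                        family_id: str = "") -> AmplificationRecord:
    """Amplification record from a family's copy number and young-node count."""
    return AmplificationRecord(family_id=family_id, n_total=n_total,
                               d_young=d_young)


# ---------------------------------------------------------------------------
# size distribution
# ---------------------------------------------------------------------------

def fit_powerlaw(sizes, method: str = "ols") -> PowerLawFit:
    """Fit the family-size frequency distribution to f(x) = a * x^-b.

    ``sizes`` is either the raw size list or a precomputed histogram (dict
    or Series mapping size class to frequency).  The default mirrors the
    classic presentation: ordinary least squares of log(frequency) on
    log(size) over the occupied size classes, reporting a = exp(intercept),
    b = -slope and the regression R^2.  ``method='mle'`` instead fits the
    discrete power-law exponent by maximum likelihood on the raw sizes
    (R^2 then refers to the OLS diagnostic fit).
    """
    if isinstance(sizes, dict):
        sizes = pd.Series(sizes)
    if isinstance(sizes, pd.Series):
        classes = sizes.index.to_numpy(dtype=float)
        freqs = sizes.to_numpy(dtype=float)
        order = np.argsort(classes)
        classes, freqs = classes[order], freqs[order]
        keep = freqs > 0
        classes, freqs = classes[keep], freqs[keep]
        raw = None
    else:
        raw = np.asarray(sizes, dtype=int)
        if raw.size == 0:
            raise ValueError("no family sizes given")
        classes, freqs = np.unique(raw, return_counts=True)
    # regress over the contiguous run of occupied size classes: isolated
    # frequency-1 classes in the sparse tail carry no frequency information
    # and only flatten the log-log slope
    gaps = np.where(np.diff(classes) > 1)[0]
    if gaps.size:
        classes, freqs = classes[: gaps[0] + 1], freqs[: gaps[0] + 1]
    if len(classes) < 2:
        raise ValueError("power-law fit needs at least two size classes")
    x = np.log(classes.astype(float))
    y = np.log(freqs.astype(float))
    ols = stats.linregress(x, y)
    a = float(np.exp(ols.intercept))
    b = -float(ols.slope)
    r2 = float(ols.rvalue**2)
    if method == "ols":
        return PowerLawFit(a=a, b=b, r_squared=r2)
    if method == "mle":
        if raw is None:
            raise ValueError("MLE fitting needs raw sizes, not a histogram")
        support = np.arange(raw.min(), raw.max() + 1, dtype=float)

        def nll(expo):
            logpmf = -expo * np.log(support)
            logz = np.log(np.exp(logpmf).sum())
            return -(np.sum(-expo * np.log(raw)) - raw.size * logz)

        from scipy.optimize import minimize_scalar

        res = minimize_scalar(nll, bounds=(1.0001, 10.0), method="bounded")
        return PowerLawFit(a=a, b=float(res.x), r_squared=r2)
    raise ValueError(f"unknown method {method!r}")


def compare_sizes(sizes_a: pd.DataFrame, sizes_b: pd.DataFrame,
                  on: str = "family", value_a: str = "size_a",
                  value_b: str = "size_b"):
    """Inner-join two family-size tables and correlate copy numbers.

    Returns ``(joined, r, larger_than_reference)``: the joined frame, the
    Pearson correlation of the two size columns, and the list of families
    whose first-table size strictly exceeds the reference.
    """
    joined = sizes_a.merge(sizes_b, on=on, how="inner",
                           suffixes=("_a", "_b"))
    cols = [c for c in joined.columns if c != on]
    va = value_a if value_a in joined.columns else cols[0]
    vb = value_b if value_b in joined.columns else cols[1]
    if len(joined) < 2:
        raise ValueError("need at least two shared families to correlate")
    r = float(np.corrcoef(joined[va], joined[vb])[0, 1])
    larger = joined.loc[joined[va] > joined[vb], on].tolist()
    return joined, r, larger


def load_amplified_family_table() -> pd.DataFrame:
    """The bundled amplified-family copy-number table (reference study).

    Columns: family, apple, arabidopsis, poplar, n_young_ks (copy number
    with Ks < 0.4) and d_young (duplication events among young paralogs).
    """
    ref = importlib.resources.files("paralogy.data") / "amplified_families.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
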