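"""Gene Ontology annotation and Fisher-exact enrichment.

Annotations are consumed (two-column gene/term TSV or GAF 2.x), closed over
their ancestors in the ontology DAG ("a gene annotated to a term is
annotated to all parental terms"), lifted to gene families with the
30%-of-members rule, and compared between gene sets with a two-sided Fisher
exact test at a raw significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd
from scipy import stats

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "load_ontology",
    "term_ancestors",
    "load_annotations",
    "annotate_family",
    "fisher_enrichment",
]

_RELATIONS = ("is_a", "part_of")


class OntologyFormatError(ValueError):
    """The ontology file is not a usable DAG."""


def load_ontology(path) -> nx.MultiDiGraph:
    """Parse an OBO file into a DAG of is_a / part_of edges.

    Edges point child -> parent (the obonet convention).  Obsolete terms are
    dropped with a warning; a cyclic graph is rejected.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)
    obsolete = [n for n, d in graph.nodes(data=True)
                if d.get("is_obsolete") in ("true", True)]
    if obsolete:
        warnings.warn(f"dropping {len(obsolete)} obsolete ontology terms")
        graph.remove_nodes_from(obsolete)
    drop_edges = [
        (u, v, k) for u, v, k in graph.edges(keys=True) if k not in _RELATIONS
    ]
    graph.remove_edges_from(drop_edges)
    if not nx.is_directed_acyclic_graph(graph):
        raise OntologyFormatError("ontology graph contains cycles")
    return graph


def term_ancestors(graph: nx.MultiDiGraph, term: str) -> set[str]:
    """All ancestors (parents, transitively) of a term.

    Edges point child -> parent, so ancestors are the graph descendants.
    """
    return set(nx.descendants(graph, term))


@dataclass
class AnnotationSet:
    """Gene -> GO term sets after ancestor closure, plus the ontology DAG."""

    gene_terms: dict
    ontology: nx.MultiDiGraph = field(repr=False, default=None)

    def terms_of(self, gene: str) -> frozenset:
        return self.gene_terms.get(gene, frozenset())

    def annotated_genes(self, term: str, genes) -> int:
        return sum(1 for g in genes if term in self.terms_of(g))

    @property
    def all_terms(self) -> set:
        out: set = set()
        for terms in self.gene_terms.values():
            out |= terms
        return out


def load_annotations(path, ontology: nx.MultiDiGraph) -> AnnotationSet:
    """Read a gene->term table and close it over ontology ancestors.

    Accepts a two-column TSV (gene, term) or GAF 2.x rows (``!`` comments
    skipped, gene in column 2, term in column 5, other columns ignored).
    Terms absent from the ontology (e.g. annotations to obsolete terms) are
    skipped with a warning.
    """
    gene_terms: dict[str, set] = {}
    skipped: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF 2.x
                gene, term = fields[1], fields[4]
            elif len(fields) >= 2:
                gene, term = fields[0], fields[1]
            else:
                continue
            if term not in ontology:
                skipped.add(term)
                continue
            closure = gene_terms.setdefault(gene, set())
            closure.add(term)
            closure |= term_ancestors(ontology, term)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} annotation terms absent from the ontology"
        )
    return AnnotationSet(
        gene_terms={g: frozenset(t) for g, t in gene_terms.items()},
        ontology=ontology,
    )


def annotate_family(members, annotations: AnnotationSet,
                    threshold: float = 0.30) -> frozenset:
    """Terms held by at least ``threshold`` of a family's members.

    The fraction is computed after ancestor closure and the boundary is
    inclusive (3 of 10 members at the default 30% qualifies).
    """
    members = list(members)
    if not members:
        return frozenset()
    counts: dict[str, int] = {}
    for gene in members:
        for term in annotations.terms_of(gene):
            counts[term] = counts.get(term, 0) + 1
    need = threshold * len(members)
    return frozenset(t for t, c in counts.items() if c >= need - 1e-9)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher 2x2 outcome for one term between a test and a background set."""

    term: str
    a: int  # test-set members annotated to the term
    b: int  # test-set members not annotated
    c: int  # background members annotated
    d: int  # background members not annotated
    odds_direction: str  # 'over' | 'under'
    p_value: float
    significant: bool


def fisher_enrichment(test_terms: dict, background_terms: dict,
                      alpha: float = 0.01, fdr: bool = False):
    """Two-sided Fisher exact enrichment of terms between two gene groups.

    ``test_terms`` and ``background_terms`` map each unit (gene or family)
    to its term set.  Every term present in at least one group is tested;
    direction comes from the sign of the log-odds; results are sorted by
    p-value.  No multiple-testing correction is applied by default (the
    classic raw ``P < alpha`` rule); ``fdr=True`` adds Benjamini-Hochberg
    adjusted p-values in an extra field of the returned DataFrame.

    Returns ``(results, frame)``: the list of EnrichmentResult and a tidy
    DataFrame view.
    """
    n_test = len(test_terms)
    n_bg = len(background_terms)
    terms: set = set()
    for t in test_terms.values():
        terms |= set(t)
    for t in background_terms.values():
        terms |= set(t)

    rows = []
    for term in sorted(terms):
        a = sum(1 for t in test_terms.values() if term in t)
        c = sum(1 for t in background_terms.values() if term in t)
        b, d = n_test - a, n_bg - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        over = a * d > b * c
        rows.append(EnrichmentResult(
            term=term, a=a, b=b, c=c, d=d,
            odds_direction="over" if over else "under",
            p_value=float(p), significant=bool(p < alpha),
        ))
    rows.sort(key=lambda r: (r.p_value, r.term))
    frame = pd.DataFrame(
        [{"term": r.term, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
          "direction": r.odds_direction, "p_value": r.p_value,
          "significant": r.significant} for r in rows]
    )
    if fdr and len(frame):
        m = len(frame)
        order = frame["p_value"].rank(method="first")
        adj = frame["p_value"] * m / order
        frame["p_bh"] = adj.iloc[::-1].cummin().iloc[::-1].clip(upper=1.0)
    return rows, frame
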