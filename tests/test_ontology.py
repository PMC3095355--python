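"""Tests for ontology loading, annotation closure and Fisher enrichment."""

import math
from itertools import product

import numpy as np
import pytest

from paralogy.ontology import (AnnotationSet, OntologyFormatError,
                               annotate_family, fisher_enrichment,
                               load_annotations, load_ontology,
                               term_ancestors)

_OBO_HEADER = "format-version: 1.2\nontology: toy\n\n"


def _write_obo(tmp_path, stanzas, name="toy.obo"):
    path = tmp_path / name
    path.write_text(_OBO_HEADER + "\n".join(stanzas))
    return path


def _term(tid, name="x", is_a=(), obsolete=False, part_of=()):
    lines = [f"[Term]", f"id: {tid}", f"name: {name}"]
    for parent in is_a:
        lines.append(f"is_a: {parent}")
    for parent in part_of:
        lines.append(f"relationship: part_of {parent}")
    if obsolete:
        lines.append("is_obsolete: true")
    return "\n".join(lines) + "\n"


class TestLoadOntology:
    def test_chain_ancestors(self, tmp_path):
        obo = _write_obo(tmp_path, [
            _term("GO:0000001"),
            _term("GO:0000002", is_a=["GO:0000001"]),
            _term("GO:0000003", is_a=["GO:0000002"]),
        ])
        graph = load_ontology(obo)
        assert term_ancestors(graph, "GO:0000003") == {"GO:0000002",
                                                       "GO:0000001"}

    def test_multiple_parents_both_in_closure(self, tmp_path):
        obo = _write_obo(tmp_path, [
            _term("GO:0000001"), _term("GO:0000002"),
            _term("GO:0000003", is_a=["GO:0000001"],
                  part_of=["GO:0000002"]),
        ])
        graph = load_ontology(obo)
        assert term_ancestors(graph, "GO:0000003") == {"GO:0000001",
                                                       "GO:0000002"}

    def test_obsolete_terms_dropped_with_warning(self, tmp_path):
        obo = _write_obo(tmp_path, [
            _term("GO:0000001"),
            _term("GO:0000009", obsolete=True),
        ])
        with pytest.warns(UserWarning, match="obsolete"):
            graph = load_ontology(obo)
        assert "GO:0000009" not in graph

    def test_cyclic_graph_rejected(self, tmp_path):
        obo = _write_obo(tmp_path, [
            _term("GO:0000001", is_a=["GO:0000002"]),
            _term("GO:0000002", is_a=["GO:0000001"]),
        ])
        with pytest.raises(OntologyFormatError, match="cycle"):
            load_ontology(obo)


class TestAnnotations:
    @pytest.fixture()
    def graph(self, tmp_path):
        return load_ontology(_write_obo(tmp_path, [
            _term("GO:0000001"),
            _term("GO:0000002", is_a=["GO:0000001"]),
            _term("GO:0000003", is_a=["GO:0000002"]),
        ]))

    def test_closure_applied_on_load(self, tmp_path, graph):
        table = tmp_path / "annot.tsv"
        table.write_text("g1\tGO:0000003\n")
        annset = load_annotations(table, graph)
        assert annset.terms_of("g1") == {"GO:0000003", "GO:0000002",
                                         "GO:0000001"}

    def test_unknown_terms_skipped_with_warning(self, tmp_path, graph):
        table = tmp_path / "annot.tsv"
        table.write_text("g1\tGO:0000003\ng2\tGO:9999999\n")
        with pytest.warns(UserWarning, match="absent"):
            annset = load_annotations(table, graph)
        assert annset.terms_of("g2") == frozenset()

    def test_closure_is_idempotent(self, tmp_path, graph):
        table = tmp_path / "annot.tsv"
        table.write_text("g1\tGO:0000002\n")
        a1 = load_annotations(table, graph)
        closed_again = {
            g: frozenset().union(terms, *(term_ancestors(graph, t)
                                          for t in terms))
            for g, terms in a1.gene_terms.items()
        }
        assert closed_again == a1.gene_terms


class TestAnnotateFamily:
    def _annset(self, annotated_genes, term="GO:1"):
        return AnnotationSet(gene_terms={g: frozenset({term})
                                         for g in annotated_genes})

    def test_inclusive_30_percent_boundary(self):
        members = [f"g{i}" for i in range(10)]
        annset = self._annset(members[:3])
        assert annotate_family(members, annset) == {"GO:1"}
        assert annotate_family(members, self._annset(members[:2])) == \
            frozenset()

    def test_one_of_three_qualifies(self):
        members = ["a", "b", "c"]
        assert annotate_family(members, self._annset(["a"])) == {"GO:1"}


class TestFisherEnrichment:
    def test_fully_separated_table_hand_computed(self):
        test = {f"t{i}": frozenset({"GO:1"}) for i in range(10)}
        background = {f"b{i}": frozenset() for i in range(10)}
        rows, _ = fisher_enrichment(test, background)
        (res,) = rows
        assert res.term == "GO:1"
        assert (res.a, res.b, res.c, res.d) == (10, 0, 0, 10)
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert res.odds_direction == "over"
        assert res.significant

    def test_identical_proportions_not_significant(self):
        test = {f"t{i}": frozenset({"GO:1"} if i < 5 else set())
                for i in range(10)}
        background = {f"b{i}": frozenset({"GO:1"} if i < 5 else set())
                      for i in range(10)}
        rows, _ = fisher_enrichment(test, background)
        assert rows[0].p_value == pytest.approx(1.0)

    def test_term_absent_everywhere_excluded(self):
        rows, frame = fisher_enrichment({"t": frozenset()}, {"b": frozenset()})
        assert rows == [] and len(frame) == 0

    def test_matches_hypergeometric_enumeration_small_margins(self):
        # brute-force two-sided Fisher: sum of hypergeometric point
        # probabilities no larger than the observed table's
        from scipy import stats as ss

        def brute(a, b, c, d):
            n, r1, c1 = a + b + c + d, a + b, a + c
            obs = (math.comb(r1, a) * math.comb(n - r1, c1 - a)
                   / math.comb(n, c1))
            total = 0.0
            for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
                p = (math.comb(r1, x) * math.comb(n - r1, c1 - x)
                     / math.comb(n, c1))
                if p <= obs * (1 + 1e-9):
                    total += p
            return total

        for a, b, c, d in product(range(0, 7), repeat=4):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            _, p = ss.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert p == pytest.approx(brute(a, b, c, d), abs=1e-9), \
                (a, b, c, d)

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(4)
        hits = 0
        for rep in range(10):
            test = {f"t{i}": frozenset({"GO:X"} if rng.random() < 0.30
                                       else set()) for i in range(500)}
            background = {f"b{i}": frozenset({"GO:X"} if rng.random() < 0.10
                                             else set()) for i in range(500)}
            rows, _ = fisher_enrichment(test, background, alpha=0.01)
            row = next(r for r in rows if r.term == "GO:X")
            if row.significant and row.odds_direction == "over":
                hits += 1
        assert hits >= 9

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(1)
        test = {f"t{i}": frozenset({f"GO:{j}" for j in range(5)
                                    if rng.random() < 0.3})
                for i in range(40)}
        bg = {f"b{i}": frozenset({f"GO:{j}" for j in range(5)
                                  if rng.random() < 0.25})
              for i in range(40)}
        _, frame = fisher_enrichment(test, bg, fdr=True)
        assert (frame["p_bh"] >= frame["p_value"] - 1e-12).all()
        assert frame["p_bh"].is_monotonic_increasing
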