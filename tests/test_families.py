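"""Tests for family clustering, node dating, amplification and power law."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from paralogy.families import (GeneFamily, amplification_ratio,
                               cluster_families, compare_sizes,
                               count_young_nodes, date_duplications,
                               fit_powerlaw, load_amplified_family_table,
                               young_subset)


class TestClusterFamilies:
    def test_transitivity_groups_one_family(self):
        fams = cluster_families([("A", "B"), ("B", "C")])
        assert len(fams) == 1
        assert fams[0].members == {"A", "B", "C"}

    def test_no_edges_no_families(self):
        assert cluster_families([]) == []

    def test_spanning_forest_edge_count(self):
        rng = np.random.default_rng(1)
        edges = {tuple(sorted(rng.choice(40, 2, replace=False).astype(str)))
                 for _ in range(60)}
        fams = cluster_families(edges)
        import networkx as nx

        g = nx.Graph(list(edges))
        forest_edges = g.number_of_nodes() - nx.number_connected_components(g)
        assert sum(f.size - 1 for f in fams) == forest_edges


class TestDateDuplications:
    def test_pair_family_single_node(self):
        fam = GeneFamily("f", frozenset({"A", "B"}))
        nodes = date_duplications(fam, {("A", "B"): 0.3})
        assert len(nodes) == 1
        assert nodes[0].age_ks == pytest.approx(0.3)

    def test_triple_by_hand(self):
        fam = GeneFamily("f", frozenset({"A", "B", "C"}))
        ks = {("A", "B"): 0.1, ("A", "C"): 0.5, ("B", "C"): 0.5}
        ages = sorted(n.age_ks for n in date_duplications(fam, ks))
        assert ages == pytest.approx([0.1, 0.5])

    def test_matches_scipy_upgma_on_full_matrices(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            n = int(rng.integers(4, 8))
            members = [f"g{i}" for i in range(n)]
            condensed = rng.uniform(0.05, 1.9, size=n * (n - 1) // 2)
            ks = {}
            for (i, a), (j, b) in itertools.combinations(
                    enumerate(members), 2):
                ks[(a, b)] = squareform(condensed)[i, j]
            fam = GeneFamily("f", frozenset(members))
            ages = sorted(node.age_ks for node in date_duplications(fam, ks))
            ref = sorted(linkage(condensed, method="average")[:, 2])
            assert np.allclose(ages, ref, atol=1e-10)

    def test_missing_pairs_do_not_enter_age_means(self):
        # A-B observed young; C attaches with only one observed distance:
        # the imputed values steer topology but the node age averages only
        # the observed cross-cluster Ks
        fam = GeneFamily("f", frozenset({"A", "B", "C"}))
        ks = {("A", "B"): 0.1, ("A", "C"): 0.9}  # B-C missing
        ages = sorted(n.age_ks for n in date_duplications(fam, ks))
        assert ages == pytest.approx([0.1, 0.9])

    def test_single_member_family_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            date_duplications(GeneFamily("f", frozenset({"A"})), {})

    def test_node_ages_nondecreasing_toward_root_for_ultrametric(self):
        fam = GeneFamily("f", frozenset({"A", "B", "C", "D"}))
        ks = {("A", "B"): 0.2, ("C", "D"): 0.3,
              ("A", "C"): 1.1, ("A", "D"): 1.1,
              ("B", "C"): 1.1, ("B", "D"): 1.1}
        ages = [n.age_ks for n in date_duplications(fam, ks)]
        assert ages == sorted(ages)

    def test_recovers_simulated_node_ages(self, small_dataset):
        # families evolve on ultrametric trees: UPGMA on true pairwise Ks
        # must return exactly the simulated node ages
        by_family: dict = {}
        for (a, b), v in small_dataset.true_pair_ks.items():
            by_family.setdefault(small_dataset.true_family_ids[a],
                                 {})[(a, b)] = v
        for fam_id, ks in list(by_family.items())[:10]:
            members = frozenset({g for pair in ks for g in pair})
            ages = sorted(n.age_ks
                          for n in date_duplications(
                              GeneFamily(fam_id, members), ks))
            true_ages = sorted(set(ks.values()))
            assert np.allclose(ages, true_ages, atol=1e-9)


class TestYoungAndAmplification:
    def test_young_reclustering_uses_strict_cutoff(self):
        ks = {("A", "B"): 0.39, ("B", "C"): 0.4, ("C", "D"): 1.2}
        fams = young_subset(ks, cutoff=0.4)
        assert len(fams) == 1
        assert fams[0].members == {"A", "B"}

    def test_young_node_count(self):
        fam = GeneFamily("f", frozenset({"A", "B", "C"}))
        ks = {("A", "B"): 0.2, ("A", "C"): 1.5, ("B", "C"): 1.5}
        nodes = date_duplications(fam, ks)
        assert count_young_nodes(nodes, 0.4) == 1
        assert count_young_nodes(nodes, 0.0) == 0

    @pytest.mark.parametrize("n,d,ratio", [(6, 5, 6.00), (18, 8, 1.80),
                                           (7, 0, 1.00), (29, 11, 1.61)])
    def test_ratio_arithmetic(self, n, d, ratio):
        assert amplification_ratio(n, d).ratio == ratio

    def test_degenerate_ratio_rejected(self):
        with pytest.raises(ValueError):
            amplification_ratio(5, 5)

    def test_reference_table_ratios(self):
        table = load_amplified_family_table()
        assert len(table) == 17
        ratios = [amplification_ratio(int(r.apple), int(r.d_young)).ratio
                  for r in table.itertuples()]
        row_s5 = table[table.family == "40S ribosomal protein S5"].iloc[0]
        assert amplification_ratio(int(row_s5.apple),
                                   int(row_s5.d_young)).ratio == 6.00
        assert round(float(np.mean(ratios)), 2) == 2.36


class TestPowerLaw:
    def test_exact_noiseless_fit(self):
        hist = pd.Series({x: 100.0 * x**-2.0 for x in range(2, 21)})
        fit = fit_powerlaw(hist)
        assert fit.b == pytest.approx(2.0, abs=1e-9)
        assert fit.a == pytest.approx(100.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_single_size_class_rejected(self):
        with pytest.raises(ValueError, match="size classes"):
            fit_powerlaw([3] * 50)

    def test_halving_factor(self):
        hist = pd.Series({x: 50.0 * x**-2.35 for x in range(2, 15)})
        fit = fit_powerlaw(hist)
        assert fit.halving_factor() == pytest.approx(2.0**2.35, rel=1e-6)

    def test_mle_variant_close_to_ols(self):
        from paralogy.simulate import simulate_family_sizes

        sizes = simulate_family_sizes(2000, 2.35, seed=9)
        mle = fit_powerlaw(sizes, method="mle")
        assert mle.b == pytest.approx(2.35, abs=0.15)


class TestCompareSizes:
    def test_identical_tables_correlate_perfectly(self):
        t = pd.DataFrame({"family": list("abcd"), "size": [2, 5, 9, 20]})
        _, r, larger = compare_sizes(t, t.rename(columns={"size": "size"}))
        assert r == pytest.approx(1.0)
        assert larger == []

    def test_anti_ordered_sizes_negative(self):
        a = pd.DataFrame({"family": list("abc"), "size": [1, 5, 9]})
        b = pd.DataFrame({"family": list("abc"), "size": [9, 5, 1]})
        _, r, _ = compare_sizes(a, b)
        assert r < 0

    def test_reference_amplified_families_all_larger(self):
        table = load_amplified_family_table()
        a = table[["family", "apple"]]
        b = table[["family", "arabidopsis"]]
        joined, r, larger = compare_sizes(a, b)
        assert len(larger) == 17  # every amplified family exceeds the
        assert r > 0              # reference copy number
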