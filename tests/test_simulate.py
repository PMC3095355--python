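"""Tests of the synthetic-data generator against closed forms and truth."""

import math

import numpy as np
import pytest
from scipy import stats

from paralogy._codons import STOP_CODONS, codons_of
from paralogy.families import fit_powerlaw
from paralogy.ks import codon_align, ng86_ks
from paralogy.simulate import (MixtureTruth, SimulationConfig,
                               simulate_age_sample, simulate_codon_pair,
                               simulate_dataset, simulate_expression,
                               simulate_family_sizes)


class TestMixtureTruthConfig:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureTruth(w_exp=0.5, components=((0.2, 0.01, 0.2),))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="death_rate"):
            MixtureTruth(death_rate=-1, w_exp=1.0, components=())

    def test_config_invariants(self):
        with pytest.raises(ValueError, match="powerlaw"):
            SimulationConfig(seed=0, powerlaw_exponent=1.0)


class TestCodonPair:
    def test_zero_divergence_is_identical(self):
        a, b = simulate_codon_pair(50, 0.0, seed=1)
        assert a == b

    def test_no_stops_and_frame_preserved(self):
        a, b = simulate_codon_pair(120, 1.5, seed=4)
        for cds in (a, b):
            assert len(cds) % 3 == 0
            assert not any(c in STOP_CODONS for c in codons_of(cds))

    def test_counting_oracle_brackets_target(self):
        # NG86-counted dS on the simulated pair should sit near the target
        a, b = simulate_codon_pair(500, 0.5, omega=0.2, kappa=2.0, seed=1)
        ds = ng86_ks(codon_align(a, b)).ks
        assert 0.35 <= ds <= 0.65

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_codon_pair(50, -0.1)

    def test_determinism(self):
        assert simulate_codon_pair(60, 0.3, seed=9) == \
            simulate_codon_pair(60, 0.3, seed=9)


class TestAgeSample:
    def test_truncated_exponential_mean_matches_closed_form(self):
        lam, upper, n = 1.892, 2.0, 100_000
        truth = MixtureTruth(w_exp=1.0, components=())
        ages = simulate_age_sample(n, truth, upper=upper, seed=1)
        expected = 1.0 / lam - upper * math.exp(-lam * upper) / (
            1 - math.exp(-lam * upper))
        assert np.mean(ages) == pytest.approx(expected, rel=0.01)
        assert np.all((ages > 0) & (ages <= upper))

    def test_single_normal_median(self):
        truth = MixtureTruth(w_exp=0.0,
                             components=((0.185, 0.08**2, 1.0),))
        ages = simulate_age_sample(100_000, truth, seed=2)
        assert np.median(ages) == pytest.approx(0.185, abs=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 1"):
            simulate_age_sample(0, MixtureTruth())

    def test_component_proportions_match_weights(self, default_truth):
        ages, labels = simulate_age_sample(100_000, default_truth, seed=3,
                                           return_labels=True)
        # acceptance probability differs per component under truncation
        lam = default_truth.death_rate
        p_exp = 1 - math.exp(-lam * 2.0)
        accept = [p_exp]
        for mu, var, _ in default_truth.components:
            sd = math.sqrt(var)
            accept.append(stats.norm.cdf(2.0, mu, sd)
                          - stats.norm.cdf(0.0, mu, sd))
        weights = np.array([default_truth.w_exp]
                           + [w for _, _, w in default_truth.components])
        expected = weights * accept
        expected /= expected.sum()
        observed = np.bincount(labels, minlength=len(weights))
        chi2 = stats.chisquare(observed, expected * len(ages))
        assert chi2.pvalue > 0.01


class TestFamilySizes:
    def test_large_exponent_collapses_to_min_size(self):
        sizes = simulate_family_sizes(200, 60.0, min_size=2, max_size=50,
                                      seed=1)
        assert np.all(sizes == 2)

    def test_exponent_recovered_by_regression(self):
        sizes = simulate_family_sizes(2000, 2.35, min_size=2, max_size=250,
                                      seed=5)
        fit = fit_powerlaw(sizes)
        assert fit.b == pytest.approx(2.35, abs=0.15)

    def test_single_family_in_range(self):
        sizes = simulate_family_sizes(1, 2.35, seed=2)
        assert sizes.shape == (1,) and 2 <= sizes[0] <= 250


class TestExpression:
    def test_coregulated_pair_correlates_at_depth(self):
        # a deep library and enough background genes that the multinomial
        # competition between the two paralogs is negligible
        genes = ["g1", "g2"] + [f"bg{i}" for i in range(100)]
        counts, truth = simulate_expression(
            genes, 14, 200_000, coregulated_fraction=1.0,
            seed=1, pairs=[("g1", "g2")])
        assert truth[("g1", "g2")] == "coregulated"
        r = np.corrcoef(counts.loc["g1"], counts.loc["g2"])[0, 1]
        assert r > 0.99

    def test_disjoint_support_pair_anticorrelates(self):
        counts, truth = simulate_expression(
            ["g1", "g2"], 14, 5000, coregulated_fraction=0.0,
            tissue_shift_fraction=1.0, seed=2, pairs=[("g1", "g2")])
        assert truth[("g1", "g2")] == "tissue-shifted"
        r = np.corrcoef(counts.loc["g1"], counts.loc["g2"])[0, 1]
        assert r <= 0

    def test_determinism(self):
        a, _ = simulate_expression(["x", "y", "z"], 4, 100, 0.5, seed=7,
                                   pairs=[("x", "y")])
        b, _ = simulate_expression(["x", "y", "z"], 4, 100, 0.5, seed=7,
                                   pairs=[("x", "y")])
        assert a.equals(b)


class TestDataset:
    def test_same_seed_identical_dataset(self):
        cfg = SimulationConfig(seed=42, n_families=8, library_sizes=300)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        assert [g.cds for g in d1.genes] == [g.cds for g in d2.genes]
        assert d1.true_pair_ks == d2.true_pair_ks
        assert d1.counts.equals(d2.counts)

    def test_truth_tables_are_consistent(self, small_dataset):
        ids = set(small_dataset.gene_ids)
        for (a, b), ks in small_dataset.true_pair_ks.items():
            assert a in ids and b in ids
            assert 0 < ks <= small_dataset.config.upper_ks
            # pairs only exist within one family
            assert (small_dataset.true_family_ids[a]
                    == small_dataset.true_family_ids[b])

    def test_family_labels_match_pair_connectivity(self, small_dataset):
        import networkx as nx

        g = nx.Graph(list(small_dataset.true_pair_ks))
        for comp in nx.connected_components(g):
            fams = {small_dataset.true_family_ids[x] for x in comp}
            assert len(fams) == 1

    def test_sequences_are_clean(self, small_dataset):
        for gene in small_dataset.genes[:50]:
            assert len(gene.cds) % 3 == 0
            assert not any(c in STOP_CODONS for c in codons_of(gene.cds))

    def test_node_age_multiset_matches_pairwise_mrca_structure(self,
                                                               small_dataset):
        # within a family the n-1 distinct node ages must appear among the
        # pairwise Ks values, and the largest pairwise Ks joins everything
        fams: dict = {}
        for (a, b), ks in small_dataset.true_pair_ks.items():
            fams.setdefault(small_dataset.true_family_ids[a], []).append(ks)
        for fam_id, kss in fams.items():
            members = [g for g, f in small_dataset.true_family_ids.items()
                       if f == fam_id]
            n = len(members)
            assert len(kss) == n * (n - 1) // 2
            assert len(set(np.round(kss, 12))) == n - 1
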