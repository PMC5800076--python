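"""Generators: determinism, model faithfulness, simulate-then-fit closure."""

import numpy as np
import pytest

from opsinphylo import synthetic_data as sd
from opsinphylo.codon_selection import fit_branch_model
from opsinphylo.phylo_core import (
    CODON_AMINO_ACIDS,
    ValidationError,
    write_newick,
)
from opsinphylo.trait_reconstruction import MkModel


class TestSimulateTree:
    def test_two_tips_is_cherry(self):
        tree = sd.simulate_tree(2, seed=0)
        assert tree.n_tips == 2
        assert len(tree.root.children) == 2

    def test_seed_determinism(self):
        a = sd.simulate_tree(15, seed=42)
        b = sd.simulate_tree(15, seed=42)
        assert write_newick(a) == write_newick(b)

    @pytest.mark.parametrize("n", [2, 7, 33])
    def test_exact_tip_count_and_positive_branches(self, n):
        tree = sd.simulate_tree(n, seed=n)
        assert tree.n_tips == n
        assert all(node.length > 0 for node in tree.branches())

    def test_single_tip_rejected(self):
        with pytest.raises(ValidationError):
            sd.simulate_tree(1, seed=0)


class TestSimulateCodons:
    def test_omega_zero_never_changes_amino_acid(self):
        tree = sd.simulate_tree(8, seed=1)
        cfg = sd.SimulationConfig(n_codon_sites=60, site_model="one_ratio",
                                  omega=0.0, seed=2)
        aln, _ = sd.simulate_codon_alignment(tree, cfg)
        for site in range(aln.n_codon_sites):
            aas = {CODON_AMINO_ACIDS[c] for c in aln.codons[:, site]}
            assert len(aas) == 1

    def test_seed_determinism(self):
        tree = sd.simulate_tree(5, seed=3)
        cfg = sd.SimulationConfig(n_codon_sites=30, site_model="M7", seed=9)
        a, _ = sd.simulate_codon_alignment(tree, cfg)
        b, _ = sd.simulate_codon_alignment(tree, cfg)
        assert np.array_equal(a.codons, b.codons)

    def test_root_draws_match_stationary_frequencies(self):
        tree = sd.simulate_tree(2, seed=4)
        cfg = sd.SimulationConfig(n_codon_sites=6000, site_model="one_ratio",
                                  omega=0.5, seed=5)
        aln, info = sd.simulate_codon_alignment(tree, cfg)
        freqs = np.bincount(aln.codons.ravel(), minlength=61) / aln.codons.size
        assert np.abs(freqs - 1.0 / 61).max() < 0.01

    def test_one_ratio_recovery_loop(self):
        """Fitting the one-ratio model to data simulated at omega = 0.2
        (300 codons, 10 tips) recovers omega in [0.1, 0.35] as the median
        over 10 seeds."""
        hats = []
        for seed in range(10):
            tree = sd.simulate_tree(10, seed=700 + seed)
            cfg = sd.SimulationConfig(n_codon_sites=300, site_model="one_ratio",
                                      omega=0.2, seed=800 + seed)
            aln, _ = sd.simulate_codon_alignment(tree, cfg)
            fit = fit_branch_model(aln, tree, "one_ratio", seed=seed, n_restarts=1)
            hats.append(fit.estimates["omega"])
        assert 0.1 <= float(np.median(hats)) <= 0.35


class TestSimulateTraits:
    def test_zero_rate_keeps_root_state(self):
        tree = sd.simulate_tree(10, seed=6)
        model = MkModel(["a", "b"], "ER", [0.0])
        tips = sd.simulate_discrete_trait(tree, model, "b", seed=7)
        assert set(tips.values()) == {"b"}

    def test_huge_rate_approaches_stationary_frequencies(self):
        tree = sd.simulate_tree(300, seed=8)
        model = MkModel(["a", "b", "c"], "ER", [200.0])
        tips = sd.simulate_discrete_trait(tree, model, "a", seed=9)
        freqs = np.array([list(tips.values()).count(s) for s in "abc"]) / 300
        assert np.abs(freqs - 1 / 3).max() < 0.12

    def test_discrete_seed_determinism(self):
        tree = sd.simulate_tree(12, seed=10)
        model = MkModel(["a", "b"], "ER", [0.7])
        assert sd.simulate_discrete_trait(tree, model, "a", seed=11) == \
            sd.simulate_discrete_trait(tree, model, "a", seed=11)

    def test_zero_sigma_keeps_root_value(self):
        tree = sd.simulate_tree(6, seed=12)
        vals = sd.simulate_continuous_trait(tree, 0.0, 3.25, seed=13)
        assert set(vals.values()) == {3.25}

    def test_tip_variance_tracks_depth(self):
        tree = sd.simulate_tree(4, seed=14)
        tip = tree.tips()[0]
        depth = tree.depths()[id(tip)]
        sigma2 = 2.5
        draws = [sd.simulate_continuous_trait(tree, sigma2, 0.0, seed=s)[tip.label]
                 for s in range(200)]
        assert np.var(draws) == pytest.approx(sigma2 * depth, rel=0.3)

    def test_sister_tips_covary_through_shared_path(self):
        tree = sd.simulate_tree(6, seed=15)
        # find a cherry: two tips sharing a parent
        cherry = None
        for node in tree.postorder():
            if not node.is_tip and all(c.is_tip for c in node.children) \
                    and len(node.children) == 2:
                cherry = node
                break
        assert cherry is not None
        shared = tree.depths()[id(cherry)]
        sigma2 = 1.5
        a_vals, b_vals = [], []
        for s in range(300):
            vals = sd.simulate_continuous_trait(tree, sigma2, 0.0, seed=5000 + s)
            a_vals.append(vals[cherry.children[0].label])
            b_vals.append(vals[cherry.children[1].label])
        cov = np.cov(a_vals, b_vals)[0, 1]
        assert cov == pytest.approx(sigma2 * shared, rel=0.35)


class TestFixtures:
    def test_presence_matrix_consistent_with_counts(self):
        fx = sd.published_fixtures()
        sums = fx.opsin_presence.sum(axis=1)
        for lineage in ("mammals", "reptiles", "birds"):
            assert sums[lineage] == fx.repertoire_counts[lineage]

    def test_phenotype_examples(self):
        fx = sd.published_fixtures()
        human = fx.phenotype_examples.loc["Homo_sapiens"]
        rat = fx.phenotype_examples.loc["Rattus_norvegicus"]
        assert human["orbit_convergence"] == 79.3
        assert human["visual_acuity"] == 64.0
        assert rat["orbit_convergence"] == 32.0
        assert rat["visual_acuity"] == 1.6
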