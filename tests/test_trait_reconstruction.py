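"""Mk and Brownian-motion reconstructions, Moran's I, aggregation, Wilcoxon."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from conftest import brute_force_marginals, brute_force_site_logliks
from opsinphylo import synthetic_data as sd
from opsinphylo.phylo_core import ValidationError, parse_newick
from opsinphylo.trait_reconstruction import (
    MkModel,
    aggregate_across_genes,
    bm_ancestral,
    compare_mk_schemes,
    fit_mk,
    marginal_ancestral_states,
    mk_loglik,
    moran_weights,
    morans_i,
    wilcoxon_ranksum,
)


def _codes(tip_states, states):
    index = {s: i for i, s in enumerate(states)}
    return {t: np.array([index[s]]) for t, s in tip_states.items()}


class TestMk:
    def test_loglik_matches_brute_force_enumeration(self):
        tree = parse_newick("(((A:0.4,B:0.7):0.3,C:1.0):0.2,D:0.9);")
        states = ["x", "y", "z"]
        model = MkModel(states, "ARD", [0.3, 0.1, 0.5, 0.2, 0.4, 0.6])
        tips = {"A": "x", "B": "z", "C": "y", "D": "x"}
        got = mk_loglik(tree, tips, model)
        Q = model.generator()
        P_stacks = {id(n): expm(Q * n.length)[None] for n in tree.branches()}
        want = brute_force_site_logliks(
            tree, _codes(tips, states), P_stacks,
            np.full(3, 1 / 3), np.array([1.0]))
        assert got == pytest.approx(want[0], abs=1e-8)

    def test_fewer_than_two_observed_states_is_error(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValidationError, match="two observed states"):
            fit_mk(tree, {"A": "s", "B": "s"})

    def test_degenerate_data_with_explicit_states_pins_ancestor(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        fit = fit_mk(tree, {t: "a" for t in "ABCD"}, "ER",
                     states=["a", "b"], n_restarts=1)
        recon = marginal_ancestral_states(tree, {t: "a" for t in "ABCD"}, fit)
        assert (recon.table["a"] > 0.999).all()

    def test_two_tip_symmetric_root_is_even(self):
        tree = parse_newick("(A:1,B:1);")
        model = MkModel(["A", "B"], "ER", [0.3])
        recon = marginal_ancestral_states(tree, {"A": "A", "B": "B"}, model)
        assert np.allclose(recon.table.loc["root"], [0.5, 0.5])

    @pytest.mark.parametrize("newick,tips", [
        ("((A:0.4,B:0.7):0.3,C:1.0);", {"A": "x", "B": "y", "C": "y"}),
        ("(((A:0.4,B:0.7):0.3,C:1.0):0.2,D:0.9);",
         {"A": "x", "B": "z", "C": "y", "D": "x"}),
    ])
    def test_marginals_match_brute_force_bayes(self, newick, tips):
        tree = parse_newick(newick)
        states = ["x", "y", "z"]
        model = MkModel(states, "SYM", [0.25, 0.4, 0.15])
        recon = marginal_ancestral_states(tree, tips, model)
        P_single = {id(n): expm(model.generator() * n.length)
                    for n in tree.branches()}
        want = brute_force_marginals(tree, _codes(tips, states), P_single,
                                     np.full(3, 1 / 3))
        from opsinphylo.trait_reconstruction import _node_ids
        ids = _node_ids(tree)
        for node_id, probs in want.items():
            label = [ids[k] for k in [node_id]][0]
            assert np.allclose(recon.table.loc[label], probs, atol=1e-8)

    def test_label_permutation_equivariance(self):
        tree = parse_newick("((A:0.4,B:0.7):0.3,C:1.0);")
        tips = {"A": "x", "B": "y", "C": "y"}
        model = MkModel(["x", "y"], "ER", [0.5])
        r1 = marginal_ancestral_states(tree, tips, model)
        swapped = {t: {"x": "y", "y": "x"}[s] for t, s in tips.items()}
        r2 = marginal_ancestral_states(tree, swapped, model)
        assert np.allclose(r1.table["x"], r2.table["y"], atol=1e-12)

    def test_root_state_recovery_beats_flat_prior(self):
        model = MkModel(["a", "b", "c"], "ER", [0.3])
        probs = []
        for seed in range(50):
            tree = sd.simulate_tree(50, seed=seed)
            tips = sd.simulate_discrete_trait(tree, model, "a", seed=1000 + seed)
            recon = marginal_ancestral_states(tree, tips, model)
            probs.append(recon.table.loc["root", "a"])
        assert np.mean(probs) > 1.0 / 3.0

    def test_er_null_rarely_prefers_ard(self):
        """ARD-vs-ER LRT on ER-simulated data stays below the chi-squared
        95% point in at least 85% of seeds."""
        truth = MkModel(["a", "b", "c"], "ER", [0.5])
        n_seeds, hits = 20, 0
        for seed in range(n_seeds):
            tree = sd.simulate_tree(100, seed=3000 + seed)
            tips = sd.simulate_discrete_trait(tree, truth, "a", seed=4000 + seed)
            try:
                er = fit_mk(tree, tips, "ER", seed=seed, n_restarts=1)
                ard = fit_mk(tree, tips, "ARD", seed=seed, n_restarts=1)
            except ValidationError:  # a seed may fix fewer than 2 states
                n_seeds -= 1
                continue
            df = ard.np - er.np
            stat, _, _ = compare_mk_schemes(er, ard)
            if stat <= chi2.ppf(0.95, df):
                hits += 1
        assert hits >= int(0.85 * n_seeds)

    def test_identical_fits_give_zero_statistic(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        tips = {"A": "x", "B": "y", "C": "x"}
        fit = fit_mk(tree, tips, "ER", n_restarts=1)
        stat, p, _ = compare_mk_schemes(fit, fit, df_override=1)
        assert stat == 0.0 and p == 1.0

    def test_default_df_for_three_state_sym_vs_ard(self):
        k = 3
        assert MkModel.n_rates(k, "ARD") - MkModel.n_rates(k, "SYM") == 3


class TestBrownianMotion:
    def test_two_equal_branches_root_is_mean(self):
        tree = parse_newick("(A:1,B:1);")
        recon = bm_ancestral(tree, {"A": 2.0, "B": 4.0})
        assert recon.table.loc["root", "estimate"] == pytest.approx(3.0)

    def test_constant_values_give_zero_variance(self):
        tree = sd.simulate_tree(8, seed=11)
        recon = bm_ancestral(tree, {t: 7.5 for t in tree.tip_labels})
        assert recon.model["sigma2"] == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(recon.table["estimate"], 7.5)
        assert np.allclose(recon.table["sd"], 0.0)

    def test_three_tip_matches_numeric_joint_optimum(self):
        """Under a Gaussian model the marginal ancestral means equal the
        joint mode, so numerically maximizing the branch-increment
        likelihood is an independent oracle for the GLS estimates."""
        tree = parse_newick("((A:0.5,B:1.5):0.7,C:2.0);")
        values = {"A": 1.0, "B": 3.0, "C": -2.0}
        recon = bm_ancestral(tree, values)
        sigma2 = recon.model["sigma2"]

        def neg_loglik(x):
            root, inner = x
            out = 0.0
            for val, anc, t in [(values["A"], inner, 0.5),
                                (values["B"], inner, 1.5),
                                (values["C"], root, 2.0),
                                (inner, root, 0.7)]:
                out += 0.5 * (val - anc) ** 2 / (sigma2 * t)
            return out

        res = minimize(neg_loglik, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        root_hat, inner_hat = res.x
        assert recon.table.loc["root", "estimate"] == pytest.approx(root_hat, abs=1e-6)
        inner_label = [ix for ix in recon.table.index if ix != "root"][0]
        assert recon.table.loc[inner_label, "estimate"] == pytest.approx(inner_hat, abs=1e-6)

    def test_root_estimate_within_tip_range(self):
        for seed in range(5):
            tree = sd.simulate_tree(12, seed=60 + seed)
            vals = sd.simulate_continuous_trait(tree, 3.0, 0.0, seed=70 + seed)
            recon = bm_ancestral(tree, vals)
            assert min(vals.values()) - 1e-9 <= recon.table.loc["root", "estimate"] \
                <= max(vals.values()) + 1e-9

    def test_zero_depth_tree_is_error(self):
        tree = parse_newick("(A:0,B:0);")
        with pytest.raises(ValidationError, match="depth"):
            bm_ancestral(tree, {"A": 1.0, "B": 2.0})

    def test_parameter_recovery_at_scale(self):
        """ER rate and BM sigma^2 recovered within +/-50% at 100 tips
        (median over 20 seeds)."""
        er_truth = MkModel(["a", "b"], "ER", [0.8])
        rate_hats, s2_hats = [], []
        for seed in range(20):
            tree = sd.simulate_tree(100, seed=8000 + seed)
            tips = sd.simulate_discrete_trait(tree, er_truth, "a", seed=8100 + seed)
            try:
                fit = fit_mk(tree, tips, "ER", seed=seed, n_restarts=1)
                rate_hats.append(fit.model.rates[0])
            except ValidationError:
                pass
            vals = sd.simulate_continuous_trait(tree, 2.0, 0.0, seed=8200 + seed)
            s2_hats.append(bm_ancestral(tree, vals).model["sigma2"])
        assert 0.4 <= np.median(rate_hats) <= 1.2
        assert 1.0 <= np.median(s2_hats) <= 3.0


class TestMoran:
    def test_expected_value_closed_form(self):
        w = 1.0 - np.eye(5)
        res = morans_i([1.0, 2.0, 5.0, 3.0, 4.0], w)
        assert res.expected == pytest.approx(-0.25)

    def test_constant_values_error(self):
        w = 1.0 - np.eye(4)
        with pytest.raises(ValidationError, match="constant"):
            morans_i([2.0, 2.0, 2.0, 2.0], w)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValidationError, match="diagonal"):
            morans_i([1.0, 2.0, 3.0], np.ones((3, 3)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        tree = sd.simulate_tree(8, seed=seed)
        vals = sd.simulate_continuous_trait(tree, 1.0, 0.0, seed=seed + 50)
        w = moran_weights(tree)
        x = pd.Series(vals).loc[w.index].to_numpy()
        res = morans_i(pd.Series(vals).loc[w.index], w)
        # oracle: literal double sums
        W = w.to_numpy()
        n = len(x)
        zbar = x.mean()
        num = sum(W[i, j] * (x[i] - zbar) * (x[j] - zbar)
                  for i in range(n) for j in range(n))
        den = sum((xi - zbar) ** 2 for xi in x)
        I_direct = n / W.sum() * num / den
        assert res.I == pytest.approx(I_direct, abs=1e-12)
        assert res.expected == pytest.approx(-1.0 / (n - 1))

    def test_weights_are_inverse_patristic(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        w = moran_weights(tree)
        assert w.loc["A", "B"] == pytest.approx(0.5)
        assert w.loc["A", "C"] == pytest.approx(0.25)
        assert np.allclose(np.diag(w.to_numpy()), 0.0)


class TestAggregation:
    def test_single_gene_mean_and_zero_sd(self):
        out = aggregate_across_genes({"g1": {"root": 40.0}})
        assert out.loc["root", "mean"] == 40.0
        assert out.loc["root", "sd"] == 0.0

    def test_two_genes_population_sd(self):
        out = aggregate_across_genes({"g1": {"root": 40.0}, "g2": {"root": 50.0}})
        assert out.loc["root", "mean"] == pytest.approx(45.0)
        assert out.loc["root", "sd"] == pytest.approx(5.0)

    def test_gated_gene_contributes_nothing(self):
        out = aggregate_across_genes(
            {"g1": {"root": 40.0}, "g2": {"root": 90.0}},
            moran_pvalues={"g1": 0.001, "g2": 0.5},
            threshold=0.003,
        )
        assert out.loc["root", "mean"] == pytest.approx(40.0)
        assert out.loc["root", "n_genes"] == 1

    def test_underrepresented_clade_excluded_per_gene(self):
        out = aggregate_across_genes(
            {"g1": {"root": 40.0, "nodeX": 10.0},
             "g2": {"root": 50.0, "nodeX": 20.0}},
            clade_counts={"g1": {"nodeX": 1}, "g2": {"nodeX": 3}},
        )
        assert out.loc["nodeX", "mean"] == pytest.approx(20.0)
        assert out.loc["root", "n_genes"] == 2


def exact_ranksum_p(a, b):
    """Enumeration oracle: two-sided p over all group assignments."""
    pooled = sorted(a + b)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in a)
    n = len(a)
    stats = [sum(comb) for comb in
             itertools.combinations(range(1, len(pooled) + 1), n)]
    mean = np.mean(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(stats)


class TestWilcoxon:
    def test_fully_separated_small_groups(self):
        _, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("a,b", [
        ([1.0, 4.0, 2.5], [3.0, 5.0]),
        ([10.0, 12.0], [11.0, 13.0, 14.0, 9.0]),
        ([1.0, 2.0, 3.0, 7.0], [4.0, 5.0, 6.0]),
    ])
    def test_matches_exact_enumeration(self, a, b):
        _, p = wilcoxon_ranksum(a, b)
        assert p == pytest.approx(exact_ranksum_p(a, b), abs=1e-12)

    def test_identical_singletons(self):
        _, p = wilcoxon_ranksum([1.0], [1.0])
        assert p == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        a = list(rng.normal(0, 1, 6))
        b = list(rng.normal(0.5, 1, 7))
        _, p1 = wilcoxon_ranksum(a, b)
        _, p2 = wilcoxon_ranksum([np.exp(x) for x in a], [np.exp(x) for x in b])
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_ranksum([], [1.0])
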