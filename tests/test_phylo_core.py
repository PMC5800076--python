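"""Trees, codon alignments and trait tables: parsing, writing, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from opsinphylo import synthetic_data as sd
from opsinphylo.phylo_core import (
    CODONS,
    MISSING,
    NewickParseError,
    TraitTable,
    ValidationError,
    parse_newick,
    patristic_distances,
    read_codon_fasta,
    write_newick,
)


class TestNewick:
    def test_minimal_two_tip_tree(self):
        t = parse_newick("(A:1.0,B:2.0):0.0;")
        assert t.tip_labels == ["A", "B"]
        assert [n.length for n in t.branches()] == [1.0, 2.0]

    def test_three_tip_patristic_from_parse(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        d = patristic_distances(t)
        assert d.loc["A", "C"] == pytest.approx(4.0)
        assert d.loc["A", "B"] == pytest.approx(2.0)

    def test_malformed_string_names_position(self):
        with pytest.raises(NewickParseError, match="malformed"):
            parse_newick("((A:1,B:2")

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            parse_newick("(A:1.0,B:-2.0);")

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises((ValidationError, NewickParseError), match="uplicate"):
            parse_newick("(A:1.0,A:2.0);")

    def test_write_then_parse_two_tips(self):
        t = parse_newick("(A:1.0,B:2.0);")
        assert write_newick(t) == "(A:1.0,B:2.0);"

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10**6), n=st.integers(2, 20))
    def test_roundtrip_random_trees(self, seed, n):
        tree = sd.simulate_tree(n, seed=seed)
        text = write_newick(tree)
        again = parse_newick(text)
        assert write_newick(again) == text
        assert again.n_tips == n

    def test_large_tree_roundtrips_losslessly(self):
        tree = sd.simulate_tree(154, seed=9)
        assert parse_newick(write_newick(tree)) == tree


class TestPatristic:
    def test_star_tree_off_diagonals(self):
        t = parse_newick("(A:0.5,B:0.5,C:0.5,D:0.5);")
        d = patristic_distances(t).to_numpy()
        off = d[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)
        assert np.allclose(np.diag(d), 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_path_enumeration(self, seed):
        tree = sd.simulate_tree(6, seed=seed)
        d = patristic_distances(tree)
        # oracle: edge sets of root paths; distance = symmetric difference sum
        paths = {}
        for tip in tree.tips():
            edges = {}
            node = tip
            while node.parent is not None:
                edges[id(node)] = node.length
                node = node.parent
            paths[tip.label] = edges
        for a in paths:
            for b in paths:
                shared = set(paths[a]) & set(paths[b])
                expect = sum(v for k, v in paths[a].items() if k not in shared)
                expect += sum(v for k, v in paths[b].items() if k not in shared)
                assert d.loc[a, b] == pytest.approx(expect, abs=1e-12)

    def test_symmetry_and_nonnegativity(self):
        tree = sd.simulate_tree(10, seed=5)
        d = patristic_distances(tree).to_numpy()
        assert (d >= 0).all()
        assert np.allclose(d, d.T)


class TestCodonFasta:
    def test_basic_two_by_two_with_gap(self):
        aln = read_codon_fasta(">A\nATGAAA\n>B\nATG---\n")
        assert aln.n_sequences == 2 and aln.n_codon_sites == 2
        assert aln.row("B")[1] == MISSING
        assert CODONS[aln.row("A")[0]] == "ATG"

    def test_internal_stop_becomes_missing_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            aln = read_codon_fasta(">A\nATGTAAAAA\n>B\nATGATGATG\n")
        assert aln.row("A")[1] == MISSING
        assert any("stop codon" in r.message for r in caplog.records)

    def test_length_not_multiple_of_three_names_record(self):
        with pytest.raises(ValidationError, match="bad_rec"):
            read_codon_fasta(">ok\nATGATG\n>bad_rec\nATGAT\n")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            read_codon_fasta(">A\nATG\n>A\nATG\n")

    def test_generator_roundtrip_shape(self):
        tree = sd.simulate_tree(154, seed=3)
        cfg = sd.SimulationConfig(n_codon_sites=300, site_model="one_ratio",
                                  omega=0.2, seed=3)
        aln, _ = sd.simulate_codon_alignment(tree, cfg)
        again = read_codon_fasta(aln.to_fasta())
        assert again.codons.shape == (154, 300)
        assert np.array_equal(again.codons, aln.codons[
            [aln.sequence_ids.index(s) for s in again.sequence_ids]])


class TestTraitTable:
    def _frame(self, **over):
        base = dict(
            species_id=["s1", "s2"],
            activity_pattern=["crepuscular", "diurnal"],
            site86_residue=["F", "Y"],
            site93_residue=["T", "P"],
            sws1_active=[True, True],
            is_primate=[False, False],
            orbit_convergence=[30.0, 80.0],
            visual_acuity=[1.5, 60.0],
        )
        base.update(over)
        return pd.DataFrame(base)

    def test_crepuscular_normalized_and_idempotent(self):
        t = TraitTable(self._frame())
        assert t.data.loc[0, "activity_pattern"] == "nocturnal"
        t2 = TraitTable(t.data)
        assert t2.data["activity_pattern"].tolist() == t.data["activity_pattern"].tolist()

    def test_unknown_activity_category_rejected(self):
        with pytest.raises(ValidationError, match="unknown activity"):
            TraitTable(self._frame(activity_pattern=["matutinal", "diurnal"]))

    def test_orbit_convergence_range_enforced(self):
        with pytest.raises(ValidationError, match="orbit_convergence"):
            TraitTable(self._frame(orbit_convergence=[30.0, 200.0]))

    def test_nonpositive_visual_acuity_rejected(self):
        with pytest.raises(ValidationError, match="visual_acuity"):
            TraitTable(self._frame(visual_acuity=[0.0, 60.0]))

    def test_duplicate_species_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            TraitTable(self._frame(species_id=["s1", "s1"]))
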