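"""Distances, neighbor joining, bootstrap, Robinson-Foulds agreement."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from ulvapop import phylo
from ulvapop import seq as sq
from ulvapop import simulate as sim


def dendropy_rf(newick1, newick2):
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestDistances:
    def test_identical_sequences_zero(self):
        d = phylo.pairwise_distances({"a": "ACGT", "b": "ACGT"})
        assert d.values[0, 1] == 0.0

    def test_p_distance_toy(self):
        d = phylo.pairwise_distances({"a": "ACGT", "b": "ACGA"}, model="p")
        assert d.values[0, 1] == pytest.approx(0.25)

    def test_jc69_closed_form_at_82_per_kb(self):
        """p = 0.082 corrects to ~0.0869 expected substitutions per site."""
        assert phylo.jc69_distance(0.082) == pytest.approx(0.08686, abs=1e-4)
        seqs = {"a": "A" * 1000, "b": "C" * 82 + "A" * 918}
        d = phylo.pairwise_distances(seqs)
        assert d.values[0, 1] == pytest.approx(phylo.jc69_distance(0.082))

    def test_saturation_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            d = phylo.pairwise_distances({"a": "AAAA", "b": "CCCC"})
        assert math.isnan(d.values[0, 1])


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        """NJ is exact on additive matrices: path lengths reproduce the
        input distances to machine precision."""
        # tree: ((a:2,b:3):1,(c:4,d:5))
        D = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
        )
        dm = phylo.DistanceMatrix(["a", "b", "c", "d"], D)
        tree = phylo.nj_tree(dm)
        for i, x in enumerate(dm.taxa):
            for j, y in enumerate(dm.taxa):
                if i < j:
                    assert tree.path_length(x, y) == pytest.approx(D[i, j])
        assert tree.bipartitions() == {frozenset({"c", "d"})} or tree.bipartitions() == {
            frozenset({"a", "b"})
        }

    def test_star_matrix_zero_internal_branches(self):
        D = np.ones((4, 4)) - np.eye(4)
        tree = phylo.nj_tree(phylo.DistanceMatrix(list("abcd"), D))
        for x, y in itertools.combinations("abcd", 2):
            assert tree.path_length(x, y) == pytest.approx(1.0)

    def test_matches_scikit_bio_on_random_additive_matrix(self):
        """Independent oracle: scikit-bio's NJ yields the same topology on a
        random additive matrix."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        # random additive matrix from a random binary tree on 8 taxa
        taxa = [f"t{i}" for i in range(8)]
        # build by random sequential attachment with random branch lengths
        seqs = {t: sq.decode(rng.integers(0, 4, 600, dtype=np.uint8)) for t in []}
        # simpler: distances from random coordinates on a line are not additive;
        # instead evolve sequences down a random tree via the simulator's panel
        spec = sim.SpeciesPanelSpec.unit_scale()
        panel = sim.simulate_panel(spec, 77)
        seqs = {s: panel.cp(s).sequence for s in spec.species}
        dm = phylo.pairwise_distances(seqs)
        ours = phylo.nj_tree(dm)
        sk_tree = skbio_nj(SkbioDM(dm.values, ids=dm.taxa))
        rf = dendropy_rf(ours.to_newick(), str(sk_tree))
        assert rf == 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylo.nj_tree(phylo.DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_six_species_strains_form_clades(self, unit_panel):
        """Strain consensuses: each species is monophyletic in the NJ tree."""
        strains = sim.default_strain_table(unit_panel, 18, hybrid=False, seed=8)
        seqs = {}
        labels = {}
        for s in strains:
            g = sim.simulate_strain_genomes(unit_panel, s)
            seqs[s.strain_id] = g.cp.sequence
            labels[s.strain_id] = s.species_id
        tree = phylo.nj_tree(phylo.pairwise_distances(seqs))
        for sp in unit_panel.spec.species:
            members = [k for k, v in labels.items() if v == sp]
            assert tree.is_monophyletic(members), sp


class TestBootstrap:
    def test_support_high_on_divergent_clades(self, unit_panel):
        seqs = {s: unit_panel.cp(s).sequence for s in unit_panel.spec.species}
        tree = phylo.bootstrap_support(seqs, n_reps=100, seed=1)
        assert tree.support
        assert all(0.0 <= v <= 1.0 for v in tree.support.values())
        assert min(tree.support.values()) > 0.95  # long internal branches

    def test_deterministic_given_seed(self, unit_panel):
        seqs = {s: unit_panel.cp(s).sequence[:2000] for s in unit_panel.spec.species}
        t1 = phylo.bootstrap_support(seqs, n_reps=50, seed=3)
        t2 = phylo.bootstrap_support(seqs, n_reps=50, seed=3)
        assert t1.support == t2.support

    def test_single_variable_site_support_by_enumeration(self):
        """One variable site among L sites: support of the single bipartition
        equals the exhaustively-computed resampling probability."""
        L = 20
        base = "A" * L
        seqs = {
            "a": base,
            "b": base,
            "c": "C" + base[1:],
            "d": "C" + base[1:],
        }
        n_reps = 4000
        tree = phylo.bootstrap_support(seqs, n_reps=n_reps, seed=9)
        bp = frozenset({"c", "d"})
        # replicate tree contains {c,d} iff the variable site is drawn >= 1
        # time; otherwise all distances are 0 and the tie-broken topology
        # still groups the lexicographically smallest pair (a,b) -> {c,d}.
        # Exhaustive: support = 1 exactly.
        assert tree.support[bp] == pytest.approx(1.0)
        # and the point tree has that bipartition
        assert bp in tree.bipartitions()

    def test_support_grows_with_sequence_length(self, unit_panel):
        """Species-edge support increases from a 1 kb to a 7 kb marker."""
        short = {s: unit_panel.cp(s).sequence[:1000] for s in unit_panel.spec.species}
        long = {s: unit_panel.cp(s).sequence[:7000] for s in unit_panel.spec.species}
        t_short = phylo.bootstrap_support(short, n_reps=200, seed=4)
        t_long = phylo.bootstrap_support(long, n_reps=200, seed=4)
        common = set(t_short.support) & set(t_long.support)
        assert common
        mean_short = np.mean([t_short.support[b] for b in common])
        mean_long = np.mean([t_long.support[b] for b in common])
        assert mean_long >= mean_short


class TestAgreement:
    def test_tree_vs_itself_zero(self, unit_panel):
        seqs = {s: unit_panel.cp(s).sequence[:3000] for s in unit_panel.spec.species}
        t = phylo.nj_tree(phylo.pairwise_distances(seqs))
        out = phylo.tree_agreement(t, t)
        assert out["rf"] == 0 and out["normalized_agreement"] == 1.0

    def test_one_nni_is_rf_two(self):
        t1 = phylo.nj_tree(
            phylo.DistanceMatrix(
                list("abcd"),
                np.array([[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], dtype=float),
            )
        )
        t2 = phylo.nj_tree(
            phylo.DistanceMatrix(
                list("abcd"),
                np.array([[0, 6, 2, 6], [6, 0, 6, 2], [2, 6, 0, 6], [6, 2, 6, 0]], dtype=float),
            )
        )
        out = phylo.tree_agreement(t1, t2)
        assert out["rf"] == 2
        # cross-check with dendropy
        assert dendropy_rf(t1.to_newick(), t2.to_newick()) == 2

    def test_rf_matches_dendropy_on_random_trees(self):
        rng = np.random.default_rng(12)
        taxa = [f"t{i}" for i in range(8)]
        for trial in range(5):
            seqs1 = {t: sq.decode(rng.integers(0, 4, 300, dtype=np.uint8)) for t in taxa}
            seqs2 = {t: sq.decode(rng.integers(0, 4, 300, dtype=np.uint8)) for t in taxa}
            t1 = phylo.nj_tree(phylo.pairwise_distances(seqs1, model="p"))
            t2 = phylo.nj_tree(phylo.pairwise_distances(seqs2, model="p"))
            assert phylo.tree_agreement(t1, t2)["rf"] == dendropy_rf(t1.to_newick(), t2.to_newick())

    def test_leaf_set_mismatch_rejected(self, unit_panel):
        seqs = {s: unit_panel.cp(s).sequence[:500] for s in unit_panel.spec.species}
        t1 = phylo.nj_tree(phylo.pairwise_distances(seqs))
        seqs2 = dict(list(seqs.items())[:4])
        t2 = phylo.nj_tree(phylo.pairwise_distances(seqs2))
        with pytest.raises(ValueError):
            phylo.tree_agreement(t1, t2)

    def test_marker_trees_agree_on_species_clusters(self, unit_panel):
        """Barcode, concatenated-CDS and 45S trees group the same strains
        into the same species clusters (the cross-marker agreement claim)."""
        from ulvapop import mapvar as mv

        strains = sim.default_strain_table(unit_panel, 18, hybrid=False, seed=2)
        markers = {"rbcl": {}, "cds": {}, "45s": {}}
        labels = {}
        for s in strains:
            g = sim.simulate_strain_genomes(unit_panel, s)
            markers["rbcl"][s.strain_id] = g.cp.gene_sequence("rbcL")
            markers["cds"][s.strain_id] = mv.extract_concat_cds(g.cp)
            markers["45s"][s.strain_id] = g.r45s_copies[0][0]
            labels[s.strain_id] = s.species_id
        trees = {m: phylo.nj_tree(phylo.pairwise_distances(v)) for m, v in markers.items()}
        for m in ("rbcl", "45s"):
            out = phylo.tree_agreement(trees[m], trees["cds"], species_labels=labels)
            # every species is a clade in every marker tree: identical
            # cluster membership; inter-species resolution may wobble by one
            # rearrangement on the shortest barcodes (as with real markers,
            # where support -- not clustering -- differed between loci)
            assert out["clusters_are_clades_both"], (m, out["cluster_table"])
            assert out["cluster_rf"] <= 2
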