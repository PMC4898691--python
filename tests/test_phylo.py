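"""Distances, neighbor joining, jackknife, consensus, rooting."""

import dendropy
import numpy as np
import pytest

from bbekit import synthetic_data as sd
from bbekit.phylo import (
    KIMURA_D_CAP,
    MSA,
    DistanceMatrix,
    jackknife_msa,
    majority_consensus,
    neighbor_joining,
    nj_newick,
    protein_distance,
    root_with_outgroup,
    run_pipeline,
    tree_bipartitions,
)


def random_tree_and_distances(n_taxa, rng):
    """A random unrooted binary tree with uniform branch lengths and its
    exact leaf-to-leaf path-length (additive) matrix — the NJ consistency
    oracle."""
    taxa = [f"T{i}" for i in range(n_taxa)]

    def blen():
        return float(rng.uniform(0.05, 1.0))

    frags = [f"{t}:{blen():.6f}" for t in taxa]
    while len(frags) > 3:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j), frags.pop(i)
        frags.append(f"({b[1]},{b[0]}):{blen():.6f}")
    newick = f"({frags[0]},{frags[1]},{frags[2]});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            d[i, j] = d[j, i] = pdm.distance(tax[taxa[i]], tax[taxa[j]])
    return tree, DistanceMatrix(tuple(taxa), d)


class TestProteinDistance:
    def test_identical_sequences_have_zero_distance(self):
        msa = MSA(("a", "b"), ("ACDEF", "ACDEF"))
        assert protein_distance(msa).matrix[0, 1] == 0.0

    def test_kimura_closed_form_at_p_0p1(self):
        msa = MSA(("a", "b"), ("A" * 9 + "C", "A" * 10))
        d = protein_distance(msa, model="kimura").matrix[0, 1]
        assert d == pytest.approx(-np.log(1 - 0.1 - 0.1 ** 2 / 5), rel=1e-12)
        assert d == pytest.approx(0.1076, abs=1e-4)

    def test_p_model_is_raw_mismatch_fraction(self):
        msa = MSA(("a", "b"), ("AAAA", "AAAC"))
        assert protein_distance(msa, model="p").matrix[0, 1] == 0.25

    def test_gaps_use_pairwise_deletion(self):
        msa = MSA(("a", "b"), ("AA-CC", "AAGC-"))  # overlap AAC vs AAC
        assert protein_distance(msa, model="p").matrix[0, 1] == 0.0

    def test_saturated_pair_capped_with_warning(self):
        msa = MSA(("a", "b"), ("ACDEFGHIKL", "LKIHGFEDCA"))  # p = 1
        with pytest.warns(UserWarning, match="capping"):
            d = protein_distance(msa).matrix[0, 1]
        assert d == KIMURA_D_CAP

    def test_zero_overlap_pair_rejected(self):
        msa = MSA(("a", "b"), ("AA--", "--CC"))
        with pytest.raises(ValueError, match="overlap"):
            protein_distance(msa)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        assert nj_newick(dm) == "(A:0.5,B:1.5,C:2.5);"

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):3,(C:4,D:5))
        d = np.array([[0, 3, 8, 9], [3, 0, 9, 10],
                      [8, 9, 0, 9], [9, 10, 9, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C", "D"), d))
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert pdm.distance(tax[a], tax[b]) == pytest.approx(
                        d[i, j], abs=1e-9)

    def test_ultrametric_matrix_path_lengths_preserved(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C", "D"), d))
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}
        for a in "ABC":
            for b in "BCD":
                if a < b:
                    assert pdm.distance(tax[a], tax[b]) == pytest.approx(2.0, abs=1e-9)

    def test_additive_reconstruction_property_over_random_trees(self):
        """NJ is consistent on additive matrices: over 100 random 4-8 taxon
        trees the topology and all path lengths are reproduced exactly."""
        rng = np.random.default_rng(99)
        for rep in range(100):
            n = int(rng.integers(4, 9))
            true_tree, dm = random_tree_and_distances(n, rng)
            est = neighbor_joining(dm)
            assert tree_bipartitions(est) == tree_bipartitions(
                true_tree, dm.ids), f"replicate {rep}"
            pdm = est.phylogenetic_distance_matrix()
            tax = {t.label: t for t in est.taxon_namespace}
            for i in range(n):
                for j in range(i + 1, n):
                    assert pdm.distance(tax[dm.ids[i]], tax[dm.ids[j]]) == \
                        pytest.approx(dm.matrix[i, j], abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            nj_newick(dm)

    def test_asymmetric_matrix_rejected_by_container(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))


class TestJackknife:
    def test_fixed_seed_reproducible(self):
        msa = MSA(("a", "b"), ("ACDEFGHIKL", "ACDEFGHIKC"))
        assert jackknife_msa(msa, 0.5, seed=1) == jackknife_msa(msa, 0.5, seed=1)

    def test_keeps_half_the_columns(self):
        msa = MSA(("a",), ("A" * 100,))
        assert jackknife_msa(msa, 0.5, seed=0).length == 50

    def test_single_column_survivor(self):
        msa = MSA(("a", "b"), ("AC", "AC"))
        rep = jackknife_msa(msa, 0.5, seed=0)
        assert rep.length == 1

    def test_column_retention_is_binomial(self):
        """Each column is kept in about half of 400 replicates at f = 0.5
        (binomial 3-sigma band)."""
        msa = MSA(("a",), ("ACDEFGHIKLMNPQRSTVWY",))
        n_rep = 400
        counts = np.zeros(20)
        base = np.array(list(msa.seqs[0]))
        for seed in range(n_rep):
            rep = jackknife_msa(msa, 0.5, seed=seed)
            kept = set()
            it = iter(range(20))
            # columns preserve order; reconstruct which indices survived
            pos = 0
            for ch in rep.seqs[0]:
                while base[pos] != ch:
                    pos += 1
                kept.add(pos)
                pos += 1
            for k in kept:
                counts[k] += 1
        sigma = np.sqrt(n_rep * 0.25)
        assert np.all(np.abs(counts - n_rep / 2) <= 3.5 * sigma)


class TestConsensus:
    def _trees(self, newicks):
        return [dendropy.Tree.get(data=nw, schema="newick") for nw in newicks]

    def test_identical_trees_full_support(self):
        trees = self._trees(["((A,B),((C,D),E));"] * 10)
        cons = majority_consensus(trees)
        assert tree_bipartitions(cons) == tree_bipartitions(trees[0])
        supports = [float(n.label) for n in cons.preorder_internal_node_iter()
                    if n.label]
        assert supports and all(s == 1.0 for s in supports)

    def test_six_vs_four_quartet_conflict(self):
        trees = self._trees(["((A,B),(C,D));"] * 6 + ["((A,C),(B,D));"] * 4)
        cons = majority_consensus(trees)
        assert tree_bipartitions(cons) == {frozenset({"C", "D"})}
        supports = [float(n.label) for n in cons.preorder_internal_node_iter()
                    if n.label]
        assert supports == [pytest.approx(0.6)]

    def test_high_threshold_collapses_to_polytomy(self):
        trees = self._trees(["((A,B),(C,D));"] * 6 + ["((A,C),(B,D));"] * 4)
        cons = majority_consensus(trees, threshold=0.99)
        assert tree_bipartitions(cons) == set()

    def test_mismatched_taxa_rejected(self):
        trees = self._trees(["((A,B),(C,D));", "((A,B),(C,E));"])
        with pytest.raises(ValueError, match="taxon set"):
            majority_consensus(trees)


class TestRooting:
    def test_three_taxon_outgroup_bipartition(self):
        tree = dendropy.Tree.get(data="(A:1,B:2,C:3);", schema="newick")
        rooted = root_with_outgroup(tree, "C")
        kids = rooted.seed_node.child_nodes()
        assert len(kids) == 2
        leafsets = [frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids]
        assert frozenset({"C"}) in leafsets and frozenset({"A", "B"}) in leafsets

    def test_rerooting_is_idempotent(self):
        tree = dendropy.Tree.get(data="(A:1,B:2,C:3);", schema="newick")
        once = root_with_outgroup(tree, "C")
        twice = root_with_outgroup(once, "C")
        assert once.as_string(schema="newick") == twice.as_string(schema="newick")

    def test_unknown_taxon_rejected(self):
        tree = dendropy.Tree.get(data="(A:1,B:2,C:3);", schema="newick")
        with pytest.raises(ValueError, match="not in tree"):
            root_with_outgroup(tree, "Z")

    def test_rooting_preserves_unrooted_bipartitions(self):
        rng = np.random.default_rng(17)
        _, dm = random_tree_and_distances(6, rng)
        tree = neighbor_joining(dm)
        before = tree_bipartitions(tree)
        rooted = root_with_outgroup(tree, dm.ids[0])
        assert tree_bipartitions(rooted) == before


class TestPipeline:
    def test_strong_signal_supports_true_bipartitions(self):
        newick = "((A:0.3,B:0.3):0.4,((C:0.3,D:0.3):0.4,(E:0.3,F:0.3):0.4):0.1);"
        msa, _ = sd.evolve_alignment(newick, 1000, 0.3, seed=3)
        cons = run_pipeline(msa, n_replicates=100, seed=11)
        true = tree_bipartitions(dendropy.Tree.get(data=newick, schema="newick"))
        support = {}
        universe = frozenset(msa.ids)
        ref = sorted(msa.ids)[0]
        for node in cons.preorder_internal_node_iter():
            if node.label:
                below = frozenset(l.taxon.label for l in node.leaf_iter())
                side = universe - below if ref in below else below
                support[side] = float(node.label)
        for bip in true:
            assert support.get(bip, 0.0) >= 0.9, bip

    def test_single_replicate_supports_are_one(self):
        newick = "((A:0.3,B:0.3):0.4,(C:0.3,D:0.3):0.4,(E:0.3,F:0.3):0.4);"
        msa, _ = sd.evolve_alignment(newick, 500, 0.3, seed=4)
        cons = run_pipeline(msa, n_replicates=1, seed=5)
        supports = [float(n.label) for n in cons.preorder_internal_node_iter()
                    if n.label]
        assert supports and all(s == 1.0 for s in supports)

    def test_star_alignment_has_weak_support(self):
        """Alignments evolved on a star tree carry no internal bipartition
        signal, so the consensus must not produce confident edges: mean
        internal support < 0.7 over 10 seeds."""
        star = "(A:0.5,B:0.5,C:0.5,D:0.5,E:0.5,F:0.5);"
        means = []
        for seed in range(10):
            msa, _ = sd.evolve_alignment(star, 200, 0.3, seed=seed)
            cons = run_pipeline(msa, n_replicates=30, seed=seed)
            sup = [float(n.label) for n in cons.preorder_internal_node_iter()
                   if n.label]
            means.append(np.mean(sup) if sup else 0.0)
        assert np.mean(means) < 0.7

    def test_fixed_seed_gives_identical_newick(self):
        newick = "((A:0.3,B:0.3):0.4,(C:0.3,D:0.3):0.4,(E:0.3,F:0.3):0.4);"
        msa, _ = sd.evolve_alignment(newick, 300, 0.3, seed=6)
        t1 = run_pipeline(msa, n_replicates=20, outgroup="A", seed=7)
        t2 = run_pipeline(msa, n_replicates=20, outgroup="A", seed=7)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_outgroup_rooting_in_pipeline(self):
        newick = "((A:0.3,B:0.3):0.4,(C:0.3,D:0.3):0.4,(E:0.3,F:0.3):0.4);"
        msa, _ = sd.evolve_alignment(newick, 500, 0.3, seed=8)
        cons = run_pipeline(msa, n_replicates=20, outgroup="F", seed=9)
        kids = cons.seed_node.child_nodes()
        leafsets = [frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids]
        assert frozenset({"F"}) in leafsets
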