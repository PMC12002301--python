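"""Distance matrices, neighbor joining, bootstrap, and clade tests."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from bombemine.align import Alignment
from bombemine.phylo import (bipartitions, bootstrap_support,
                             distance_matrix, is_in_clade_with, nj_tree,
                             read_newick, root_on_outgroup, write_newick)


def random_additive_matrix(n_taxa, rng):
    """Random binary tree with positive branch lengths -> path-length
    distance matrix plus the generating bipartition set (the oracle)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = {lab: dendropy.Node(
        taxon=dendropy.Taxon(label=lab)) for lab in labels}
    for node in nodes.values():
        node.edge.length = float(rng.uniform(0.05, 1.0))
    active = list(labels)
    tns = dendropy.TaxonNamespace([nodes[l].taxon for l in labels])
    k = 0
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[j], active[i]
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.05, 1.0))
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        name = f"_i{k}"
        k += 1
        nodes[name] = parent
        active = [x for x in active if x not in (a, b)] + [name]
    root = dendropy.Node()
    for lab in active:
        root.add_child(nodes[lab])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    dm = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in labels:
        for b in labels:
            if a != b:
                dm.loc[a, b] = pdm.distance(tns.get_taxon(a),
                                            tns.get_taxon(b))
    return dm, bipartitions(tree)


class TestDistanceMatrix:
    def _msa(self, rows):
        return Alignment(rows=rows)

    def test_identical_rows_zero(self):
        dm = distance_matrix(self._msa([("a", "GPTY"), ("b", "GPTY"),
                                        ("c", "GPTY")]))
        assert np.allclose(dm.values, 0.0)

    def test_kimura_formula(self):
        # 1 mismatch in 10 compared columns -> p=0.1
        rows = [("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAC"),
                ("c", "AAAAAAAAAA")]
        dm = distance_matrix(self._msa(rows), correction="kimura_protein")
        expected = -math.log(1 - 0.1 - 0.2 * 0.01)
        assert dm.loc["a", "b"] == pytest.approx(expected, abs=1e-9)
        assert dm.loc["a", "b"] == pytest.approx(0.10758, abs=1e-4)

    def test_pairwise_gap_deletion(self):
        rows = [("a", "G-TY"), ("b", "GPTY"), ("c", "GPTA")]
        dm = distance_matrix(self._msa(rows))
        assert dm.loc["a", "b"] == 0.0          # 3 compared, 0 mismatch
        assert dm.loc["b", "c"] == pytest.approx(0.25)

    def test_saturation_capped_with_warning(self):
        rows = [("a", "AAAAAAAAAA"), ("b", "CCCCCCCCCC"),
                ("c", "AAAAAAAAAA")]
        with pytest.warns(UserWarning, match="capping"):
            dm = distance_matrix(self._msa(rows), correction="kimura_protein")
        assert np.isfinite(dm.loc["a", "b"])

    def test_zero_overlap_rejected(self):
        rows = [("a", "GP--"), ("b", "--TY"), ("c", "GPTY")]
        with pytest.raises(ValueError):
            distance_matrix(self._msa(rows))


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        dm = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float)
        tree = nj_tree(dm)
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        # additivity: recovered path lengths reproduce the matrix
        pdm = tree.phylogenetic_distance_matrix()
        tns = tree.taxon_namespace
        for a in "ABCD":
            for b in "ABCD":
                if a != b:
                    assert pdm.distance(tns.get_taxon(a), tns.get_taxon(b)) \
                        == pytest.approx(dm.loc[a, b])

    def test_three_taxa_closed_form(self):
        dm = pd.DataFrame([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                          index=list("abc"), columns=list("abc"), dtype=float)
        tree = nj_tree(dm)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 3.0})

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(7)
        for trial in range(40):
            n = int(rng.integers(4, 9))
            dm, truth_bps = random_additive_matrix(n, rng)
            got = bipartitions(nj_tree(dm))
            assert got == truth_bps, f"trial {trial}, n={n}"

    def test_matches_independent_nj_implementation(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(3)
        dm, _ = random_additive_matrix(6, rng)
        ours = bipartitions(nj_tree(dm))
        sk_tree = skbio_nj(SkbioDM(dm.values, ids=list(dm.index)))
        sk = dendropy.Tree.get(data=str(sk_tree), schema="newick")
        assert ours == bipartitions(sk)

    def test_asymmetric_matrix_rejected(self):
        dm = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                          index=list("abc"), columns=list("abc"), dtype=float)
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_ultrametric_agrees_with_upgma(self):
        from scipy.cluster.hierarchy import linkage, to_tree
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(11)
        # build an ultrametric matrix from a random UPGMA-style hierarchy
        dm, _ = random_additive_matrix(6, rng)
        # ultrametrize: cophenetic distances of average-linkage clustering
        Z = linkage(squareform(dm.values, checks=False), method="average")
        from scipy.cluster.hierarchy import cophenet
        um = pd.DataFrame(squareform(cophenet(Z)), index=dm.index,
                          columns=dm.columns)
        nj_bps = bipartitions(nj_tree(um))

        def upgma_bipartitions(Z, labels):
            tree_root = to_tree(Z)
            out = set()
            all_set = frozenset(labels)
            ref = min(all_set)

            def leaves(node):
                if node.is_leaf():
                    return frozenset([labels[node.id]])
                return leaves(node.left) | leaves(node.right)

            def walk(node):
                if node.is_leaf():
                    return
                below = leaves(node)
                side = all_set - below if ref in below else below
                if 1 < len(side) < len(all_set) - 1:
                    out.add(side)
                walk(node.left)
                walk(node.right)

            walk(tree_root)
            return out

        assert nj_bps == upgma_bipartitions(Z, list(dm.index))


def two_clade_msa(seed=1, n_cols=200):
    rng = np.random.default_rng(seed)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    base1 = "".join(rng.choice(aa, n_cols))
    base2 = "".join(rng.choice(aa, n_cols))

    def mutate(s, n):
        s = list(s)
        for i in rng.choice(len(s), n, replace=False):
            s[i] = rng.choice(aa)
        return "".join(s)

    rows = [("a1", mutate(base1, 5)), ("a2", mutate(base1, 5)),
            ("a3", mutate(base1, 5)), ("b1", mutate(base2, 5)),
            ("b2", mutate(base2, 5))]
    return Alignment(rows=rows)


class TestBootstrap:
    def test_clean_split_high_support(self):
        msa = two_clade_msa()
        _, support = bootstrap_support(msa, n_reps=100, seed=5)
        assert support[frozenset({"b1", "b2"})] >= 0.95

    def test_single_replicate_support_binary(self):
        msa = two_clade_msa()
        _, support = bootstrap_support(msa, n_reps=1, seed=2)
        assert set(support.values()) <= {0.0, 1.0}

    def test_seed_determinism(self):
        msa = two_clade_msa()
        _, s1 = bootstrap_support(msa, n_reps=20, seed=9)
        _, s2 = bootstrap_support(msa, n_reps=20, seed=9)
        assert s1 == s2

    def test_leaf_order_permutation_invariance(self):
        msa = two_clade_msa()
        perm = Alignment(rows=list(reversed(msa.rows)))
        _, s1 = bootstrap_support(msa, n_reps=25, seed=4)
        _, s2 = bootstrap_support(perm, n_reps=25, seed=4)
        assert set(s1) == set(s2)


class TestCladeTest:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_query_groups_with_references(self):
        t = self._tree("((q:1,(r1:1,r2:1):1):1,(c1:1,c2:1):1,out:3);")
        ok, clade = is_in_clade_with(t, "q", ["r1", "r2"], ["out"])
        assert ok and clade == {"q", "r1", "r2"}

    def test_query_sister_to_contrast(self):
        t = self._tree("(((q:1,c1:1):1,c2:1):1,(r1:1,r2:1):1,out:3);")
        ok, clade = is_in_clade_with(t, "q", ["r1", "r2"], ["out"])
        assert not ok

    def test_all_non_outgroup_reference_vacuously_true(self):
        t = self._tree("((q:1,c1:1):1,(r1:1,r2:1):1,out:3);")
        ok, _ = is_in_clade_with(t, "q", ["r1", "r2", "c1"], ["out"])
        assert ok

    def test_query_in_outgroup_rejected(self):
        t = self._tree("((q:1,r1:1):1,r2:1,out:3);")
        with pytest.raises(ValueError):
            is_in_clade_with(t, "out", ["r1"], ["out"])

    def test_midpoint_fallback_without_outgroup(self):
        t = self._tree("((a:1,b:1):1,(c:1,d:5):1);")
        rooted = root_on_outgroup(t, [])
        assert rooted.seed_node is not None


def test_newick_round_trip(tmp_path):
    msa = two_clade_msa()
    tree, support = bootstrap_support(msa, n_reps=10, seed=1)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    assert bipartitions(back) == bipartitions(tree)
    orig = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    rt = {lf.taxon.label: lf.edge.length for lf in back.leaf_node_iter()}
    for k in orig:
        assert rt[k] == pytest.approx(orig[k], abs=1e-9)
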