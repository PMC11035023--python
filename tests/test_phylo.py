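import math

import dendropy
import numpy as np
import pytest

from chemorep.phylo import (
    DistanceMatrix,
    bootstrap_support,
    nj_tree,
    node_support,
    pc_distance_matrix,
    read_newick,
    tree_bipartitions,
    write_newick,
)


class TestPCDistance:
    def test_identical_pair_zero(self):
        dm = pc_distance_matrix({"a": "MKLV", "b": "MKLV"})
        assert dm.matrix[0, 1] == 0.0

    def test_half_different_analytic(self):
        dm = pc_distance_matrix({"a": "AAAA", "b": "AATT"})
        assert dm.matrix[0, 1] == pytest.approx(-math.log(0.5), abs=1e-4)

    def test_pairwise_deletion_hand_count(self):
        # 10 columns, 2 gapped, 2 mismatches among the 8 compared
        a = "AAAAAAAA-A"
        b = "AATTAAAAA-"
        dm = pc_distance_matrix({"a": a, "b": b})
        assert dm.matrix[0, 1] == pytest.approx(-math.log(1 - 0.25), abs=1e-4)

    def test_saturation_is_error_naming_pair(self):
        with pytest.raises(ValueError, match="seqY"):
            pc_distance_matrix({"seqX": "AAAA", "seqY": "TTTT"})

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(ValueError, match="no comparable"):
            pc_distance_matrix({"a": "AA--", "b": "--AA"})

    def test_distance_dominates_p_difference(self):
        # PC correction always stretches: d >= p for p in (0, 1)
        for p in (0.1, 0.3, 0.5, 0.7):
            assert -math.log(1 - p) >= p


class TestNJ:
    def test_additive_four_taxon_split_recovered(self):
        # tips 0.1, internal edge 0.2: d_AB = d_CD = 0.2, cross pairs 0.4
        ids = ["A", "B", "C", "D"]
        m = np.array([
            [0.0, 0.2, 0.4, 0.4],
            [0.2, 0.0, 0.4, 0.4],
            [0.4, 0.4, 0.0, 0.2],
            [0.4, 0.4, 0.2, 0.0],
        ])
        tree = nj_tree(DistanceMatrix(ids, m))
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.head_node is not tree.seed_node
                    and not e.head_node.is_leaf()]
        assert internal == pytest.approx([0.2])

    def test_three_taxa_tip_lengths(self):
        ids = ["A", "B", "C"]
        m = np.array([[0, 0.2, 0.3], [0.2, 0, 0.3], [0.3, 0.3, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids, m))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.1)
        assert lengths["C"] == pytest.approx(0.2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))

    def test_random_additive_matrices_recover_topology(self):
        # oracle: the generating tree's bipartitions; additive distances are
        # exact path lengths, which NJ provably inverts
        rng = np.random.default_rng(77)
        for rep in range(25):
            n = int(rng.integers(4, 9))
            tree = _random_tree(rng, n)
            dm = _path_distance_matrix(tree)
            rebuilt = nj_tree(dm)
            assert tree_bipartitions(rebuilt) == tree_bipartitions(tree)

    def test_equal_distance_matrix_gives_zero_internal_edges(self):
        ids = list("ABCD")
        m = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(DistanceMatrix(ids, m))
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.head_node is not tree.seed_node
                    and not e.head_node.is_leaf()]
        assert all(abs(l) < 1e-12 for l in internal)

    def test_agrees_with_independent_nj_implementation(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        tree = _random_tree(rng, 7)
        dm = _path_distance_matrix(tree)
        ours = tree_bipartitions(nj_tree(dm))
        import io

        sk_tree = skbio_nj(SkbioDM(dm.matrix, ids=dm.ids))
        buf = io.StringIO()
        sk_tree.write(buf)
        theirs = tree_bipartitions(read_newick(buf.getvalue()))
        assert ours == theirs


def _random_tree(rng, n):
    taxa = [f"t{i}" for i in range(n)]
    nodes = [dendropy.Node() for _ in taxa]
    ns = dendropy.TaxonNamespace(taxa)
    for node, label in zip(nodes, taxa):
        node.taxon = ns.get_taxon(label)
        node.edge.length = float(rng.uniform(0.05, 0.5))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        p = dendropy.Node()
        p.add_child(a)
        p.add_child(b)
        p.edge.length = float(rng.uniform(0.05, 0.5))
        nodes.append(p)
    root = dendropy.Node()
    for x in nodes:
        root.add_child(x)
    t = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    t.is_rooted = False
    return t


def _path_distance_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    ids = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
    return DistanceMatrix(ids, m)


class TestBootstrap:
    # constant right-hand block keeps every pair below saturation
    ALN = {
        "A": "AAAAAGGGGG",
        "B": "AAAATGGGGG",
        "C": "TTTTAGGGGG",
        "D": "TTTTTGGGGG",
    }

    def test_uniform_signal_gives_full_support(self):
        aln = {
            "A": "A" * 15 + "G" * 15,
            "B": "A" * 15 + "G" * 14 + "C",
            "C": "T" * 15 + "G" * 14 + "A",
            "D": "T" * 15 + "G" * 15,
        }
        tree = bootstrap_support(aln, n_reps=50, seed=1)
        sups = [node_support(n) for n in tree.preorder_internal_node_iter()
                if n.parent_node is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_single_replicate_support_is_zero_or_hundred(self):
        tree = bootstrap_support(self.ALN, n_reps=1, seed=3)
        sups = [node_support(n) for n in tree.preorder_internal_node_iter()
                if n.parent_node is not None]
        assert all(s in (0.0, 100.0) for s in sups)

    def test_fixed_seed_reproducible(self):
        t1 = bootstrap_support(self.ALN, n_reps=20, seed=7)
        t2 = bootstrap_support(self.ALN, n_reps=20, seed=7)
        assert write_newick(t1) == write_newick(t2)

    def test_leaf_order_permutation_invariant_supports(self):
        perm = {k: self.ALN[k] for k in ["D", "B", "A", "C"]}
        s1 = _support_by_bipartition(bootstrap_support(self.ALN, 40, seed=9))
        s2 = _support_by_bipartition(bootstrap_support(perm, 40, seed=9))
        assert s1 == s2


def _support_by_bipartition(tree):
    from chemorep.phylo import _internal_nodes_with_bipartitions

    return {bip: node_support(n) for n, bip in _internal_nodes_with_bipartitions(tree)}


class TestNewickIO:
    def test_supports_read_as_internal_labels(self):
        t = read_newick("((a,b)95,(c,d)80);")
        sups = sorted(node_support(n) for n in t.preorder_internal_node_iter()
                      if n.parent_node is not None)
        assert sups == [80.0, 95.0]

    def test_round_trip(self, tmp_path):
        t = read_newick("((a:1,b:2)90:0.5,c:3);")
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        t2 = read_newick(p)
        assert tree_bipartitions(t) == tree_bipartitions(t2)
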