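import itertools

import numpy as np
import pytest

from repeatst.cluster_phylo import (DistanceMatrix, TreeNode, bipartitions,
                                    bootstrap_support,
                                    identity_distance_matrix, nj_tree,
                                    pairwise_distance)


def additive_matrix(split, pendant, internal):
    """Distance matrix of the quartet tree (xy)|(zw) with given pendant
    branch lengths and internal edge length (construction oracle)."""
    (x, y), (z, w) = split
    labels = sorted([x, y, z, w])
    m = np.zeros((4, 4))
    for a, b in itertools.combinations(labels, 2):
        same = {a, b} in ({x, y}, {z, w})
        d = pendant[a] + pendant[b] + (0 if same else internal)
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


class TestPairwiseDistance:
    def test_identical_zero(self):
        assert pairwise_distance("AAAA", "AAAA") == 0.0

    def test_single_mismatch(self):
        assert pairwise_distance("AAAA", "AATA") == pytest.approx(0.25)

    def test_disjoint_alphabets_near_one(self):
        assert pairwise_distance("AAAAAAAA", "TTTTTTTT") >= 0.99

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pairwise_distance("", "AAA")


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[1, 1], [1, 0]], float))

    def test_phylip_round_shape(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]))
        text = dm.to_phylip()
        assert text.splitlines()[0] == "2"


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(["x", "y", "z"], m))
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == pytest.approx({"x": 1.0, "y": 2.0, "z": 3.0})

    def test_exhaustive_quartet_topologies(self):
        rng = np.random.default_rng(42)
        taxa = ["a", "b", "c", "d"]
        quartets = [(("a", "b"), ("c", "d")), (("a", "c"), ("b", "d")),
                    (("a", "d"), ("b", "c"))]
        for split in quartets:
            for _ in range(10):
                pendant = {t: float(rng.uniform(0.5, 3.0)) for t in taxa}
                internal = float(rng.uniform(1.0, 4.0))
                dm = additive_matrix(split, pendant, internal)
                tree = nj_tree(dm)
                expected = frozenset([frozenset(split[0]), frozenset(split[1])])
                assert expected in bipartitions(tree)

    def test_additive_branch_lengths_recovered(self):
        split = (("a", "b"), ("c", "d"))
        pendant = {"a": 1.0, "b": 2.0, "c": 1.5, "d": 2.5}
        tree = nj_tree(additive_matrix(split, pendant, 3.0))
        for leaf in tree.leaves():
            assert leaf.length == pytest.approx(pendant[leaf.name])

    def test_identical_sequences_form_zero_length_cherry(self):
        seqs = {"a": "AAAAAAAA", "b": "AAAAAAAA", "c": "TTTTTTTT", "d": "TTTTGGGG"}
        tree = nj_tree(DistanceMatrix.from_sequences(seqs))
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["a"] == pytest.approx(0.0, abs=1e-12)
        assert lengths["b"] == pytest.approx(0.0, abs=1e-12)
        assert frozenset([frozenset("ab"), frozenset("cd")]) in bipartitions(tree)

    def test_deterministic_under_ties(self):
        m = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(DistanceMatrix(list("abcd"), m.copy()))
        t2 = nj_tree(DistanceMatrix(list("abcd"), m.copy()))
        assert t1.newick() == t2.newick()

    def test_fewer_than_three_raises(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_matches_skbio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        n = 6
        # random additive-ish symmetric matrix
        coords = rng.uniform(0, 5, size=(n, 3))
        m = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        labels = [f"t{i}" for i in range(n)]
        mine = nj_tree(DistanceMatrix(labels, m))
        ref = skbio.tree.nj(skbio.DistanceMatrix(m, ids=labels))
        ref_splits = set()
        all_leaves = frozenset(labels)
        for node in ref.non_tips():
            clade = frozenset(t.name for t in node.tips())
            if 1 < len(clade) < n - 1:
                ref_splits.add(frozenset([clade, all_leaves - clade]))
        assert bipartitions(mine) == ref_splits


class TestBootstrap:
    ALIGNED = {"a": "AAAAAAAAGG", "b": "AAAAAAAAGT", "c": "TTTTTTTTGG",
               "d": "TTTTTTTTGT"}

    def test_fixed_seed_reproducible(self):
        t1 = bootstrap_support(self.ALIGNED, n_replicates=50, seed=9)
        t2 = bootstrap_support(self.ALIGNED, n_replicates=50, seed=9)
        assert t1.newick() == t2.newick()

    def test_single_replicate_supports_binary(self):
        tree = bootstrap_support(self.ALIGNED, n_replicates=1, seed=0)
        supports = [n.support for n in _internal(tree) if n.support is not None]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_clear_split_high_support(self):
        tree = bootstrap_support(self.ALIGNED, n_replicates=200, seed=1)
        target = frozenset([frozenset("ab"), frozenset("cd")])
        for node in _internal(tree):
            clade = frozenset(node.leaf_names())
            rest = frozenset(tree.leaf_names()) - clade
            if frozenset([clade, rest]) == target:
                assert node.support > 95
                return
        pytest.fail("expected split not in tree")

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.ALIGNED, n_replicates=0, seed=0)

    def test_identity_matrix_subsampling(self):
        dm = identity_distance_matrix(self.ALIGNED, columns=[0, 1, 2, 3])
        i, j = dm.labels.index("a"), dm.labels.index("c")
        assert dm.matrix[i, j] == pytest.approx(1.0)


def _internal(tree: TreeNode):
    out = []

    def walk(n):
        if not n.is_leaf():
            out.append(n)
            for c in n.children:
                walk(c)

    walk(tree)
    return out


class TestSyntheticClades:
    def test_leaves_group_by_template(self):
        from repeatst.synthetic_data import GeneratorConfig, generate_family
        templates = [GeneratorConfig(st_type="I", repeat_len=25, n_repeats=5),
                     GeneratorConfig(st_type="IIa", repeat_len=26, n_repeats=7)]
        records, truths = generate_family(4, 2, templates, seed=5)
        dm = DistanceMatrix.from_sequences({r.id: r.residues for r in records})
        tree = nj_tree(dm)
        clades = {t.seq_id: t.clade for t in truths}
        group0 = frozenset(sid for sid, c in clades.items() if c == "clade0")
        group1 = frozenset(sid for sid, c in clades.items() if c == "clade1")
        assert frozenset([group0, group1]) in bipartitions(tree)
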