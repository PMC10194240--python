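"""Pairwise distances, neighbor joining and the two-group separation test."""

import itertools

import numpy as np
import pytest

import dendropy

from talscan.phylo import (
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    additive_matrix_from_tree,
    distance_matrix,
    neighbor_joining,
    pairwise_distance,
    two_group_separation,
)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("ACDEFG", "ACDEFG", 0.0),
        ("ACDEFG", "ACDEFA", 1 / 6),
    ],
)
def test_pairwise_distance_examples(a, b, expected):
    assert pairwise_distance(a, b) == pytest.approx(expected)


def test_pairwise_distance_symmetric_zero_diagonal():
    seqs = ["MKLVVTADEQ", "MKLVVSADEQ", "AAAWWWYYYH"]
    dm = distance_matrix(["a", "b", "c"], seqs)
    assert np.allclose(dm.d, dm.d.T)
    assert np.allclose(np.diag(dm.d), 0.0)
    assert pairwise_distance(seqs[0], seqs[0]) == 0.0


def test_three_taxa_closed_form_branch_lengths():
    """For 3 taxa the unrooted tree is unique and branch lengths follow the
    three-point formulas la = (dab + dac − dbc)/2 etc."""
    d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
    tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
    lengths = {frozenset(clade): ln for clade, ln in tree.edges()}
    assert lengths[frozenset({"a"})] == pytest.approx((4 + 6 - 8) / 2)
    assert lengths[frozenset({"b"})] == pytest.approx((4 + 8 - 6) / 2)
    assert lengths[frozenset({"c"})] == pytest.approx((6 + 8 - 4) / 2)


def test_nj_recovers_quartet_topology_from_additive_distances():
    """((a,b),(c,d)) additive distances → the ab|cd split, not the two
    alternative quartets."""
    d = np.array([[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]], float)
    tree = neighbor_joining(DistanceMatrix(list("abcd"), d))
    splits = {frozenset(c) for c, _ in tree.edges() if 1 < len(c) < 3}
    assert frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits
    # four-point condition oracle: ab|cd is the (strictly) smallest pairing
    s_ab = d[0, 1] + d[2, 3]
    s_ac = d[0, 2] + d[1, 3]
    s_ad = d[0, 3] + d[1, 2]
    assert s_ab < min(s_ac, s_ad)


def _random_additive(rng, n):
    """Random binary tree on n leaves with positive branch lengths."""
    nodes = [TreeNode(label=f"t{i}") for i in range(n)]
    lengths = {id(nd): float(rng.uniform(0.05, 1.0)) for nd in nodes}
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode(children=[(b, lengths[id(b)]), (a, lengths[id(a)])])
        lengths[id(parent)] = float(rng.uniform(0.05, 1.0))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=[(nd, lengths[id(nd)]) for nd in nodes])
    return PhyloTree(root=root)


def test_nj_reconstructs_additive_matrices_exactly():
    """On additive matrices (n ≤ 8) NJ reproduces all path distances to
    1e-9, which by tree-metric uniqueness fixes the topology."""
    rng = np.random.default_rng(7)
    for n in (4, 5, 6, 8):
        truth = _random_additive(rng, n)
        dm = additive_matrix_from_tree(truth)
        rec = neighbor_joining(dm)
        dm2 = additive_matrix_from_tree(rec)
        assert dm2.labels == dm.labels
        assert np.allclose(dm2.d, dm.d, atol=1e-9)


def test_nj_quartet_splits_match_four_point_oracle():
    """Every induced quartet split agrees with the four-point condition."""
    rng = np.random.default_rng(13)
    truth = _random_additive(rng, 6)
    dm = additive_matrix_from_tree(truth)
    tree = neighbor_joining(dm)
    clades = [set(c) for c, _ in tree.edges()]
    labels = dm.labels
    idx = {l: i for i, l in enumerate(labels)}
    d = dm.d
    for quartet in itertools.combinations(labels, 4):
        a, b, c, e = quartet
        sums = {
            frozenset([frozenset([a, b]), frozenset([c, e])]): d[idx[a], idx[b]] + d[idx[c], idx[e]],
            frozenset([frozenset([a, c]), frozenset([b, e])]): d[idx[a], idx[c]] + d[idx[b], idx[e]],
            frozenset([frozenset([a, e]), frozenset([b, c])]): d[idx[a], idx[e]] + d[idx[b], idx[c]],
        }
        oracle_split = min(sums, key=lambda k: sums[k])
        # the tree induces the quartet split whose pairs are separated by some edge
        induced = None
        for clade in clades:
            inside = set(quartet) & clade
            if len(inside) == 2:
                pair = frozenset(inside)
                other = frozenset(set(quartet) - inside)
                induced = frozenset([pair, other])
                break
        assert induced == oracle_split


def test_equal_distances_resolve_deterministically():
    d = np.ones((4, 4)) - np.eye(4)
    t1 = neighbor_joining(DistanceMatrix(list("abcd"), d))
    t2 = neighbor_joining(DistanceMatrix(list("abcd"), d))
    assert t1.to_newick() == t2.to_newick()
    lengths = [ln for _, ln in t1.edges()]
    assert all(ln >= 0 for ln in lengths)


def test_nj_input_validation():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b", "c"], np.arange(9.0).reshape(3, 3))


@pytest.mark.parametrize(
    "mapping, expected",
    [
        ({"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"}, True),
        ({"a1": "g2", "a2": "g1", "b1": "g2", "b2": "g1"}, False),
    ],
)
def test_two_group_separation_on_quartet(mapping, expected):
    d = np.array([[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]], float)
    tree = neighbor_joining(DistanceMatrix(["a1", "a2", "b1", "b2"], d))
    ok, edge = two_group_separation(tree, mapping)
    assert ok is expected
    assert (edge is not None) is expected


def test_two_divergent_seed_families_separate():
    """Sequences generated from two divergent seeds split cleanly, as the
    podovirus/myovirus NLPC/P60 groups do."""
    rng = np.random.default_rng(21)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seed1 = "".join(rng.choice(aas, size=60))
    seed2 = "".join(rng.choice(aas, size=60))

    def mutate(seq, k):
        s = list(seq)
        for pos in rng.choice(len(s), size=k, replace=False):
            s[pos] = str(rng.choice(aas))
        return "".join(s)

    labels, seqs, mapping = [], [], {}
    for i in range(4):
        labels.append(f"podo{i}")
        seqs.append(mutate(seed1, 4))
        mapping[f"podo{i}"] = "group1"
        labels.append(f"myo{i}")
        seqs.append(mutate(seed2, 4))
        mapping[f"myo{i}"] = "group2"
    tree = neighbor_joining(distance_matrix(labels, seqs))
    ok, _ = two_group_separation(tree, mapping)
    assert ok


def test_newick_roundtrip_preserves_leaves_and_lengths():
    rng = np.random.default_rng(3)
    truth = _random_additive(rng, 6)
    newick = neighbor_joining(additive_matrix_from_tree(truth)).to_newick()
    parsed = dendropy.Tree.get(data=newick, schema="newick")
    leaves = {lf.taxon.label for lf in parsed.leaf_node_iter()}
    assert leaves == {f"t{i}" for i in range(6)}
    total_len = sum(e.length for e in parsed.edges() if e.length)
    expected = sum(ln for _, ln in neighbor_joining(additive_matrix_from_tree(truth)).edges())
    assert total_len == pytest.approx(expected, abs=1e-4)


def test_quoted_labels_in_newick():
    tree = PhyloTree(root=TreeNode(children=[
        (TreeNode(label="a b"), 1.0), (TreeNode(label="c(d)"), 1.0), (TreeNode(label="e"), 1.0)]))
    nwk = tree.to_newick()
    assert "'a b'" in nwk and "'c(d)'" in nwk
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert {lf.taxon.label for lf in parsed.leaf_node_iter()} == {"a b", "c(d)", "e"}
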