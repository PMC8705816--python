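"""Intergenomic distance formulas, NJ additivity, rooting, link clustering."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from bifiphage.phylogeny import (
    LinkClusterConfig,
    gbdp_distance,
    gbdp_matrices,
    link_clusters,
    midpoint_root,
    nj_tree,
)


def test_distance_formulas_on_trivial_pairs():
    rng = np.random.default_rng(1)
    a = "".join(rng.choice(list("ACGT"), 2_000))
    r = gbdp_distance(a, a)
    assert (r.d0, r.d4, r.d6) == (0.0, 0.0, 0.0)
    r = gbdp_distance("A" * 500, "C" * 500)
    assert (r.d0, r.d4, r.d6) == (1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        gbdp_distance("", "ACGT")


def test_distance_formulas_hand_computed_hsp():
    """1,000 bp sequences sharing a single 500-column HSP with 450 identical
    columns: d0 = 1 - 2*500/2000, d4 = 1 - 450/500, d6 = 1 - 2*450/2000."""
    rng = np.random.default_rng(3)
    common = "".join(rng.choice(list("ACGT"), 500))
    mut = list(common)
    for p in range(15, 15 + 50 * 9, 9):  # 50 interior substitutions
        mut[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[p]]
    a = "A" * 250 + common + "A" * 250
    b = "C" * 250 + "".join(mut) + "C" * 250
    r = gbdp_distance(a, b)
    assert r.n_hsps == 1 and r.total_length == 500 and r.total_identities == 450
    assert r.d0 == pytest.approx(0.5, abs=1e-12)
    assert r.d4 == pytest.approx(0.1, abs=1e-12)
    assert r.d6 == pytest.approx(0.55, abs=1e-12)


def test_distances_symmetric_and_bounded():
    rng = np.random.default_rng(4)
    seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 1_500)) for i in range(3)}
    seqs["s3"] = seqs["s0"][:750] + "".join(rng.choice(list("ACGT"), 750))
    mats = gbdp_matrices(seqs)
    for f, df in mats.items():
        m = df.to_numpy()
        assert np.allclose(m, m.T)
        assert (m >= 0).all() and (m <= 1).all()
        assert np.allclose(np.diag(m), 0.0)


def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    return lambda x, y: pdm.patristic_distance(tax[x], tax[y])


def _additive_matrix_from_newick(newick, labels):
    t = dendropy.Tree.get(data=newick, schema="newick")
    dist = _patristic(t)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dist(labels[i], labels[j])
    return pd.DataFrame(m, index=labels, columns=labels)


@pytest.mark.parametrize(
    "newick,labels",
    [
        ("((A:2,B:3):1,(C:4,D:5):2);", ["A", "B", "C", "D"]),
        (
            "(((A:1.5,B:0.7):0.9,(C:2.2,(D:0.4,E:1.1):0.6):0.3):0.8,(F:1.9,(G:0.2,H:2.4):1.3):0.5);",
            list("ABCDEFGH"),
        ),
    ],
)
def test_nj_recovers_additive_matrices_exactly(newick, labels):
    """NJ on an additive matrix reproduces every leaf-to-leaf distance."""
    matrix = _additive_matrix_from_newick(newick, labels)
    tree = nj_tree(matrix)
    dist = _patristic(tree)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            assert dist(labels[i], labels[j]) == pytest.approx(matrix.iloc[i, j], abs=1e-9)


def test_nj_agrees_with_dendropy_topology():
    labels = list("ABCDEF")
    newick = "((A:1,(B:2,C:1.2):0.8):0.5,(D:0.9,(E:1.4,F:0.3):0.7):0.4);"
    matrix = _additive_matrix_from_newick(newick, labels)
    mine = nj_tree(matrix)

    csv = "," + ",".join(labels) + "\n"
    for a in labels:
        csv += a + "," + ",".join(str(matrix.loc[a, b]) for b in labels) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=__import__("io").StringIO(csv), taxon_namespace=mine.taxon_namespace
    )
    ref = pdm.nj_tree()
    d = dendropy.calculate.treecompare.symmetric_difference(
        mine.clone(depth=1), ref.clone(depth=1)
    )
    assert d == 0


def test_nj_three_taxa_closed_form():
    m = pd.DataFrame(
        [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
    )
    tree = nj_tree(m)
    dist = _patristic(tree)
    assert dist("A", "B") == pytest.approx(0.2, abs=1e-12)
    assert dist("A", "C") == pytest.approx(0.3, abs=1e-12)
    assert dist("B", "C") == pytest.approx(0.4, abs=1e-12)
    with pytest.raises(ValueError):
        nj_tree(m.iloc[:2, :2])


def test_ultrametric_pairs_form_cherries():
    m = pd.DataFrame(
        [
            [0.0, 0.1, 1.0, 1.0],
            [0.1, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 0.1],
            [1.0, 1.0, 0.1, 0.0],
        ],
        index=list("ABCD"),
        columns=list("ABCD"),
    )
    tree = nj_tree(m)
    tree.encode_bipartitions()
    splits = {frozenset(leaf.taxon.label for leaf in e.head_node.leaf_iter()) for e in tree.edges()}
    assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits


def test_midpoint_rooting_properties():
    # symmetric two-leaf tree: root equidistant from both leaves
    two = dendropy.Tree.get(data="(A:1.0,B:1.0);", schema="newick")
    rooted = midpoint_root(two)
    depths = sorted(rooted.calc_node_root_distances(return_leaf_distances_only=True))
    assert depths == pytest.approx([1.0, 1.0])

    # caterpillar with one long pendant edge: the root lies on that edge
    cat = dendropy.Tree.get(data="((((A:0.1,B:0.1):0.1,C:0.1):0.1,D:0.1):0.1,E:5.0);", schema="newick")
    rooted = midpoint_root(cat)
    kids = rooted.seed_node.child_nodes()
    assert any(k.is_leaf() and k.taxon.label == "E" for k in kids)
    rooted.calc_node_root_distances()
    leaf_depths = {
        leaf.taxon.label: leaf.root_distance for leaf in rooted.leaf_node_iter()
    }
    assert max(leaf_depths.values()) == pytest.approx(leaf_depths["E"])

    once = midpoint_root(cat)
    twice = midpoint_root(once)
    assert once.as_string(schema="newick") == twice.as_string(schema="newick")


def _dist_df(groups, within, cross_close, t=0.2, far=0.9):
    """Two groups with the given number of cross pairs <= t."""
    ids = [f"{g}{i}" for g, n in groups for i in range(n)]
    n = len(ids)
    m = np.full((n, n), far)
    np.fill_diagonal(m, 0.0)
    sizes = [n_ for _, n_ in groups]
    a = list(range(sizes[0]))
    b = list(range(sizes[0], n))
    for i in a:
        for j in a:
            if i != j:
                m[i, j] = within
    for i in b:
        for j in b:
            if i != j:
                m[i, j] = within
    placed = 0
    for i in a:
        for j in b:
            if placed < cross_close:
                m[i, j] = m[j, i] = t - 0.05
                placed += 1
    return pd.DataFrame(m, index=ids, columns=ids)


def test_link_clusters_fusion_rule():
    cfg = LinkClusterConfig(threshold=0.2, link_fraction=0.5)
    # 5 of 9 cross pairs within t: majority of links -> one cluster
    df = _dist_df([("x", 3), ("y", 3)], within=0.05, cross_close=5)
    assert len(link_clusters(df, cfg)) == 1
    # 4 of 9: below F = 0.5 -> the two groups stay apart
    df = _dist_df([("x", 3), ("y", 3)], within=0.05, cross_close=4)
    assert len(link_clusters(df, cfg)) == 2
    # no cross pair within t
    df = _dist_df([("x", 3), ("y", 3)], within=0.05, cross_close=0)
    assert link_clusters(df, cfg) == [["x0", "x1", "x2"], ["y0", "y1", "y2"]]


def test_link_fraction_one_is_complete_linkage():
    cfg = LinkClusterConfig(threshold=0.2, link_fraction=1.0)
    df = _dist_df([("x", 3), ("y", 3)], within=0.05, cross_close=8)
    assert len(link_clusters(df, cfg)) == 2  # one cross pair above t blocks fusion
    df = _dist_df([("x", 3), ("y", 3)], within=0.05, cross_close=9)
    assert len(link_clusters(df, cfg)) == 1
    with pytest.raises(ValueError):
        LinkClusterConfig(threshold=0.2, link_fraction=0.0)
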