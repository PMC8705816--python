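"""Protein similarity graph, Markov clustering and cluster selection."""

import math

import numpy as np
import pandas as pd
import pytest
import networkx as nx

from bifiphage.families import (
    SelectedCluster,
    all_vs_all_protein,
    mcl,
    presence_absence,
    profile_jaccard,
    select_clusters,
)
from bifiphage.genome_io import Feature, GenomeRecord
from bifiphage.regions import ProphageRegion
from oracles import gotoh_local_protein_score, hand_mcl_3path

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _protein(rng, n):
    return "".join(rng.choice(AA, n))


def test_identical_proteins_form_maximal_edge():
    rng = np.random.default_rng(1)
    p = _protein(rng, 100)
    q = _protein(rng, 100)
    g = all_vs_all_protein({"x1": p, "x2": p, "y": q})
    assert g.has_edge("x1", "x2")
    weights = nx.get_edge_attributes(g, "weight")
    assert weights[("x1", "x2") if ("x1", "x2") in weights else ("x2", "x1")] == max(weights.values())


def test_random_pair_scores_below_cutoff_by_independent_formula():
    """Score an unrelated 50-aa pair with a from-scratch Gotoh aligner and
    evaluate E = m * n_db * 2**(-S') with lambda 0.267, K 0.041: far above
    the 1e-5 cutoff, so the graph has no edge."""
    rng = np.random.default_rng(2)
    a, b = _protein(rng, 50), _protein(rng, 50)
    g = all_vs_all_protein({"a": a, "b": b})
    assert g.number_of_edges() == 0
    score = gotoh_local_protein_score(a, b)
    n_db = len(a) + len(b)
    s_bits = (0.267 * score - math.log(0.041)) / math.log(2)
    e = len(a) * n_db * 2.0 ** (-s_bits)
    assert e > 1e-5


def test_single_protein_rejected():
    with pytest.raises(ValueError):
        all_vs_all_protein({"only": "MKV" * 30})


def _graph(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


def test_mcl_two_disjoint_triangles():
    g = _graph([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")])
    res = mcl(g)
    assert res.converged
    assert sorted(map(sorted, res.clusters)) == [["a", "b", "c"], ["x", "y", "z"]]


def test_mcl_singleton_graph():
    g = nx.Graph()
    g.add_node("solo")
    res = mcl(g)
    assert res.clusters == [["solo"]]


def test_mcl_three_node_path_matches_hand_iteration():
    """Unit-weight path a-b-c at inflation 2: the limit matrix is doubly
    idempotent and the partition matches an explicitly hand-run
    expansion/inflation loop."""
    res = mcl(_graph([("a", "b"), ("b", "c")]), inflation=2.0)
    oracle_partition, limit, _ = hand_mcl_3path(inflation=2.0)
    assert {frozenset(c) for c in res.clusters} == oracle_partition
    # doubly idempotent: stable under one more expansion and one more inflation
    exp = limit @ limit
    assert np.allclose(exp, limit, atol=1e-6)
    infl = limit**2
    infl = infl / infl.sum(axis=0, keepdims=True)
    assert np.allclose(infl, limit, atol=1e-6)
    assert np.allclose(res.limit, limit, atol=1e-8)


def test_mcl_partition_stochasticity_and_relabelling_invariance():
    rng = np.random.default_rng(3)
    nodes = [f"n{i}" for i in range(12)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(12):
        for j in range(i + 1, 12):
            if rng.random() < 0.3:
                g.add_edge(nodes[i], nodes[j], weight=float(rng.integers(1, 5)))
    res = mcl(g)
    flat = [v for c in res.clusters for v in c]
    assert sorted(flat) == sorted(nodes)  # partition: disjoint and complete
    cols = res.limit.sum(axis=0)
    assert np.allclose(cols[cols > 0], 1.0, atol=1e-9)  # column-stochastic limit

    relabel = {n: f"z{99 - i}" for i, n in enumerate(nodes)}
    res2 = mcl(nx.relabel_nodes(g, relabel))
    back = {frozenset(relabel[v] for v in c) for c in res.clusters}
    assert {frozenset(c) for c in res2.clusters} == back


def test_presence_absence_matrix():
    fams = [["o1", "o2", "o3"], ["o4"]]
    mapping = {"o1": "R1", "o2": "R2", "o3": "R3", "o4": "R1"}
    m = presence_absence(fams, mapping)
    assert m.shape == (2, 4 - 1)
    assert m.loc["F0001"].sum() == 3
    assert m.loc["F0002"].sum() == 1
    single = presence_absence([["o1"]], {"o1": "R1"})
    assert single.shape == (1, 1) and single.iloc[0, 0] == 1
    with pytest.raises(KeyError):
        presence_absence([["orphan"]], {"o1": "R1"})


def _region(name, length, completeness, genome_id="g"):
    return ProphageRegion(
        name=name,
        genome_id=genome_id,
        start=1000,
        end=1000 + length,
        completeness=completeness,
        gc=0.6,
        modules_present=frozenset({"head_tail"}),
        boundary_flags={},
    )


def test_select_clusters_rules():
    matrix = pd.DataFrame(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
        index=["F1", "F2", "F3", "F4"],
        columns=["p1", "p2", "q1", "q2"],
    )
    assert profile_jaccard(matrix, "p1", "p2") == 1.0
    assert profile_jaccard(matrix, "p1", "q1") == 0.0
    regions = {
        "p1": _region("p1", 30_000, "likely_complete"),
        "p2": _region("p2", 30_000, "partial"),
        "q1": _region("q1", 9_000, "likely_complete"),
        "q2": _region("q2", 9_000, "likely_complete"),
        "s1": _region("s1", 30_000, "likely_complete"),
    }
    partition = [["p1", "p2"], ["q1", "q2"], ["s1"]]
    got = select_clusters(partition, matrix, regions)
    # q-cluster rejected (< 13 kb members), singleton rejected
    assert [s.members for s in got] == [["p1", "p2"]]
    assert isinstance(got[0], SelectedCluster) and got[0].has_complete


def test_select_clusters_shared_integration_flag():
    host_feats = [
        Feature("CDS", 0, 900, "+", "elongation factor Tu"),
        Feature("CDS", 32_200, 33_000, "-", "MFS transporter"),
    ]
    genome = GenomeRecord(id="g", sequence="ACGT" * 10_000, features=host_feats)
    matrix = pd.DataFrame([[1, 1]], index=["F1"], columns=["p1", "p2"])
    regions = {
        "p1": _region("p1", 30_000, "likely_complete"),
        "p2": _region("p2", 30_000, "likely_complete"),
    }
    got = select_clusters([["p1", "p2"]], matrix, regions, genomes={"g": genome})
    assert got[0].shared_integration  # identical flanks on both sides
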