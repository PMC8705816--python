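"""Protein gene families: all-vs-all similarity graph, from-scratch Markov
clustering (MCL), binary presence/absence matrix and cluster selection.

The similarity graph scores every ORF pair with a local BLOSUM62 alignment
(gap open 11, extend 1), converts raw scores to bit scores with
Karlin-Altschul parameters (lambda = 0.267, K = 0.041) and keeps edges at
E <= 1e-5, where E = m * n_db * 2**(-S') with m the query length and n_db the
summed protein length of the dataset.  Edge weights are -log10 E (capped).

MCL alternates expansion (matrix squaring) with inflation (entrywise power
and column renormalisation) on the column-stochastic adjacency matrix with
unit self-loops, pruning small entries, until the matrix change falls below a
tolerance.  Clusters are read off the attractor rows of the limit matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import AA_K, AA_LAMBDA, log10_evalue, protein_alignment_score


def _shared_words(a: str, b: str, k: int = 4) -> int:
    if len(a) < k or len(b) < k:
        return 0
    words = {a[i : i + k] for i in range(len(a) - k + 1)}
    return sum(1 for i in range(len(b) - k + 1) if b[i : i + k] in words)


def all_vs_all_protein(
    proteins: dict[str, str],
    evalue_max: float = 1e-5,
    weight_cap: float = 200.0,
    prefilter_words: int = 2,
) -> nx.Graph:
    """Similarity graph over named proteins (edge weight = -log10 E).

    Pairs sharing fewer than ``prefilter_words`` exact 4-mers are skipped
    before alignment (two-hit seeding, as protein search tools do); at the
    stated cutoff such pairs cannot reach significance on realistic data.
    """
    ids = sorted(proteins)
    if len(ids) < 2:
        raise ValueError("all_vs_all_protein requires at least 2 proteins")
    n_db = sum(len(p) for p in proteins.values())
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(ids)):
        pi = proteins[ids[i]]
        for j in range(i + 1, len(ids)):
            pj = proteins[ids[j]]
            if pi != pj and _shared_words(pi, pj) < prefilter_words:
                continue
            score = protein_alignment_score(pi, pj)
            log_e = log10_evalue(score, len(pi), n_db, AA_LAMBDA, AA_K)
            if log_e <= np.log10(evalue_max):
                g.add_edge(ids[i], ids[j], weight=min(-log_e, weight_cap), score=score)
    return g


@dataclass
class MclResult:
    clusters: list[list[str]]
    converged: bool
    n_iter: int
    limit: np.ndarray
    nodes: list[str]


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    prune: float = 1e-6,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> MclResult:
    """Markov clustering of a weighted graph; deterministic under relabelling.

    Non-convergence within ``max_iter`` is flagged on the result, never
    silent.  The returned ``clusters`` always form a partition of the nodes.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("mcl requires a non-empty graph")
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[index[u], index[v]] = w
        m[index[v], index[u]] = w
    np.fill_diagonal(m, 1.0)  # unit self-loops
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = m @ m  # expansion
        m = m**inflation  # inflation
        m[m < prune] = 0.0
        colsums = m.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        m = m / colsums
        if prev.shape == m.shape and np.max(np.abs(m - prev)) < tol:
            converged = True
            break

    # attractor interpretation: rows with mass define clusters; overlapping
    # attractor systems merge.
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        members = np.flatnonzero(m[i] > prune)
        if m[i, i] > prune:
            for j in members:
                g.add_edge(i, int(j))
    # columns with no attractor (rare, from pruning): attach to argmax row
    for j in range(n):
        if g.degree[j] == 0 and m[:, j].max() > 0:
            g.add_edge(int(np.argmax(m[:, j])), j)
    clusters = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(g)]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return MclResult(clusters=clusters, converged=converged, n_iter=it, limit=m, nodes=nodes)


def presence_absence(families: list[list[str]], orf_to_region: dict[str, str]) -> pd.DataFrame:
    """Binary family x prophage matrix: 1 iff the prophage contributes at
    least one ORF to the family.  Family ids are assigned largest-first."""
    for fam in families:
        for orf in fam:
            if orf not in orf_to_region:
                raise KeyError(f"ORF {orf!r} is not assigned to any region")
    regions = sorted(set(orf_to_region.values()))
    ordered = sorted(families, key=lambda c: (-len(c), c[0]))
    data = np.zeros((len(ordered), len(regions)), dtype=np.int8)
    ridx = {r: j for j, r in enumerate(regions)}
    for i, fam in enumerate(ordered):
        for orf in fam:
            data[i, ridx[orf_to_region[orf]]] = 1
    fam_ids = [f"F{i + 1:04d}" for i in range(len(ordered))]
    return pd.DataFrame(data, index=fam_ids, columns=regions)


def profile_jaccard(matrix: pd.DataFrame, a: str, b: str) -> float:
    """Jaccard similarity of two prophages' gene-family profiles."""
    va = matrix[a].to_numpy(dtype=bool)
    vb = matrix[b].to_numpy(dtype=bool)
    union = np.logical_or(va, vb).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(va, vb).sum() / union)


@dataclass
class SelectedCluster:
    """An ANI cluster passing the gene-sharing / completeness selection."""

    members: list[str]
    has_complete: bool
    shared_integration: bool
    mean_jaccard: float
    rationale: str


def _flank_signature(region, genome, window: int = 2000):
    left = tuple(
        f.product
        for f in sorted(genome.features, key=lambda f: f.start)
        if f.kind in ("CDS", "tRNA") and f.end <= region.start and region.start - f.end <= window
    )
    right = tuple(
        f.product
        for f in sorted(genome.features, key=lambda f: f.start)
        if f.kind in ("CDS", "tRNA") and f.start >= region.end and f.start - region.end <= window
    )
    return left, right


def select_clusters(
    ani_partition: list[list[str]],
    matrix: pd.DataFrame,
    regions: dict,
    genomes: dict | None = None,
    min_jaccard: float = 0.5,
    min_length: int = 13_000,
    flank_window: int = 2000,
) -> list[SelectedCluster]:
    """Clusters of interest: >=2 members, mean pairwise profile Jaccard >=
    ``min_jaccard``, at least one likely-complete member, every member at
    least ``min_length`` bp.  ``shared_integration`` is set when two members
    have identical flanking-feature products on both sides (allowing an
    orientation swap)."""
    selected = []
    for members in ani_partition:
        if len(members) < 2:
            continue
        regs = [regions[m] for m in members]
        if any(r.length < min_length for r in regs):
            continue
        if not any(r.completeness == "likely_complete" for r in regs):
            continue
        in_matrix = [m for m in members if m in matrix.columns]
        if len(in_matrix) < 2:
            continue
        jac = [
            profile_jaccard(matrix, in_matrix[i], in_matrix[j])
            for i in range(len(in_matrix))
            for j in range(i + 1, len(in_matrix))
        ]
        mean_jac = float(np.mean(jac))
        if mean_jac < min_jaccard:
            continue
        shared = False
        if genomes is not None:
            sigs = []
            for r in regs:
                left, right = _flank_signature(r, genomes[r.genome_id], flank_window)
                sigs.append(frozenset([("L",) + left, ("R",) + right]))
            shared = any(sigs[i] == sigs[j] for i in range(len(sigs)) for j in range(i + 1, len(sigs)))
        selected.append(
            SelectedCluster(
                members=sorted(members),
                has_complete=True,
                shared_integration=shared,
                mean_jaccard=mean_jac,
                rationale=(
                    f"{len(members)} members, mean profile Jaccard {mean_jac:.2f}, "
                    f">=1 likely-complete, all >= {min_length} bp"
                ),
            )
        )
    selected.sort(key=lambda s: (-len(s.members), s.members[0]))
    return selected


def write_edges_tsv(graph: nx.Graph, path) -> None:
    lines = ["orf_a\torf_b\tscore\tneg_log10_evalue"]
    for u, v, data in sorted(graph.edges(data=True)):
        lines.append(f"{u}\t{v}\t{data.get('score', 0):.1f}\t{data.get('weight', 0):.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_families_tsv(families: list[list[str]], path) -> None:
    ordered = sorted(families, key=lambda c: (-len(c), c[0]))
    lines = ["family\torf"]
    for i, fam in enumerate(ordered, start=1):
        for orf in sorted(fam):
            lines.append(f"F{i:04d}\t{orf}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_selected_tsv(selected: list[SelectedCluster], path) -> None:
    lines = ["cluster\tmembers\thas_complete\tshared_integration\tmean_jaccard\trationale"]
    for i, s in enumerate(selected, start=1):
        lines.append(
            f"S{i:02d}\t{','.join(s.members)}\t{int(s.has_complete)}\t"
            f"{int(s.shared_integration)}\t{s.mean_jaccard:.3f}\t{s.rationale}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
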