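"""Intergenomic distances from gapless HSPs, neighbor-joining trees, midpoint
rooting and link-fraction clustering.

For a sequence pair with lengths L1, L2, let H be the summed alignment length
of the greedily non-overlapping HSP set and I the summed identical columns.
The three distance formulas are

    d0 = 1 - 2H / (L1 + L2)        (coverage)
    d4 = 1 - I / H                 (identity within matches; 1 when H = 0)
    d6 = 1 - 2I / (L1 + L2)        (combined)

all clamped to [0, 1]; identical sequences give (0, 0, 0), seedless pairs
(1, 1, 1).  Trees are built with neighbor joining (standard Q criterion,
lexicographic tie-breaks, negative branch lengths clamped to zero) and
midpoint-rooted.  Taxon groups are formed by agglomerative merging where two
clusters fuse iff the fraction of cross-pairs at distance <= t reaches the
link fraction F.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignment import gapless_hsps, select_nonoverlapping


@dataclass(frozen=True)
class DistanceResult:
    a: str
    b: str
    d0: float
    d4: float
    d6: float
    n_hsps: int
    total_length: int
    total_identities: int


def gbdp_distance(
    a: str, b: str, a_id: str = "a", b_id: str = "b", k: int = 11, min_score: int = 40
) -> DistanceResult:
    """Pairwise intergenomic distances d0/d4/d6 from non-overlapping HSPs."""
    if not a or not b:
        raise ValueError("empty sequence")
    hsps = select_nonoverlapping(gapless_hsps(a, b, k=k, min_score=min_score))
    H = sum(h.length for h in hsps)
    I = sum(h.identities for h in hsps)
    denom = len(a) + len(b)
    d0 = 1.0 - 2.0 * H / denom
    d4 = 1.0 - I / H if H > 0 else 1.0
    d6 = 1.0 - 2.0 * I / denom
    clamp = lambda x: min(max(x, 0.0), 1.0)  # noqa: E731
    return DistanceResult(
        a=a_id,
        b=b_id,
        d0=clamp(d0),
        d4=clamp(d4),
        d6=clamp(d6),
        n_hsps=len(hsps),
        total_length=H,
        total_identities=I,
    )


def gbdp_matrices(sequences: dict[str, str], k: int = 11, min_score: int = 40) -> dict[str, pd.DataFrame]:
    """Symmetric distance matrices for each formula over named sequences."""
    ids = sorted(sequences)
    mats = {f: np.zeros((len(ids), len(ids))) for f in ("d0", "d4", "d6")}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = gbdp_distance(sequences[ids[i]], sequences[ids[j]], k=k, min_score=min_score)
            for f in mats:
                v = getattr(r, f)
                mats[f][i, j] = mats[f][j, i] = v
    return {f: pd.DataFrame(m, index=ids, columns=ids) for f, m in mats.items()}


# ---------------------------------------------------------------------------
# neighbor joining


def _nj_newick(ids: list[str], d: np.ndarray) -> str:
    """Neighbor joining to an unrooted newick string.

    Ties in the Q criterion break by the lexicographic pair of clade labels
    (a clade is labelled by its smallest leaf).  The final three nodes join at
    a central vertex with closed-form branch lengths.
    """
    n = len(ids)
    if n < 3:
        raise ValueError("nj_tree requires at least 3 taxa")
    d = d.astype(float).copy()
    labels = list(ids)  # clade label = smallest leaf in clade
    newick = {i: ids[i] for i in range(n)}
    active = list(range(n))

    def dist(i, j):
        return d[i, j]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        u = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[u, x] = d[x, u] = (d[i, x] + d[j, x] - d[i, j]) / 2.0
        newick[u] = f"({newick[i]}:{max(li, 0.0):.10g},{newick[j]}:{max(lj, 0.0):.10g})"
        labels.append(min(labels[i], labels[j]))
        active = [x for x in active if x not in (i, j)] + [u]

    i, j, kk = active
    li = (dist(i, j) + dist(i, kk) - dist(j, kk)) / 2.0
    lj = (dist(i, j) + dist(j, kk) - dist(i, kk)) / 2.0
    lk = (dist(i, kk) + dist(j, kk) - dist(i, j)) / 2.0
    return (
        f"({newick[i]}:{max(li, 0.0):.10g},{newick[j]}:{max(lj, 0.0):.10g},"
        f"{newick[kk]}:{max(lk, 0.0):.10g});"
    )


def nj_tree(matrix: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix."""
    ids = list(matrix.index)
    d = matrix.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or list(matrix.columns) != ids:
        raise ValueError("matrix must be square with matching index/columns")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("matrix must have a zero diagonal")
    newick = _nj_newick(ids, d)
    return dendropy.Tree.get(data=newick, schema="newick")


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a copy of the tree at the midpoint of its longest leaf-to-leaf
    path.  Idempotent; a zero-diameter tree keeps its seed root."""
    rooted = tree.clone(depth=1)
    if len(rooted.leaf_nodes()) < 2:
        raise ValueError("midpoint rooting requires at least 2 leaves")
    pdm = rooted.phylogenetic_distance_matrix()
    diameter = max(
        (pdm.patristic_distance(t1, t2) for t1, t2 in pdm.distinct_taxon_pair_iter()),
        default=0.0,
    )
    if diameter <= 0:
        return rooted
    if len(rooted.leaf_nodes()) == 2:
        # two-leaf trees cannot be derooted; balance the two pendant edges
        kids = rooted.seed_node.child_nodes()
        if len(kids) == 2:
            for kid in kids:
                kid.edge.length = diameter / 2.0
        return rooted
    # deroot first: dendropy's midpoint rerooting degenerates when the
    # seed root already bifurcates at the midpoint
    rooted.deroot()
    rooted.reroot_at_midpoint(update_bipartitions=True)
    return rooted


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree.as_string(schema="newick").strip() + "\n")


# ---------------------------------------------------------------------------
# link-fraction clustering


@dataclass(frozen=True)
class LinkClusterConfig:
    threshold: float
    link_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.link_fraction <= 1:
            raise ValueError("link fraction must lie in (0, 1]")


def link_clusters(matrix: pd.DataFrame, config: LinkClusterConfig) -> list[list[str]]:
    """Agglomerative clustering with a fraction-of-links fusion rule.

    At each step the candidate pair with the smallest mean cross-distance is
    examined first; two clusters fuse iff the fraction of cross-pairs with
    distance <= t reaches F.  With F = 1 this is complete linkage at t.
    """
    ids = list(matrix.index)
    d = matrix.to_numpy(dtype=float)
    clusters: list[list[int]] = [[i] for i in range(len(ids))]
    while True:
        candidates = []
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                cross = [d[i, j] for i in clusters[a] for j in clusters[b]]
                frac = sum(1 for x in cross if x <= config.threshold) / len(cross)
                candidates.append((float(np.mean(cross)), ids[clusters[a][0]], a, b, frac))
        candidates.sort()
        merged = False
        for _, _, a, b, frac in candidates:
            if frac >= config.link_fraction:
                clusters[a] = sorted(clusters[a] + clusters[b])
                del clusters[b]
                merged = True
                break
        if not merged:
            break
    out = [sorted(ids[i] for i in c) for c in clusters]
    out.sort(key=lambda c: (-len(c), c[0]))
    return out
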