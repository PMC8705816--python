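"""Fragment-based average nucleotide identity (ANIb convention) and
single-linkage clustering at an ANI cut-off.

The query is chopped into consecutive 1,020 bp fragments; each fragment is
locally aligned (affine gaps, both strands) against the subject and accepted
when alignment identity is at least 30% and the aligned span covers at least
70% of the fragment.  ANI is the mean identity over accepted fragments and
coverage the accepted aligned query length divided by the query length.
Matrices are symmetrised by the arithmetic mean of the two directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import NT_SCORING, SubjectIndex, windowed_local_alignments


@dataclass(frozen=True)
class AniResult:
    query: str
    subject: str
    ani: float
    coverage: float
    n_fragments: int
    n_accepted: int


def pairwise_ani(
    a: str,
    b: str,
    fragment_len: int = 1020,
    min_identity: float = 0.3,
    min_span_frac: float = 0.7,
    query_id: str = "a",
    subject_id: str = "b",
    subject_index: SubjectIndex | None = None,
) -> AniResult:
    """One-directional fragment ANI of ``a`` against ``b``."""
    if not a or not b:
        raise ValueError("empty sequence")
    if subject_index is None:
        subject_index = SubjectIndex(b)
    fragments = [a[i : i + fragment_len] for i in range(0, len(a), fragment_len)] or [a]
    identities = []
    aligned = 0
    for frag in fragments:
        # exact occurrence of the whole fragment is the optimal local
        # alignment (maximal score, identity 1): skip the DP
        if subject_index.strands["+"].find(frag) >= 0 or subject_index.strands["-"].find(frag) >= 0:
            identities.append(1.0)
            aligned += len(frag)
            continue
        # a homologous fragment shares many 11-mers with its counterpart
        # (>=300 at 10% divergence); correlated stray seeds between
        # unrelated coding sequences are not worth a DP
        min_seeds = 6 if len(frag) >= 200 else 1
        alns = windowed_local_alignments(
            frag, b, scoring=NT_SCORING, max_bands=2, band_min_seeds=min_seeds, subject_index=subject_index
        )
        if not alns:
            continue
        best = alns[0]
        if best.identity >= min_identity and best.query_span >= min_span_frac * len(frag):
            identities.append(best.identity)
            aligned += best.query_span
    if not identities:
        return AniResult(query_id, subject_id, ani=0.0, coverage=0.0, n_fragments=len(fragments), n_accepted=0)
    return AniResult(
        query_id,
        subject_id,
        ani=float(np.mean(identities)),
        coverage=aligned / len(a),
        n_fragments=len(fragments),
        n_accepted=len(identities),
    )


@dataclass
class AniMatrix:
    """Symmetric ANI matrix (unit diagonal) with companion coverage matrix."""

    ids: list[str]
    ani: np.ndarray
    coverage: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.ani, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().round(6).to_csv(path, sep="\t", index_label="region")


def ani_matrix(sequences: dict[str, str], fragment_len: int = 1020) -> AniMatrix:
    """All-vs-all symmetrised fragment ANI over named sequences."""
    ids = sorted(sequences)
    if len(ids) < 2:
        raise ValueError("ani_matrix requires at least 2 sequences")
    n = len(ids)
    ani = np.eye(n)
    cov = np.eye(n)
    indexes = {i: SubjectIndex(sequences[i]) for i in ids}
    for i in range(n):
        for j in range(i + 1, n):
            fwd = pairwise_ani(sequences[ids[i]], sequences[ids[j]], fragment_len, subject_index=indexes[ids[j]])
            rev = pairwise_ani(sequences[ids[j]], sequences[ids[i]], fragment_len, subject_index=indexes[ids[i]])
            ani[i, j] = ani[j, i] = (fwd.ani + rev.ani) / 2.0
            cov[i, j] = cov[j, i] = (fwd.coverage + rev.coverage) / 2.0
    return AniMatrix(ids=ids, ani=ani, coverage=cov)


def cluster_by_ani(matrix: AniMatrix, threshold: float = 0.9) -> list[list[str]]:
    """Single-linkage components of the graph with edges where ANI >= t.

    Clusters come back largest first (ties by lexicographically smallest
    member), members sorted.
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.ani[i, j] >= threshold:
                g.add_edge(matrix.ids[i], matrix.ids[j])
    clusters = [sorted(c) for c in nx.connected_components(g)]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


def write_clusters_tsv(clusters: list[list[str]], path) -> None:
    lines = ["cluster\tregion"]
    for ci, members in enumerate(clusters, start=1):
        for m in members:
            lines.append(f"C{ci:03d}\t{m}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
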