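"""Independent oracle implementations used by the test suite.

Each function here recomputes, by a route independent of the package
implementation, a quantity that a package operation is expected to match:
an exhaustive six-frame ORF scan, a direct whole-sequence local alignment,
a from-first-principles Gotoh protein aligner, a hand-iterated Markov
clustering run on the three-node path, and a brute-force repeat-triple
enumeration for CRISPR arrays.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

COMP = str.maketrans("ACGTN", "TGCAN")
STARTS = ("ATG", "GTG", "TTG")
STOPS = ("TAA", "TAG", "TGA")


def rc(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def brute_orfs(seq: str, min_aa: int) -> set[tuple[int, int, str]]:
    """Exhaustive six-frame scan: for every stop, the leftmost qualifying
    start after the previous in-frame stop.  Returns forward-strand
    (start, end, strand) triples, end inclusive of the stop codon."""
    out = set()
    for strand, s in (("+", seq), ("-", rc(seq))):
        n = len(s)
        for frame in range(3):
            codon_starts = list(range(frame, n - 2, 3))
            stop_positions = [p for p in codon_starts if s[p : p + 3] in STOPS]
            prev = frame - 3
            for stop in stop_positions:
                starts = [
                    p
                    for p in codon_starts
                    if prev + 3 <= p < stop and s[p : p + 3] in STARTS
                ]
                if starts:
                    first = min(starts)
                    if (stop - first) // 3 >= min_aa:
                        a, b = first, stop + 3
                        if strand == "-":
                            a, b = len(seq) - b, len(seq) - a
                        out.add((a, b, strand))
                prev = stop
    return out


def direct_local_identity(a: str, b: str) -> float:
    """Best whole-sequence affine local alignment identity over both strands
    (match +2 / mismatch -3 / open -5 / extend -2), identical columns over
    alignment columns including gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    best = None
    for s in (b, rc(b)):
        alns = aligner.align(a, s)
        if len(alns) == 0:
            continue
        aln = alns[0]
        if best is None or aln.score > best.score:
            best = aln
    if best is None:
        return 0.0
    target, query = str(best.target), str(best.query)
    tb, qb = best.aligned
    ident = sum(
        sum(1 for x, y in zip(target[ts:te], query[qs:qe]) if x == y)
        for (ts, te), (qs, qe) in zip(tb, qb)
    )
    btot = sum(te - ts for ts, te in tb)
    cols = (tb[-1][1] - tb[0][0]) + (qb[-1][1] - qb[0][0]) - btot
    return ident / cols


def gotoh_local_protein_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Local protein alignment score by explicit Gotoh dynamic programming
    (BLOSUM62), independent of any library aligner."""
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)
    F = np.full((n + 1, m + 1), -np.inf)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - gap_extend, H[i, j - 1] - gap_open)
            F[i, j] = max(F[i - 1, j] - gap_extend, H[i - 1, j] - gap_open)
            s = blosum[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def hand_mcl_3path(inflation: float = 2.0, prune: float = 1e-6, tol: float = 1e-9):
    """Hand-run expansion/inflation on the unit-weight 3-node path a-b-c.

    Returns (partition as set of frozensets over {'a','b','c'}, limit matrix,
    n_iterations)."""
    m = np.array(
        [
            [1.0, 1.0, 0.0],
            [1.0, 1.0, 1.0],
            [0.0, 1.0, 1.0],
        ]
    )
    m = m / m.sum(axis=0, keepdims=True)
    for it in range(1, 201):
        prev = m
        m = m @ m
        m = m**inflation
        m[m < prune] = 0.0
        m = m / m.sum(axis=0, keepdims=True)
        if np.max(np.abs(m - prev)) < tol:
            break
    names = ["a", "b", "c"]
    groups = []
    for i in range(3):
        if m[i, i] > prune:
            groups.append({names[j] for j in np.flatnonzero(m[i] > prune)} | {names[i]})
    merged: list[set] = []
    for g in groups:
        for h in merged:
            if g & h:
                h |= g
                break
        else:
            merged.append(set(g))
    covered = set().union(*merged) if merged else set()
    for j, nm in enumerate(names):
        if nm not in covered:
            merged.append({nm})
    return {frozenset(g) for g in merged}, m, it


def brute_crispr(
    seq: str,
    dr_min: int = 23,
    dr_max: int = 55,
    sp_min: int = 25,
    sp_max: int = 60,
    min_copies: int = 3,
) -> set[tuple[tuple[int, int], ...]]:
    """Brute-force enumeration of qualifying repeat arrays.

    Every word of length ``dr_min`` occurring >= ``min_copies`` times is
    chained by plausible spacing; the repeat is recovered by direct maximal
    common extension of all copies (pairwise character comparison), then the
    copy set is validated against the length/gap/copy-count rules.  Returns
    the set of copy-interval tuples of maximal qualifying arrays."""
    occ: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - dr_min + 1):
        w = seq[i : i + dr_min]
        if "N" not in w:
            occ[w].append(i)
    results = set()
    for w, ps in occ.items():
        if len(ps) < min_copies:
            continue
        rest = list(ps)
        while len(rest) >= min_copies:
            chain = [rest[0]]
            for p in rest[1:]:
                if dr_min + sp_min <= p - chain[-1] <= dr_max + sp_max:
                    chain.append(p)
            rest = [p for p in rest if p not in chain]
            if len(chain) < min_copies:
                continue
            # maximal common extension by direct comparison
            left = 0
            while (
                chain[0] - left - 1 >= 0
                and len({seq[p - left - 1] for p in chain}) == 1
                and dr_min + left + 1 <= dr_max
            ):
                left += 1
            right = 0
            while (
                chain[-1] + dr_min + right < len(seq)
                and len({seq[p + dr_min + right] for p in chain}) == 1
                and dr_min + left + right + 1 <= dr_max
            ):
                right += 1
            rep_len = dr_min + left + right
            copies = tuple((p - left, p - left + rep_len) for p in chain)
            gaps = [copies[i + 1][0] - copies[i][1] for i in range(len(copies) - 1)]
            if not dr_min <= rep_len <= dr_max:
                continue
            if any(g < sp_min or g > sp_max for g in gaps):
                continue
            repeat = seq[copies[0][0] : copies[0][1]]
            if any(seq[a:b] != repeat for a, b in copies):
                continue
            results.add(copies)
    # overlap resolution per the stated rule: most copies, then longest
    # repeat, then leftmost
    ordered = sorted(results, key=lambda c: (-len(c), -(c[0][1] - c[0][0]), c[0][0]))
    kept: list[tuple[tuple[int, int], ...]] = []
    for c in ordered:
        span = (c[0][0], c[-1][1])
        if all(span[1] <= k[0][0] or k[-1][1] <= span[0] for k in kept):
            kept.append(c)
    return set(kept)
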