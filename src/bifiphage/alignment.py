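"""Shared local-alignment machinery: seeds, gapless HSPs, windowed affine
alignment and Karlin-Altschul significance.

Three consumers with different needs sit on top of this module:

* fragment ANI (``ani``) - a 1,020 bp fragment is located in the subject by
  exact 11-mer seeds and then locally aligned (affine gaps) inside a padded
  window around the seeded diagonal band;
* protospacer matching (``protospacers``) - same windowed strategy with short
  queries, plus ungapped-BLASTN Karlin-Altschul statistics;
* intergenomic distances (``phylogeny``) - gapless X-drop HSPs found directly
  on seeded diagonals, made non-overlapping greedily.

Scoring defaults follow the common nucleotide convention match +2,
mismatch -3, gap open -5, gap extend -2 (the open penalty applies to the
first gapped column, the extension to each subsequent one).  ``N`` never
matches anything, including itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

_COMP = str.maketrans("ACGTN", "TGCAN")

NT_SCORING = (2, -3, -5, -2)  # match, mismatch, gap open, gap extend

#: Karlin-Altschul parameters used for ungapped nucleotide statistics.
NT_LAMBDA, NT_K = 0.625, 0.41
#: Karlin-Altschul parameters for gapped BLOSUM62 protein alignments.
AA_LAMBDA, AA_K = 0.267, 0.041


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def bit_score(raw_score: float, lam: float, K: float) -> float:
    """Normalised (bit) score S' = (lambda*S - ln K) / ln 2."""
    return (lam * raw_score - math.log(K)) / math.log(2.0)


def log10_evalue(raw_score: float, m: int, n: int, lam: float, K: float) -> float:
    """log10 of E = m * n * 2**(-S'), computed in log space (no underflow)."""
    return math.log10(m) + math.log10(n) - bit_score(raw_score, lam, K) * math.log10(2.0)


def evalue(raw_score: float, m: int, n: int, lam: float, K: float) -> float:
    return 10.0 ** max(log10_evalue(raw_score, m, n, lam, K), -320.0)


# ---------------------------------------------------------------------------
# seeding


def kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    """Positions of every k-mer not containing N."""
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" in word:
            continue
        idx.setdefault(word, []).append(i)
    return idx


def seed_diagonals(query: str, subject_index: dict[str, list[int]], k: int) -> dict[int, int]:
    """Map diagonal (q_pos - s_pos) -> number of shared k-mer seeds."""
    diags: dict[int, int] = {}
    for i in range(len(query) - k + 1):
        word = query[i : i + k]
        if "N" in word:
            continue
        for j in subject_index.get(word, ()):
            d = i - j
            diags[d] = diags.get(d, 0) + 1
    return diags


# ---------------------------------------------------------------------------
# gapless HSPs on seeded diagonals


@dataclass(frozen=True)
class Hsp:
    """Gapless high-scoring segment pair.

    Coordinates are 0-based half-open on the *forward* strands of both
    sequences; for ``strand == '-'`` the query segment aligns to the reverse
    complement of the subject interval.
    """

    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str
    score: int
    length: int
    identities: int


def _segments_on_diagonal(scores: np.ndarray, min_score: int, xdrop: int):
    """Maximal scoring segments of a +/- score vector (X-drop style split)."""
    segments = []
    cur = 0
    cur_start = 0
    best = 0
    best_end = -1
    best_start = 0
    for i, v in enumerate(scores.tolist()):
        if cur == 0:
            cur_start = i
        cur += v
        if cur > best:
            best = cur
            best_end = i
            best_start = cur_start
        if cur <= 0 or best - cur >= xdrop:
            if best >= min_score:
                segments.append((best_start, best_end + 1, best))
            cur = 0
            best = 0
            best_end = -1
    if best >= min_score:
        segments.append((best_start, best_end + 1, best))
    return segments


def gapless_hsps(
    query: str,
    subject: str,
    k: int = 11,
    match: int = 2,
    mismatch: int = -3,
    min_score: int = 40,
    xdrop: int = 20,
    both_strands: bool = True,
) -> list[Hsp]:
    """Find gapless HSPs by scanning every diagonal that carries a seed."""
    if not query or not subject:
        raise ValueError("empty sequence")
    qa = np.frombuffer(query.encode(), dtype=np.uint8)
    n_code = ord("N")
    hsps: list[Hsp] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        sub = subject if strand == "+" else revcomp(subject)
        sa = np.frombuffer(sub.encode(), dtype=np.uint8)
        idx = kmer_positions(sub, k)
        for d in sorted(seed_diagonals(query, idx, k)):
            q0 = max(0, d)
            s0 = q0 - d
            span = min(len(query) - q0, len(sub) - s0)
            if span < k:
                continue
            qs = qa[q0 : q0 + span]
            ss = sa[s0 : s0 + span]
            is_match = (qs == ss) & (qs != n_code)
            scores = np.where(is_match, match, mismatch)
            for a, b, sc in _segments_on_diagonal(scores, min_score, xdrop):
                ident = int(is_match[a:b].sum())
                qstart, qend = q0 + a, q0 + b
                s_lo, s_hi = s0 + a, s0 + b
                if strand == "-":
                    s_lo, s_hi = len(sub) - s_hi, len(sub) - s_lo
                hsps.append(
                    Hsp(
                        qstart=qstart,
                        qend=qend,
                        sstart=s_lo,
                        send=s_hi,
                        strand=strand,
                        score=int(sc),
                        length=b - a,
                        identities=ident,
                    )
                )
    # the same HSP can be reached from several seeds on one diagonal; diagonals
    # are scanned once per strand, so duplicates only arise across strands of
    # palindromic repeats -- keep everything, callers resolve overlaps.
    hsps.sort(key=lambda h: (-h.score, h.qstart, h.sstart, h.strand))
    return hsps


def select_nonoverlapping(hsps: list[Hsp]) -> list[Hsp]:
    """Greedy non-overlap filter (higher score first) on both sequences."""
    kept: list[Hsp] = []
    for h in sorted(hsps, key=lambda h: (-h.score, h.qstart, h.sstart, h.strand)):
        clash = False
        for g in kept:
            if h.qstart < g.qend and g.qstart < h.qend:
                clash = True
                break
            if h.sstart < g.send and g.sstart < h.send:
                clash = True
                break
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.qstart, h.sstart))
    return kept


# ---------------------------------------------------------------------------
# windowed affine local alignment (Biopython DP behind seed location)


@lru_cache(maxsize=8)
def _nt_aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@lru_cache(maxsize=1)
def _aa_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass(frozen=True)
class LocalAlignment:
    """A scored local alignment of a query against one subject locus."""

    score: float
    identity: float  # identical columns / alignment columns (gaps included)
    columns: int
    identities: int
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart


def _parse_alignment(aln, strand: str, window_offset: int, subject_len: int) -> LocalAlignment:
    # Biopython's target is the first sequence passed (our query), its query
    # is the second (the subject window).
    target, query = str(aln.target), str(aln.query)
    tb, qb = aln.aligned  # target blocks, window blocks
    ident = 0
    btot = 0
    for (ts, te), (qs, qe) in zip(tb, qb):
        seg_t = target[ts:te]
        seg_q = query[qs:qe]
        ident += sum(1 for a, b in zip(seg_t, seg_q) if a == b and a != "N")
        btot += te - ts
    t_lo, t_hi = int(tb[0][0]), int(tb[-1][1])
    q_lo, q_hi = int(qb[0][0]), int(qb[-1][1])
    columns = (t_hi - t_lo) + (q_hi - q_lo) - btot
    # target == query sequence of the caller; query == subject window
    s_lo = window_offset + q_lo
    s_hi = window_offset + q_hi
    if strand == "-":
        s_lo, s_hi = subject_len - s_hi, subject_len - s_lo
    return LocalAlignment(
        score=float(aln.score),
        identity=ident / columns if columns else 0.0,
        columns=columns,
        identities=ident,
        qstart=t_lo,
        qend=t_hi,
        sstart=s_lo,
        send=s_hi,
        strand=strand,
    )


def _band_windows(diags: dict[int, int], qlen: int, sublen: int, pad: int, max_bands: int, min_seeds: int = 1):
    """Cluster seeded diagonals into bands and return subject windows."""
    if not diags:
        return []
    ds = sorted(diags)
    bands: list[list[int]] = [[ds[0]]]
    for d in ds[1:]:
        if d - bands[-1][-1] <= 40:
            bands[-1].append(d)
        else:
            bands.append([d])
    bands = [b for b in bands if sum(diags[d] for d in b) >= min_seeds]
    scored = sorted(bands, key=lambda b: (-sum(diags[d] for d in b), b[0]))[:max_bands]
    windows = []
    for band in scored:
        # query position q sits at subject position q - d
        s_min = max(0, 0 - max(band) - pad)
        s_max = min(sublen, qlen - min(band) + pad)
        s_min = max(0, min(s_min, sublen - 1))
        if s_max > s_min:
            windows.append((s_min, s_max))
    return windows


class SubjectIndex:
    """Precomputed k-mer indexes of a subject's two strands, shareable
    across many queries against the same subject."""

    def __init__(self, subject: str, k: int = 11):
        self.subject = subject
        self.k = k
        self.strands = {"+": subject, "-": revcomp(subject)}
        self.indexes = {s: kmer_positions(seq, k) for s, seq in self.strands.items()}


def windowed_local_alignments(
    query: str,
    subject: str,
    k: int = 11,
    scoring: tuple[int, int, int, int] = NT_SCORING,
    pad: int = 150,
    max_bands: int = 4,
    both_strands: bool = True,
    band_min_seeds: int = 1,
    subject_index: SubjectIndex | None = None,
) -> list[LocalAlignment]:
    """Seed-located affine local alignments of ``query`` against ``subject``.

    Returns one alignment per candidate band (possibly several loci), sorted
    by descending score.  Empty when no seed is shared (or, with
    ``band_min_seeds`` > 1, when no band carries enough seeds).  For queries
    shorter than ``k`` the whole subject is aligned directly.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    aligner = _nt_aligner(*scoring)
    out: list[LocalAlignment] = []
    strands = ("+", "-") if both_strands else ("+",)
    use_k = min(k, len(query))
    if subject_index is not None and subject_index.k != use_k:
        subject_index = None
    for strand in strands:
        if subject_index is not None:
            sub = subject_index.strands[strand]
        else:
            sub = subject if strand == "+" else revcomp(subject)
        if len(query) < k or len(sub) < k:
            windows = [(0, len(sub))]
        else:
            idx = subject_index.indexes[strand] if subject_index is not None else kmer_positions(sub, use_k)
            diags = seed_diagonals(query, idx, use_k)
            windows = _band_windows(diags, len(query), len(sub), pad, max_bands, band_min_seeds)
        for s_min, s_max in windows:
            window = sub[s_min:s_max]
            alns = aligner.align(query, window)
            # never call len(alns): counting co-optimal paths is exponential
            if alns.score <= 0:
                continue
            try:
                first = alns[0]
            except IndexError:
                continue
            out.append(_parse_alignment(first, strand, s_min, len(sub)))
    out.sort(key=lambda a: (-a.score, a.sstart, a.strand))
    return out


def best_local_alignment(
    query: str,
    subject: str,
    k: int = 11,
    scoring: tuple[int, int, int, int] = NT_SCORING,
    pad: int = 150,
    max_bands: int = 4,
) -> LocalAlignment | None:
    """Best windowed local alignment over both strands, or ``None``."""
    alns = windowed_local_alignments(query, subject, k=k, scoring=scoring, pad=pad, max_bands=max_bands)
    return alns[0] if alns else None


def protein_alignment_score(a: str, b: str) -> float:
    """Local BLOSUM62 alignment score (gap open 11, extend 1)."""
    if not a or not b:
        raise ValueError("empty protein")
    return float(_aa_aligner().score(a, b))
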