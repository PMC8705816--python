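"""Six-frame ORF calling and bacterial (table 11) translation.

A deliberately simple prokaryotic gene caller for prophage regions: all six
frames are scanned, starts are {ATG, GTG, TTG}, stops {TAA, TAG, TGA}, and for
each stop codon the longest ORF (leftmost qualifying start after the previous
in-frame stop) is reported.  Codons containing ``N`` never match a start or
stop and translate to ``X``; ORFs whose protein is more than 10% ``X`` are
discarded.  No coding-statistics or RBS model is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.Data import CodonTable

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(seq: str) -> str:
    """Translate a CDS with the bacterial code (table 11).

    The trailing stop, if present, is omitted; an internal stop is an error.
    Codons containing ``N`` translate to ``X``.  Initiator replacement
    (GTG/TTG -> M) is the caller's job, not this function's.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    aas = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon} at position {3 * i}")
        aas.append(_TABLE11.forward_table.get(codon, "X"))
    return "".join(aas)


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); ``N`` excluded from numerator and denominator."""
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return gc / (gc + at)


@dataclass(frozen=True)
class Orf:
    """A predicted ORF on a region, 0-based half-open on the forward strand.

    ``frame`` is the reading frame (0-2) on the ORF's own strand; the interval
    includes the stop codon, the protein does not.
    """

    region_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str

    @property
    def id(self) -> str:
        return f"{self.region_id}|{self.start}-{self.end}{self.strand}"


def _scan_strand(seq: str, min_aa: int, max_x_frac: float):
    """Yield (start, end, frame, protein) for one strand of ``seq``."""
    n = len(seq)
    for frame in range(3):
        pending_start = None  # leftmost start since the previous in-frame stop
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if pending_start is None and codon in START_CODONS:
                pending_start = pos
            if codon in STOP_CODONS:
                if pending_start is not None:
                    aa_len = (pos - pending_start) // 3
                    if aa_len >= min_aa:
                        body = seq[pending_start : pos + 3]
                        protein = "M" + translate(body)[1:] if aa_len else ""
                        if protein.count("X") <= max_x_frac * len(protein):
                            yield pending_start, pos + 3, frame, protein
                pending_start = None


def find_orfs(
    seq: str,
    min_aa: int = 30,
    region_id: str = "",
    max_x_frac: float = 0.10,
) -> list[Orf]:
    """Six-frame ORF scan.

    Coordinates are reported on the forward strand of ``seq`` regardless of
    the ORF's strand; output is sorted by (start, end, strand).
    """
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    orfs: list[Orf] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for start, end, frame, protein in _scan_strand(s, min_aa, max_x_frac):
            if strand == "-":
                start, end = len(seq) - end, len(seq) - start
            orfs.append(
                Orf(region_id=region_id, start=start, end=end, strand=strand, frame=frame, protein=protein)
            )
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def select_genes(orfs: list[Orf], max_overlap: int = 30) -> list[Orf]:
    """Reduce a six-frame ORF set to a plausible gene complement.

    Greedy longest-first selection keeping ORFs that overlap already-kept
    ones by at most ``max_overlap`` bp, which is how prokaryotic gene callers
    resolve the spurious short ORFs a naive six-frame scan produces inside
    and antisense to real genes.
    """
    kept: list[Orf] = []
    for o in sorted(orfs, key=lambda o: (-(o.end - o.start), o.start, o.strand)):
        if all(min(o.end, g.end) - max(o.start, g.start) <= max_overlap for g in kept):
            kept.append(o)
    kept.sort(key=lambda o: (o.start, o.end, o.strand))
    return kept


def orf_sequence(orf: Orf, region_seq: str) -> str:
    """Nucleotide sequence of an ORF on its own strand (stop included)."""
    sub = region_seq[orf.start : orf.end]
    return sub if orf.strand == "+" else revcomp(sub)


def write_protein_fasta(orfs: list[Orf], path: str | Path) -> None:
    lines = []
    for i, o in enumerate(orfs):
        lines.append(f">{o.region_id}|{i} {o.start}-{o.end}({o.strand})")
        for j in range(0, len(o.protein), 80):
            lines.append(o.protein[j : j + 80])
    Path(path).write_text("\n".join(lines) + "\n")
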