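"""Genome and feature IO with a fixed internal coordinate convention.

Internally every interval is 0-based half-open ``[start, end)``.  GenBank and
GFF3 are 1-based inclusive; the two readers and the GFF3 writer perform the
(unique) conversion at the boundary and nowhere else.  Each contig of a
multi-record file becomes an independent :class:`GenomeRecord`.

Sequences are restricted to the alphabet ``{A, C, G, T, N}``; other IUPAC
ambiguity codes are rejected at parse time so that downstream identity
arithmetic is unambiguous.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
SPECIES_LABELS = (
    "adolescentis",
    "bifidum",
    "breve",
    "longum_longum",
    "longum_infantis",
    "other",
)

FEATURE_KINDS = ("CDS", "tRNA", "repeat_region", "misc")


class FormatError(ValueError):
    """A file could not be parsed in the named format."""


class EmptyDatasetError(ValueError):
    """A parse produced zero genome records."""


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a genome (0-based, half-open)."""

    kind: str
    start: int
    end: int
    strand: str = "."
    product: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"feature interval empty or inverted: [{self.start}, {self.end})")
        if self.kind in ("CDS", "tRNA") and self.strand not in "+-":
            raise ValueError(f"{self.kind} feature requires a defined strand, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Feature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class GenomeRecord:
    """One contig with its features.

    ``species_label`` is one of the human-associated *Bifidobacterium* taxa
    handled by the survey (``adolescentis``, ``bifidum``, ``breve``,
    ``longum_longum``, ``longum_infantis``) or ``other``.
    """

    id: str
    sequence: str
    species_label: str = "other"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"genome {self.id!r}: sequence contains characters outside A/C/G/T/N: {sorted(bad)}"
            )
        if self.species_label not in SPECIES_LABELS:
            raise ValueError(f"genome {self.id!r}: unknown species label {self.species_label!r}")
        n = len(self.sequence)
        for f in self.features:
            if f.start < 0 or f.end > n:
                raise ValueError(
                    f"genome {self.id!r}: feature [{f.start}, {f.end}) outside [0, {n})"
                )
        self.features.sort(key=lambda f: (f.start, f.end, f.kind))

    def __len__(self) -> int:
        return len(self.sequence)


def slice_region(genome: GenomeRecord, start: int, end: int, new_id: str | None = None) -> GenomeRecord:
    """Extract ``[start, end)`` as a new record.

    Features wholly inside the interval are kept with shifted coordinates;
    features straddling either boundary are dropped.
    """
    if not (0 <= start < end <= len(genome)):
        raise ValueError(
            f"slice [{start}, {end}) out of bounds for genome {genome.id!r} of length {len(genome)}"
        )
    kept = [f.shifted(-start) for f in genome.features if f.start >= start and f.end <= end]
    return GenomeRecord(
        id=new_id or f"{genome.id}:{start}-{end}",
        sequence=genome.sequence[start:end],
        species_label=genome.species_label,
        features=kept,
    )


def _genbank_records(path: Path) -> list[GenomeRecord]:
    genomes = []
    for rec in SeqIO.parse(str(path), "genbank"):
        feats = []
        for f in rec.features:
            if f.type not in ("CDS", "tRNA", "repeat_region"):
                continue
            strand = "+" if f.location.strand in (1, None) else "-"
            product = f.qualifiers.get("product", [""])[0]
            feats.append(
                Feature(
                    kind=f.type,
                    start=int(f.location.start),
                    end=int(f.location.end),
                    strand=strand if f.type != "repeat_region" else ".",
                    product=product,
                )
            )
        try:
            genomes.append(GenomeRecord(id=rec.id, sequence=str(rec.seq).upper(), features=feats))
        except ValueError as exc:
            raise FormatError(f"record {rec.id!r}: {exc}") from exc
    return genomes


def _fasta_gff3_records(fasta_path: Path, gff_path: Path) -> list[GenomeRecord]:
    by_id: dict[str, list[Feature]] = {}
    if gff_path.exists():
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        for f in db.all_features():
            kind = f.featuretype if f.featuretype in FEATURE_KINDS else "misc"
            product = (f.attributes.get("product") or [""])[0]
            strand = f.strand if f.strand in "+-" else ("." if kind not in ("CDS", "tRNA") else "+")
            by_id.setdefault(f.seqid, []).append(
                # GFF3 start is 1-based inclusive -> subtract 1 from start only.
                Feature(kind=kind, start=f.start - 1, end=f.end, strand=strand, product=product)
            )
    genomes = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        try:
            genomes.append(
                GenomeRecord(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    features=by_id.get(rec.id, []),
                )
            )
        except ValueError as exc:
            raise FormatError(f"record {rec.id!r}: {exc}") from exc
    return genomes


def read_genomes(path: str | Path, format: str, gff_path: str | Path | None = None) -> list[GenomeRecord]:
    """Read genomes as ``genbank`` or ``fasta+gff3``.

    For ``fasta+gff3`` the companion annotation defaults to the FASTA path
    with a ``.gff3`` suffix.  Raises :class:`EmptyDatasetError` when the file
    parses but contains no records, and :class:`FormatError` naming the
    offending record otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        genomes = _genbank_records(path)
    elif format == "fasta+gff3":
        gff = Path(gff_path) if gff_path is not None else path.with_suffix(".gff3")
        genomes = _fasta_gff3_records(path, gff)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'genbank' or 'fasta+gff3')")
    if not genomes:
        raise EmptyDatasetError(f"no genome records parsed from {path}")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate genome ids in {path}: {dup}")
    return genomes


def _gff3_escape(value: str) -> str:
    return urllib.parse.quote(value, safe=" ()./-_'")


def _gff3_unescape(value: str) -> str:
    return urllib.parse.unquote(value)


def write_genomes(genomes: list[GenomeRecord], fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write a dataset as multi-FASTA plus one GFF3 with all features."""
    fasta_lines = []
    for g in genomes:
        fasta_lines.append(f">{g.id} species={g.species_label}")
        for i in range(0, len(g.sequence), 80):
            fasta_lines.append(g.sequence[i : i + 80])
    Path(fasta_path).write_text("\n".join(fasta_lines) + "\n")

    gff_lines = ["##gff-version 3"]
    for g in genomes:
        gff_lines.append(f"##sequence-region {g.id} 1 {len(g)}")
        for j, f in enumerate(g.features, start=1):
            attrs = f"ID={g.id}.f{j}"
            if f.product:
                attrs += f";product={_gff3_escape(f.product)}"
            gff_lines.append(
                "\t".join(
                    [g.id, "bifiphage", f.kind, str(f.start + 1), str(f.end), ".", f.strand, ".", attrs]
                )
            )
    Path(gff_path).write_text("\n".join(gff_lines) + "\n")


def write_regions(regions, path: str | Path) -> None:
    """Write prophage regions as GFF3 (1-based inclusive coordinates).

    Accepts any objects with ``name``, ``genome_id``, ``start``, ``end``
    attributes; duplicate region names are an error.  An empty list yields a
    valid header-only file.
    """
    names = [r.name for r in regions]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate region names: {dup}")
    lines = ["##gff-version 3"]
    for r in regions:
        attrs = f"ID={_gff3_escape(r.name)};Name={_gff3_escape(r.name)}"
        completeness = getattr(r, "completeness", None)
        if completeness:
            attrs += f";completeness={completeness}"
        lines.append(
            "\t".join(
                [
                    r.genome_id,
                    "bifiphage",
                    "mobile_genetic_element",
                    str(r.start + 1),
                    str(r.end),
                    ".",
                    ".",
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class RegionLine:
    """A prophage region read back from a region GFF3."""

    name: str
    genome_id: str
    start: int
    end: int


def read_regions(path: str | Path) -> list[RegionLine]:
    """Read a region GFF3 written by :func:`write_regions`."""
    out = []
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 9:
            raise FormatError(f"malformed GFF3 line in {path}: {raw!r}")
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
        out.append(
            RegionLine(
                name=_gff3_unescape(attrs.get("ID", "")),
                genome_id=cols[0],
                start=int(cols[3]) - 1,
                end=int(cols[4]),
            )
        )
    return out
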