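"""Prophage candidate scanning, boundary refinement, completeness and naming.

Candidates are maximal runs of CDS features with phage-lexicon products.
Boundaries are then revised to a fixed point with three criteria, applied to
each side and capped at 15 kb of extension per side:

(i)   a tRNA gene or an integrase-product feature within 2 kb beyond the
      boundary is absorbed;
(ii)  a run of hypothetical-product CDS bridging to a lexicon-matching CDS is
      absorbed together with that CDS;
(iii) the next CDS is absorbed while it shares the strand of the current edge
      CDS and the intergenic gap is under 1 kb (putative co-transcription).

Completeness follows the size/module heuristics of prophage surveys: under
13 kb, or missing both the structural and packaging modules, a region is a
remnant; at or above 30 kb, or at 20 kb with at least four modules and a
boundary integrase, it is likely complete; everything else is partial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import Feature, GenomeRecord
from .lexicon import MODULES, is_hypothetical_product, is_phage_product, product_module
from .orfs import gc_content

SPECIES_ABBREV = {
    "adolescentis": "Bad",
    "bifidum": "Bif",
    "breve": "Bre",
    "longum_longum": "Blong",
    "longum_infantis": "Blong",
}

COMPLETENESS_CLASSES = ("remnant", "partial", "likely_complete")


@dataclass
class ProphageRegion:
    """A located, named, classified prophage interval on a host genome."""

    name: str
    genome_id: str
    start: int
    end: int
    completeness: str
    gc: float
    modules_present: frozenset
    boundary_flags: dict

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_candidates(
    genome: GenomeRecord,
    lexicon: dict | None = None,
    min_hits: int = 4,
    max_gap: int = 5000,
) -> list[tuple[int, int]]:
    """Maximal runs of lexicon-matching CDS; run spans first to last match.

    Consecutive matching features more than ``max_gap`` apart break the run;
    runs with fewer than ``min_hits`` matches are discarded.
    """
    matches = [
        f
        for f in sorted(genome.features, key=lambda f: f.start)
        if f.kind == "CDS" and is_phage_product(f.product, lexicon)
    ]
    runs: list[list[Feature]] = []
    for f in matches:
        if runs and f.start - runs[-1][-1].end <= max_gap:
            runs[-1].append(f)
        else:
            runs.append([f])
    return [(run[0].start, run[-1].end) for run in runs if len(run) >= min_hits]


def _is_integrase(product: str, lexicon: dict | None) -> bool:
    return product_module(product, lexicon) == "integration_excision"


def refine_boundaries(
    candidate: tuple[int, int],
    genome: GenomeRecord,
    lexicon: dict | None = None,
    flank_window: int = 2000,
    cotrans_gap: int = 1000,
    side_cap: int = 15_000,
) -> tuple[int, int]:
    """Iterate the three boundary criteria to a fixed point (widening only)."""
    start, end = candidate
    if not (0 <= start < end <= len(genome)):
        raise ValueError(f"candidate [{start}, {end}) outside genome {genome.id!r}")
    cap_left = max(0, start - side_cap)
    cap_right = min(len(genome), end + side_cap)
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    changed = True
    while changed:
        changed = False
        # ---- left side -------------------------------------------------
        outside = [f for f in feats if f.end <= start]
        new_start = _extend_left(start, outside, lexicon, flank_window, cotrans_gap, cap_left, feats)
        if new_start < start:
            start = new_start
            changed = True
        # ---- right side ------------------------------------------------
        outside = [f for f in feats if f.start >= end]
        new_end = _extend_right(end, outside, lexicon, flank_window, cotrans_gap, cap_right, feats)
        if new_end > end:
            end = new_end
            changed = True
    return start, end


def _extend_left(start, outside, lexicon, flank_window, cotrans_gap, cap, feats):
    outside = sorted(outside, key=lambda f: -f.end)  # nearest first
    # (i) tRNA or integrase within the flank window
    for f in outside:
        if start - f.end > flank_window:
            break
        if (f.kind == "tRNA" or (f.kind == "CDS" and _is_integrase(f.product, lexicon))) and f.start >= cap:
            return f.start
    cds_out = [f for f in outside if f.kind == "CDS"]
    # (ii) hypothetical run bridging to a lexicon CDS
    i = 0
    while i < len(cds_out) and is_hypothetical_product(cds_out[i].product) and start - cds_out[i].start <= flank_window + 5000:
        i += 1
    if 0 < i < len(cds_out) and is_phage_product(cds_out[i].product, lexicon) and cds_out[i].start >= cap:
        return cds_out[i].start
    # (iii) same-strand CDS within the co-transcription gap
    if cds_out:
        nxt = cds_out[0]
        edge = _edge_cds(feats, start, side="left")
        if (
            edge is not None
            and nxt.strand == edge.strand
            and start - nxt.end < cotrans_gap
            and nxt.start >= cap
        ):
            return nxt.start
    return start


def _extend_right(end, outside, lexicon, flank_window, cotrans_gap, cap, feats):
    outside = sorted(outside, key=lambda f: f.start)  # nearest first
    for f in outside:
        if f.start - end > flank_window:
            break
        if (f.kind == "tRNA" or (f.kind == "CDS" and _is_integrase(f.product, lexicon))) and f.end <= cap:
            return f.end
    cds_out = [f for f in outside if f.kind == "CDS"]
    i = 0
    while i < len(cds_out) and is_hypothetical_product(cds_out[i].product) and cds_out[i].end - end <= flank_window + 5000:
        i += 1
    if 0 < i < len(cds_out) and is_phage_product(cds_out[i].product, lexicon) and cds_out[i].end <= cap:
        return cds_out[i].end
    if cds_out:
        nxt = cds_out[0]
        edge = _edge_cds(feats, end, side="right")
        if (
            edge is not None
            and nxt.strand == edge.strand
            and nxt.start - end < cotrans_gap
            and nxt.end <= cap
        ):
            return nxt.end
    return end


def _edge_cds(feats, boundary, side):
    """Nearest CDS inside the region at the given boundary."""
    if side == "left":
        inside = [f for f in feats if f.kind == "CDS" and f.start >= boundary]
        return min(inside, key=lambda f: f.start, default=None)
    inside = [f for f in feats if f.kind == "CDS" and f.end <= boundary]
    return max(inside, key=lambda f: f.end, default=None)


def region_modules(genome: GenomeRecord, interval: tuple[int, int], lexicon: dict | None = None) -> frozenset:
    """Phage modules represented among CDS products inside the interval."""
    start, end = interval
    mods = set()
    for f in genome.features:
        if f.kind == "CDS" and f.start >= start and f.end <= end:
            m = product_module(f.product, lexicon)
            if m:
                mods.add(m)
    return frozenset(mods)


def boundary_flags(
    genome: GenomeRecord, interval: tuple[int, int], lexicon: dict | None = None, window: int = 1500
) -> dict:
    """Integrase/tRNA presence near each boundary (within ``window`` bp,
    inside or just outside the region)."""
    start, end = interval
    flags = {"left_integrase": False, "right_integrase": False, "left_trna": False, "right_trna": False}
    for f in genome.features:
        near_left = abs(f.start - start) <= window or abs(f.end - start) <= window
        near_right = abs(f.start - end) <= window or abs(f.end - end) <= window
        if f.kind == "tRNA":
            flags["left_trna"] |= near_left
            flags["right_trna"] |= near_right
        elif f.kind == "CDS" and _is_integrase(f.product, lexicon):
            flags["left_integrase"] |= near_left
            flags["right_integrase"] |= near_right
    return flags


def classify_completeness(length: int, modules_present: frozenset, boundary_integrase: bool) -> str:
    """Three-way completeness call from length, modules and boundary context."""
    if length <= 0:
        raise ValueError("zero-length region")
    structural_absent = "head_tail" not in modules_present and "dna_packaging" not in modules_present
    if length < 13_000 or structural_absent:
        return "remnant"
    if length >= 30_000:
        return "likely_complete"
    if length >= 20_000 and len(modules_present) >= 4 and boundary_integrase:
        return "likely_complete"
    return "partial"


def name_prophage(species_label: str, strain: str, ordinal: int) -> str:
    """Survey nomenclature: species abbreviation + strain + 'ph' + ordinal."""
    if species_label not in SPECIES_ABBREV:
        raise ValueError(f"unknown species label {species_label!r}")
    if ordinal < 1:
        raise ValueError("ordinal must be >= 1")
    return f"{SPECIES_ABBREV[species_label]}{strain}ph{ordinal}"


def build_regions(
    genome: GenomeRecord,
    lexicon: dict | None = None,
    min_hits: int = 4,
    max_gap: int = 5000,
) -> list[ProphageRegion]:
    """Scan, refine, classify and name every prophage region of one genome."""
    intervals = [refine_boundaries(c, genome, lexicon) for c in scan_candidates(genome, lexicon, min_hits, max_gap)]
    regions = []
    for ordinal, (start, end) in enumerate(sorted(intervals), start=1):
        mods = region_modules(genome, (start, end), lexicon)
        flags = boundary_flags(genome, (start, end), lexicon)
        regions.append(
            ProphageRegion(
                name=name_prophage(genome.species_label, genome.id, ordinal),
                genome_id=genome.id,
                start=start,
                end=end,
                completeness=classify_completeness(
                    end - start, mods, flags["left_integrase"] or flags["right_integrase"]
                ),
                gc=gc_content(genome.sequence[start:end]),
                modules_present=mods,
                boundary_flags=flags,
            )
        )
    return regions


@dataclass
class SizeSummary:
    """Count and size statistics of a region set."""

    count: int
    min: int | None
    max: int | None
    median: float | None
    mode: int | None
    mean_per_genome: float

    def report_mean_per_genome(self) -> float:
        return round(self.mean_per_genome, 2)


def size_summary(lengths: list[int], n_genomes: int, mode_bin: int = 100) -> SizeSummary:
    """Summary statistics; mode is the lower edge of the most common
    ``mode_bin``-bp length bin (smallest bin wins ties)."""
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if not lengths:
        return SizeSummary(count=0, min=None, max=None, median=None, mode=None, mean_per_genome=0.0)
    arr = np.asarray(lengths)
    bins = arr // mode_bin
    uniq, counts = np.unique(bins, return_counts=True)
    mode = int(uniq[np.argmax(counts)]) * mode_bin
    return SizeSummary(
        count=len(lengths),
        min=int(arr.min()),
        max=int(arr.max()),
        median=float(np.median(arr)),
        mode=mode,
        mean_per_genome=len(lengths) / n_genomes,
    )
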