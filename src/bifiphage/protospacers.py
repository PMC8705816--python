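"""Mapping CRISPR spacers onto prophage regions (protospacer detection).

Spacers are located by 11-bp exact seeds on both strands and aligned with
affine-gap local alignment (match +2, mismatch -3, open -5, extend -2).
Significance uses ungapped nucleotide Karlin-Altschul statistics
(lambda = 0.625, K = 0.41) with m the spacer length and n the summed region
length; hits require E <= 0.01 and identity >= 98% over alignment columns
(gaps included).  The best hit per (spacer, region, locus) is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import NT_K, NT_LAMBDA, NT_SCORING, SubjectIndex, evalue, windowed_local_alignments
from .crispr import Spacer
from .orfs import Orf


@dataclass(frozen=True)
class ProtospacerHit:
    spacer_id: str
    region_name: str
    sstart: int
    send: int
    strand: str
    identity: float
    length: int  # alignment columns
    score: float
    e_value: float


def match_spacers(
    spacers: list[Spacer],
    regions: dict[str, str],
    evalue_max: float = 0.01,
    identity_min: float = 0.98,
) -> list[ProtospacerHit]:
    """All significant spacer-vs-region hits, deterministically ordered."""
    if not spacers or not regions:
        raise ValueError("match_spacers requires non-empty spacer and region sets")
    n_total = sum(len(s) for s in regions.values())
    indexes = {name: SubjectIndex(regions[name]) for name in regions}
    hits: list[ProtospacerHit] = []
    for sp in sorted(spacers, key=lambda s: s.id):
        for name in sorted(regions):
            seq = regions[name]
            alns = windowed_local_alignments(
                sp.sequence, seq, k=11, scoring=NT_SCORING, pad=60, subject_index=indexes[name]
            )
            best_per_locus: dict[tuple[int, int], ProtospacerHit] = {}
            for a in alns:
                e = evalue(a.score, len(sp.sequence), n_total, NT_LAMBDA, NT_K)
                if e > evalue_max or a.identity < identity_min:
                    continue
                hit = ProtospacerHit(
                    spacer_id=sp.id,
                    region_name=name,
                    sstart=a.sstart,
                    send=a.send,
                    strand=a.strand,
                    identity=a.identity,
                    length=a.columns,
                    score=a.score,
                    e_value=e,
                )
                # loci overlapping an already-kept hit: keep the higher score
                replaced = False
                for key, prev in list(best_per_locus.items()):
                    if hit.sstart < prev.send and prev.sstart < hit.send:
                        if hit.score > prev.score:
                            del best_per_locus[key]
                            best_per_locus[(hit.sstart, hit.send)] = hit
                        replaced = True
                        break
                if not replaced:
                    best_per_locus[(hit.sstart, hit.send)] = hit
            hits.extend(best_per_locus[k] for k in sorted(best_per_locus))
    hits.sort(key=lambda h: (h.spacer_id, h.region_name, h.sstart))
    return hits


def unique_hit_sequences(hits: list[ProtospacerHit]) -> tuple[int, dict[str, list[tuple[int, int]]]]:
    """Merge overlapping subject intervals per region; count merged loci."""
    per_region: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        per_region.setdefault(h.region_name, []).append((h.sstart, h.send))
    merged: dict[str, list[tuple[int, int]]] = {}
    total = 0
    for region in sorted(per_region):
        ivs = sorted(per_region[region])
        out = [list(ivs[0])]
        for a, b in ivs[1:]:
            if a <= out[-1][1]:  # >= 1 bp overlap or abutment at shared base
                out[-1][1] = max(out[-1][1], b)
            else:
                out.append([a, b])
        merged[region] = [tuple(x) for x in out]
        total += len(out)
    return total, merged


@dataclass
class TargetGene:
    """A prophage gene targeted by one or more spacers."""

    region_name: str
    orf: Orf | None
    product: str
    n_supporting_hits: int
    n_distinct_spacers: int


def targeted_genes(
    hits: list[ProtospacerHit],
    orfs_by_region: dict[str, list[Orf]],
    region_records: dict | None = None,
) -> list[TargetGene]:
    """Assign each hit to the ORF with maximal overlap (ties: leftmost ORF).

    A hit overlapping no ORF is reported as intergenic.  When the sliced
    region records (with CDS annotations) are supplied, each ORF inherits the
    product of the annotation it overlaps most; otherwise products default to
    'hypothetical protein'.
    """
    buckets: dict[tuple[str, tuple | None], list[ProtospacerHit]] = {}
    for h in hits:
        if h.region_name not in orfs_by_region:
            raise KeyError(f"no ORFs supplied for region {h.region_name!r}")
        best: Orf | None = None
        best_ov = 0
        for orf in sorted(orfs_by_region[h.region_name], key=lambda o: (o.start, o.end)):
            ov = min(h.send, orf.end) - max(h.sstart, orf.start)
            if ov > best_ov:
                best_ov = ov
                best = orf
        key = (h.region_name, (best.start, best.end, best.strand) if best else None)
        buckets.setdefault(key, []).append(h)

    out: list[TargetGene] = []
    for (region_name, orf_key), bucket in sorted(buckets.items(), key=lambda kv: (kv[0][0], kv[0][1] or (-1,))):
        orf = None
        product = "intergenic"
        if orf_key is not None:
            start, end, strand = orf_key
            orf = next(
                o for o in orfs_by_region[region_name] if (o.start, o.end, o.strand) == (start, end, strand)
            )
            product = "hypothetical protein"
            if region_records is not None and region_name in region_records:
                rec = region_records[region_name]
                best_p, best_ov = product, 0
                for f in rec.features:
                    if f.kind != "CDS":
                        continue
                    ov = min(end, f.end) - max(start, f.start)
                    if ov > best_ov:
                        best_ov = ov
                        best_p = f.product or product
                product = best_p
        out.append(
            TargetGene(
                region_name=region_name,
                orf=orf,
                product=product,
                n_supporting_hits=len(bucket),
                n_distinct_spacers=len({h.spacer_id for h in bucket}),
            )
        )
    return out


def write_hits_tsv(hits: list[ProtospacerHit], path) -> None:
    from pathlib import Path

    lines = ["spacer\tregion\tstart\tend\tstrand\tidentity\talign_len\tscore\tevalue"]
    for h in hits:
        lines.append(
            f"{h.spacer_id}\t{h.region_name}\t{h.sstart}\t{h.send}\t{h.strand}\t"
            f"{h.identity:.4f}\t{h.length}\t{h.score:.1f}\t{h.e_value:.3e}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_target_genes_tsv(genes: list[TargetGene], path) -> None:
    from pathlib import Path

    lines = ["region\torf_start\torf_end\tstrand\tproduct\tn_hits\tn_spacers"]
    for g in genes:
        if g.orf is None:
            lines.append(f"{g.region_name}\t.\t.\t.\t{g.product}\t{g.n_supporting_hits}\t{g.n_distinct_spacers}")
        else:
            lines.append(
                f"{g.region_name}\t{g.orf.start}\t{g.orf.end}\t{g.orf.strand}\t"
                f"{g.product}\t{g.n_supporting_hits}\t{g.n_distinct_spacers}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
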