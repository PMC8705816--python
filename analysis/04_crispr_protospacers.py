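"""CRISPR arrays, non-redundant spacers and protospacer mapping.

Detects repeat-spacer arrays on every study genome, deduplicates spacers
(CD-HIT-style greedy clustering at 0.9 identity), maps the representatives
onto the detected prophage regions at E <= 0.01 / identity >= 98%, and
extracts the targeted genes.  Writes arrays, spacers, hits and target-gene
tables to results/.
"""

from pathlib import Path

from bifiphage.crispr import (
    dedupe_spacers,
    find_arrays,
    write_arrays_gff3,
    write_cluster_map_tsv,
    write_spacer_fasta,
)
from bifiphage.orfs import find_orfs, select_genes
from bifiphage.genome_io import slice_region
from bifiphage.protospacers import (
    match_spacers,
    targeted_genes,
    unique_hit_sequences,
    write_hits_tsv,
    write_target_genes_tsv,
)
from bifiphage.regions import build_regions
from bifiphage.synthetic import GeneratorConfig, generate_dataset

STUDY_SEED = 7

def main() -> None:
    ds = generate_dataset(GeneratorConfig(seed=STUDY_SEED))
    by_id = {g.id: g for g in ds.genomes}
    out = Path("results")
    out.mkdir(exist_ok=True)

    arrays = [a for g in ds.genomes for a in find_arrays(g)]
    spacers = [s for a in arrays for s in a.spacers]
    write_arrays_gff3(arrays, out / "arrays.gff3")
    write_spacer_fasta(spacers, out / "spacers.fna")
    print(f"arrays detected  : {len(arrays)}  spacers: {len(spacers)} "
          f"(truth: {len(ds.truth.spacers)})")

    reps, assignment = dedupe_spacers(spacers)
    write_cluster_map_tsv(assignment, out / "spacer_clusters.tsv")
    print(f"non-redundant    : {len(reps)} representatives")

    regions = [r for g in ds.genomes for r in build_regions(g)]
    rec = {r.name: slice_region(by_id[r.genome_id], r.start, r.end, new_id=r.name) for r in regions}
    seqs = {name: x.sequence for name, x in rec.items()}
    hits = match_spacers(reps, seqs)
    write_hits_tsv(hits, out / "hits.tsv")
    n_unique, _ = unique_hit_sequences(hits)
    print(f"significant hits : {len(hits)}  merged unique loci: {n_unique}")

    orfs = {name: select_genes(find_orfs(s, min_aa=30, region_id=name)) for name, s in seqs.items()}
    targets = targeted_genes(hits, orfs, rec)
    write_target_genes_tsv(targets, out / "target_genes.tsv")
    products = sorted({t.product for t in targets})
    print(f"targeted genes   : {len(targets)}  products: {products}")

if __name__ == "__main__":
    main()
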