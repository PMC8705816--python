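"""Comparative analysis of the detected prophages: fragment ANI at the 0.9
cut-off, all-vs-all protein families by Markov clustering, and selection of
clusters of interest (gene sharing + completeness + length rules).

Writes the ANI matrix, cluster memberships, the binary gene-family
presence/absence matrix and the selected-cluster report to results/.
"""

from pathlib import Path

from bifiphage.ani import ani_matrix, cluster_by_ani, write_clusters_tsv
from bifiphage.families import (
    all_vs_all_protein,
    mcl,
    presence_absence,
    select_clusters,
    write_edges_tsv,
    write_families_tsv,
    write_selected_tsv,
)
from bifiphage.genome_io import slice_region
from bifiphage.orfs import find_orfs, select_genes
from bifiphage.regions import build_regions
from bifiphage.synthetic import GeneratorConfig, generate_dataset

STUDY_SEED = 7

def main() -> None:
    ds = generate_dataset(GeneratorConfig(seed=STUDY_SEED))
    by_id = {g.id: g for g in ds.genomes}
    regions = [r for g in ds.genomes for r in build_regions(g)]
    seqs = {r.name: by_id[r.genome_id].sequence[r.start : r.end] for r in regions}
    out = Path("results")
    out.mkdir(exist_ok=True)

    matrix = ani_matrix(seqs)
    matrix.write_tsv(out / "ani_matrix.tsv")
    clusters = cluster_by_ani(matrix, threshold=0.9)
    write_clusters_tsv(clusters, out / "ani_clusters.tsv")
    print(f"ANI clusters at 0.9   : {len(clusters)} "
          f"(sizes {sorted((len(c) for c in clusters), reverse=True)})")

    orfs = {
        r.name: select_genes(find_orfs(seqs[r.name], min_aa=30, region_id=r.name))
        for r in regions
    }
    proteins = {o.id: o.protein for ro in orfs.values() for o in ro}
    graph = all_vs_all_protein(proteins)
    write_edges_tsv(graph, out / "family_edges.tsv")
    res = mcl(graph)
    print(f"gene families (MCL)   : {len(res.clusters)} from {len(proteins)} ORFs "
          f"({'converged' if res.converged else 'NOT converged'} in {res.n_iter} it)")
    write_families_tsv(res.clusters, out / "families.tsv")
    pa = presence_absence(res.clusters, {o.id: o.region_id for ro in orfs.values() for o in ro})
    pa.to_csv(out / "presence_absence.tsv", sep="\t", index_label="family")

    selected = select_clusters(clusters, pa, {r.name: r for r in regions}, genomes=by_id)
    write_selected_tsv(selected, out / "selected_clusters.tsv")
    print(f"selected clusters     : {len(selected)}")
    for s in selected:
        print(f"  {','.join(s.members)}  jaccard={s.mean_jaccard:.2f} "
              f"shared_integration={s.shared_integration}")

if __name__ == "__main__":
    main()
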