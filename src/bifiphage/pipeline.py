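"""End-to-end orchestration: simulate/load -> prophage regions -> ORFs ->
ANI + gene families + cluster selection -> CRISPR spacers -> protospacer
matching -> intergenomic distances and trees -> recovery scoring.

The report bundle is a directory of plain-text artefacts listed in
``manifest.tsv``.  Under a fixed seed the bundle is byte-identical across
runs; the on-disk run log therefore records stages and parameters only
(timings go to stdout).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from time import perf_counter

import pandas as pd

from . import ani as ani_mod
from . import crispr as crispr_mod
from . import families as fam_mod
from . import phylogeny as phylo_mod
from . import protospacers as proto_mod
from .genome_io import GenomeRecord, read_genomes, slice_region, write_regions
from .orfs import find_orfs, select_genes, write_protein_fasta
from .regions import ProphageRegion, build_regions, size_summary
from .synthetic import Dataset, GeneratorConfig, TruthTable, generate_dataset, write_dataset


@dataclass
class PipelineConfig:
    """One config object covering every stage; all thresholds overridable."""

    outdir: str
    generator: GeneratorConfig | None = None
    input_fasta: str | None = None
    input_gff: str | None = None
    input_format: str = "fasta+gff3"
    # prophage scanning / refinement
    min_hits: int = 4
    max_gap: int = 5000
    # ANI
    ani_fragment: int = 1020
    ani_threshold: float = 0.9
    # gene families
    family_evalue: float = 1e-5
    inflation: float = 2.0
    min_jaccard: float = 0.5
    # CRISPR + protospacers
    dedupe_identity: float = 0.9
    spacer_evalue: float = 0.01
    spacer_identity: float = 0.98
    # phylogeny
    link_threshold: float = 0.25
    link_fraction: float = 0.5
    min_phylo_taxa: int = 3

    def __post_init__(self) -> None:
        if self.generator is None and self.input_fasta is None:
            raise ValueError("config needs a generator or an input path")
        for name, lo, hi in (
            ("ani_threshold", 0.0, 1.0),
            ("min_jaccard", 0.0, 1.0),
            ("dedupe_identity", 0.0, 1.0),
            ("spacer_identity", 0.0, 1.0),
            ("link_fraction", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} = {v} outside [{lo}, {hi}]")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        gen = d.pop("generator", None)
        if gen is not None:
            gen["implants_range"] = tuple(gen["implants_range"])
            gen["implant_size_range"] = tuple(gen["implant_size_range"])
            gen = GeneratorConfig(**gen)
        return cls(generator=gen, **d)


@dataclass
class RecoveryMetrics:
    """Prediction-vs-truth scores on synthetic data.

    Empty denominators default to 1.0 (a pipeline that predicts nothing on a
    phage-free dataset is perfectly precise).
    """

    n_truth: int
    n_predicted: int
    n_matched: int
    region_precision: float
    region_recall: float
    mean_boundary_error_bp: float
    completeness_confusion: dict
    intact_complete_fraction: float
    remnant_remnant_fraction: float
    n_truth_spacers: int
    n_detected_spacers: int
    spacer_recovery: float
    protospacer_precision: float
    protospacer_recall: float

    def to_tsv(self, path: str | Path) -> None:
        rows = {k: v for k, v in asdict(self).items() if k != "completeness_confusion"}
        lines = ["metric\tvalue"]
        for k in rows:
            v = rows[k]
            lines.append(f"{k}\t{v:.6g}" if isinstance(v, float) else f"{k}\t{v}")
        for (t, p), c in sorted(self.completeness_confusion.items()):
            lines.append(f"confusion[{t}->{p}]\t{c}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PipelineResult:
    config: PipelineConfig
    genomes: list[GenomeRecord]
    truth: TruthTable | None
    regions: list[ProphageRegion]
    region_records: dict
    orfs_by_region: dict
    ani: ani_mod.AniMatrix | None
    ani_clusters: list
    families: list
    presence: pd.DataFrame | None
    selected: list
    arrays: list
    spacers: list
    representatives: list
    assignment: dict
    hits: list
    distances: dict
    metrics: RecoveryMetrics | None
    manifest: dict = field(default_factory=dict)


def _touch_tsv(path: Path, header: str) -> None:
    path.write_text(header + "\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, tuple[str, str]] = {}
    log_lines: list[str] = []

    def note(stage: str, files: dict[str, Path], t0: float) -> None:
        for label, p in files.items():
            manifest[p.name] = (stage, label)
        log_lines.append(f"stage={stage}")
        print(f"[bifiphage] {stage}: {perf_counter() - t0:.1f}s")

    # ---- stage: dataset ------------------------------------------------
    t0 = perf_counter()
    truth: TruthTable | None = None
    if config.generator is not None:
        dataset = generate_dataset(config.generator)
        genomes, truth = dataset.genomes, dataset.truth
        paths = write_dataset(dataset, out)
        note("dataset", {k: v for k, v in paths.items()}, t0)
        log_lines.append(f"generator={json.dumps(asdict(config.generator), sort_keys=True)}")
    else:
        genomes = read_genomes(config.input_fasta, config.input_format, config.input_gff)
        note("dataset", {}, t0)

    # ---- stage: prophage regions --------------------------------------
    t0 = perf_counter()
    regions: list[ProphageRegion] = []
    for g in genomes:
        regions.extend(build_regions(g, min_hits=config.min_hits, max_gap=config.max_gap))
    regions.sort(key=lambda r: (r.genome_id, r.start))
    regions_tsv = out / "regions.tsv"
    lines = ["name\tgenome\tstart\tend\tlength\tgc\tcompleteness\tmodules\tboundary_flags"]
    for r in regions:
        flags = ",".join(k for k, v in sorted(r.boundary_flags.items()) if v)
        lines.append(
            f"{r.name}\t{r.genome_id}\t{r.start}\t{r.end}\t{r.length}\t{r.gc:.4f}\t"
            f"{r.completeness}\t{','.join(sorted(r.modules_present))}\t{flags}"
        )
    regions_tsv.write_text("\n".join(lines) + "\n")
    write_regions(regions, out / "regions.gff3")
    summ = size_summary([r.length for r in regions], n_genomes=max(len(genomes), 1))
    (out / "size_summary.tsv").write_text(
        "count\tmin\tmax\tmedian\tmode\tmean_per_genome\n"
        f"{summ.count}\t{summ.min}\t{summ.max}\t{summ.median}\t{summ.mode}\t"
        f"{summ.report_mean_per_genome()}\n"
    )
    note(
        "regions",
        {"regions_tsv": regions_tsv, "regions_gff3": out / "regions.gff3", "size": out / "size_summary.tsv"},
        t0,
    )

    # ---- stage: ORFs ---------------------------------------------------
    t0 = perf_counter()
    genome_by_id = {g.id: g for g in genomes}
    region_records = {
        r.name: slice_region(genome_by_id[r.genome_id], r.start, r.end, new_id=r.name) for r in regions
    }
    orfs_by_region = {
        name: select_genes(find_orfs(rec.sequence, min_aa=30, region_id=name))
        for name, rec in region_records.items()
    }
    all_orfs = [o for name in sorted(orfs_by_region) for o in orfs_by_region[name]]
    write_protein_fasta(all_orfs, out / "orfs.faa")
    note("orfs", {"orfs": out / "orfs.faa"}, t0)

    # ---- stage: ANI ----------------------------------------------------
    t0 = perf_counter()
    region_seqs = {name: rec.sequence for name, rec in region_records.items()}
    ani_matrix = None
    ani_clusters: list = []
    if len(region_seqs) >= 2:
        ani_matrix = ani_mod.ani_matrix(region_seqs, fragment_len=config.ani_fragment)
        ani_matrix.write_tsv(out / "ani_matrix.tsv")
        ani_clusters = ani_mod.cluster_by_ani(ani_matrix, threshold=config.ani_threshold)
    else:
        _touch_tsv(out / "ani_matrix.tsv", "region")
    ani_mod.write_clusters_tsv(ani_clusters, out / "ani_clusters.tsv")
    note("ani", {"matrix": out / "ani_matrix.tsv", "clusters": out / "ani_clusters.tsv"}, t0)

    # ---- stage: gene families -----------------------------------------
    t0 = perf_counter()
    proteins = {o.id: o.protein for o in all_orfs}
    orf_to_region = {o.id: o.region_id for o in all_orfs}
    families: list = []
    presence = None
    selected: list = []
    if len(proteins) >= 2:
        graph = fam_mod.all_vs_all_protein(proteins, evalue_max=config.family_evalue)
        fam_mod.write_edges_tsv(graph, out / "family_edges.tsv")
        mcl_result = fam_mod.mcl(graph, inflation=config.inflation)
        families = mcl_result.clusters
        if not mcl_result.converged:
            log_lines.append("warning=mcl_not_converged")
        presence = fam_mod.presence_absence(families, orf_to_region)
        presence.to_csv(out / "presence_absence.tsv", sep="\t", index_label="family")
        selected = fam_mod.select_clusters(
            ani_clusters,
            presence,
            {r.name: r for r in regions},
            genomes=genome_by_id,
            min_jaccard=config.min_jaccard,
        )
    else:
        _touch_tsv(out / "family_edges.tsv", "orf_a\torf_b\tscore\tneg_log10_evalue")
        _touch_tsv(out / "presence_absence.tsv", "family")
    fam_mod.write_families_tsv(families, out / "families.tsv")
    fam_mod.write_selected_tsv(selected, out / "selected_clusters.tsv")
    note(
        "families",
        {
            "edges": out / "family_edges.tsv",
            "families": out / "families.tsv",
            "presence": out / "presence_absence.tsv",
            "selected": out / "selected_clusters.tsv",
        },
        t0,
    )

    # ---- stage: CRISPR -------------------------------------------------
    t0 = perf_counter()
    arrays: list = []
    for g in genomes:
        arrays.extend(crispr_mod.find_arrays(g))
    spacers = [sp for arr in arrays for sp in arr.spacers]
    crispr_mod.write_arrays_gff3(arrays, out / "arrays.gff3")
    crispr_mod.write_spacer_fasta(spacers, out / "spacers.fna")
    representatives: list = []
    assignment: dict = {}
    if spacers:
        representatives, assignment = crispr_mod.dedupe_spacers(spacers, config.dedupe_identity)
    crispr_mod.write_cluster_map_tsv(assignment, out / "spacer_clusters.tsv")
    note(
        "crispr",
        {"arrays": out / "arrays.gff3", "spacers": out / "spacers.fna", "map": out / "spacer_clusters.tsv"},
        t0,
    )

    # ---- stage: protospacer matching ----------------------------------
    t0 = perf_counter()
    hits: list = []
    if representatives and region_seqs:
        hits = proto_mod.match_spacers(
            representatives,
            region_seqs,
            evalue_max=config.spacer_evalue,
            identity_min=config.spacer_identity,
        )
    proto_mod.write_hits_tsv(hits, out / "hits.tsv")
    n_unique, merged = proto_mod.unique_hit_sequences(hits)
    uh_lines = ["region\tstart\tend"] + [
        f"{region}\t{a}\t{b}" for region in sorted(merged) for a, b in merged[region]
    ]
    (out / "unique_hits.tsv").write_text("\n".join(uh_lines) + f"\n# merged_total\t{n_unique}\n")
    targets = proto_mod.targeted_genes(hits, orfs_by_region, region_records) if hits else []
    proto_mod.write_target_genes_tsv(targets, out / "target_genes.tsv")
    note(
        "match",
        {"hits": out / "hits.tsv", "unique": out / "unique_hits.tsv", "targets": out / "target_genes.tsv"},
        t0,
    )

    # ---- stage: phylogeny ----------------------------------------------
    t0 = perf_counter()
    distances: dict = {}
    if len(region_seqs) >= config.min_phylo_taxa:
        distances = phylo_mod.gbdp_matrices(region_seqs)
        for formula, df in distances.items():
            df.round(6).to_csv(out / f"dist_{formula}.tsv", sep="\t", index_label="region")
            tree = phylo_mod.midpoint_root(phylo_mod.nj_tree(df))
            phylo_mod.write_newick(tree, out / f"tree_{formula}.nwk")
        parts = phylo_mod.link_clusters(
            distances["d6"],
            phylo_mod.LinkClusterConfig(threshold=config.link_threshold, link_fraction=config.link_fraction),
        )
    else:
        parts = []
        for formula in ("d0", "d4", "d6"):
            _touch_tsv(out / f"dist_{formula}.tsv", "region")
            (out / f"tree_{formula}.nwk").write_text(";\n")
    lc_lines = ["cluster\tregion"]
    for ci, members in enumerate(parts, start=1):
        for m in members:
            lc_lines.append(f"L{ci:03d}\t{m}")
    (out / "link_clusters.tsv").write_text("\n".join(lc_lines) + "\n")
    note(
        "phylogeny",
        {
            **{f"dist_{f}": out / f"dist_{f}.tsv" for f in ("d0", "d4", "d6")},
            **{f"tree_{f}": out / f"tree_{f}.nwk" for f in ("d0", "d4", "d6")},
            "link_clusters": out / "link_clusters.tsv",
        },
        t0,
    )

    # ---- stage: evaluation ---------------------------------------------
    metrics = None
    if truth is not None:
        metrics = evaluate_recovery(
            regions,
            truth,
            genomes=genome_by_id,
            detected_spacers=spacers,
            assignment=assignment,
            hits=hits,
        )
        metrics.to_tsv(out / "evaluation.tsv")
        manifest["evaluation.tsv"] = ("evaluate", "metrics")

    # ---- manifest + log -------------------------------------------------
    man_lines = ["file\tstage\tlabel"]
    for fname in sorted(manifest):
        stage, label = manifest[fname]
        man_lines.append(f"{fname}\t{stage}\t{label}")
    (out / "manifest.tsv").write_text("\n".join(man_lines) + "\n")
    # paths are machine-specific; the log echoes analysis parameters only
    cfg_echo = {
        k: v
        for k, v in asdict(config).items()
        if k not in ("generator", "outdir", "input_fasta", "input_gff")
    }
    log_lines.append(f"config={json.dumps(cfg_echo, sort_keys=True)}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        config=config,
        genomes=genomes,
        truth=truth,
        regions=regions,
        region_records=region_records,
        orfs_by_region=orfs_by_region,
        ani=ani_matrix,
        ani_clusters=ani_clusters,
        families=families,
        presence=presence,
        selected=selected,
        arrays=arrays,
        spacers=spacers,
        representatives=representatives,
        assignment=assignment,
        hits=hits,
        distances=distances,
        metrics=metrics,
        manifest={k: v for k, v in manifest.items()},
    )


# ---------------------------------------------------------------------------
# recovery scoring


def _reciprocal_matches(regions: list[ProphageRegion], truth: TruthTable):
    """One-to-one matching by >= 50% reciprocal overlap, best overlap first."""
    pairs = []
    for ri, r in enumerate(regions):
        for ti, t in enumerate(truth.records):
            if r.genome_id != t.genome_id:
                continue
            ov = min(r.end, t.end) - max(r.start, t.start)
            if ov <= 0:
                continue
            if ov >= 0.5 * r.length and ov >= 0.5 * t.length:
                pairs.append((ov, ri, ti))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_r: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for ov, ri, ti in pairs:
        if ri in used_r or ti in used_t:
            continue
        used_r.add(ri)
        used_t.add(ti)
        matches.append((ri, ti))
    return matches


def _rc(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def evaluate_recovery(
    regions: list[ProphageRegion],
    truth: TruthTable,
    genomes: dict | None = None,
    detected_spacers: list | None = None,
    assignment: dict | None = None,
    hits: list | None = None,
) -> RecoveryMetrics:
    """Score predictions against generator truth.

    Region matching uses >= 50% reciprocal overlap.  A protospacer hit counts
    as correct when a mutation-free truth spacer of the hit's representative
    cluster has an origin sequence occurring (either strand) in the hit
    region; the expected-hit set for recall is every (representative, region)
    pair with such an occurrence.
    """
    genome_ids = {t.genome_id for t in truth.records} | {s.genome_id for s in truth.spacers}
    if genomes is not None:
        missing = genome_ids - set(genomes)
        if missing:
            raise ValueError(f"truth references unknown genomes: {sorted(missing)}")

    matches = _reciprocal_matches(regions, truth)
    n_matched = len(matches)
    precision = n_matched / len(regions) if regions else 1.0
    recall = n_matched / len(truth.records) if truth.records else 1.0
    if matches:
        errs = []
        confusion: dict = {}
        intact_total = intact_complete = 0
        remnant_total = remnant_remnant = 0
        for ri, ti in matches:
            r, t = regions[ri], truth.records[ti]
            errs.append((abs(r.start - t.start) + abs(r.end - t.end)) / 2.0)
            label = "intact" if t.intact else "degraded"
            confusion[(label, r.completeness)] = confusion.get((label, r.completeness), 0) + 1
            if t.intact:
                intact_total += 1
                intact_complete += r.completeness == "likely_complete"
            if "head_tail" not in t.modules_present and "dna_packaging" not in t.modules_present:
                remnant_total += 1
                remnant_remnant += r.completeness == "remnant"
        boundary = float(sum(errs) / len(errs))
        intact_frac = intact_complete / intact_total if intact_total else 1.0
        remnant_frac = remnant_remnant / remnant_total if remnant_total else 1.0
    else:
        boundary = 0.0
        confusion = {}
        intact_frac = 1.0 if not any(t.intact for t in truth.records) else 0.0
        remnant_frac = 1.0
        if truth.records and regions:
            boundary = 0.0

    # ---- spacer recovery ------------------------------------------------
    detected_spacers = detected_spacers or []
    detected_seqs = {s.sequence for s in detected_spacers}
    n_truth_sp = len(truth.spacers)
    recovered = sum(1 for s in truth.spacers if s.sequence in detected_seqs or _rc(s.sequence) in detected_seqs)
    spacer_recovery = recovered / n_truth_sp if n_truth_sp else 1.0

    # ---- protospacer precision / recall ---------------------------------
    proto_precision = proto_recall = 1.0
    if genomes is not None and assignment is not None and hits is not None:
        by_seq = {}
        for s in detected_spacers:
            by_seq.setdefault(s.sequence, s.id)
        truth_to_rep = {}
        for ts in truth.spacers:
            det_id = ts.spacer_id if ts.spacer_id in assignment else by_seq.get(ts.sequence) or by_seq.get(_rc(ts.sequence))
            if det_id in assignment:
                truth_to_rep[ts.spacer_id] = assignment[det_id]
        rep_to_origins: dict[str, list[str]] = {}
        for ts in truth.spacers:
            if ts.n_mutations or ts.spacer_id not in truth_to_rep:
                continue
            origin = genomes[ts.genome_id].sequence[ts.origin_start : ts.origin_end]
            rep_to_origins.setdefault(truth_to_rep[ts.spacer_id], []).append(origin)
        region_seq = {r.name: genomes[r.genome_id].sequence[r.start : r.end] for r in regions}
        expected = set()
        for rep, origins in rep_to_origins.items():
            for name, seq in region_seq.items():
                if any(o in seq or _rc(o) in seq for o in origins):
                    expected.add((rep, name))
        found = {(h.spacer_id, h.region_name) for h in hits}
        if found:
            proto_precision = len(found & expected) / len(found)
        if expected:
            proto_recall = len(found & expected) / len(expected)

    return RecoveryMetrics(
        n_truth=len(truth.records),
        n_predicted=len(regions),
        n_matched=n_matched,
        region_precision=precision,
        region_recall=recall,
        mean_boundary_error_bp=boundary,
        completeness_confusion=confusion,
        intact_complete_fraction=intact_frac,
        remnant_remnant_fraction=remnant_frac,
        n_truth_spacers=n_truth_sp,
        n_detected_spacers=len(detected_spacers),
        spacer_recovery=spacer_recovery,
        protospacer_precision=proto_precision,
        protospacer_recall=proto_recall,
    )
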