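"""Synthetic annotated *Bifidobacterium*-like genomes with known ground truth.

The generator emulates the features of the real survey data that the pipeline
stages consume, at desk scale:

* high-GC host chromosomes (per-species defaults 0.59-0.62) carrying 0-6
  implanted prophages of 4.5-51.2 kb drawn Poisson(0.82) per genome;
* modular prophage gene architecture (integration/excision, lysis, DNA
  replication, DNA packaging, head/tail morphogenesis), an integrase at one
  sequence boundary, packaging and structural genes mutually adjacent;
* degraded remnant prophages produced by deleting whole modules;
* tRNA genes adjacent to the integration sites of a configurable fraction of
  implants;
* CRISPR repeat-spacer arrays whose spacers are sampled (exactly, or with
  per-base substitutions) from the implanted prophages of the same genome.

Every implant and every spacer is recorded in a :class:`TruthTable` so that
recovery of regions, completeness classes, spacers and protospacer hits can
be scored exactly.  Host background genes carry no phage-lexicon products, so
false positives are measurable.

Insertion sites sit in gene-sparse "integration islands" at least 2.5 kb from
the nearest host CDS: boundary refinement extends through same-strand
neighbours only across gaps under 1 kb, so a correctly refined region can
absorb the adjacent tRNA but never a host gene.  tRNA annotations and CRISPR
loci are written in place over intergenic background, so the final genome
length is exactly the host length plus the summed implant lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome_io import Feature, GenomeRecord, write_genomes
from .lexicon import MODULES

BASES = np.array(list("ACGT"))

#: Products used for generated phage genes, per module.
MODULE_PRODUCTS: dict[str, tuple[str, ...]] = {
    "integration_excision": ("phage integrase", "excisionase"),
    "lysis": ("holin", "endolysin"),
    "dna_replication": ("DNA primase", "replicative DNA helicase", "phage DNA replication protein"),
    "dna_packaging": ("terminase large subunit", "portal protein"),
    "head_tail": (
        "major capsid protein",
        "head maturation protease",
        "major tail protein",
        "minor tail protein",
        "tail fiber protein",
    ),
}

#: Extra genes appended to large phages (kept inside the head/tail block).
EXTRA_PRODUCTS = ("minor tail protein", "putative tail protein", "hypothetical protein")

#: Host background products; none of these matches the phage lexicon.
HOST_PRODUCTS = (
    "ABC transporter ATP-binding protein",
    "MFS transporter",
    "ribosomal protein L3",
    "elongation factor Tu",
    "sugar ABC transporter permease",
    "LacI family transcriptional regulator",
    "aminopeptidase",
    "phosphoglycerate kinase",
    "cell division protein FtsZ",
    "chaperone protein DnaK",
    "UDP-glucose 4-epimerase",
    "branched-chain amino acid aminotransferase",
)

#: Host GC defaults per species (prophage GC tracks the host in the survey).
SPECIES_GC = {
    "adolescentis": 0.590,
    "bifidum": 0.620,
    "breve": 0.598,
    "longum_longum": 0.610,
    "longum_infantis": 0.610,
}

#: Relative species abundances of the 585-genome survey (52/96/108/288/41).
SPECIES_WEIGHTS = {
    "adolescentis": 52,
    "bifidum": 96,
    "breve": 108,
    "longum_longum": 288,
    "longum_infantis": 41,
}

STOP_CODONS = ("TAA", "TAG", "TGA")


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def make_gene(rng: np.random.Generator, length: int, gc: float) -> str:
    """A real ORF: ATG + stop-free GC-biased codons + TAA, ``length`` nt."""
    length -= length % 3
    if length < 9:
        raise ValueError("gene length must be at least 9 nt")
    codons = []
    while 3 * len(codons) < length - 6:
        codon = random_dna(rng, 3, gc)
        if codon in STOP_CODONS:
            continue
        codons.append(codon)
    return "ATG" + "".join(codons) + "TAA"


def mutate_sequence(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Per-base substitution at ``rate``; returns (sequence, n substitutions)."""
    if rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    for i in np.flatnonzero(mask):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), int(mask.sum())


# ---------------------------------------------------------------------------
# phage templates and instances


@dataclass(frozen=True)
class PhageTemplate:
    """Abstract recipe for a modular temperate phage.

    The integrase-bearing module must be first or last in ``module_order``
    and the packaging and head/tail modules must be adjacent, mirroring the
    conserved gene order of temperate actinobacteriophages.
    """

    template_id: str
    module_order: tuple[str, ...] = (
        "integration_excision",
        "lysis",
        "dna_replication",
        "dna_packaging",
        "head_tail",
    )
    genes_per_module: dict[str, int] = field(
        default_factory=lambda: {
            "integration_excision": 2,
            "lysis": 2,
            "dna_replication": 3,
            "dna_packaging": 2,
            "head_tail": 5,
        }
    )
    gene_len_range: tuple[int, int] = (600, 1500)
    intergenic_range: tuple[int, int] = (2, 200)
    pad_range: tuple[int, int] = (10, 50)
    gc: float = 0.60
    target_length: int | None = None

    def __post_init__(self) -> None:
        if sorted(self.module_order) != sorted(MODULES):
            raise ValueError("module_order must contain each of the five modules exactly once")
        idx = {m: i for i, m in enumerate(self.module_order)}
        if idx["integration_excision"] not in (0, len(self.module_order) - 1):
            raise ValueError("integration/excision module must be first or last")
        if abs(idx["head_tail"] - idx["dna_packaging"]) != 1:
            raise ValueError("head/tail and packaging modules must be adjacent")


@dataclass(frozen=True)
class GeneUnit:
    """One gene plus its trailing intergenic gap within a phage instance."""

    module: str
    product: str
    strand: str
    unit_start: int
    gene_start: int
    gene_end: int
    unit_end: int


@dataclass
class PhageInstance:
    """A concrete phage sequence with features and module bookkeeping."""

    template_id: str
    sequence: str
    features: list[Feature]
    units: list[GeneUnit]
    gc: float

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def modules_present(self) -> frozenset:
        return frozenset(u.module for u in self.units)


def generate_phage(template: PhageTemplate, rng: np.random.Generator) -> PhageInstance:
    """Instantiate a template into sequence + features.

    The integrase lands at the integration-module end of the sequence; genes
    within a module share a strand and strand flips only happen across module
    boundaries, so the same-strand/<1 kb co-transcription criterion holds
    within intact implants.
    """
    for m in MODULES:
        if template.genes_per_module.get(m, 0) < 1:
            raise ValueError(f"template {template.template_id!r}: module {m!r} has no genes")

    # plan (module, product) gene list
    plan: list[tuple[str, str]] = []
    last = len(template.module_order) - 1
    for mi, module in enumerate(template.module_order):
        n = template.genes_per_module[module]
        products = [MODULE_PRODUCTS[module][i % len(MODULE_PRODUCTS[module])] for i in range(n)]
        if module == "integration_excision" and mi == last:
            products.reverse()  # integrase last gene overall
        plan.append((module, products[0]))
        plan.extend((module, p) for p in products[1:])

    lo, hi = template.gene_len_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in plan]
    gaps = [int(rng.integers(*template.intergenic_range)) for _ in plan]
    if template.target_length is not None:
        mean_unit = (lo + hi) / 2 + sum(template.intergenic_range) / 2
        ht_end = max(i for i, (m, _) in enumerate(plan) if m == "head_tail")
        est = sum(lengths) + sum(gaps[:-1]) + 2 * sum(template.pad_range) // 2
        j = 0
        while est + mean_unit < template.target_length:
            product = EXTRA_PRODUCTS[j % len(EXTRA_PRODUCTS)]
            glen = int(rng.integers(lo, hi + 1))
            gap = int(rng.integers(*template.intergenic_range))
            plan.insert(ht_end + 1, ("head_tail", product))
            lengths.insert(ht_end + 1, glen)
            gaps.insert(ht_end + 1, gap)
            ht_end += 1
            est += glen + gap
            j += 1

    strands: list[str] = []
    cur = "+"
    prev_module = None
    for module, _ in plan:
        if prev_module is not None and module != prev_module and rng.random() < 0.5:
            cur = "-" if cur == "+" else "+"
        strands.append(cur)
        prev_module = module

    parts: list[str] = []
    units: list[GeneUnit] = []
    features: list[Feature] = []
    pos = int(rng.integers(*template.pad_range))
    parts.append(random_dna(rng, pos, template.gc))
    for i, ((module, product), glen, strand) in enumerate(zip(plan, lengths, strands)):
        gene = make_gene(rng, glen, template.gc)
        if strand == "-":
            gene = gene.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        gene_start, gene_end = pos, pos + len(gene)
        gap = gaps[i] if i < len(plan) - 1 else 0
        parts.append(gene)
        if gap:
            parts.append(random_dna(rng, gap, template.gc))
        units.append(
            GeneUnit(
                module=module,
                product=product,
                strand=strand,
                unit_start=gene_start,
                gene_start=gene_start,
                gene_end=gene_end,
                unit_end=gene_end + gap,
            )
        )
        features.append(Feature(kind="CDS", start=gene_start, end=gene_end, strand=strand, product=product))
        pos = gene_end + gap
    right_pad = int(rng.integers(*template.pad_range))
    parts.append(random_dna(rng, right_pad, template.gc))
    return PhageInstance(
        template_id=template.template_id,
        sequence="".join(parts),
        features=features,
        units=units,
        gc=template.gc,
    )


def degrade_prophage(
    phage: PhageInstance, drop_modules: set[str], rng: np.random.Generator
) -> PhageInstance:
    """Remove all genes of the dropped modules together with their trailing
    intergenic spans; remaining gene order is preserved."""
    del rng  # interface symmetry; degradation itself is deterministic
    if not drop_modules:
        raise ValueError("drop_modules must be a non-empty subset of the five modules")
    if not drop_modules <= set(MODULES):
        raise ValueError(f"unknown modules: {sorted(set(drop_modules) - set(MODULES))}")
    if drop_modules >= set(MODULES):
        raise ValueError("cannot drop all five modules: phage would be empty")
    kept = [u for u in phage.units if u.module not in drop_modules]
    if not kept:
        raise ValueError("degradation would remove every gene")
    left_pad = phage.sequence[: phage.units[0].unit_start]
    right_pad = phage.sequence[phage.units[-1].unit_end :]
    parts = [left_pad]
    new_units: list[GeneUnit] = []
    new_features: list[Feature] = []
    pos = len(left_pad)
    for u in kept:
        span = phage.sequence[u.unit_start : u.unit_end]
        shift = pos - u.unit_start
        new_units.append(
            GeneUnit(
                module=u.module,
                product=u.product,
                strand=u.strand,
                unit_start=u.unit_start + shift,
                gene_start=u.gene_start + shift,
                gene_end=u.gene_end + shift,
                unit_end=u.unit_end + shift,
            )
        )
        new_features.append(
            Feature(
                kind="CDS",
                start=u.gene_start + shift,
                end=u.gene_end + shift,
                strand=u.strand,
                product=u.product,
            )
        )
        parts.append(span)
        pos += len(span)
    parts.append(right_pad)
    return PhageInstance(
        template_id=phage.template_id,
        sequence="".join(parts),
        features=new_features,
        units=new_units,
        gc=phage.gc,
    )


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class SpacerProvenance:
    """Where one implanted CRISPR spacer came from."""

    spacer_id: str
    genome_id: str
    array_index: int
    position: int
    sequence: str
    origin_start: int
    origin_end: int
    origin_strand: str
    n_mutations: int


@dataclass
class TruthRecord:
    """Ground truth for one implanted prophage."""

    genome_id: str
    start: int
    end: int
    intact: bool
    modules_present: frozenset
    trna_adjacent: bool
    template_id: str
    genes: list[tuple[int, int, str, str]] = field(default_factory=list)  # start, end, strand, product
    spacer_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)
    spacers: list[SpacerProvenance] = field(default_factory=list)

    def implants_for(self, genome_id: str) -> list[TruthRecord]:
        return [r for r in self.records if r.genome_id == genome_id]


# ---------------------------------------------------------------------------
# host scaffolds


@dataclass
class Island:
    """A gene-sparse insertion island; implants land only here."""

    start: int
    end: int
    trna: tuple[int, int] | None = None
    used: bool = False


@dataclass
class HostScaffold:
    genome: GenomeRecord
    islands: list[Island]
    crispr_zone: tuple[int, int]
    crispr_cursor: int
    truths: list[TruthRecord] = field(default_factory=list)
    n_arrays: int = 0


ISLAND_LEN = 6000
CRISPR_ZONE_LEN = 4000


def build_host(
    genome_id: str,
    species_label: str,
    length: int,
    gc: float,
    rng: np.random.Generator,
    n_islands: int = 8,
) -> HostScaffold:
    """Random annotated host chromosome with alternating gene blocks and
    insertion islands, plus a reserved intergenic zone for CRISPR arrays."""
    min_len = n_islands * ISLAND_LEN + CRISPR_ZONE_LEN + (n_islands + 1) * 2000
    if length < min_len:
        raise ValueError(f"host length {length} too short (minimum {min_len})")
    sequence = random_dna(rng, length, gc)
    features: list[Feature] = []
    islands: list[Island] = []
    block_len = (length - n_islands * ISLAND_LEN - CRISPR_ZONE_LEN) // (n_islands + 1)

    pos = 0
    for b in range(n_islands + 1):
        block_end = pos + block_len
        cursor = pos + int(rng.integers(150, 400))
        while True:
            glen = int(rng.integers(750, 1050))
            if cursor + glen > block_end - 150:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            product = HOST_PRODUCTS[int(rng.integers(0, len(HOST_PRODUCTS)))]
            features.append(Feature(kind="CDS", start=cursor, end=cursor + glen, strand=strand, product=product))
            cursor += glen + int(rng.integers(150, 400))
        pos = block_end
        if b < n_islands:
            island = Island(start=pos, end=pos + ISLAND_LEN)
            if b % 2 == 0:
                t0 = pos + ISLAND_LEN // 2 - 38
                island.trna = (t0, t0 + 76)
                features.append(Feature(kind="tRNA", start=t0, end=t0 + 76, strand="+", product="tRNA-Met"))
            islands.append(island)
            pos += ISLAND_LEN
    zone = (pos, pos + CRISPR_ZONE_LEN)
    genome = GenomeRecord(id=genome_id, sequence=sequence, species_label=species_label, features=features)
    return HostScaffold(genome=genome, islands=islands, crispr_zone=zone, crispr_cursor=zone[0] + 50)


def _shift_scaffold(scaffold: HostScaffold, site: int, delta: int) -> None:
    g = scaffold.genome
    g.features = [f.shifted(delta) if f.start >= site else f for f in g.features]
    for isl in scaffold.islands:
        if isl.start >= site:
            isl.start += delta
            isl.end += delta
            if isl.trna:
                isl.trna = (isl.trna[0] + delta, isl.trna[1] + delta)
    if scaffold.crispr_zone[0] >= site:
        scaffold.crispr_zone = (scaffold.crispr_zone[0] + delta, scaffold.crispr_zone[1] + delta)
        scaffold.crispr_cursor += delta
    for t in scaffold.truths:
        if t.start >= site:
            t.start += delta
            t.end += delta
            t.genes = [(a + delta, b + delta, s, p) for a, b, s, p in t.genes]


def implant_prophage(
    scaffold: HostScaffold,
    phage: PhageInstance,
    rng: np.random.Generator,
    trna_adjacent: bool,
    intact: bool | None = None,
    site: int | None = None,
) -> TruthRecord:
    """Insert a phage instance into the host at an insertion island.

    When ``trna_adjacent`` the site is placed 50-300 bp from an annotated tRNA
    so the refined boundary can absorb it while staying within 500 bp of
    truth.  ``site`` overrides island selection (unit-test hook); it must not
    fall inside an existing feature.
    """
    g = scaffold.genome
    if site is None:
        wanted = [i for i in scaffold.islands if not i.used and (i.trna is not None) == trna_adjacent]
        fallback = [i for i in scaffold.islands if not i.used]
        pool = wanted or fallback
        if not pool:
            raise ValueError(f"genome {g.id!r}: no free insertion island for implant")
        island = pool[int(rng.integers(0, len(pool)))]
        if island.trna is not None:
            site = island.trna[1] + int(rng.integers(50, 301))
        else:
            site = (island.start + island.end) // 2
        island.used = True
        actually_adjacent = island.trna is not None
    else:
        actually_adjacent = any(
            f.kind == "tRNA" and min(abs(f.end - site), abs(site - f.start)) <= 500 for f in g.features
        )
    for f in g.features:
        if f.start < site < f.end:
            raise ValueError(f"insertion site {site} inside feature [{f.start}, {f.end})")

    L = len(phage)
    _shift_scaffold(scaffold, site, L)
    g.sequence = g.sequence[:site] + phage.sequence + g.sequence[site:]
    g.features.extend(f.shifted(site) for f in phage.features)
    g.features.sort(key=lambda f: (f.start, f.end, f.kind))
    truth = TruthRecord(
        genome_id=g.id,
        start=site,
        end=site + L,
        intact=bool(intact) if intact is not None else (phage.modules_present == frozenset(MODULES)),
        modules_present=phage.modules_present,
        trna_adjacent=actually_adjacent,
        template_id=phage.template_id,
        genes=[(u.gene_start + site, u.gene_end + site, u.strand, u.product) for u in phage.units],
    )
    scaffold.truths.append(truth)
    scaffold.truths.sort(key=lambda t: t.start)
    return truth


def implant_crispr(
    scaffold: HostScaffold,
    n_spacers: int,
    rng: np.random.Generator,
    spacer_len: int = 33,
    mutation_rate: float = 0.0,
) -> list[SpacerProvenance]:
    """Write a repeat-spacer locus R S1 R S2 ... R over the reserved zone.

    Spacers are sampled from gene bodies of this genome's implants, on either
    strand, each independently mutated per base at ``mutation_rate``.
    """
    if not scaffold.truths:
        raise ValueError("implant_crispr requires at least one implanted prophage")
    if n_spacers < 1:
        raise ValueError("n_spacers must be >= 1")
    g = scaffold.genome
    repeat_len = int(rng.integers(26, 41))
    repeat = random_dna(rng, repeat_len, 0.5)
    ai = scaffold.n_arrays
    provenances: list[SpacerProvenance] = []
    parts = [repeat]
    for si in range(n_spacers):
        truth = scaffold.truths[int(rng.integers(0, len(scaffold.truths)))]
        genes = [gn for gn in truth.genes if gn[1] - gn[0] >= spacer_len + 2]
        if not genes:
            raise ValueError(
                f"genome {g.id!r}: implant at {truth.start} has no gene long enough for a "
                f"{spacer_len} bp spacer"
            )
        gs, ge, _, _ = genes[int(rng.integers(0, len(genes)))]
        o = int(rng.integers(gs, ge - spacer_len + 1))
        raw = g.sequence[o : o + spacer_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            raw = raw.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seq, n_mut = mutate_sequence(rng, raw, mutation_rate)
        sp_id = f"{g.id}|arr{ai}|sp{si}"
        provenances.append(
            SpacerProvenance(
                spacer_id=sp_id,
                genome_id=g.id,
                array_index=ai,
                position=si,
                sequence=seq,
                origin_start=o,
                origin_end=o + spacer_len,
                origin_strand=strand,
                n_mutations=n_mut,
            )
        )
        truth.spacer_ids.append(sp_id)
        parts.append(seq)
        parts.append(repeat)
    locus = "".join(parts)
    start = scaffold.crispr_cursor
    if start + len(locus) + 50 > scaffold.crispr_zone[1]:
        raise ValueError(f"genome {g.id!r}: CRISPR zone exhausted")
    g.sequence = g.sequence[:start] + locus + g.sequence[start + len(locus) :]
    g.features.append(
        Feature(kind="repeat_region", start=start, end=start + len(locus), strand=".", product="CRISPR direct repeat region")
    )
    g.features.sort(key=lambda f: (f.start, f.end, f.kind))
    scaffold.crispr_cursor = start + len(locus) + int(rng.integers(120, 200))
    scaffold.n_arrays += 1
    return provenances


# ---------------------------------------------------------------------------
# whole-dataset generation


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic datasets.

    Defaults mirror the printed conditions of the survey: 0.82 prophages per
    genome within a 0-6 range, implant sizes within 4.5-51.2 kb, per-species
    host GC 0.59-0.62, and mutation-free spacer acquisition.
    """

    seed: int
    n_genomes: int = 20
    host_length: int = 120_000
    species_gc: dict = field(default_factory=lambda: dict(SPECIES_GC))
    implants_range: tuple[int, int] = (0, 6)
    mean_implants: float = 0.82
    implant_size_range: tuple[int, int] = (4_500, 51_200)
    remnant_fraction: float = 0.4
    spacers_per_array: int = 5
    spacer_len: int = 33
    spacer_mutation_rate: float = 0.0
    implant_mutation_rate: float = 0.0
    n_intact_templates: int = 5
    n_remnant_templates: int = 4
    trna_adjacent_prob: float = 0.6
    n_islands: int = 8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.implants_range[0] >= self.implants_range[1]:
            raise ValueError("implants_range must be non-degenerate")
        if self.implant_size_range[0] >= self.implant_size_range[1]:
            raise ValueError("implant_size_range must be non-degenerate")
        if not 25 <= self.spacer_len <= 60:
            raise ValueError("spacer_len must lie in [25, 60]")
        if self.n_genomes < 0:
            raise ValueError("n_genomes must be >= 0")


@dataclass
class Dataset:
    genomes: list[GenomeRecord]
    truth: TruthTable


def _make_templates(config: GeneratorConfig, rng: np.random.Generator):
    """Instantiate the template pools once per dataset.

    Intact templates target >= 22 kb so that an all-module implant satisfies
    the likely-complete rule (>= 20 kb + boundary integrase + >= 4 modules);
    remnant-source templates span down to 15 kb and shrink under degradation,
    covering the small end of the printed 4.5-51.2 kb size range.
    """
    lo, hi = config.implant_size_range
    intact, remnant = [], []
    for i in range(config.n_intact_templates):
        target = int(rng.integers(max(lo, 22_000), hi + 1))
        gc = float(np.mean(list(config.species_gc.values())) + rng.normal(0, 0.005))
        tpl = PhageTemplate(template_id=f"T{i:02d}", gc=round(min(max(gc, 0.3), 0.8), 4), target_length=target)
        intact.append(generate_phage(tpl, rng))
    for i in range(config.n_remnant_templates):
        target = int(rng.integers(max(lo, 15_000), hi + 1))
        gc = float(np.mean(list(config.species_gc.values())) + rng.normal(0, 0.005))
        tpl = PhageTemplate(
            template_id=f"R{i:02d}", gc=round(min(max(gc, 0.3), 0.8), 4), target_length=target
        )
        remnant.append(generate_phage(tpl, rng))
    return intact, remnant


def _mutated_copy(inst: PhageInstance, rate: float, rng: np.random.Generator) -> PhageInstance:
    if rate <= 0:
        return inst
    seq, _ = mutate_sequence(rng, inst.sequence, rate)
    return replace(inst, sequence=seq)


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Generate the full synthetic dataset; deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    if config.n_genomes == 0:
        return Dataset(genomes=[], truth=TruthTable())
    intact_pool, remnant_pool = _make_templates(config, rng)
    labels = sorted(SPECIES_WEIGHTS)
    weights = np.array([SPECIES_WEIGHTS[s] for s in labels], dtype=float)
    weights /= weights.sum()

    genomes: list[GenomeRecord] = []
    truth = TruthTable()
    for i in range(config.n_genomes):
        species = labels[int(rng.choice(len(labels), p=weights))]
        strain = f"S{i + 1:03d}"
        scaffold = build_host(
            genome_id=strain,
            species_label=species,
            length=config.host_length,
            gc=config.species_gc[species],
            rng=rng,
            n_islands=config.n_islands,
        )
        n_impl = int(min(max(rng.poisson(config.mean_implants), config.implants_range[0]), config.implants_range[1]))
        n_impl = min(n_impl, len(scaffold.islands))
        for _ in range(n_impl):
            make_intact = rng.random() >= config.remnant_fraction
            if make_intact:
                inst = intact_pool[int(rng.integers(0, len(intact_pool)))]
            else:
                base = remnant_pool[int(rng.integers(0, len(remnant_pool)))]
                drops = {"head_tail", "dna_packaging"}
                if rng.random() < 0.5:
                    drops.add("lysis")
                inst = degrade_prophage(base, drops, rng)
            inst = _mutated_copy(inst, config.implant_mutation_rate, rng)
            trna_adj = rng.random() < config.trna_adjacent_prob
            implant_prophage(scaffold, inst, rng, trna_adjacent=trna_adj)
        if scaffold.truths and config.spacers_per_array >= 1:
            provs = implant_crispr(
                scaffold,
                n_spacers=config.spacers_per_array,
                rng=rng,
                spacer_len=config.spacer_len,
                mutation_rate=config.spacer_mutation_rate,
            )
            truth.spacers.extend(provs)
        truth.records.extend(scaffold.truths)
        genomes.append(scaffold.genome)
    return Dataset(genomes=genomes, truth=truth)


# ---------------------------------------------------------------------------
# plain-text writers / readers for the truth tables


def write_dataset(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write genomes (FASTA + GFF3) and truth tables (TSV) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genomes.fna",
        "gff3": outdir / "genomes.gff3",
        "implants": outdir / "truth_implants.tsv",
        "genes": outdir / "truth_genes.tsv",
        "spacers": outdir / "truth_spacers.tsv",
    }
    write_genomes(dataset.genomes, paths["fasta"], paths["gff3"])
    lines = ["genome_id\tstart\tend\tintact\tmodules\ttrna_adjacent\ttemplate_id\tspacer_ids"]
    for r in dataset.truth.records:
        lines.append(
            "\t".join(
                [
                    r.genome_id,
                    str(r.start),
                    str(r.end),
                    str(int(r.intact)),
                    ",".join(sorted(r.modules_present)),
                    str(int(r.trna_adjacent)),
                    r.template_id,
                    ",".join(r.spacer_ids),
                ]
            )
        )
    paths["implants"].write_text("\n".join(lines) + "\n")
    lines = ["genome_id\timplant_start\tgene_start\tgene_end\tstrand\tproduct"]
    for r in dataset.truth.records:
        for a, b, s, p in r.genes:
            lines.append(f"{r.genome_id}\t{r.start}\t{a}\t{b}\t{s}\t{p}")
    paths["genes"].write_text("\n".join(lines) + "\n")
    lines = [
        "spacer_id\tgenome_id\tarray_index\tposition\tsequence\torigin_start\torigin_end\torigin_strand\tn_mutations"
    ]
    for s in dataset.truth.spacers:
        lines.append(
            "\t".join(
                [
                    s.spacer_id,
                    s.genome_id,
                    str(s.array_index),
                    str(s.position),
                    s.sequence,
                    str(s.origin_start),
                    str(s.origin_end),
                    s.origin_strand,
                    str(s.n_mutations),
                ]
            )
        )
    paths["spacers"].write_text("\n".join(lines) + "\n")
    return paths
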