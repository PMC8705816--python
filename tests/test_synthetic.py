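"""Generator invariants: determinism, conservation, provenance, degradation."""

import numpy as np
import pytest

from bifiphage.lexicon import MODULES, product_module
from bifiphage.synthetic import (
    GeneratorConfig,
    PhageTemplate,
    build_host,
    degrade_prophage,
    generate_dataset,
    generate_phage,
    implant_crispr,
    implant_prophage,
    mutate_sequence,
    write_dataset,
)
from oracles import rc


def test_phage_construction_rules():
    """Exactly one integrase at the sequence boundary, structural genes
    present, genes non-overlapping, same seed reproduces the sequence."""
    tpl = PhageTemplate(template_id="t")
    inst = generate_phage(tpl, np.random.default_rng(5))
    products = [u.product for u in inst.units]
    assert products.count("phage integrase") == 1
    assert products[0] == "phage integrase"  # module first -> boundary gene
    assert any("capsid" in p for p in products)
    for a, b in zip(inst.units, inst.units[1:]):
        assert a.gene_end <= b.gene_start
    again = generate_phage(tpl, np.random.default_rng(5))
    assert again.sequence == inst.sequence


def test_template_invariants_enforced():
    with pytest.raises(ValueError, match="first or last"):
        PhageTemplate(
            template_id="bad",
            module_order=("lysis", "integration_excision", "dna_replication", "dna_packaging", "head_tail"),
        )
    with pytest.raises(ValueError, match="adjacent"):
        PhageTemplate(
            template_id="bad2",
            module_order=("integration_excision", "dna_packaging", "dna_replication", "head_tail", "lysis"),
        )
    tpl = PhageTemplate(template_id="empty")
    tpl.genes_per_module["lysis"] = 0
    with pytest.raises(ValueError, match="no genes"):
        generate_phage(tpl, np.random.default_rng(0))


def test_targeted_template_lengths_within_configured_range():
    rng = np.random.default_rng(9)
    for i in range(10):
        target = int(rng.integers(15_000, 51_200))
        tpl = PhageTemplate(template_id=f"t{i}", target_length=target)
        inst = generate_phage(tpl, rng)
        assert 4_500 <= len(inst) <= 51_200
        assert abs(len(inst) - target) < 3_000


def test_degradation_arithmetic_and_errors():
    tpl = PhageTemplate(template_id="t")
    inst = generate_phage(tpl, np.random.default_rng(2))
    rng = np.random.default_rng(0)

    removed_span = sum(u.unit_end - u.unit_start for u in inst.units if u.module == "lysis")
    rem = degrade_prophage(inst, {"lysis"}, rng)
    assert len(inst) - len(rem) == removed_span
    assert [u.product for u in rem.units] == [u.product for u in inst.units if u.module != "lysis"]

    rem2 = degrade_prophage(inst, {"head_tail", "dna_packaging"}, rng)
    assert not any(
        "capsid" in u.product or "terminase" in u.product for u in rem2.units
    )
    assert rem2.modules_present == frozenset(MODULES) - {"head_tail", "dna_packaging"}

    with pytest.raises(ValueError):
        degrade_prophage(inst, set(), rng)
    with pytest.raises(ValueError):
        degrade_prophage(inst, set(MODULES), rng)


def test_implant_conserves_length_and_trna_adjacency():
    rng = np.random.default_rng(3)
    host = build_host("h1", "breve", 120_000, 0.60, rng)
    host_len = len(host.genome.sequence)
    tpl = PhageTemplate(template_id="t", target_length=20_000)
    inst = generate_phage(tpl, rng)
    truth = implant_prophage(host, inst, rng, trna_adjacent=True)
    assert len(host.genome.sequence) == host_len + len(inst)
    assert truth.end - truth.start == len(inst)
    trnas = [f for f in host.genome.features if f.kind == "tRNA"]
    assert any(min(abs(truth.start - t.end), abs(t.start - truth.end)) <= 500 for t in trnas)
    # insertion site was intergenic: no feature straddles the boundary
    for f in host.genome.features:
        assert not (f.start < truth.start < f.end)


def test_crispr_locus_structure_and_mutation_free_provenance():
    rng = np.random.default_rng(4)
    host = build_host("h2", "bifidum", 120_000, 0.62, rng)
    inst = generate_phage(PhageTemplate(template_id="t", target_length=25_000), rng)
    implant_prophage(host, inst, rng, trna_adjacent=False)
    provs = implant_crispr(host, n_spacers=3, rng=rng, spacer_len=33, mutation_rate=0.0)
    assert len(provs) == 3
    seq = host.genome.sequence
    locus_feat = [f for f in host.genome.features if f.kind == "repeat_region"][0]
    locus = seq[locus_feat.start : locus_feat.end]
    # R S1 R S2 R S3 R: 4 identical repeat copies
    repeat = locus[: (len(locus) - 3 * 33) // 4]
    assert locus.count(repeat) == 4
    for p in provs:
        origin = seq[p.origin_start : p.origin_end]
        assert p.sequence in (origin, rc(origin))
        assert p.n_mutations == 0
        assert p.sequence in locus


def test_mutation_rate_binomial_expectation():
    """33 bp at per-base rate 0.05 over 1000 replicates: mean substitutions
    approximately 33 * 0.05 = 1.65, within a generous binomial CI."""
    rng = np.random.default_rng(6)
    base = "ACGT" * 9  # 36 -> use 33
    base = base[:33]
    muts = [mutate_sequence(rng, base, 0.05)[1] for _ in range(1000)]
    mean = np.mean(muts)
    sd = np.sqrt(33 * 0.05 * 0.95 / 1000)
    assert abs(mean - 1.65) < 4 * sd + 0.05


def test_dataset_determinism_and_length_conservation(tmp_path):
    cfg = GeneratorConfig(seed=1, n_genomes=3)
    d1 = generate_dataset(cfg)
    d2 = generate_dataset(GeneratorConfig(seed=1, n_genomes=3))
    p1 = write_dataset(d1, tmp_path / "a")
    p2 = write_dataset(d2, tmp_path / "b")
    assert p1["fasta"].read_bytes() == p2["fasta"].read_bytes()
    assert p1["gff3"].read_bytes() == p2["gff3"].read_bytes()
    for g in d1.genomes:
        implanted = sum(t.length for t in d1.truth.implants_for(g.id))
        assert len(g.sequence) == cfg.host_length + implanted


def test_dataset_edge_configs():
    empty = generate_dataset(GeneratorConfig(seed=1, n_genomes=0))
    assert empty.genomes == [] and empty.truth.records == []
    allrem = generate_dataset(GeneratorConfig(seed=2, n_genomes=4, remnant_fraction=1.0))
    assert not any(t.intact for t in allrem.truth.records)
    with pytest.raises(ValueError):
        GeneratorConfig(seed=1, implants_range=(3, 3))


def test_host_background_is_lexicon_free():
    rng = np.random.default_rng(8)
    host = build_host("h3", "breve", 120_000, 0.60, rng)
    for f in host.genome.features:
        if f.kind == "CDS":
            assert product_module(f.product) is None


def test_default_dataset_spacers_all_trace_to_implants(default_dataset):
    """Provenance soundness on the study dataset: every spacer's origin lies
    inside its implant and, mutation-free, occurs verbatim in the genome."""
    by_genome = {g.id: g for g in default_dataset.genomes}
    for sp in default_dataset.truth.spacers:
        implants = default_dataset.truth.implants_for(sp.genome_id)
        assert any(t.start <= sp.origin_start and sp.origin_end <= t.end for t in implants)
        origin = by_genome[sp.genome_id].sequence[sp.origin_start : sp.origin_end]
        assert sp.sequence in (origin, rc(origin))
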