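"""Candidate scanning, boundary refinement, completeness, naming, sizes."""

import itertools

import numpy as np
import pytest

from bifiphage.genome_io import Feature, GenomeRecord
from bifiphage.lexicon import MODULES
from bifiphage.regions import (
    classify_completeness,
    name_prophage,
    refine_boundaries,
    scan_candidates,
    size_summary,
)
from bifiphage.synthetic import PhageTemplate, build_host, generate_phage, implant_prophage


def _genome(features, length=60_000, seed=0):
    rng = np.random.default_rng(seed)
    return GenomeRecord(id="g", sequence="".join(rng.choice(list("ACGT"), length)), features=features)


def _cds(start, end, product, strand="+"):
    return Feature("CDS", start, end, strand, product)


def test_scan_requires_lexicon_matches():
    g = _genome([_cds(1000, 1900, "elongation factor Tu"), _cds(2000, 2900, "MFS transporter")])
    assert scan_candidates(g) == []


def test_scan_finds_each_implant_once(default_dataset):
    """Every mutation-free implant yields exactly one candidate overlapping
    its truth interval; implants in one genome stay disjoint."""
    by_genome = {g.id: g for g in default_dataset.genomes}
    for gid, g in by_genome.items():
        truths = default_dataset.truth.implants_for(gid)
        cands = scan_candidates(g)
        assert len(cands) == len(truths)
        for t in sorted(truths, key=lambda t: t.start):
            overlapping = [c for c in cands if min(c[1], t.end) - max(c[0], t.start) > 0]
            assert len(overlapping) == 1
        for (a1, b1), (a2, b2) in itertools.combinations(cands, 2):
            assert min(b1, b2) <= max(a1, a2)


def test_refine_absorbs_nearby_integrase_but_not_distant_cds():
    run = [_cds(10_000 + i * 1_100, 10_000 + i * 1_100 + 900, p) for i, p in enumerate(
        ["holin", "endolysin", "terminase large subunit", "major capsid protein"]
    )]
    candidate = (run[0].start, run[-1].end)

    # integrase ending 800 bp left of the candidate: absorbed (criterion i)
    integrase = _cds(8_300, 9_200, "phage integrase")
    g = _genome(run + [integrase])
    assert refine_boundaries(candidate, g) == (8_300, candidate[1])

    # same-strand plain CDS 1,500 bp beyond the edge: not absorbed (iii needs < 1 kb)
    plain = _cds(candidate[1] + 1_500, candidate[1] + 2_400, "elongation factor Tu")
    g = _genome(run + [plain])
    assert refine_boundaries(candidate, g) == candidate

    # same-strand CDS 800 bp beyond: absorbed by co-transcription rule
    near = _cds(candidate[1] + 800, candidate[1] + 1_700, "elongation factor Tu")
    g = _genome(run + [near])
    assert refine_boundaries(candidate, g) == (candidate[0], near.end)


def test_refine_bridges_hypotheticals_to_lexicon_cds():
    run = [_cds(20_000 + i * 1_100, 20_000 + i * 1_100 + 900, "holin") for i in range(4)]
    candidate = (run[0].start, run[-1].end)
    bridge = [
        _cds(candidate[1] + 1_200, candidate[1] + 1_500, "hypothetical protein", "-"),
        _cds(candidate[1] + 1_700, candidate[1] + 2_000, "hypothetical protein", "-"),
        _cds(candidate[1] + 2_200, candidate[1] + 3_100, "major tail protein", "-"),
    ]
    g = _genome(run + bridge)
    refined = refine_boundaries(candidate, g)
    assert refined == (candidate[0], bridge[-1].end)
    assert refine_boundaries(refined, g) == refined  # idempotent at the fixed point


def test_refine_widening_only_with_side_cap():
    # a pathological same-strand gene chain: absorption stops at the 15 kb cap
    chain = [_cds(30_000 + i * 950, 30_000 + i * 950 + 800, "elongation factor Tu") for i in range(25)]
    run = [_cds(54_000 + i * 1_000, 54_000 + i * 1_000 + 900, p) for i, p in enumerate(
        ["holin", "terminase large subunit", "portal protein", "major capsid protein"]
    )]
    g = _genome(chain + run, length=80_000)
    candidate = (run[0].start, run[-1].end)
    refined = refine_boundaries(candidate, g)
    assert refined[0] >= candidate[0] - 15_000
    assert refined[0] <= candidate[0] and refined[1] >= candidate[1]  # widening only


def test_refine_idempotent_on_study_regions(pipeline_run):
    """Refined study regions are fixed points of another refinement pass."""
    by_genome = {g.id: g for g in pipeline_run.genomes}
    for r in pipeline_run.regions:
        assert refine_boundaries((r.start, r.end), by_genome[r.genome_id]) == (r.start, r.end)


def test_refine_fixed_point_when_flanked_by_distant_trnas():
    run = [_cds(10_000 + i * 1_100, 10_000 + i * 1_100 + 900, "holin") for i in range(4)]
    candidate = (run[0].start, run[-1].end)
    trnas = [
        Feature("tRNA", candidate[0] - 2_500, candidate[0] - 2_424, "+", "tRNA-Met"),
        Feature("tRNA", candidate[1] + 2_500, candidate[1] + 2_576, "+", "tRNA-Met"),
    ]
    g = _genome(run + trnas)
    assert refine_boundaries(candidate, g) == candidate  # outside the 2 kb window


def test_completeness_rules_and_monotonicity():
    allmod = frozenset(MODULES)
    assert classify_completeness(12_000, allmod, True) == "remnant"
    assert classify_completeness(35_000, allmod, True) == "likely_complete"
    assert classify_completeness(25_000, frozenset({"integration_excision", "lysis"}), True) == "remnant"
    assert classify_completeness(25_000, allmod, True) == "likely_complete"
    assert classify_completeness(25_000, allmod, False) == "partial"
    with pytest.raises(ValueError):
        classify_completeness(0, allmod, True)

    rank = {"remnant": 0, "partial": 1, "likely_complete": 2}
    for length in (5_000, 15_000, 25_000, 40_000):
        for base_size in range(len(MODULES)):
            for base in itertools.combinations(MODULES, base_size):
                for extra in set(MODULES) - set(base):
                    lo = classify_completeness(length, frozenset(base), True)
                    hi = classify_completeness(length, frozenset(base) | {extra}, True)
                    assert rank[hi] >= rank[lo]


def test_prophage_naming():
    assert name_prophage("bifidum", "BIOML-A4", 1) == "BifBIOML-A4ph1"
    assert name_prophage("breve", "BR3", 5) == "BreBR3ph5"
    assert name_prophage("adolescentis", "X", 2) == "BadXph2"
    assert name_prophage("longum_infantis", "ATCC15697", 1) == "BlongATCC15697ph1"
    with pytest.raises(ValueError):
        name_prophage("other", "X", 1)


def test_size_summary_statistics():
    s = size_summary([4_000, 4_000, 9_000], n_genomes=3)
    assert (s.median, s.mode) == (4_000.0, 4_000)
    assert s.report_mean_per_genome() == 1.0

    survey = size_summary([10_000] * 480, n_genomes=585)
    assert survey.report_mean_per_genome() == 0.82

    one = size_summary([14_321], n_genomes=1)
    assert one.min == one.max == 14_321 and one.median == 14_321.0 and one.mode == 14_300

    empty = size_summary([], n_genomes=5)
    assert empty.count == 0 and empty.min is None
    with pytest.raises(ValueError):
        size_summary([1_000], n_genomes=0)


def test_two_implants_in_one_genome_give_two_candidates():
    rng = np.random.default_rng(44)
    host = build_host("h", "breve", 130_000, 0.6, rng)
    for adjacent in (True, False):
        inst = generate_phage(PhageTemplate(template_id="t", target_length=16_000), rng)
        implant_prophage(host, inst, rng, trna_adjacent=adjacent)
    cands = scan_candidates(host.genome)
    assert len(cands) == 2
    assert cands[0][1] < cands[1][0]
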