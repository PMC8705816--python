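"""Published counts from the RefSeq survey of human-associated
*Bifidobacterium* prophages that this package re-implements at desk scale.

These tables are inputs, not results: the survey's full dataset (585 RefSeq
assemblies, web-service prophage predictions) cannot be regenerated offline,
but its printed per-taxon counts support exact arithmetic-consistency checks
(totals, ratios) that the analysis scripts and the acceptance script
recompute.
"""

from __future__ import annotations

#: RefSeq genomes per taxon in the survey dataset (total 585).
GENOME_COUNTS = {
    "adolescentis": 52,
    "bifidum": 96,
    "breve": 108,
    "longum_longum": 288,
    "longum_infantis": 41,
}

#: Predicted prophage-like regions per taxon (total 480).
PROPHAGE_COUNTS = {
    "adolescentis": 52,
    "bifidum": 55,
    "breve": 121,
    "longum_longum": 245,
    "longum_infantis": 7,
}

#: Non-redundant CRISPR spacers per species (total 14,501).
SPACER_COUNTS = {
    "adolescentis": 1513,
    "bifidum": 883,
    "breve": 2895,
    "longum": 9210,
}

#: Other headline counts of the survey.
PROTOSPACER_TOTAL = 38_676
SIGNIFICANT_HITS = 1_488
UNIQUE_HIT_SEQUENCES = 638
ANI_CLUSTERS = 24
COMBINED_CLUSTERS = 14
COMBINED_CLUSTER_PROPHAGES = 253
SELECTED_CLUSTERS = 6
SELECTED_PROPHAGES = 17
REGIONS_OVER_30KB = 47

#: Region size statistics (bp) and GC.
SIZE_RANGE_BP = (4_500, 51_200)
MEDIAN_SIZE_BP = 14_300
MODE_SIZE_BP = 9_900
MEDIAN_GC = 0.608


def total_genomes() -> int:
    return sum(GENOME_COUNTS.values())


def total_prophages() -> int:
    return sum(PROPHAGE_COUNTS.values())


def total_spacers() -> int:
    return sum(SPACER_COUNTS.values())


def longum_genomes() -> int:
    """Genomes of the two *B. longum* subspecies combined."""
    return GENOME_COUNTS["longum_longum"] + GENOME_COUNTS["longum_infantis"]


def mean_prophages_per_genome() -> float:
    return total_prophages() / total_genomes()


def mean_unique_spacers_per_genome() -> float:
    return total_spacers() / total_genomes()
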