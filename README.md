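# bifiphage

Comparative analysis of prophages and CRISPR–Cas spacer arrays in
human-associated *Bifidobacterium* genomes (*B. adolescentis*, *B. bifidum*,
*B. breve*, *B. longum* subsp. *longum*/*infantis*), re-implemented as a
tested, desk-scale pipeline over synthetic genomes with known ground truth.

Prophages — phage genomes integrated into the bacterial chromosome — are a
major reservoir of gut phages, and the spacers of bacterial CRISPR arrays
record past encounters with them. The published survey this package follows
analysed 585 RefSeq genomes and found 480 prophage-like regions (0.82 per
genome) and 14,501 non-redundant spacers; neither the RefSeq download nor
the web-service prophage predictor is reproducible offline, so this package
pairs (a) the full analysis machinery with (b) a generator of annotated
synthetic genomes carrying implanted prophages and CRISPR arrays, letting
every stage be scored exactly against truth.

## What the pipeline computes

1. **Prophage regions** — candidate regions as runs of CDS with
   phage-lexicon products; boundary revision to a fixed point with three
   criteria (tRNA/integrase within 2 kb; bridging runs of hypothetical
   proteins to the next phage-lexicon CDS; same-strand co-transcribed
   neighbours at gaps < 1 kb), capped at 15 kb per side; completeness
   classes (*remnant* < 13 kb or lacking structural+packaging modules,
   *likely complete* ≥ 30 kb or ≥ 20 kb with ≥ 4 of 5 modules and a boundary
   integrase, *partial* otherwise); survey nomenclature
   (`BifBIOML-A4ph1` = first phage of *B. bifidum* BIOML-A4).
2. **ANI clustering** — fragment-based average nucleotide identity (1,020 bp
   fragments, affine local alignment, identity ≥ 30% and fragment coverage
   ≥ 70% acceptance), symmetrised matrix, single-linkage clusters at
   ANI ≥ 0.9.
3. **Gene families** — six-frame ORF calling (table 11) with
   longest-first gene selection, all-vs-all BLOSUM62 local alignment with
   Karlin–Altschul E-values (edges at E ≤ 1e−5), from-scratch Markov
   clustering (expansion/inflation, r = 2), binary family × prophage
   presence/absence matrix, and selection of clusters of interest
   (≥ 2 members, mean profile Jaccard ≥ 0.5, ≥ 1 likely-complete member,
   all members ≥ 13 kb).
4. **CRISPR spacers** — exact repeat-spacer array detection (repeat
   23–55 bp, spacers 25–60 bp, ≥ 3 copies) and CD-HIT-style greedy
   deduplication at 90% identity.
5. **Protospacers** — spacer-vs-prophage matching (11-bp seeds, affine
   local alignment) at E ≤ 0.01 and identity ≥ 98%, merged unique target
   loci, and targeted-gene extraction.
6. **Phylogeny** — intergenomic distances from non-overlapping HSPs,
   d0 = 1 − 2H/(L1+L2), d4 = 1 − I/H, d6 = 1 − 2I/(L1+L2); midpoint-rooted
   neighbor-joining trees per formula; link-fraction clustering (F = 0.5).

## Worked example

```python
from bifiphage import GeneratorConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="results/pipeline",
                     generator=GeneratorConfig(seed=7))
result = run_pipeline(cfg)
m = result.metrics
print(m.n_truth, m.region_precision, m.region_recall,
      round(m.mean_boundary_error_bp, 1), m.spacer_recovery)
```

prints (seed 7):

```
12 1.0 1.0 130.6 1.0
```

meaning: the generator implanted 12 prophages across 20 genomes; every one
was recovered (precision and recall 1.0) with a mean boundary error of
130.6 bp against the implanted coordinates, and all 40 implanted CRISPR
spacers were re-detected verbatim. The report bundle under
`results/pipeline/` (see `manifest.tsv`) holds the region tables, ANI and
distance matrices, family matrices, spacer FASTA, protospacer hits and
newick trees; `evaluation.tsv` holds the scores above.

The numbered scripts under `analysis/` run the same stages as a narrative:
`01_simulate.py` … `07_survey_consistency.py`, each printing what it found
and writing its tables under `results/`.

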