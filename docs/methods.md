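# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic data does and does not emulate, and the design
decisions taken where the procedure was genuinely open.

## Coordinates and formats

Internal intervals are 0-based half-open; GenBank and GFF3 IO converts to
and from 1-based inclusive at the boundary and nowhere else. Sequences are
restricted to {A, C, G, T, N}: other IUPAC ambiguity codes are rejected at
parse time because downstream identity arithmetic (fragment ANI, protospacer
identity) must be unambiguous. Multi-contig inputs become independent
records; regions never span contigs.

## Synthetic data: what it emulates

The generator produces the study conditions the analysis is tested under:

* **Hosts.** 20 chromosomes of 120 kb (defaults), GC 0.59–0.62 by species,
  drawn per base. Background genes carry housekeeping products only — no
  phage-lexicon keyword appears outside implants, so every false positive is
  attributable. Species are assigned with the relative abundances of the
  585-genome survey (52/96/108/288/41).
* **Prophages.** Implants per genome are Poisson(0.82) truncated to [0, 6]
  — the survey's printed mean and range. Each implant instantiates one of a
  small pool of templates (5 intact, 4 remnant-source) so that template
  reuse across genomes creates the ANI/gene-sharing clusters the
  comparative stages must find. Templates have the five-module architecture
  (integration/excision, lysis, DNA replication, DNA packaging, head/tail),
  an integrase as the boundary gene, packaging and structural modules
  adjacent, genes of 600–1,500 bp (real ORFs: start codon, stop-free body,
  stop), intergenic gaps of 2–200 bp, and strand flips only across module
  boundaries — which is exactly what makes the same-strand/<1 kb
  co-transcription criterion hold within an implant.
* **Template sizes.** Intact templates target U[22.0, 51.2] kb;
  remnant-source templates U[15.0, 51.2] kb before degradation. The lower
  intact bound is forced by the completeness rule itself: an all-module
  phage under 20 kb would classify "partial", and the recovery contract
  requires intact implants to classify likely-complete. Degraded remnants
  (structural + packaging modules deleted, sometimes lysis too) populate
  the small end of the printed 4.5–51.2 kb size range.
* **Geometry.** Implant sites sit in eight gene-sparse "integration
  islands" ≥ 2.5 kb from the nearest host CDS. This keeps boundary
  refinement honest: the co-transcription rule only reaches across gaps
  under 1 kb, so a refined boundary can absorb the adjacent tRNA (placed
  50–300 bp from the site on tRNA islands) but never a host gene. tRNA
  annotations and CRISPR loci are written in place over intergenic
  background, so final length = host length + Σ implant lengths exactly.
* **CRISPR arrays.** One array per implant-bearing genome: a random repeat
  of 26–40 bp and 5 spacers of 33 bp sampled from gene bodies of that
  genome's implants, on either strand, each base independently mutated at
  the configured rate (default 0 — the mutation-free condition the recovery
  contracts assume).

What it does **not** emulate: real bifidophage sequence composition beyond
GC and architecture, indels (all mutations are substitutions), Cas operons,
degenerate repeat copies, multi-contig draft assemblies, or annotation
noise. Passing recovery tests therefore demonstrate correctness of the
machinery under clean conditions, not expected performance on RefSeq data.

## Prophage regions

Scanning finds maximal runs of CDS whose products match the module lexicon
(runs broken by > 5 kb between consecutive matches; ≥ 4 matches required).
The lexicon (keyword → module) replaces HMM-based viral annotation, which
needs an external database; it is editable plain text. Boundary revision
iterates three rules to a fixed point, each side capped at 15 kb of total
extension from the input candidate: (i) a tRNA or integrase-product feature
within 2 kb beyond the boundary is absorbed — the 2 kb window is a choice,
the criterion itself states no distance; (ii) a run of hypothetical-product
CDS bridging to a phage-lexicon CDS is absorbed with that CDS (our reading
of the "consecutive hypothetical proteins with prophage-like functions"
criterion, which conflates the two notions); (iii) the next CDS is absorbed
while it shares the edge CDS's strand at an intergenic gap under 1 kb.
Refinement only widens. It is idempotent whenever it reaches a natural
fixed point; if the pathological same-strand gene chain forces the 15 kb
cap, a second application anchors the cap to the new interval and may
extend further — the cap is a guard, not part of the model.

Completeness: remnant if < 13 kb **or** both structural and packaging
modules absent; likely complete if ≥ 30 kb, or ≥ 20 kb with ≥ 4 of 5
modules and a boundary integrase; partial otherwise. The 13/20/30 kb
thresholds are the survey's stated heuristics; combining the 20 kb and
30 kb statements into one rule is our reconciliation. The three-way class
keeps both published dichotomies expressible. Classification is monotone in
modules at fixed length. The size-summary mode is computed on 100 bp bins
(lower edge reported); a raw-bp mode would be degenerate.

## Alignment core

One seeding layer serves three consumers. Exact 11-mer seeds locate
candidate diagonals; diagonal bands are either scanned gaplessly
(X-drop-style maximal scoring segments, match +2 / mismatch −3, X-drop 20,
minimum segment score 40 ≈ 20 matched bases) or passed to an affine-gap
local alignment (Biopython's PairwiseAligner; +2/−3, open −5 applied to the
first gapped column, extend −2) over a padded subject window. `N` never
matches anything. Identity is identical columns over alignment columns,
gaps included. Seed-limited sensitivity is a stated property: alignments
with no shared 11-mer (or, for ANI fragments, fewer than two seeds in a
band) are not found; at the identity levels the cut-offs require
(≥ 30%, ≥ 90%, ≥ 98%) this loses nothing.

E-values use the Karlin–Altschul form E = m·n·2^(−S′) with
S′ = (λS − ln K)/ln 2; λ = 0.625, K = 0.41 for ungapped nucleotide
statistics (protospacers, n = summed region length), λ = 0.267, K = 0.041
for gapped BLOSUM62 (gene families, n = summed protein length). These are
the standard published constants; exact parity with any particular BLAST
build is not claimed.

## ANI

ANIb convention: the query is chopped into consecutive 1,020 bp fragments
(trailing remainder kept so self-ANI is exactly 1); a fragment is accepted
when alignment identity ≥ 0.3 and aligned query span ≥ 0.7 of the fragment;
ANI is the mean identity over accepted fragments, coverage the accepted
span over the query length. Matrices are symmetrised by the arithmetic mean
of the two directions, diagonal set to 1. Clustering is single linkage on
ANI ≥ 0.9 (the published cut-off; the linkage is our choice), clusters
ordered by size then smallest member. Coverage is reported but unused in
clustering.

## Gene families

The six-frame ORF caller (starts ATG/GTG/TTG, stops TAA/TAG/TGA, table 11,
longest ORF per stop, min 30 aa, N-codons → X, ORFs > 10% X discarded) is
deliberately simple — no coding statistics or RBS model. A greedy
longest-first selection keeping ORFs that overlap kept ones by ≤ 30 bp
reduces the six-frame set to a plausible gene complement, standing in for a
prokaryotic gene caller. Pairs sharing < 2 exact amino-acid 4-mers are
skipped before alignment (two-hit seeding, as protein search tools do).
Edges at E ≤ 1e−5 carry weight −log10 E (capped at 200).

MCL is implemented from scratch: unit self-loops, column normalisation,
then expansion (matrix squaring) alternating with inflation (entrywise
power r = 2.0, column renormalisation), pruning entries < 1e−6, until the
matrix changes by < 1e−9 or 200 iterations (non-convergence is flagged on
the result, never silent). Clusters are the connected attractor systems of
the limit; output is always a partition and invariant under node
relabelling. The presence/absence matrix is binary family × prophage —
"gene similarity" is membership of the same MCL family, not literal 100%
identity between members (a literal reading would make the clustering
redundant).

Cluster selection quantifies the survey's qualitative criteria: an ANI
cluster is selected iff it has ≥ 2 members, mean pairwise Jaccard of the
members' family profiles ≥ 0.5, at least one likely-complete member, and
every member ≥ 13 kb; `shared_integration` is set when two members show
identical flanking-feature products on both sides within 2 kb (orientation
swap allowed). These thresholds are explicit surrogates for a manual
"individually investigated" step and are exposed in the config.

## CRISPR and protospacers

Array detection is exact: repeated 23-mers seed copy chains with plausible
spacing, chains extend to maximal identical copies, and an array qualifies
with repeat length in [23, 55], spacer gaps in [25, 60] and ≥ 3 copies;
overlapping candidates resolve by most copies, then longest repeat, then
leftmost. Repeat copies must be exactly identical — the generator emits
identical copies and the brute-force oracle enumerates under the same rule;
tolerance for degenerate or truncated terminal copies is deliberately not
implemented. Deduplication is greedy incremental clustering (CD-HIT style):
candidates sorted by length desc then lexicographically join the first
representative reaching 90% ungapped identity over the shorter length on
either strand; deterministic and idempotent.

Protospacer matching keeps the best hit per (spacer, region, locus) passing
E ≤ 0.01 and identity ≥ 98%. With 33 bp spacers a single substitution gives
32/33 ≈ 97.0% and is rejected — the optimal affine alignment of a
one-mismatch spacer scores higher than any trimmed perfect sub-alignment,
so the filter sees the full-length identity. "Unique sequences" are merged
overlapping subject intervals per region (≥ 1 bp overlap), an explicit
surrogate for an unstated published derivation. Each hit is assigned to the
ORF with maximal overlap (ties: leftmost), inheriting the product of the
most-overlapping CDS annotation; hits overlapping no ORF are reported
intergenic.

## Phylogeny

For a pair with lengths L1, L2: HSPs from the gapless scanner are made
non-overlapping greedily (higher score first, both sequences); with
H = Σ alignment lengths and I = Σ identities, d0 = 1 − 2H/(L1+L2),
d4 = 1 − I/H (1 when H = 0), d6 = 1 − 2I/(L1+L2), clamped to [0, 1].
Identical sequences give (0, 0, 0); pairs sharing no seed give (1, 1, 1).

Trees are neighbor joining (standard Q criterion; ties broken by the
lexicographic pair of clade labels, a clade labelled by its smallest leaf;
negative branch lengths clamped to zero; the final three nodes join at a
central vertex with closed-form lengths). NJ recovers additive matrices
exactly, which is what makes it testable; it replaces the published
balanced-minimum-evolution/SPR inference as a documented deviation adequate
at desk scale. Midpoint rooting and newick IO use dendropy (the tree is
derooted first — dendropy's midpoint rerooting degenerates when the seed
root already sits at the midpoint). Pseudo-bootstrap support is omitted: no
site-resampling scheme is defined for whole-sequence distances. Taxon
groups use the link-fraction rule: agglomerative merging, smallest mean
cross-distance first, two clusters fusing iff the fraction of cross-pairs
at distance ≤ t reaches F (default F = 0.5, t = 0.25 on d6; t is ours —
the published thresholds belong to a tool whose file formats are out of
scope). F = 1 reduces to complete linkage.

## Pipeline and evaluation

`run_pipeline` chains all stages and writes a plain-text report bundle with
a manifest; empty inputs yield header-only tables. Under a fixed seed the
bundle is byte-identical across runs; stage wall times are printed to
stdout and deliberately kept out of the on-disk log. Recovery scoring
matches predictions to implants by ≥ 50% reciprocal overlap (one-to-one,
best overlap first); precision of an empty prediction set is defined as 1.
Boundary error is the mean of |Δstart| and |Δend| averaged over matches. A
protospacer hit counts as correct when a mutation-free truth spacer of the
hit's representative cluster has an origin sequence occurring (either
strand) in the hit region — this credits the biologically intended
cross-genome hits of template-shared prophages; the expected set for recall
is every (representative, region) pair with such an occurrence.

## Problem sizes

The study dataset is 20 genomes of 120 kb (≈ 16 expected implants, ≈ 55
spacers); unit tests use sequences of 0.5–10 kb. These sizes exercise every
code path (multi-member ANI clusters, remnant and intact classes,
cross-genome protospacer hits) while keeping the full suite and the
acceptance run in the minutes range on one CPU.
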