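# Methods

This note documents the models, parameter choices, numerical conventions,
and limitations behind `komagen`, in the order the pipeline runs.

## Manifest curation

A manifest freezes the dataset before analysis: one row per assembly with
accession, species and strain labels, assembly size, source, and a
clonal/derivative exclusion flag.  Exclusion exists because near-identical
genomes inflate plasmid-sharing and conservation signals; applying the
exclusion list is idempotent and never mutates the input.  Summary
conventions: the median for an even number of genomes is the arithmetic
mean of the two central values; sizes are reported in Mb rounded half-up
to two decimals; species are counted on the label verbatim (no taxonomy
resolution) and a singleton species has exactly one genome.  The bundled
reference table records assembly sizes only for included genomes; the four
excluded rows carry `size_bp = 0`, which the loader accepts only together
with the exclusion flag.

## Sketching and Mash distances

A sketch keeps the *s* smallest 64-bit hash values over the distinct
canonical k-mers of a sequence (canonical = lexicographic minimum of the
k-mer and its reverse complement; k-mers containing non-ACGT bases are
skipped entirely so ambiguity codes cannot create phantom sharing).  The
hash is the splitmix64 finalizer applied to the 2-bit packing XOR a
seed-derived constant — fixed and documented so sketches are bit-identical
across platforms; the test suite checks the vectorized implementation
against a scalar re-implementation.

The Jaccard estimate for two sketches is the union-sketch containment
`j = |X ∩ A ∩ B| / |X|` with `X` the bottom-*s* of `A ∪ B`, converted by
the Mash transform `d = -(1/k) ln(2j/(1+j))`, with `d = 1` at `j = 0`
(the log is undefined there) and clamped to `[0, 1]`.  Defaults are
`k = 16`, `s = 1000` for plasmids and `s = 2000` for chromosomes: a modest
k keeps tens-of-kb plasmids from sketch starvation while `4^16` keeps
random collisions negligible.  Both are exposed as parameters.  On seeded
sequence pairs at substitution rates 0.005–0.02 the sketch estimate stays
within ±0.01 of the distance computed from the exact Jaccard of the full
canonical k-mer sets (asserted in the acceptance suite).

Neighbor joining is the classical Q-matrix agglomeration with two
determinism rules: labels are sorted lexicographically before
construction and tied Q minima resolve to the lowest (row, col) index
pair.  Negative branch lengths are clamped to zero.  On additive matrices
the tree reproduces all pairwise path lengths to 1e-9 and agrees with
scikit-bio's independent implementation.

## Plasmid homology clusters and conservation classes

Clusters are single-linkage connected components of the graph joining
pairs with `d ≤ threshold` (default 0.10).  Single linkage is deliberate:
it lets a tight backbone and loosely attached mosaic members form one
cluster, which is exactly the structure the dispersion summary then
exposes.  Cluster IDs are dense from 1, ordered by descending size then
lexicographically smallest member, so "Cluster 1" is reproducibly the
largest.  Size-1 components are retained, flagged `singleton`, and
excluded from clustered-plasmid counts and (by default) from presence
matrices.

The conservation call uses the within-cluster **median** Mash distance:
`< 0.02` highly conserved, `[0.02, 0.05]` moderately conserved (both
boundaries fall in the closed middle interval, since the outer classes
are defined by strict inequalities), `> 0.05` mosaic-like.  These are
within-dataset descriptors of distance dispersion, not externally
benchmarked plasmid family definitions.  CDS-product concordance
(pairwise Jaccard of case-folded, whitespace-collapsed, trailing-
punctuation-stripped product strings; `J(∅, ∅) = 1`) provides an
annotation-level cross-check, and mobility tables are ingested with
case-insensitive category normalization, bucketing unrecognized labels
as `unknown` with a warning.

## bcs anchoring, window signals, and PCA

Cross-genome comparison of multi-copy bcs architectures is standardized
on a per-genome anchor contig: the contig on which bcsA and bcsZ
co-localize.  When several contigs qualify, the one with the most
distinct bcs targets wins, then the longer contig, then the
lexicographically smallest ID.  The anchor *locus* for the window rule is
the full span of bcs hits on the anchor contig, extended symmetrically —
the span is conservative and avoids privileging any single gene as the
locus point.  A GGDEF or EAL gene counts if its CDS interval intersects
the span ± 50 kb (closed intervals, anchor contig only, clipped to the
contig).  Genomes whose bcsA/bcsZ never co-localize are flagged, kept in
the feature matrix with presence-based features, and zero-imputed for
window features; they are never an error.

The feature vector is a reconstruction covering every named signal:
bcsA copy count and dispersal flag, on-anchor presence of bcsB/C/D/Z/Q,
GGDEF/EAL presence and counts in the window, and per-target medoid
similarities.  Protein similarity is alignment-free — one minus the
Jaccard of amino-acid 5-mer sets, relative to the medoid (the carrier
minimizing summed pairwise distance, ties to the smallest genome ID) —
keeping the module deterministic and dependency-free.  Features are
z-scored (constant columns dropped and recorded) and projected by
eigendecomposition of the covariance matrix; components are ordered by
eigenvalue and each loading's sign is fixed so its largest-magnitude
entry is positive.  Dual GGDEF+EAL domain proteins count under both
targets.

## Mobilome burden

Burden is computed from coordinates, never from sequence, so fragmented
or coordinate-only inputs summarize identically: an element spanning
1-based inclusive `(start, end)` contributes `end − start + 1` bp.
Genomes present in the manifest but absent from the annotation table are
reported with count 0 — absence of annotation is evidence of absence in
this summary.  Length distributions use linear-interpolation (type-7)
quantiles and left-closed bins: short `< 20 kb`, medium `20–50 kb`, long
`≥ 50 kb`; the edges operationalize "medium-length fragments" and are
configurable.  Cross-tool concordance is the Spearman rho of per-genome
totals over the shared genome set.

## Pangenome composition and linkage statistics

Core clusters are present in 100% of genomes (strict intersection —
multi-copy core structure is deliberately collapsed, since copy number
is not represented in a binary membership table), singletons in exactly
one, accessory in between.  Per-genome counts restrict to carried
clusters, and fractions divide by the per-genome total.

Spearman rho is the Pearson correlation of mid-ranks (average ranks for
ties).  Two-sided p values come from exact enumeration of all `n!`
pairings for `n ≤ 9` and from the t approximation with `n − 2` degrees
of freedom otherwise.  Zero-variance inputs leave rho undefined and
raise; the linkage driver drops such pairs with a warning.  NA handling
is pairwise-complete and each pair reports its n.  Benjamini–Hochberg
q values are the step-up `q(i) = min_{j ≥ i} m·p(j)/j`, capped at 1,
applied across all pairs of one `linkage_analysis` call — subset
analyses (e.g. plasmid-bearing genomes only) are run as separate calls
so each family is corrected on its own.  Note that BH is not idempotent:
re-adjusting q values inflates them again through the `m/j` multiplier,
so q values must never be fed back through the adjustment.

## Synthetic data generator

The generator emulates the data shapes the pipeline consumes and records
every planted value in a truth set, making parameter recovery assertable
exactly.  What it emulates: multi-replicon assemblies; plasmid families
related either by a mutated shared backbone or by a shared module
embedded in independent filler; multi-copy bcsA architectures with and
without co-localized bcsZ; GGDEF/EAL genes placed inside or outside the
50-kb window; planted IS elements and prophage-length regions placed
without overlap by rejection sampling; and a core/accessory/singleton
membership table.  What it does not emulate: realistic base or codon
composition (uniform ACGT), indels and rearrangements (backbone mutation
is substitution-only, keeping exact-Jaccard oracles simple), operon
transcription structure, or annotation noise.  Passing recovery tests
therefore demonstrates the correctness of the pipeline's logic under its
own assumptions, not robustness to real annotation error.

Default conditions echo the curated dataset: 18 genomes over 10 species
labels (3 singletons); twelve plasmid families — sizes 7 (mosaic, module
fraction 0.3), 6, three 3s and seven 2s, 36 plasmids over 13 host
genomes, with species assignments giving spans of 6 and 4 species for
the two large clusters, two 2-species clusters and eight single-species
clusters; one genome with non-co-localized bcsA/bcsZ, three with
dispersed bcsA, four lacking both window signals; IS counts uniform in
[50, 181] with element lengths 700–2500 bp; prophage counts 1–4 with
lengths uniform in [10080, 70900] bp.  Conserved backbones mutate at
per-base rate 0.005 (pairwise divergence ≈ 0.01, inside the highly
conserved band); moderately conserved families at 0.015 (≈ 0.03,
mid-band); the mosaic module fraction 0.3 yields expected Mash ≈ 0.075.
All family sizes are at least 2 so every cluster is classifiable by its
median pair distance.  Chromosomes default to 2 Mb — about half the real
genomes — which keeps the heaviest planted IS loads near 23% occupancy
(realistic) while keeping generated sets light; the bcs block sits at
one quarter of the chromosome with fixed gene offsets.

Randomness comes only from PCG64 (`numpy.random.default_rng`) streams
spawned from one seed in a fixed order, so identical (config, seed)
pairs write byte-identical files.  Infeasible configurations (elements
exceeding ~80% of a contig, impossible placements) fail before any file
is written.

## Problem sizes used in tests

The test and acceptance runs use the default 18-genome synthetic set for
end-to-end recovery; 10–30 kb sequences with 20 replicates per condition
for the sketch-vs-exact-Jaccard and conservation-recovery properties;
200 random instances for the clustering oracle; and 200 (type-I) plus
100 (power) replicates at n = 18 for the linkage statistics.  These
sizes are the package's own choices for a fast, deterministic suite;
all thresholds under test are the model constants above, not tuned
values.

## Known limitations

- Clustering threshold (0.10) and Mash parameters are unreported in the
  source analyses this pipeline standardizes; they are explicit defaults
  here, exposed as arguments.
- The richness feature vector is a reconstruction; different feature sets
  or scalings yield different PC coordinates, so PC values are comparable
  within a run, not across feature definitions.
- Conservation categories depend on the median only; heavy-tailed
  within-cluster dispersion is visible in min/max but not in the class.
- The linkage analysis treats genomes as independent observations;
  phylogenetic non-independence (close relatives are not independent
  draws) is out of scope and would require phylogeny-aware regression.
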