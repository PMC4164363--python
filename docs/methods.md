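# Methods

## Scope and model

`barcodekit` implements the standard curation-and-identification protocol
for COI-5P barcode libraries of marine fishes: quality screening, Kimura
2-parameter (K2P) distance analysis, neighbour-joining (NJ) clustering at a
2% divergence ceiling, A–E reliability grading of reference species, blind
assignment of query barcodes with a ≥98%-identity fallback, and a >2%
intraspecific-divergence screen for candidate cryptic lineages.

The underlying assumptions are those of threshold-based barcoding: a
"barcode gap" separates intraspecific variation (almost always <2% K2P in
marine fishes) from congeneric divergence (typically ≥ several percent), so
cluster membership below the threshold is diagnostic of conspecificity.
Where that assumption fails — introgression, very recent speciation, deep
population structure — the pipeline does not silently misbehave: mixed
clusters yield `ambiguous`, deep splits are flagged, and non-monophyly
demotes a species to grade E.

## Quality control

A sequence passes when (i) some reading frame (0/1/2) has zero stop codons
under the vertebrate mitochondrial code (TAA, TAG, AGA, AGG), ties between
frames resolving to the lowest index; (ii) it contains no internal gap
character (the operational reading of "no insertions or deletions", since
no alignment-based indel test is defined for unaligned input); (iii) its
length is within [`min_len` = 500, 652] bp; and (iv) at most half of its
symbols are ambiguous. The 500 bp floor keeps fragments long enough for a
meaningful distance while tolerating modest trimming differences between
sequencing runs; trimming itself is configurable, not inferred.

## Distances

`d = −½ ln[(1 − 2P − Q)√(1 − 2Q)]` with transition (P) and transversion (Q)
proportions over sites where both sequences carry an unambiguous base
(pairwise deletion — the convention of the usual distance-summary tools).
The transform is undefined when a log argument is non-positive or when
fewer than `min_overlap` = 100 sites are shared; such pairs are recorded in
`undefined_pairs`, excluded from summaries, and must be pruned before tree
building (`prune_undefined` removes the fewest specimens that clear them).
Equal-length inputs are treated as pre-aligned on the barcode coordinate;
mixed lengths go through an end-gap-free global alignment (Biopython
`PairwiseAligner`). Rank summaries (conspecific / congeneric / confamilial)
are reported in percent with `se = sd / √n_pairs`, and a level with zero
pairs is reported absent rather than zero.

## Tree, bootstrap, clusters

NJ follows the classical agglomeration with two conventions chosen purely
for reproducibility: Q-criterion ties break on the lexicographically
smallest pair of (minimum contained) leaf ids, and a negative branch length
at a join is clamped to zero with the deficit moved to its sibling so path
lengths are preserved. On additive matrices the implementation recovers the
generating topology and path lengths to numerical precision (verified in
the tests against exhaustive topology enumeration with least-squares
scoring, and against scikit-bio's independent NJ).

Bootstrap support resamples alignment columns with replacement, rebuilds NJ
per replicate, and reports the percentage of replicates containing each
original bipartition. Replicate matrices clip out-of-domain log arguments
to a tiny positive value instead of flagging them, because a replicate must
yield a complete matrix; this only affects pairs already at saturation.
Support values are reported on the tree but never gate assignment — the
assignment rule uses cluster membership only.

Clusters are the maximal clades whose within-clade maximum pairwise K2P
distance is strictly below the threshold (default 2%), read off a midpoint
rooting so cluster boundaries fall on the deepest divergence; leaves in no
qualifying multi-leaf clade become single-entry clusters, and the result is
always a partition of the leaves. The within-cluster criterion uses matrix
(pairwise) distances, not patristic ones, for consistency with the distance
module; patristic distances are exposed separately
(`patristic_distances`) for users who prefer that reading. Raising the
threshold can only merge clusters (monotonicity, tested).

Species monophyly is assessed on the unrooted tree via bipartitions (no
outgroup is assumed): a species is monophyletic iff its specimen set equals
one side of some bipartition; single-specimen species are not evaluable.

## Grading

Precedence E > C > A > B > D, with discordance deliberately overriding
sample size: any specimen whose best external hit (≥ the 98% identity
floor) names a different species, or species-level non-monophyly, gives E;
otherwise >2% among ≥3 specimens gives C; a concordant external match at
≥98% gives A; ≥3 concordant specimens without external corroboration give
B; everything else (1–2 specimens, no match) gives D. A 2-specimen species
split by >2% cannot satisfy the ≥3-specimen clause of C and is graded D
with the explicit rationale `two_specimens_deep_split`. External
corroboration is a pluggable local snapshot (FASTA + taxonomy) rather than
a live web query, so graded runs are reproducible; the identity floor for
"congruence" reuses the 98% assignment threshold, and concordance is
evaluated at species level with per-specimen outliers recorded.

Note that without an external snapshot a label swap inside a reference
library is only detectable through non-monophyly, and when the mislabelled
specimen is genetically interior to a star-shaped conspecific cloud the
remaining specimens may or may not form a clade — the tree cannot decide.
The snapshot route (per-specimen discordant hits) is the deterministic
detector, and the grading tests are built on it.

## Assignment

Two stages, mirroring the blind protocol. Stage 1: a query in a <2% cluster
whose reference members are species-pure takes that species; clusters with
no reference members leave their queries unassigned; clusters mixing
reference species yield `ambiguous` (a mixed cluster never donates a name).
Stage 2, only for unassigned queries and only when a candidate snapshot is
supplied: percent identity over compared positions (end-gap-free alignment
for unequal lengths), coverage floor 95% of the 652 bp barcode as the
operational reading of "the whole length of the barcode", acceptance at
≥98%, highest identity wins, and an exact tie across distinct species is
`ambiguous` rather than an arbitrary pick. A query with nothing at or above
the floor is `no_match` (reported with its best below-threshold hit); a
query with no reference cluster and no snapshot to search is `new_record`
(a first-time barcode). Morphology labels are used only after assignment,
to classify `confirmed` vs `mismatch`; blindness is structural (the
assignment path never reads query labels) and is asserted by a test that
permutes them.

The deep-divergence screen flags species with intraspecific K2P > 2%,
counts sub-clusters by restricting the cluster partition to the species'
specimens, reports geographic sorting (every sub-cluster region-pure,
regions pairwise distinct), and emits both the maximum intraspecific
distance and the mean between-sub-cluster distance so either reading of a
two-lineage split is checkable.

## Synthetic data

The generator evolves sequences down the taxonomy (shared root → family →
genus → species → specimen) under a K80 process with transition bias
`kappa` = 4 (a typical COI value), using exact K80 transition probabilities
per branch, with codon rejection-resampling so no simulated barcode ever
acquires a frame-0 stop codon (negligible distance bias at the divergences
used). Branch lengths are set so realised divergences land near the
configured expectations: conspecific 0.4%, congeneric 9%, confamilial 16%,
between-family 26% (`theta_order`, needed to keep even the deepest pairs
inside the K2P domain). Specimens radiate from their species root in a
star; cryptic species instead draw from one of two lineage roots separated
by `cryptic_depth` (default 6%), region-pure (NEA vs MED) when
`region_sorting` is on. `singleton_fraction` thins species to one specimen;
`misid_rate` relabels query specimens to a random congener (the library
records the reported label; the truth table keeps both); reference-side
swaps for grading experiments are available through `inject_errors`
directly. Held-out species (`holdout_species_fraction`) contribute only
queries, producing true first-time barcodes.

What the generator does not emulate: rate variation among sites and
lineages, indels, codon selection, haplotype sharing between species,
geographic population structure below the planted splits, and uneven,
taxon-specific divergence (real confamilial distances reach >30% in some
families). Passing tests therefore demonstrate correct recovery of planted
structure under a clean barcode-gap regime, not performance on libraries
where the gap closes.

## Problem sizes and numerics

The default study is 5 families × 2 genera × 4 species × 4 specimens
(~140–150 barcodes after thinning, ~30% queries) — large enough for every
grade, outcome and flag to occur, small enough that the whole analysis
including a 100-replicate bootstrap runs in seconds. Cluster thresholds are
strict "<" for the 2% cluster rule and "≤" for the grading rule, matching
the two phrasings of the criterion. Tolerances used in tests: 1e-12 for the
K2P closed form, 1e-9 for NJ path lengths on additive input, 3-sigma
binomial bounds for stochastic recoveries. Determinism: every stochastic
component (simulation, bootstrap) takes an explicit seed, and a fixed seed
reproduces all written reports byte for byte (tested).

## Known limitations

- NJ is O(n³) in pure numpy-backed Python; fine to a few thousand leaves,
  not for tens of thousands.
- Cluster extraction depends on midpoint rooting; a pathological tree whose
  deepest divergence falls inside a true cluster could split it (not
  observed under the simulated regime).
- Grade A/E decisions are only as good as the external snapshot; the live
  databases the field uses are larger and noisier than any local copy.
- The identity search is alignment-based, not BLAST-accelerated; snapshots
  of ~10⁴ candidates are the practical ceiling per query batch.
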