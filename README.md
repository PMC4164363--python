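# barcodekit

Curation and blind species assignment for COI-5P DNA barcode reference
libraries, aimed at people who maintain or audit regional barcode libraries
(fish monitoring programmes, seafood-authentication labs, museum collections)
and want the whole protocol — quality control, distance summaries,
reliability grading, blind identification, cryptic-lineage screening — as
reproducible code instead of a chain of web tools.

## The method

A *reference library* pairs each specimen's ~652 bp COI-5P barcode with its
morphology-based taxonomy; a *query dataset* holds barcodes whose species
labels are hidden during identification and used only afterwards as an
audit. The pipeline:

1. **Quality control.** A barcode passes when some reading frame is free of
   stop codons under the vertebrate mitochondrial code, it has no internal
   gaps, and its length lies in [500, 652] bp.
2. **Distances.** Pairwise Kimura 2-parameter distances,
   `d = −½ ln[(1 − 2P − Q)√(1 − 2Q)]`, with *P*/*Q* the transition and
   transversion proportions over shared unambiguous sites (pairwise
   deletion). Summaries are reported at the conspecific, congeneric and
   confamilial levels in percent.
3. **Tree and clusters.** A neighbour-joining tree from the K2P matrix
   (optionally bootstrapped by column resampling), partitioned into the
   maximal monophyletic clusters whose within-cluster maximum K2P distance
   is below 2%.
4. **Reliability grades.** Each reference species gets a grade: **A**
   (externally corroborated, ≤2% intraspecific), **B** (≥3 concordant
   specimens, no external match), **C** (>2% among ≥3 specimens), **D** (1–2
   specimens, no external match), **E** (discordant external match or
   non-monophyly). Precedence E > C > A > B > D.
5. **Blind assignment.** A query inside a <2% cluster whose reference
   members carry one species name takes that name; queries left over fall
   back to a ≥98%-identity search against a local snapshot of published
   barcodes (highest identity wins, exact ties across species are
   ambiguous). Outcomes: `confirmed`, `mismatch`, `ambiguous`, `no_match`,
   `new_record`.
6. **Deep-divergence screen.** Species with intraspecific K2P >2% are
   flagged with their sub-cluster count and whether the sub-clusters sort
   perfectly by sampling region (NE Atlantic vs Mediterranean) — the classic
   signature of cryptic lineages.

A seeded synthetic-data generator (`simulate_library`) produces libraries
with known truth — conspecific clouds near 0.4%, congeneric divergence near
9%, confamilial near 16%, optional cryptic splits, singletons and congener
label swaps — so every stage is testable without downloads.

## Worked example

```python
import barcodekit as bk

cfg = bk.SimulationConfig(seed=7, cryptic_fraction=0.1, cryptic_depth=0.06,
                          singleton_fraction=0.15, misid_rate=0.02,
                          query_fraction=0.3)
library, truth = bk.simulate_library(cfg)
bundle = bk.run_analysis(library.references(), library.queries())
print(bk.render_distance_table(bundle.summary_all).to_string(index=False))
```

```
Comparison   N  Minimum Distance Mean Distance±SE  Maximum Distance
   Species 102              0.00        0.84±0.16              8.33
     Genus 444              5.93        9.37±0.09             15.22
    Family 576             11.45       15.85±0.09             21.46
```

The conspecific maximum (8.33%) is not noise: it is one of the four planted
cryptic splits, which the screen recovers exactly, each with its two
region-sorted sub-clusters:

```
      species  max_intra_pct  n_subclusters  geographic_sorting
Genus02a sp01           4.76              2                True
Genus04a sp03           8.33              2                True
Genus05a sp04           5.62              2                True
Genus05b sp02           6.78              2                True
```

`bundle.stats` shows the assignment headline — 108 reference and 34 query
barcodes, 44 clusters (6 single-entry), 100% of queries matched by the
cluster rule and 100% of matches confirmed against morphology — and the
grade table comes out as 30 × B, 4 × C (the cryptic species) and 6 × D (the
singletons); with an external snapshot the B grades would be eligible for A.

The same analysis runs from the shell:

```bash
barcodekit simulate --seed 7 --out-dir sim --cryptic-fraction 0.1
barcodekit validate sim/library.fasta sim/library.tsv
barcodekit assign --reference-fasta ... --query-fasta ... --out-dir out
```

Real libraries enter through `read_library(fasta, tsv)` — e.g. the FASTA of
downloaded GenBank accessions plus a specimen metadata table — and flow
through `run_pipeline`/`run_analysis` unchanged.

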