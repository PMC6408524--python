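# Methods

## The design grammar

A ZFN dimer configuration is a triple (architecture, gap length, skip
plan per monomer). Architectures fix the strand of each half-site via
the FokI attachment point:

| arch | left site | right site | note |
|------|-----------|------------|------|
| CC   | bottom    | top        | canonical; 5′ ends gap-proximal |
| NC   | top       | top        | both half-sites on one strand |
| CN   | bottom    | bottom     | mirror of NC |
| NN   | top       | bottom     | strand inverse of CC |

NC and CN are structurally the same protein pair but are counted as
distinct configurations at a fixed locus: they impose different
strand/sequence requirements there.

Skip plans are subsets of the two permitted junctions (six fingers:
J2-3, J4-5; five fingers: J2-3, J3-4), each skip inserting exactly one
unconstrained base between adjacent fingers' triplets; the recognition
span is `3 × fingers + skips`. The configuration multiplicity at a
fixed base step factorizes as `|archs| × plans²`, giving the 4-, 16-
and 64-fold increases over the canonical no-skip baseline.

**Gap sets** (spacer lengths, configurable per call): NC/CN {6, 7} —
the spacings used when the amino-terminal linkers were selected, with
6 bp the minimal spacing compatible with FokI dimerization; NN
{7, 8, 9} — the range with consistently active pairs; CC {5, 6} — the
conventional spacing of carboxy-terminal linkers. The CC set is the
one genuinely open choice (no single canonical set is established);
{5, 6} was fixed once as the conventional default and is overridable.

**Coordinates.** 0-based, half-open throughout. The cleavage center of
a gap `[b, c)` is `(b + c)/2`; odd gaps give a half-integer center,
assigned deterministically to base step `floor(center)` so that every
design maps to exactly one base step.

**Orientation convention.** Module triplets are stored 5′→3′ along the
target site; by antiparallel zinc-finger polarity, finger N
(carboxy-terminal) binds the 5′-most triplet. Junction Jk-(k+1)
therefore sits between site-triplet indices `F−k−1` and `F−k` from the
5′ end. Six-finger ZFPs are assembled from three 2-finger modules, so
both skippable junctions are inter-module. Five-finger ZFPs default to
composition (2, 2, 1) with the 1-finger module carboxy-terminal
(binding the 5′-most triplet); under this composition J2-3 is
inter-module while J3-4 falls inside a 2-finger module and is only
available when that module is flagged internally skip-capable
(the GNN archive disables this). Composition is configurable.

## Scanning and pairing

`find_zfp_sites` reports every (offset, strand, skip plan, ordered
module triple) whose pattern — concatenated triplets with an `N` at
each skipped junction — matches the sequence, exactly once, in
deterministic (position, strand, plan, module-ids) order. IUPAC
degeneracy in archive triplets is expanded; a sequence code matches a
pattern code only if every base it could be is allowed (so a genomic
`N` matches only a pattern `N`). Internally, concrete patterns are
hash-looked-up per position and degenerate patterns fall back to
per-position set comparison; the unit and acceptance suites check the
output against an independent exhaustive enumeration.

`pair_dimers` joins site pairs whose strands, skip plans and
inter-site gap realize a configuration. Designs are deduplicated by
(layout, module choices): identical layout with different modules is a
different protein pair, hence a distinct design. Overlapping sites
never pair (gaps are positive by construction). Output order is
(cleavage base step, architecture, left start, design id), with the id
a content hash, so runs are stable across input orderings.

**Targeting density.** A region of length L is scored over L base
steps (one per position — matching the positional accounting in which
a 28-bp segment has 28 scorable cleavage positions). Density is the
fraction of base steps with at least one design.

The dense-tiling round trip (`simulate.dense_tiling_designs`) plants
one design per base step. Planted sites span ~40 bp and overlap
between adjacent steps, so each step's design is planted into its own
copy of the background genome and scanned independently — the same
logic as a saturation scan, where a separate nuclease pair is built
per base step; the pooled designs then yield the density profile.

## Indel quantification

Reads are globally aligned to the amplicon with biopython's
PairwiseAligner: match +1, mismatch −1, gap of length L costs
−(8 + L), end gaps free on both sequences (read overhangs and short
coverage are not edits). Identical reads are aligned once. Reads whose
alignment spans <50% of the amplicon are discarded into a QC tally.
Each internal indel is left-normalized (shifted to its leftmost
equivalent placement), and the allele key is the sorted tuple of indel
ops — substitution-only reads share the wild-type key, which keeps
keys stable under sequencing error. A read is an indel read iff any op
overlaps the expected cut window (default ±20 bp around the annotated
gap center in the CLI; artifacts far from the cut are ignored).

Background correction reclassifies treated indel alleles whose key
also occurs among the control's indel alleles as non-indel; totals are
unchanged, the operation is idempotent and can only lower %indels.
Significance is a two-sided Fisher's exact test on (indel vs
non-indel) × (treated vs control) with Bonferroni adjustment
`p_adj = min(1, p × n_tests)`; a locus is called significant only when
`p_adj < 0.05` *and* the treated indel fraction exceeds the control's.
Tests verify the p-values against direct hypergeometric enumeration
(exact integer weights) for every 2×2 table with grand total ≤ 50.

## Off-target cascade

The pipeline consumes mapped integration events (BED6-like TSV with
per-event equally-best-hit counts), not raw reads — trimming and
alignment belong to standard external tools. Operational choices where
the procedure leaves granularity open:

- *Same locus in control*: control events within the treated cluster
  interval padded by the clustering window (100 bp).
- *Fold rule*: inclusive — `treated ≥ 5 × control` passes, and a
  control count of 0 always passes. Boundary behavior is tested
  exactly (10 vs 2 passes; 9 vs 2 fails).
- *Multimap rule*: every member event must map equally well to fewer
  than 3 loci (`n_best_hits < 3`).
- *Known region*: a configurable chromosome whitelist, defaulting to a
  primary-assembly name pattern (chr1–22, X, Y, M).
- *Control pairing*: treated replicate r is compared against control
  replicate r when control carries matching replicate ids, else
  against the pooled control (pooling inflates control counts, so
  matched pairing is preferred when available).
- *Replicate consensus*: applied after the per-replicate filter
  cascade; loci are merged across replicates by ≥1-bp interval overlap
  (transitively), kept when supported in ≥2 replicates, and ranked by
  summed capture events with a (chrom, start) tie-break, on-target
  first when present.

The cascade is monotone — relaxing any threshold never removes a
passing locus — and clustering is a partition invariant under input
permutation; both are tested.

## Synthetic data

Generators are deterministic functions of (parameters, seed), one RNG
stream each. `random_genome` draws i.i.d. bases at a target GC.
`plant_design` realizes a configuration's layout around a chosen base
step and writes a concrete, strand-correct site sequence drawn from
the archive (degenerate codes and skipped bases randomized).
`simulate_amplicon_reads` draws allele counts multinomially and
applies substitution-only errors (indel errors are off by default so
the planted indel truth stays exact; substitutions exercise allele-key
robustness). `simulate_capture_events` draws Poisson event counts per
locus per replicate with uniform positions, emulating a quadruplicate
capture experiment, with shared-with-control and multimapping decoys
on request.

What the simulations do not emulate: quality-dependent error
profiles, PCR duplicates and chimeras, non-uniform genomic background,
mappability structure, or binding-affinity differences between
modules. Passing tests therefore demonstrate correctness of the
algorithms under their stated models, not performance on real
sequencing data.

## Problem sizes and tolerances

The test suite uses sequences ≤ 200 bp with small random archives for
oracle equivalence (200 cases in the acceptance suite), 10⁴ reads ×
20 seeds × 3 fractions for indel recovery (within 3 binomial SE of the
planted fraction; the caller is exact on error-free reads), the full
2×2 enumeration to total 50 for Fisher, and 4-replicate capture
simulations with ~10–15 events per true locus. The acceptance script
scales the oracle comparison to 50 cases; all of it completes in
seconds. Floating-point comparisons for p-values use absolute
tolerance 1e-10 against an enumeration that mirrors the conventional
two-sided definition (tables with probability ≤ (1 + 1e-7) × observed).

## Known limitations

- No activity or specificity prediction: which designs cut well is
  outside scope; the scanner reports existence, not efficacy.
- Recognition-helix sequences and linker chemistry are annotations
  only; no structural modeling of FokI or linker geometry.
- Archives other than the built-in GNN set must be supplied by the
  user; degenerate-triplet archives are supported but matching is
  conservative (subset semantics).
- The indel caller consumes merged single-end reads; paired-end
  merging and demultiplexing are upstream concerns.
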