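# zfndesign

Design-space tooling for zinc-finger nucleases (ZFNs) with an expanded
dimer grammar, plus the two standard editing readouts: amplicon indel
quantification and duplex-capture off-target candidate calling.

A ZFN cleaves DNA as a dimer: two zinc-finger proteins (ZFPs), each
fused to the FokI cleavage domain, bind half-sites flanking a short
spacer gap in which cleavage occurs. Classically both FokI domains are
carboxy-terminal (the CC architecture), forcing the half-sites onto
opposite strands with no unread bases inside either half-site — a
strong constraint on which base steps can be targeted. This package
implements an expanded grammar:

- **Four dimer architectures** — CC, NC, CN, NN — from amino- or
  carboxy-terminal FokI attachment on each monomer. NC/CN place both
  half-sites on the same strand; NN is the strand inverse of CC.
- **Base-skipping junctions** — a linker that skips exactly 1 unread
  base between adjacent fingers, allowed at fingers 2–3/4–5 of a
  six-finger ZFP (2–3/3–4 for five fingers), giving 4 skip plans per
  monomer.

At any fixed cleavage base step this multiplies the available
configurations by |architectures| × (skip plans)² = 4 × 4 × 4 = **64**
over the canonical no-skip baseline. The library:

- models one-/two-finger **module archives** (including the built-in
  GNN archive: 16 one-finger + 256 two-finger modules over all GNN
  triplets) — `zfndesign.archive`;
- enumerates and realizes dimer **configurations** as strand-assigned
  genome geometry — `zfndesign.grammar`;
- **scans** sequences for assemblable binding sites, pairs them into
  dimer designs, and reports per-base-step **targeting density**
  (fraction of base steps with ≥1 design) — `zfndesign.scanner`;
- quantifies **%indels** from amplicon reads (affine-gap alignment,
  left-normalized allele keys, treated-vs-control background
  correction, Fisher + Bonferroni significance) — `zfndesign.indels`;
- calls **candidate off-target loci** from mapped integration events
  (100-bp single-linkage clustering; ≥5-fold over control; <3
  equally-best hits; known chromosome; ≥10 kb from the on-target;
  support in ≥2 replicates) — `zfndesign.offtarget`;
- generates fully **deterministic synthetic data** with planted truth
  for every pipeline — `zfndesign.simulate`.

## Worked example

`examples/targeting_density.py` plants one dimer design per base step
of a 28-bp window (the `HBG1_SEGMENT` promoter fixture embedded in
random context), rediscovers each by scanning with the GNN archive
under the full grammar, and scores density:

```
window: 28-bp segment TTCCCCACACTATCTCAATGCAAATATC at (100, 128)
designs recovered by scanning: 28
covered base steps: 28/28  density = 1.000
after dropping designs at 3 base steps: 25/28  density = 0.893
```

Density 1.0 means every base step of the window has at least one
ZFN dimer design centering cleavage on it; removing the designs at 3
steps reproduces the 25/28 ≈ 0.893 arithmetic of a scan in which three
base steps lack designs. The other scripts in `examples/` demonstrate
the archive combinatorics (`×4 / ×16 / ×64`), planted-design scanning,
indel quantification with background correction, and the off-target
filter cascade, each printing the numbers it computes.

A thin CLI mirrors the library (`zfndesign archive|grammar|scan|
density|indels|offtarget|simulate`); see `zfndesign --help`.

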