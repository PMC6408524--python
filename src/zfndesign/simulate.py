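"""Deterministic synthetic data: toy genomes with planted ZFN dimer
targets, amplicon read sets with planted indel spectra, and capture
event tables with planted off-target structure.

Every generator takes an explicit seed and records a truth object
sufficient to compute the downstream expected values exactly, so the
scanner, indel caller and off-target cascade can each be checked
against planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._iupac import IUPAC_SETS, revcomp
from .archive import FingerModule, ModuleArchive
from .grammar import DimerConfiguration, DimerLayout, realize_layout
from .indels import AmpliconRef, EditOp, apply_edits
from .offtarget import IntegrationEvent
from .scanner import DEFAULT_COMPOSITIONS, _candidate_modules, _site_structure, _Slot

__all__ = [
    "TruthRecord",
    "random_genome",
    "plant_design",
    "dense_tiling_designs",
    "simulate_amplicon_reads",
    "simulate_capture_events",
]

_BASES = np.array(list("ACGT"))


@dataclass
class TruthRecord:
    """What was planted, where, and under which seed."""

    kind: str
    seed: int
    details: dict = field(default_factory=dict)


def random_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random genome with the given GC fraction (i.i.d. bases)."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def _resolve_base(code: str, rng: np.random.Generator) -> str:
    choices = sorted(IUPAC_SETS[code])
    return choices[rng.integers(len(choices))] if len(choices) > 1 else choices[0]


def _concrete_site(
    archive: ModuleArchive,
    plan,
    composition: Sequence[int],
    rng: np.random.Generator,
) -> tuple[str, list[str]]:
    """Pick one module per slot and emit a concrete site sequence
    (degenerate codes and skipped bases resolved randomly)."""
    slots = _site_structure(plan.finger_count, plan, composition)
    seq_parts: list[str] = []
    module_ids: list[str] = []
    pos = 0
    for slot in slots:
        mods = _candidate_modules(archive, slot)
        if not mods:
            raise ValueError(
                f"archive has no {'skip-capable ' if slot.intra_skip else ''}"
                f"{slot.n_fingers}-finger module for the requested plan"
            )
        m = mods[rng.integers(len(mods))]
        module_ids.append(m.id)
        if slot.offset > pos:  # inter-slot skipped base
            seq_parts.append(_resolve_base("N", rng))
            pos += 1
        pattern = m.triplets[0]
        if slot.intra_skip:
            pattern = m.triplets[0] + "N" + m.triplets[1]
        elif slot.n_fingers == 2:
            pattern = m.triplets[0] + m.triplets[1]
        seq_parts.append("".join(_resolve_base(c, rng) for c in pattern))
        pos += slot.length
    return "".join(seq_parts), module_ids


def plant_design(
    genome: str,
    center: int,
    config: DimerConfiguration,
    archive: ModuleArchive,
    seed: int = 0,
    gap_sets=None,
    composition: Sequence[int] | None = None,
) -> tuple[str, TruthRecord]:
    """Write a matchable dimer target into a genome so that scanning
    finds at least one design cleaving at ``center``.

    For each half-site a random archive module triple consistent with
    the configuration's skip plan is chosen and its concrete sequence
    written at the realized layout interval (reverse-complemented for
    bottom-strand sites; skipped bases randomized).
    """
    rng = np.random.default_rng(seed)
    layout: DimerLayout = realize_layout(center, config, gap_sets=gap_sets)
    lo, hi = layout.span
    if lo < 0 or hi > len(genome):
        raise ValueError(f"layout [{lo}, {hi}) does not fit in genome of length {len(genome)}")
    g = list(genome.upper())
    sides = {}
    for side, (start, end, strand), plan in (
        ("left", layout.left_site, config.left_skip),
        ("right", layout.right_site, config.right_skip),
    ):
        comp = tuple(composition or DEFAULT_COMPOSITIONS[plan.finger_count])
        site_seq, module_ids = _concrete_site(archive, plan, comp, rng)
        placed = site_seq if strand == "+" else revcomp(site_seq)
        g[start:end] = list(placed)
        sides[side] = {"interval": [start, end], "strand": strand, "modules": module_ids}
    truth = TruthRecord(
        kind="planted_design",
        seed=seed,
        details={
            "center": center,
            "config": config.label(),
            "layout": {
                "left": list(layout.left_site),
                "gap": list(layout.gap),
                "right": list(layout.right_site),
            },
            "sides": sides,
        },
    )
    return "".join(g), truth


def dense_tiling_designs(
    genome: str,
    window: tuple[int, int],
    archive: ModuleArchive,
    configs: Sequence[DimerConfiguration] | None = None,
    seed: int = 0,
    scan_configs: Sequence[DimerConfiguration] | None = None,
):
    """Plant one dimer design per base step of a window and rediscover
    them by scanning.

    Overlapping planted sites would overwrite each other, so each base
    step's design is planted into its own copy of ``genome`` (mirroring
    a saturation scan, where a separate nuclease pair is designed per
    base step) and each planted genome is scanned independently.  The
    pooled designs, restricted to those cleaving at their planted step,
    cover every base step of the window; their density profile is the
    round-trip readout.

    ``configs`` are cycled across base steps (default: a spread over
    all four architectures with and without skips).  Returns
    (designs, truth).
    """
    from .grammar import Arch, SkipPlan, enumerate_skip_plans
    from .scanner import find_zfp_sites, pair_dimers

    if configs is None:
        plans = enumerate_skip_plans(6)
        configs = [
            DimerConfiguration(Arch.CC, 6, plans[0], plans[0]),
            DimerConfiguration(Arch.NC, 6, plans[1], plans[0]),
            DimerConfiguration(Arch.CN, 7, plans[0], plans[2]),
            DimerConfiguration(Arch.NN, 8, plans[3], plans[0]),
        ]
    rng = np.random.default_rng(seed)
    designs = []
    planted = []
    for i, step in enumerate(range(window[0], window[1])):
        cfg = configs[i % len(configs)]
        g, truth = plant_design(genome, step, cfg, archive, seed=int(rng.integers(2**31)))
        fcs = {cfg.left_skip.finger_count, cfg.right_skip.finger_count}
        sites = []
        for fc in sorted(fcs):
            sites.extend(find_zfp_sites(g, archive, fc))
        found = [
            d
            for d in pair_dimers(sites, list(scan_configs) if scan_configs else [cfg])
            if d.cleavage_base_step == step
        ]
        designs.extend(found)
        planted.append({"step": step, "config": cfg.label(), "found": len(found)})
    truth = TruthRecord(kind="dense_tiling", seed=seed, details={"window": list(window), "planted": planted})
    return designs, truth


def simulate_amplicon_reads(
    ref: AmpliconRef,
    alleles: Sequence[tuple[Sequence[EditOp], float]],
    n_reads: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], TruthRecord]:
    """Simulate amplicon reads with a planted allele spectrum.

    ``alleles`` lists (edit ops, fraction) pairs; the remaining fraction
    is wild type.  Reads are drawn multinomially and subjected to
    i.i.d. per-base substitution errors at ``error_rate``.  Returns
    (reads, truth) where reads are (read_id, sequence) pairs.
    """
    fracs = [f for _, f in alleles]
    if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-9:
        raise ValueError("allele fractions must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    probs = fracs + [1.0 - sum(fracs)]
    counts = rng.multinomial(n_reads, probs)
    sequences = [apply_edits(ref.sequence, ops) for ops, _ in alleles] + [ref.sequence]
    reads: list[tuple[str, str]] = []
    idx = 0
    for allele_i, (seq, n) in enumerate(zip(sequences, counts)):
        for _ in range(n):
            s = seq
            if error_rate > 0:
                arr = np.frombuffer(s.encode(), dtype="S1").astype("U1")
                hits = rng.random(len(arr)) < error_rate
                for j in np.flatnonzero(hits):
                    others = [b for b in "ACGT" if b != arr[j]]
                    arr[j] = others[rng.integers(3)]
                s = "".join(arr)
            reads.append((f"read{idx}_a{allele_i}", s))
            idx += 1
    # shuffle so allele identity is not encoded in read order
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = TruthRecord(
        kind="amplicon_reads",
        seed=seed,
        details={
            "locus": ref.locus_id,
            "n_reads": n_reads,
            "error_rate": error_rate,
            "allele_counts": {
                str(list(map(list, a[0]))): int(c) for a, c in zip(alleles, counts)
            },
            "wild_type_count": int(counts[-1]),
        },
    )
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Write (id, sequence) reads as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_capture_events(
    true_loci: Sequence[tuple[str, int, int, float]],
    control_rate: float = 0.0,
    n_replicates: int = 4,
    seed: int = 0,
    shared_loci: Sequence[tuple[str, int, int, float, float]] = (),
    multimap_loci: Sequence[tuple[str, int, int, float]] = (),
    multimap_best_hits: int = 3,
) -> tuple[list[IntegrationEvent], list[IntegrationEvent], TruthRecord]:
    """Simulate replicated duplex-capture integration events.

    ``true_loci`` are (chrom, start, end, rate) planted off-targets:
    per replicate, Poisson(rate) treated events uniform in the interval
    and Poisson(control_rate) control events.  ``shared_loci`` add
    decoys with events in both arms at (treated_rate, control_rate);
    ``multimap_loci`` add decoys whose treated events carry
    ``multimap_best_hits`` equally-best alignments.  Returns (treated
    events, control events, truth).
    """
    rng = np.random.default_rng(seed)
    treated: list[IntegrationEvent] = []
    control: list[IntegrationEvent] = []

    def emit(chrom, start, end, rate, arm, rep, n_best=1):
        n = rng.poisson(rate)
        positions = sorted(set(int(p) for p in rng.integers(start, end, size=n)))
        for p in positions:
            strand = "+" if rng.random() < 0.5 else "-"
            ev = IntegrationEvent(
                chrom=chrom, pos=p, strand=strand, n_best_hits=n_best,
                replicate=rep, arm=arm,
            )
            (treated if arm == "treated" else control).append(ev)

    for r in range(1, n_replicates + 1):
        rep = f"rep{r}"
        for chrom, start, end, rate in true_loci:
            emit(chrom, start, end, rate, "treated", rep)
            if control_rate > 0:
                emit(chrom, start, end, control_rate, "control", rep)
        for chrom, start, end, t_rate, c_rate in shared_loci:
            emit(chrom, start, end, t_rate, "treated", rep)
            emit(chrom, start, end, c_rate, "control", rep)
        for chrom, start, end, rate in multimap_loci:
            emit(chrom, start, end, rate, "treated", rep, n_best=multimap_best_hits)
    truth = TruthRecord(
        kind="capture_events",
        seed=seed,
        details={
            "true_loci": [list(l) for l in true_loci],
            "shared_loci": [list(l) for l in shared_loci],
            "multimap_loci": [list(l) for l in multimap_loci],
            "control_rate": control_rate,
            "n_replicates": n_replicates,
        },
    )
    return treated, control, truth
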