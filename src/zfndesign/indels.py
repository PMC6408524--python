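"""Amplicon indel quantification with background correction.

Editing efficiency is read out by deep sequencing of a PCR amplicon
spanning the cut site.  Each read is globally aligned to the reference
amplicon (affine gap penalties, free end gaps for read overhangs); a
read carries an indel allele iff its alignment contains at least one
insertion or deletion overlapping the expected cut window.  Alleles are
keyed by their left-normalized indel edit description, which makes the
keys canonical and comparable across samples.

Background correction follows the treated-vs-control rule: indel
alleles whose edit description also occurs among the control sample's
indel alleles are reclassified as non-indel in the treated table
(sequencing/PCR artifacts rather than nuclease edits).  Per-locus
significance is a two-sided Fisher's exact test on the 2x2 table
(indel vs non-indel x treated vs control) with Bonferroni correction
across the loci tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import Align
from scipy import stats

__all__ = [
    "AmpliconRef",
    "Allele",
    "AlleleTable",
    "AlignParams",
    "IndelTestResult",
    "EditOp",
    "call_alleles",
    "background_correct",
    "indel_significance",
    "apply_edits",
]

# An edit op is ("del", ref_pos, length) or ("ins", ref_pos, inserted_seq).
EditOp = tuple


@dataclass(frozen=True)
class AmpliconRef:
    """Reference amplicon with the expected cut window (0-based
    half-open interval within the amplicon)."""

    locus_id: str
    sequence: str
    cut_window: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        w0, w1 = self.cut_window
        if not (0 <= w0 <= w1 <= len(self.sequence)):
            raise ValueError("cut window must lie within the amplicon")


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -8.0
    gap_extend: float = -1.0
    #: reads aligning over less than this fraction of the amplicon are
    #: discarded (QC tally); guards against junk/truncated reads
    min_aligned_frac: float = 0.5


@dataclass
class Allele:
    key: tuple[EditOp, ...]
    count: int
    is_indel: bool
    sequence: str


@dataclass
class AlleleTable:
    """Per-amplicon allele counts with indel classification."""

    locus_id: str
    alleles: dict[tuple, Allele] = field(default_factory=dict)
    discarded: int = 0

    @property
    def total_reads(self) -> int:
        return sum(a.count for a in self.alleles.values())

    @property
    def indel_reads(self) -> int:
        return sum(a.count for a in self.alleles.values() if a.is_indel)

    @property
    def pct_indels(self) -> float:
        total = self.total_reads
        return 100.0 * self.indel_reads / total if total else 0.0

    def indel_keys(self) -> set[tuple]:
        return {k for k, a in self.alleles.items() if a.is_indel}


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    # a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    # free end gaps on both sequences (read overhangs / short coverage)
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _left_normalize(op: EditOp, ref: str) -> EditOp:
    """Shift an indel to its leftmost equivalent placement on the
    reference (canonical keys in repetitive context)."""
    if op[0] == "del":
        _, pos, length = op
        while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
            pos -= 1
        return ("del", pos, length)
    _, pos, seq = op
    while pos > 0 and seq and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return ("ins", pos, seq)


def _alignment_edits(aln, read: str, ref_len: int, params: AlignParams) -> list[EditOp] | None:
    """Extract internal indel ops from an alignment.

    Returns the op list, or None if the read fails the aligned-fraction
    QC threshold (its alignment spans too little of the amplicon).  End
    gaps (read overhang or short coverage) are not edits.
    """
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0:
        return None
    aligned_t = int(sum(int(b[1] - b[0]) for b in tblocks))
    if aligned_t < params.min_aligned_frac * ref_len:
        return None
    ops: list[EditOp] = []
    for i in range(1, len(tblocks)):
        t_gap = int(tblocks[i][0] - tblocks[i - 1][1])
        q_gap = int(qblocks[i][0] - qblocks[i - 1][1])
        ref_pos = int(tblocks[i - 1][1])
        if t_gap > 0:
            ops.append(("del", ref_pos, t_gap))
        if q_gap > 0:
            ops.append(("ins", ref_pos + t_gap, read[int(qblocks[i - 1][1]) : int(qblocks[i][0])]))
    return ops


def _op_overlaps_window(op: EditOp, window: tuple[int, int]) -> bool:
    w0, w1 = window
    if op[0] == "del":
        _, pos, length = op
        return pos < w1 and pos + length > w0
    _, pos, _seq = op
    return w0 <= pos <= w1


def call_alleles(
    reads: Iterable,
    ref: AmpliconRef,
    params: AlignParams | None = None,
) -> AlleleTable:
    """Align reads to the amplicon and tabulate alleles.

    ``reads`` may be plain sequences or Bio.SeqIO records.  Identical
    read sequences are aligned once.  A read is an indel allele iff any
    internal insertion/deletion in its best alignment overlaps the cut
    window; alleles are keyed by the left-normalized tuple of indel
    ops (substitution-only reads share the empty key with wild type).
    """
    params = params or AlignParams()
    counts: dict[str, int] = {}
    for r in reads:
        seq = str(getattr(r, "seq", r)).upper()
        counts[seq] = counts.get(seq, 0) + 1
    if not counts:
        raise ValueError("no reads supplied")
    aligner = _make_aligner(params)
    table = AlleleTable(locus_id=ref.locus_id)
    for seq in sorted(counts):
        n = counts[seq]
        ops = _alignment_edits(aligner.align(ref.sequence, seq)[0], seq, len(ref.sequence), params)
        if ops is None:
            table.discarded += n
            continue
        key = tuple(sorted(_left_normalize(op, ref.sequence) for op in ops))
        is_indel = any(_op_overlaps_window(op, ref.cut_window) for op in key)
        allele = table.alleles.get(key)
        if allele is None:
            table.alleles[key] = Allele(key=key, count=n, is_indel=is_indel, sequence=seq)
        else:
            allele.count += n
    return table


def background_correct(treated: AlleleTable, control: AlleleTable) -> AlleleTable:
    """Reclassify treated indel alleles that also occur among the
    control's indel alleles as non-indel.  Totals are unchanged and the
    operation is idempotent."""
    if treated.locus_id != control.locus_id:
        raise ValueError(
            f"locus mismatch: {treated.locus_id!r} vs {control.locus_id!r}"
        )
    shared = treated.indel_keys() & control.indel_keys()
    corrected = AlleleTable(locus_id=treated.locus_id, discarded=treated.discarded)
    for key, a in treated.alleles.items():
        corrected.alleles[key] = Allele(
            key=key,
            count=a.count,
            is_indel=a.is_indel and key not in shared,
            sequence=a.sequence,
        )
    return corrected


@dataclass(frozen=True)
class IndelTestResult:
    p_raw: float
    p_adjusted: float
    significant: bool
    undefined: bool = False


def indel_significance(
    treated: AlleleTable, control: AlleleTable, n_tests: int = 1
) -> IndelTestResult:
    """Two-sided Fisher's exact test (indel vs non-indel x treated vs
    control) with Bonferroni correction over ``n_tests`` loci.

    A locus is significant iff the adjusted p-value is < 0.05 and the
    treated indel fraction exceeds the control's.  Zero total reads in
    either arm yields an undefined, flagged result.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    t_ind, t_tot = treated.indel_reads, treated.total_reads
    c_ind, c_tot = control.indel_reads, control.total_reads
    if t_tot == 0 or c_tot == 0:
        return IndelTestResult(math.nan, math.nan, False, undefined=True)
    table = [[t_ind, t_tot - t_ind], [c_ind, c_tot - c_ind]]
    p_raw = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    p_adj = min(1.0, p_raw * n_tests)
    significant = p_adj < 0.05 and (t_ind / t_tot) > (c_ind / c_tot)
    return IndelTestResult(p_raw, p_adj, significant)


def apply_edits(ref_seq: str, ops: Sequence[EditOp]) -> str:
    """Apply indel edit ops to a reference sequence (used to construct
    allele sequences; ops applied right-to-left so positions stay
    valid)."""
    seq = ref_seq
    for op in sorted(ops, key=lambda o: o[1], reverse=True):
        if op[0] == "del":
            _, pos, length = op
            seq = seq[:pos] + seq[pos + length :]
        elif op[0] == "ins":
            _, pos, ins = op
            seq = seq[:pos] + ins + seq[pos:]
        else:
            raise ValueError(f"unknown edit op {op!r}")
    return seq
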