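"""IUPAC nucleotide code utilities shared across modules."""

from __future__ import annotations

from Bio.Seq import reverse_complement as _bio_revcomp

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)


def is_iupac(seq: str) -> bool:
    return all(b in IUPAC_SETS for b in seq.upper())


def revcomp(seq: str) -> str:
    """Reverse complement, degenerate codes included."""
    return _bio_revcomp(seq)


def pattern_matches_at(pattern: str, seq: str, offset: int) -> bool:
    """True if ``pattern`` (IUPAC) matches ``seq`` starting at ``offset``.

    A sequence base matches a pattern code when every base the sequence
    code could be is allowed by the pattern code (so a genomic ``N`` only
    matches a pattern ``N``).
    """
    if offset < 0 or offset + len(pattern) > len(seq):
        return False
    for p, s in zip(pattern, seq[offset : offset + len(pattern)]):
        if not IUPAC_SETS[s] <= IUPAC_SETS[p]:
            return False
    return True
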