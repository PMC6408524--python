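"""Dimer architecture grammar for zinc-finger nucleases.

A ZFN dimer cleaves in the spacer gap between two ZFP binding sites.
The canonical architecture (CC) fuses the FokI cleavage domain to the
carboxy terminus of both ZFPs, putting the two half-sites on opposite
strands converging over the gap.  Amino-terminal FokI fusions reverse
the strand a ZFP must bind, yielding three further dimer architectures:

========  ==================  ===================
arch      left site strand    right site strand
========  ==================  ===================
CC        bottom (-)          top (+)
NC        top (+)             top (+)
CN        bottom (-)          bottom (-)
NN        top (+)             bottom (-)
========  ==================  ===================

NC and CN place both half-sites on the same strand; NN is the strand
inverse of CC.  Independently, base-skipping inter-finger linkers let a
ZFP leave exactly one unread base between adjacent fingers' triplets at
designated junctions: fingers 2-3 or 4-5 of a six-finger array, fingers
2-3 or 3-4 of a five-finger array.  Four architectures times four skip
plans per monomer multiply the configurations available for cleaving at
a fixed base step by 4 x 4 x 4 = 64 over the canonical no-skip baseline.

Coordinates are 0-based half-open.  The cleavage center of a gap
``[b, c)`` is ``(b + c) / 2``; an odd gap gives a half-integer center,
assigned to base step ``floor(center)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Arch",
    "SkipPlan",
    "DimerConfiguration",
    "DimerLayout",
    "ALLOWED_JUNCTIONS",
    "ARCH_STRANDS",
    "DEFAULT_GAP_SETS",
    "enumerate_skip_plans",
    "configuration_multiplicity",
    "enumerate_configurations",
    "realize_layout",
    "GrammarConfig",
    "load_grammar_config",
]


class Arch(str, Enum):
    """Dimer architecture, named by the FokI attachment point of the
    upstream (left) and downstream (right) ZFN: N = amino-terminal,
    C = carboxy-terminal."""

    CC = "CC"
    NC = "NC"
    CN = "CN"
    NN = "NN"


#: Junctions at which a 1-bp skip linker may be inserted, per finger count.
ALLOWED_JUNCTIONS: dict[int, tuple[str, ...]] = {
    6: ("J2-3", "J4-5"),
    5: ("J2-3", "J3-4"),
}

#: (left site strand, right site strand) per architecture.
ARCH_STRANDS: dict[Arch, tuple[str, str]] = {
    Arch.CC: ("-", "+"),
    Arch.NC: ("+", "+"),
    Arch.CN: ("-", "-"),
    Arch.NN: ("+", "-"),
}

#: Allowed gap (spacer) lengths per architecture.  NC/CN follow the
#: selection targets (6 or 7 bp, with 6 bp the minimal spacing allowing
#: FokI dimerization); NN defaults to the actively cleaving 7-9 bp
#: range; CC uses the conventional 5-6 bp spacing of carboxy-fusion
#: linkers.  All overridable per call.
DEFAULT_GAP_SETS: dict[Arch, tuple[int, ...]] = {
    Arch.CC: (5, 6),
    Arch.NC: (6, 7),
    Arch.CN: (6, 7),
    Arch.NN: (7, 8, 9),
}


@dataclass(frozen=True)
class SkipPlan:
    """Which inter-finger junctions of a 5- or 6-finger ZFP carry a
    1-bp base-skipping linker."""

    finger_count: int
    skipped_junctions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.finger_count not in ALLOWED_JUNCTIONS:
            raise ValueError(f"finger_count must be 5 or 6, got {self.finger_count}")
        object.__setattr__(self, "skipped_junctions", frozenset(self.skipped_junctions))
        bad = self.skipped_junctions - set(ALLOWED_JUNCTIONS[self.finger_count])
        if bad:
            raise ValueError(
                f"junction(s) {sorted(bad)} not skippable in a {self.finger_count}-finger ZFP"
            )

    @property
    def n_skips(self) -> int:
        return len(self.skipped_junctions)

    @property
    def span(self) -> int:
        """Recognition span in bp: 3 per finger plus 1 per skipped base."""
        return 3 * self.finger_count + self.n_skips

    def sort_key(self) -> tuple:
        return (self.finger_count, self.n_skips, tuple(sorted(self.skipped_junctions)))

    def label(self) -> str:
        if not self.skipped_junctions:
            return f"{self.finger_count}F"
        return f"{self.finger_count}F+" + "+".join(sorted(self.skipped_junctions))


def enumerate_skip_plans(finger_count: int) -> list[SkipPlan]:
    """All skip plans for a 5- or 6-finger ZFP: every subset of the two
    allowed junctions, no-skip first then lexicographic (4 plans)."""
    junctions = ALLOWED_JUNCTIONS.get(finger_count)
    if junctions is None:
        raise ValueError(f"finger_count must be 5 or 6, got {finger_count}")
    subsets = [
        frozenset(c)
        for r in range(len(junctions) + 1)
        for c in _combinations_sorted(junctions, r)
    ]
    return [SkipPlan(finger_count, s) for s in subsets]


def _combinations_sorted(items: Sequence[str], r: int):
    from itertools import combinations

    return combinations(sorted(items), r)


@dataclass(frozen=True)
class DimerConfiguration:
    """One realizable dimer configuration: architecture, gap length and
    a skip plan per monomer."""

    arch: Arch
    gap_bp: int
    left_skip: SkipPlan
    right_skip: SkipPlan

    def label(self) -> str:
        return f"{self.arch.value}/gap{self.gap_bp}/{self.left_skip.label()}|{self.right_skip.label()}"


@dataclass(frozen=True)
class DimerLayout:
    """A configuration realized as genome geometry around a cleavage
    base step: two strand-assigned binding-site intervals flanking the
    gap.  Intervals are 0-based half-open and tile
    ``[left_start, right_end)`` exactly."""

    cleavage_center: int
    left_site: tuple[int, int, str]
    gap: tuple[int, int]
    right_site: tuple[int, int, str]
    config: DimerConfiguration

    @property
    def span(self) -> tuple[int, int]:
        return (self.left_site[0], self.right_site[1])


def configuration_multiplicity(
    archs: Iterable[Arch | str], finger_count: int, skips_enabled: bool
) -> int:
    """Number of distinct (architecture, left skip plan, right skip plan)
    configurations for cleaving at a fixed base step.

    The ratio to the canonical no-skip baseline (CC only, skips off,
    multiplicity 1) is the fold-increase in design options: 4 from the
    architectures alone, 16 from skips alone, 64 combined.
    """
    arch_set = {Arch(a) for a in archs}
    if not arch_set:
        raise ValueError("archs must be non-empty")
    m_skip = len(enumerate_skip_plans(finger_count)) if skips_enabled else 1
    return len(arch_set) * m_skip * m_skip


def enumerate_configurations(
    archs: Iterable[Arch | str] = tuple(Arch),
    finger_counts: Iterable[int] = (6,),
    skips_enabled: bool = True,
    gap_sets: Mapping[Arch, Sequence[int]] | None = None,
) -> list[DimerConfiguration]:
    """Enumerate concrete configurations over architectures, gap sets
    and per-monomer skip plans, in deterministic order."""
    gap_sets = dict(DEFAULT_GAP_SETS) if gap_sets is None else dict(gap_sets)
    arch_list = sorted({Arch(a) for a in archs}, key=lambda a: a.value)
    configs: list[DimerConfiguration] = []
    for arch in arch_list:
        for fc in sorted(set(finger_counts)):
            plans = enumerate_skip_plans(fc) if skips_enabled else [SkipPlan(fc)]
            for gap in sorted(gap_sets[arch]):
                for left, right in product(plans, plans):
                    configs.append(DimerConfiguration(arch, gap, left, right))
    return configs


@dataclass(frozen=True)
class GrammarConfig:
    """A scan-level grammar configuration: which architectures and
    finger counts to use, whether skips are enabled, and the allowed
    gap set per architecture."""

    archs: tuple[Arch, ...] = tuple(Arch)
    finger_counts: tuple[int, ...] = (6,)
    skips_enabled: bool = True
    gap_sets: dict[Arch, tuple[int, ...]] | None = None

    def configurations(self) -> list[DimerConfiguration]:
        return enumerate_configurations(
            self.archs, self.finger_counts, self.skips_enabled, self.gap_sets
        )


def load_grammar_config(path) -> GrammarConfig:
    """Load a grammar configuration from YAML.

    Recognized keys (all optional): ``archs`` (list of CC/NC/CN/NN),
    ``finger_counts`` (list of 5/6), ``skips_enabled`` (bool),
    ``gap_sets`` (mapping arch -> list of gap lengths; unlisted
    architectures keep their defaults).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gap_sets = None
    if "gap_sets" in raw:
        gap_sets = dict(DEFAULT_GAP_SETS)
        for arch, gaps in raw["gap_sets"].items():
            gap_sets[Arch(arch)] = tuple(int(g) for g in gaps)
    return GrammarConfig(
        archs=tuple(Arch(a) for a in raw.get("archs", [a.value for a in Arch])),
        finger_counts=tuple(int(f) for f in raw.get("finger_counts", [6])),
        skips_enabled=bool(raw.get("skips_enabled", True)),
        gap_sets=gap_sets,
    )


def realize_layout(
    cleavage_center: int,
    config: DimerConfiguration,
    gap_sets: Mapping[Arch, Sequence[int]] | None = None,
) -> DimerLayout:
    """Place a configuration on the genome so its cleavage falls on the
    given base step.

    Even gaps center exactly on the base step; odd gaps have a
    half-integer center and are placed so ``floor(center)`` equals the
    requested base step.  Raises ``ValueError`` if the gap length is not
    allowed for the architecture.
    """
    gap_sets = DEFAULT_GAP_SETS if gap_sets is None else gap_sets
    g = config.gap_bp
    allowed = gap_sets.get(config.arch, ())
    if g not in allowed:
        raise ValueError(
            f"gap {g} bp not allowed for architecture {config.arch.value} (allowed: {sorted(allowed)})"
        )
    gap_start = cleavage_center - g // 2 if g % 2 == 0 else cleavage_center - (g - 1) // 2
    gap_end = gap_start + g
    left_strand, right_strand = ARCH_STRANDS[config.arch]
    left = (gap_start - config.left_skip.span, gap_start, left_strand)
    right = (gap_end, gap_end + config.right_skip.span, right_strand)
    return DimerLayout(
        cleavage_center=cleavage_center,
        left_site=left,
        gap=(gap_start, gap_end),
        right_site=right,
        config=config,
    )
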