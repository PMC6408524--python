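"""Scan sequences for ZFP binding sites, pair them into dimer designs,
and score per-base-step targeting density.

A binding site is any placement of three archive modules (forming a 5-
or 6-finger ZFP under a skip plan) whose concatenated triplets — with
one unconstrained base at each skipped junction — match the sequence on
either strand.  Sites are paired into dimer designs wherever two sites
realize an allowed architecture geometry (strand pair + gap length), and
each design is assigned the base step at the center of cleavage between
the two binding sites.  Targeting density over a region is the fraction
of its base steps covered by at least one design.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._iupac import pattern_matches_at, revcomp
from .archive import FingerModule, ModuleArchive
from .grammar import (
    Arch,
    DimerConfiguration,
    DimerLayout,
    SkipPlan,
    enumerate_skip_plans,
)

__all__ = [
    "BindingSite",
    "DimerDesign",
    "DensityProfile",
    "DEFAULT_COMPOSITIONS",
    "find_zfp_sites",
    "pair_dimers",
    "targeting_density",
    "count_designs",
    "sites_to_bed",
    "designs_to_table",
    "density_to_json",
]

#: Module composition per finger count, in protein order (amino- to
#: carboxy-terminal).  Six fingers: three 2-finger modules.  Five
#: fingers: two 2-finger modules and one 1-finger module, the 1-finger
#: module carboxy-terminal (binding the 5'-most triplet of the site).
DEFAULT_COMPOSITIONS: dict[int, tuple[int, ...]] = {6: (2, 2, 2), 5: (2, 2, 1)}


@dataclass(frozen=True)
class BindingSite:
    """A concrete ZFP binding site on the reference (0-based half-open).

    ``module_ids`` and ``matched_triplets`` are ordered 5'->3' along the
    bound strand (so the carboxy-terminal module comes first).
    """

    start: int
    end: int
    strand: str
    finger_count: int
    skip_plan: SkipPlan
    module_ids: tuple[str, ...]
    matched_triplets: tuple[str, ...]
    chrom: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != self.skip_plan.span:
            raise ValueError("site interval length inconsistent with skip plan span")


@dataclass(frozen=True)
class DimerDesign:
    """A concrete ZFN pair: two binding sites realizing a dimer layout."""

    layout: DimerLayout
    left: BindingSite
    right: BindingSite
    id: str

    @property
    def cleavage_base_step(self) -> int:
        return self.layout.cleavage_center


@dataclass
class DensityProfile:
    """Per-base-step design counts over a region.

    A region of length L has L base steps (one per position, matching
    the positional accounting of a promoter scan where a 28-bp segment
    has 28 scorable base steps).
    """

    region: tuple[int, int]
    counts: np.ndarray
    chrom: str | None = None

    @property
    def density(self) -> float:
        return float((self.counts > 0).mean())

    @property
    def covered(self) -> int:
        return int((self.counts > 0).sum())


# ---------------------------------------------------------------------------
# site structure: mapping skip plans onto module slots


@dataclass(frozen=True)
class _Slot:
    n_fingers: int
    intra_skip: bool  # 1-bp skip between this module's own fingers
    offset: int  # start of the slot within the site, in bp
    length: int  # bp covered by the slot (3*n_fingers + intra skip)


def _junction_boundary(label: str, finger_count: int) -> int:
    """Site triplet-boundary index (from the 5' end) of junction Jk-(k+1).

    Finger k binds the (finger_count - k)-th triplet from the 5' end, so
    the junction between fingers k and k+1 sits between triplet indices
    finger_count-k-1 and finger_count-k.
    """
    k = int(label.split("-")[0][1:])
    return finger_count - k


def _site_structure(
    finger_count: int, plan: SkipPlan, composition: Sequence[int]
) -> list[_Slot]:
    """Lay out the three module slots of a site in 5'->3' order, placing
    each skipped base at its junction (between slots, or inside a slot)."""
    if sum(composition) != finger_count:
        raise ValueError(f"composition {composition} does not sum to {finger_count} fingers")
    slots_fingers = tuple(reversed(composition))  # site order = reverse of protein order
    cum = np.cumsum(slots_fingers)  # triplet boundaries after each slot
    inter_after = [False] * len(slots_fingers)
    intra_in: dict[int, int] = {}  # slot index -> local triplet boundary
    for label in sorted(plan.skipped_junctions):
        b = _junction_boundary(label, finger_count)
        placed = False
        for j, c in enumerate(cum[:-1]):
            if b == c:
                inter_after[j] = True
                placed = True
                break
        if not placed:
            j = int(np.searchsorted(cum, b, side="right"))
            local = b - (int(cum[j - 1]) if j > 0 else 0)
            intra_in[j] = local
    slots: list[_Slot] = []
    offset = 0
    for j, nf in enumerate(slots_fingers):
        intra = j in intra_in
        length = 3 * nf + (1 if intra else 0)
        slots.append(_Slot(nf, intra, offset, length))
        offset += length + (1 if inter_after[j] else 0)
    assert offset == plan.span
    return slots


def _slot_pattern(module: FingerModule, slot: _Slot) -> str:
    if slot.intra_skip:
        # only defined for 2-finger modules; local boundary is between
        # the module's two triplets
        return module.triplets[0] + "N" + module.triplets[1]
    return "".join(module.triplets)


def _candidate_modules(archive: ModuleArchive, slot: _Slot) -> list[FingerModule]:
    mods = archive.with_fingers(slot.n_fingers)
    if slot.intra_skip:
        mods = [m for m in mods if m.skip_capable_internal]
    return mods


def _slot_matches(
    oriented: str, slot: _Slot, modules: list[FingerModule]
) -> dict[int, list[FingerModule]]:
    """Positions (slot start, oriented coords) -> modules matching there.

    Concrete ACGT patterns go through a hash lookup; degenerate patterns
    fall back to per-position IUPAC matching.
    """
    exact: dict[str, list[FingerModule]] = {}
    degenerate: list[tuple[FingerModule, str]] = []
    skip_idx = 3 if slot.intra_skip else None
    for m in modules:
        pat = _slot_pattern(m, slot)
        core = pat if skip_idx is None else pat[:skip_idx] + pat[skip_idx + 1 :]
        if set(core) <= set("ACGT"):
            exact.setdefault(pat, []).append(m)
        else:
            degenerate.append((m, pat))
    out: dict[int, list[FingerModule]] = {}
    n = len(oriented)
    for pos in range(n - slot.length + 1):
        sub = oriented[pos : pos + slot.length]
        if skip_idx is not None:
            sub = sub[:skip_idx] + "N" + sub[skip_idx + 1 :]
        hits = exact.get(sub)
        if hits:
            out.setdefault(pos, []).extend(hits)
        for m, pat in degenerate:
            if pattern_matches_at(pat, oriented, pos):
                out.setdefault(pos, []).append(m)
    return out


def find_zfp_sites(
    seq: str,
    archive: ModuleArchive,
    finger_count: int,
    skip_plans: Iterable[SkipPlan] | None = None,
    composition: Sequence[int] | None = None,
    chrom: str | None = None,
) -> list[BindingSite]:
    """Find every archive-assemblable ZFP binding site in ``seq``.

    Every (position, strand, skip plan, ordered module triple) whose
    pattern matches is reported exactly once, sorted by (position,
    strand, plan, module ids).
    """
    if finger_count not in DEFAULT_COMPOSITIONS:
        raise ValueError(f"finger_count must be 5 or 6, got {finger_count}")
    if len(archive) == 0:
        raise ValueError("archive is empty")
    seq = seq.upper()
    if skip_plans is None:
        skip_plans = enumerate_skip_plans(finger_count)
    composition = tuple(composition or DEFAULT_COMPOSITIONS[finger_count])
    sites: list[BindingSite] = []
    n = len(seq)
    for strand in "+-":
        oriented = seq if strand == "+" else revcomp(seq)
        for plan in skip_plans:
            if plan.finger_count != finger_count:
                raise ValueError("skip plan finger_count differs from requested finger_count")
            span = plan.span
            if n < span:
                continue
            slots = _site_structure(finger_count, plan, composition)
            per_slot = []
            feasible = True
            for slot in slots:
                mods = _candidate_modules(archive, slot)
                if not mods:
                    feasible = False
                    break
                per_slot.append((slot, _slot_matches(oriented, slot, mods)))
            if not feasible:
                continue
            for o in range(n - span + 1):
                choices = []
                for slot, matches in per_slot:
                    hit = matches.get(o + slot.offset)
                    if not hit:
                        break
                    choices.append(hit)
                else:
                    for combo in product(*choices):
                        start = o if strand == "+" else n - (o + span)
                        triplets = tuple(
                            oriented[o + s.offset + 3 * i : o + s.offset + 3 * i + 3]
                            if not (s.intra_skip and i == 1)
                            else oriented[o + s.offset + 4 : o + s.offset + 7]
                            for s in slots
                            for i in range(s.n_fingers)
                        )
                        sites.append(
                            BindingSite(
                                start=start,
                                end=start + span,
                                strand=strand,
                                finger_count=finger_count,
                                skip_plan=plan,
                                module_ids=tuple(m.id for m in combo),
                                matched_triplets=triplets,
                                chrom=chrom,
                            )
                        )
    sites.sort(
        key=lambda s: (s.start, s.strand, s.skip_plan.sort_key(), s.module_ids)
    )
    return sites


def _design_id(a: BindingSite, b: BindingSite, config: DimerConfiguration) -> str:
    key = (
        a.chrom,
        a.start,
        a.end,
        a.strand,
        a.module_ids,
        b.start,
        b.end,
        b.strand,
        b.module_ids,
        config.label(),
    )
    return hashlib.sha1(repr(key).encode()).hexdigest()[:12]


def pair_dimers(
    sites: Sequence[BindingSite],
    configs: Sequence[DimerConfiguration],
    region: tuple[int, int] | None = None,
) -> list[DimerDesign]:
    """Pair binding sites into dimer designs under the given
    configurations.

    Two sites form a design for a configuration when the left (lower
    coordinate) site carries the configuration's left skip plan on the
    architecture's left strand, the right site likewise, and the bases
    between the sites equal the configuration's gap.  Designs are
    deduplicated by (layout, module choices) and sorted by (cleavage
    base step, architecture, left start, id).
    """
    from .grammar import ARCH_STRANDS

    index: dict[tuple, list[BindingSite]] = {}
    for s in sites:
        index.setdefault((s.start, s.strand, s.skip_plan), []).append(s)
    designs: dict[tuple, DimerDesign] = {}
    for config in configs:
        left_strand, right_strand = ARCH_STRANDS[config.arch]
        for a in sites:
            if a.strand != left_strand or a.skip_plan != config.left_skip:
                continue
            b_start = a.end + config.gap_bp
            for b in index.get((b_start, right_strand, config.right_skip), ()):
                if b.chrom != a.chrom:
                    continue
                step = (a.end + b.start) // 2
                if region is not None and not (region[0] <= step < region[1]):
                    continue
                layout = DimerLayout(
                    cleavage_center=step,
                    left_site=(a.start, a.end, a.strand),
                    gap=(a.end, b.start),
                    right_site=(b.start, b.end, b.strand),
                    config=config,
                )
                key = (
                    a.chrom,
                    a.start,
                    a.strand,
                    b.start,
                    b.strand,
                    config,
                    a.module_ids,
                    b.module_ids,
                )
                if key not in designs:
                    designs[key] = DimerDesign(layout, a, b, _design_id(a, b, config))
    out = list(designs.values())
    out.sort(
        key=lambda d: (
            d.cleavage_base_step,
            d.layout.config.arch.value,
            d.left.start,
            d.id,
        )
    )
    return out


def targeting_density(
    designs: Iterable[DimerDesign],
    region: tuple[int, int],
    chrom: str | None = None,
) -> DensityProfile:
    """Per-base-step design counts and coverage density over a region."""
    start, end = region
    if end - start < 1:
        raise ValueError("region must be non-empty")
    counts = np.zeros(end - start, dtype=int)
    for d in designs:
        if chrom is not None and d.left.chrom is not None and d.left.chrom != chrom:
            continue
        s = d.cleavage_base_step
        if start <= s < end:
            counts[s - start] += 1
    return DensityProfile(region=(start, end), counts=counts, chrom=chrom)


def count_designs(
    seq: str,
    archive: ModuleArchive,
    configs: Sequence[DimerConfiguration],
    composition: Mapping[int, Sequence[int]] | None = None,
) -> int:
    """Number of distinct dimer designs the grammar admits on ``seq``
    (deduplicated by layout + module choices)."""
    needed: dict[int, set[SkipPlan]] = {}
    for c in configs:
        for plan in (c.left_skip, c.right_skip):
            needed.setdefault(plan.finger_count, set()).add(plan)
    sites: list[BindingSite] = []
    for fc, plans in sorted(needed.items()):
        comp = None if composition is None else composition.get(fc)
        sites.extend(
            find_zfp_sites(
                seq,
                archive,
                fc,
                sorted(plans, key=lambda p: p.sort_key()),
                composition=comp,
            )
        )
    return len(pair_dimers(sites, configs))


# ---------------------------------------------------------------------------
# output formats


def sites_to_bed(sites: Iterable[BindingSite], default_chrom: str = ".") -> str:
    """BED6 text for binding sites (name = plan + module ids)."""
    lines = []
    for s in sites:
        name = f"{s.skip_plan.label()}:{'|'.join(s.module_ids)}"
        lines.append(
            "\t".join(
                [s.chrom or default_chrom, str(s.start), str(s.end), name, "0", s.strand]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def designs_to_table(designs: Iterable[DimerDesign]):
    """Designs as a pandas DataFrame (one row per design)."""
    rows = []
    for d in designs:
        cfg = d.layout.config
        rows.append(
            {
                "chrom": d.left.chrom or ".",
                "base_step": d.cleavage_base_step,
                "arch": cfg.arch.value,
                "gap": cfg.gap_bp,
                "left_start": d.left.start,
                "left_end": d.left.end,
                "left_strand": d.left.strand,
                "right_start": d.right.start,
                "right_end": d.right.end,
                "right_strand": d.right.strand,
                "left_plan": cfg.left_skip.label(),
                "right_plan": cfg.right_skip.label(),
                "left_modules": "|".join(d.left.module_ids),
                "right_modules": "|".join(d.right.module_ids),
                "design_id": d.id,
            }
        )
    import pandas as pd

    columns = [
        "chrom", "base_step", "arch", "gap",
        "left_start", "left_end", "left_strand",
        "right_start", "right_end", "right_strand",
        "left_plan", "right_plan", "left_modules", "right_modules", "design_id",
    ]
    return pd.DataFrame(rows, columns=columns)


def density_to_json(profile: DensityProfile) -> str:
    return json.dumps(
        {
            "chrom": profile.chrom,
            "region": list(profile.region),
            "counts": profile.counts.tolist(),
            "covered_base_steps": profile.covered,
            "total_base_steps": int(len(profile.counts)),
            "density": profile.density,
        },
        indent=2,
    )
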