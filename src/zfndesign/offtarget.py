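"""Candidate off-target calling from duplex-capture integration events.

An unbiased capture assay tags nuclease cut sites by integration of a
short double-stranded oligo; mapped integration positions are the input
here (one event per read, with the count of equally-best alignments).
Candidate off-target loci are called by a filter cascade:

1. deduplicate events (unique by position/strand/replicate/arm);
2. single-linkage cluster unique integrations within 100 bp;
3. keep clusters with >= 5-fold more integrations than the same locus
   in nuclease-free control cells (control 0 passes);
4. drop clusters containing events mapping equally well to 3 or more
   loci;
5. require the locus to lie on a known (primary-assembly) chromosome;
6. require the locus to be >= 10 kb from the intended target;
7. require candidate loci to yield capture events in at least 2 of the
   replicates, then rank by total capture events (on-target first when
   present).
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "IntegrationEvent",
    "EventCluster",
    "CandidateLocus",
    "FilterParams",
    "dedupe_events",
    "cluster_events",
    "apply_filters",
    "replicate_consensus",
    "call_candidate_loci",
    "read_events_table",
    "write_candidates_table",
]

_PRIMARY_CHROM = re.compile(r"^(chr)?([0-9]{1,2}|X|Y|M|MT)$", re.IGNORECASE)


@dataclass(frozen=True)
class IntegrationEvent:
    """A single mapped oligo-integration event."""

    chrom: str
    pos: int
    strand: str
    n_best_hits: int = 1
    replicate: str = "rep1"
    arm: str = "treated"

    def __post_init__(self) -> None:
        if self.n_best_hits < 1:
            raise ValueError("n_best_hits must be >= 1")


@dataclass
class EventCluster:
    """A cluster of unique integrations on one chromosome."""

    chrom: str
    start: int
    end: int  # half-open; max pos + 1
    events: list[IntegrationEvent]
    control_count: int = 0
    filter_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.events)

    @property
    def passed_all(self) -> bool:
        return bool(self.filter_flags) and all(self.filter_flags.values())


@dataclass
class CandidateLocus:
    """A replicate-supported candidate locus, ranked by capture events."""

    chrom: str
    start: int
    end: int
    capture_events: int
    replicate_support: int
    rank: int = 0
    is_on_target: bool = False


@dataclass(frozen=True)
class FilterParams:
    fold: float = 5.0
    max_best_hits: int = 3  # events must map equally well to fewer loci
    min_distance: int = 10_000
    window_bp: int = 100  # clustering window; also pads control lookup
    known_chroms: frozenset[str] | None = None  # None -> primary-assembly regex


def dedupe_events(events: Iterable[IntegrationEvent]) -> list[IntegrationEvent]:
    """One event per (chrom, position, strand, replicate, arm), in
    sorted order."""
    unique = {(e.chrom, e.pos, e.strand, e.replicate, e.arm): e for e in events}
    return [unique[k] for k in sorted(unique)]


def cluster_events(
    events: Sequence[IntegrationEvent], window_bp: int = 100
) -> list[EventCluster]:
    """Single-linkage clustering along each chromosome: consecutive
    sorted events at most ``window_bp`` apart join one cluster.  The
    result is a partition of the events, independent of input order."""
    by_chrom: dict[str, list[IntegrationEvent]] = {}
    for e in events:
        by_chrom.setdefault(e.chrom, []).append(e)
    clusters: list[EventCluster] = []
    for chrom in sorted(by_chrom):
        evs = sorted(by_chrom[chrom], key=lambda e: (e.pos, e.strand, e.replicate, e.arm))
        current: list[IntegrationEvent] = []
        for e in evs:
            if current and e.pos - current[-1].pos > window_bp:
                clusters.append(
                    EventCluster(chrom, current[0].pos, current[-1].pos + 1, current)
                )
                current = []
            current.append(e)
        if current:
            clusters.append(
                EventCluster(chrom, current[0].pos, current[-1].pos + 1, current)
            )
    return clusters


def _interval_distance(
    chrom_a: str, a: tuple[int, int], chrom_b: str, b: tuple[int, int]
) -> float:
    if chrom_a != chrom_b:
        return float("inf")
    if a[1] <= b[0]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return a[0] - b[1]
    return 0.0


def _is_known(chrom: str, params: FilterParams) -> bool:
    if params.known_chroms is not None:
        return chrom in params.known_chroms
    return bool(_PRIMARY_CHROM.match(chrom))


def apply_filters(
    clusters: Sequence[EventCluster],
    control_events: Sequence[IntegrationEvent],
    on_target: tuple[str, int, int],
    params: FilterParams | None = None,
) -> list[EventCluster]:
    """Apply the filter cascade to treated-arm clusters.

    Each cluster is annotated with per-filter flags (fold_pass,
    multimap_pass, known_pass, distance_pass) and its control count at
    the same locus (control events within the cluster interval padded
    by the clustering window).  Returns the clusters passing all
    filters; flags remain on every input cluster for provenance.
    """
    params = params or FilterParams()
    ot_chrom, ot_start, ot_end = on_target
    ctrl_by_chrom: dict[str, list[int]] = {}
    for e in control_events:
        ctrl_by_chrom.setdefault(e.chrom, []).append(e.pos)
    for positions in ctrl_by_chrom.values():
        positions.sort()
    passed: list[EventCluster] = []
    for c in clusters:
        lo, hi = c.start - params.window_bp, c.end + params.window_bp
        positions = ctrl_by_chrom.get(c.chrom, [])
        c.control_count = bisect.bisect_left(positions, hi) - bisect.bisect_left(positions, lo)
        fold_pass = c.control_count == 0 or c.count >= params.fold * c.control_count
        multimap_pass = all(e.n_best_hits < params.max_best_hits for e in c.events)
        known_pass = _is_known(c.chrom, params)
        distance_pass = (
            _interval_distance(c.chrom, (c.start, c.end), ot_chrom, (ot_start, ot_end))
            >= params.min_distance
        )
        c.filter_flags = {
            "fold_pass": fold_pass,
            "multimap_pass": multimap_pass,
            "known_pass": known_pass,
            "distance_pass": distance_pass,
        }
        if c.passed_all:
            passed.append(c)
    return passed


def replicate_consensus(
    per_replicate_candidates: Mapping[str, Sequence[EventCluster]],
    min_replicates: int = 2,
    on_target: tuple[str, int, int] | None = None,
) -> list[CandidateLocus]:
    """Merge per-replicate candidate clusters into consensus loci.

    Clusters from different replicates belong to the same locus when
    their intervals overlap (>= 1 bp, transitively).  Loci supported by
    at least ``min_replicates`` replicates are kept, with capture
    events summed across replicates, ranked by descending events with a
    stable (chrom, start) tie-break; an on-target locus, if present,
    is ranked first.
    """
    tagged: list[tuple[str, EventCluster]] = [
        (rep, c) for rep, cs in sorted(per_replicate_candidates.items()) for c in cs
    ]
    by_chrom: dict[str, list[tuple[str, EventCluster]]] = {}
    for rep, c in tagged:
        by_chrom.setdefault(c.chrom, []).append((rep, c))
    loci: list[CandidateLocus] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda rc: (rc[1].start, rc[1].end))
        group: list[tuple[str, EventCluster]] = []
        group_end = None
        for rep, c in items:
            if group and c.start >= group_end:
                loci.append(_merge_group(chrom, group))
                group, group_end = [], None
            group.append((rep, c))
            group_end = c.end if group_end is None else max(group_end, c.end)
        if group:
            loci.append(_merge_group(chrom, group))
    loci = [l for l in loci if l.replicate_support >= min_replicates]
    if on_target is not None:
        for l in loci:
            l.is_on_target = (
                _interval_distance(l.chrom, (l.start, l.end), on_target[0], on_target[1:3])
                == 0.0
            )
    loci.sort(key=lambda l: (not l.is_on_target, -l.capture_events, l.chrom, l.start))
    for i, l in enumerate(loci, start=1):
        l.rank = i
    return loci


def _merge_group(chrom: str, group: list[tuple[str, EventCluster]]) -> CandidateLocus:
    return CandidateLocus(
        chrom=chrom,
        start=min(c.start for _, c in group),
        end=max(c.end for _, c in group),
        capture_events=sum(c.count for _, c in group),
        replicate_support=len({rep for rep, _ in group}),
    )


def call_candidate_loci(
    treated_events: Iterable[IntegrationEvent],
    control_events: Iterable[IntegrationEvent],
    on_target: tuple[str, int, int],
    params: FilterParams | None = None,
    min_replicates: int = 2,
) -> list[CandidateLocus]:
    """Full pipeline: dedupe, cluster per replicate, filter against the
    matching control replicate (pooled control when replicate ids do
    not match), and take the replicate consensus."""
    params = params or FilterParams()
    treated = dedupe_events(treated_events)
    control = dedupe_events(control_events)
    reps = sorted({e.replicate for e in treated})
    ctrl_reps = {e.replicate for e in control}
    per_rep: dict[str, list[EventCluster]] = {}
    for rep in reps:
        rep_events = [e for e in treated if e.replicate == rep]
        rep_control = (
            [e for e in control if e.replicate == rep] if rep in ctrl_reps else control
        )
        clusters = cluster_events(rep_events, window_bp=params.window_bp)
        per_rep[rep] = apply_filters(clusters, rep_control, on_target, params)
    return replicate_consensus(per_rep, min_replicates=min_replicates, on_target=None)


# ---------------------------------------------------------------------------
# I/O: BED6-like event tables


def read_events_table(path: str | Path, arm: str, replicate: str | None = None) -> list[IntegrationEvent]:
    """Read events from a BED6-like TSV: chrom, start, end, name
    (replicate id), score (n_best_hits), strand."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
        comment="#",
    )
    return [
        IntegrationEvent(
            chrom=row.chrom,
            pos=int(row.start),
            strand=row.strand,
            n_best_hits=int(row.score),
            replicate=replicate or str(row.name),
            arm=arm,
        )
        for row in df.itertuples()
    ]


def write_candidates_table(loci: Sequence[CandidateLocus], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "rank": l.rank,
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "capture_events": l.capture_events,
                "replicate_support": l.replicate_support,
                "is_on_target": l.is_on_target,
            }
            for l in loci
        ]
    ).to_csv(path, sep="\t", index=False)
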