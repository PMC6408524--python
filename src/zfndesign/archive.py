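"""Archives of one- and two-finger zinc-finger modules.

Modular assembly builds 5- and 6-finger zinc-finger proteins (ZFPs) by
fusing three pre-characterized modules, each recognizing one or two DNA
triplets.  An archive is the catalog of available modules.  Triplets are
stored 5'->3' along the target site; by the antiparallel polarity of
zinc-finger/DNA recognition the carboxy-terminal finger of the protein
binds the 5'-most triplet.

The built-in GNN archive contains one 1-finger module per GNN triplet
(16 modules) and one 2-finger module per ordered pair of GNN triplets
(256 modules).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable

from ._iupac import IUPAC_ALPHABET

__all__ = [
    "FingerModule",
    "ModuleArchive",
    "ArchiveError",
    "build_gnn_archive",
    "load_archive",
    "save_archive",
]


class ArchiveError(ValueError):
    """Raised for malformed modules or archive files."""


@dataclass(frozen=True)
class FingerModule:
    """A one- or two-finger assembly unit.

    Parameters
    ----------
    id
        Unique module identifier within an archive.
    n_fingers
        1 or 2.
    triplets
        The recognized DNA triplets (IUPAC allowed), ordered 5'->3'
        along the target site; length equals ``n_fingers``.
    helix_labels
        Optional recognition-helix annotations (not interpreted).
    skip_capable_internal
        Whether a 1-bp base skip is permitted between this module's own
        two fingers (meaningful only for 2-finger modules).
    """

    id: str
    n_fingers: int
    triplets: tuple[str, ...]
    helix_labels: tuple[str, ...] | None = None
    skip_capable_internal: bool = False

    def __post_init__(self) -> None:
        if self.n_fingers not in (1, 2):
            raise ArchiveError(f"module {self.id!r}: n_fingers must be 1 or 2, got {self.n_fingers}")
        triplets = tuple(t.upper() for t in self.triplets)
        object.__setattr__(self, "triplets", triplets)
        if len(triplets) != self.n_fingers:
            raise ArchiveError(
                f"module {self.id!r}: {len(triplets)} triplet(s) for {self.n_fingers} finger(s)"
            )
        for t in triplets:
            if len(t) != 3 or any(b not in IUPAC_ALPHABET for b in t):
                raise ArchiveError(f"module {self.id!r}: invalid triplet {t!r}")
        if self.helix_labels is not None:
            object.__setattr__(self, "helix_labels", tuple(self.helix_labels))

    @property
    def span(self) -> int:
        """Bases recognized without an internal skip."""
        return 3 * self.n_fingers


@dataclass
class ModuleArchive:
    """A named collection of finger modules with unique ids."""

    name: str
    modules: list[FingerModule] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.modules:
            if m.id in seen:
                raise ArchiveError(f"duplicate module id {m.id!r}")
            seen.add(m.id)

    def __len__(self) -> int:
        return len(self.modules)

    def by_id(self, module_id: str) -> FingerModule:
        for m in self.modules:
            if m.id == module_id:
                return m
        raise KeyError(module_id)

    def with_fingers(self, n_fingers: int) -> list[FingerModule]:
        return [m for m in self.modules if m.n_fingers == n_fingers]

    def sorted(self) -> "ModuleArchive":
        return replace(self, modules=sorted(self.modules, key=lambda m: m.id))


_GNN_TRIPLETS = tuple("G" + a + b for a in "ACGT" for b in "ACGT")


def build_gnn_archive() -> ModuleArchive:
    """Build the archive of all GNN-triplet modules.

    Returns an archive with 16 one-finger modules (one per GNN triplet)
    and 256 two-finger modules (one per ordered pair of GNN triplets).
    Ids are deterministic: ``1F-<triplet>`` and ``2F-<t5>-<t3>`` with
    triplets in 5'->3' site order.  Internal skips are disabled.
    """
    modules = [
        FingerModule(id=f"1F-{t}", n_fingers=1, triplets=(t,)) for t in _GNN_TRIPLETS
    ]
    modules.extend(
        FingerModule(id=f"2F-{t5}-{t3}", n_fingers=2, triplets=(t5, t3))
        for t5, t3 in product(_GNN_TRIPLETS, repeat=2)
    )
    return ModuleArchive(name="GNN", modules=modules, metadata={"source": "GNN triplet set"})


_TSV_COLUMNS = ("id", "n_fingers", "triplets", "skip_capable_internal")


def save_archive(archive: ModuleArchive, path: str | Path, format: str = "tsv") -> None:
    """Serialize an archive deterministically (modules sorted by id)."""
    path = Path(path)
    arc = archive.sorted()
    if format == "tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        for m in arc.modules:
            lines.append(
                "\t".join(
                    [m.id, str(m.n_fingers), ",".join(m.triplets), str(m.skip_capable_internal).lower()]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = {
            "name": arc.name,
            "metadata": dict(sorted(arc.metadata.items())),
            "modules": [
                {
                    "id": m.id,
                    "n_fingers": m.n_fingers,
                    "triplets": list(m.triplets),
                    "skip_capable_internal": m.skip_capable_internal,
                }
                for m in arc.modules
            ],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown archive format {format!r}")


def load_archive(path: str | Path, format: str | None = None) -> ModuleArchive:
    """Load and validate an archive from TSV or JSON.

    The format is inferred from the suffix when not given.  Malformed
    triplets and duplicate ids raise :class:`ArchiveError` naming the
    offending module.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "tsv":
        lines = path.read_text().splitlines()
        if not lines or lines[0].split("\t") != list(_TSV_COLUMNS):
            raise ArchiveError(f"{path}: missing or malformed TSV header")
        modules = []
        for ln in lines[1:]:
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) != len(_TSV_COLUMNS):
                raise ArchiveError(f"{path}: bad record {ln!r}")
            mid, nf, trips, skip = fields
            modules.append(
                FingerModule(
                    id=mid,
                    n_fingers=int(nf),
                    triplets=tuple(trips.split(",")) if trips else (),
                    skip_capable_internal=skip.strip().lower() == "true",
                )
            )
        return ModuleArchive(name=path.stem, modules=modules)
    if format == "json":
        payload = json.loads(path.read_text())
        modules = [
            FingerModule(
                id=m["id"],
                n_fingers=m["n_fingers"],
                triplets=tuple(m["triplets"]),
                skip_capable_internal=m.get("skip_capable_internal", False),
            )
            for m in payload["modules"]
        ]
        return ModuleArchive(
            name=payload.get("name", path.stem),
            modules=modules,
            metadata=dict(payload.get("metadata", {})),
        )
    raise ValueError(f"unknown archive format {format!r}")
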