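"""Node atlas for structural connectivity networks.

The default atlas is the 90-region automated anatomical labeling (AAL)
parcellation of cortical and subcortical gray matter (45 regions per
hemisphere, cerebellum excluded).  Each node carries a full region name, a
conventional abbreviation suffixed ``.L``/``.R``, its hemisphere, and a
functional-system label (``default-mode``, ``visual``, ``limbic`` or
``other``) used to annotate group-difference reports.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

VALID_HEMISPHERES = frozenset({"L", "R"})
VALID_SYSTEMS = frozenset({"default-mode", "visual", "limbic", "other"})


@dataclass(frozen=True)
class AtlasEntry:
    """One network node: a gray-matter region of interest."""

    index: int
    name: str
    abbreviation: str
    hemisphere: str
    system: str

    def __post_init__(self) -> None:
        if self.hemisphere not in VALID_HEMISPHERES:
            raise ValueError(f"hemisphere must be L or R, got {self.hemisphere!r}")
        if self.system not in VALID_SYSTEMS:
            raise ValueError(f"unknown functional system {self.system!r}")


class NodeAtlas:
    """Ordered collection of region nodes defining the network's node set.

    Node order is fixed: matrix row/column ``i`` always refers to
    ``atlas[i]``.  Abbreviations must be unique; they are the public node
    labels used in every exported table.
    """

    def __init__(self, entries: Iterable[AtlasEntry]):
        self.entries: tuple[AtlasEntry, ...] = tuple(entries)
        if not self.entries:
            raise ValueError("atlas must contain at least one region")
        for pos, e in enumerate(self.entries):
            if e.index != pos:
                raise ValueError(
                    f"atlas entries out of order: entry at position {pos} "
                    f"has index {e.index}"
                )
        abbrevs = [e.abbreviation for e in self.entries]
        if len(set(abbrevs)) != len(abbrevs):
            dup = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
            raise ValueError(f"duplicate abbreviations: {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[AtlasEntry]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> AtlasEntry:
        return self.entries[i]

    @property
    def n_nodes(self) -> int:
        return len(self.entries)

    @property
    def abbreviations(self) -> list[str]:
        return [e.abbreviation for e in self.entries]

    def index_of(self, abbreviation: str) -> int:
        """Node index of a region abbreviation (e.g. ``"CUN.L"``)."""
        for e in self.entries:
            if e.abbreviation == abbreviation:
                return e.index
        raise KeyError(f"no region with abbreviation {abbreviation!r}")

    def indices_of(self, abbreviations: Iterable[str]) -> list[int]:
        return [self.index_of(a) for a in abbreviations]

    def system_of(self, index: int) -> str:
        return self.entries[index].system

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NodeAtlas):
            return NotImplemented
        return self.entries == other.entries

    def __hash__(self) -> int:
        return hash(self.entries)


def load_atlas(path: str | Path) -> NodeAtlas:
    """Read an atlas from CSV with columns index,name,abbreviation,hemisphere,system."""
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                AtlasEntry(
                    index=int(row["index"]),
                    name=row["name"],
                    abbreviation=row["abbreviation"],
                    hemisphere=row["hemisphere"].strip().upper(),
                    system=row["system"].strip().lower(),
                )
            )
    return NodeAtlas(entries)


def write_atlas(atlas: NodeAtlas, path: str | Path) -> None:
    """Write an atlas as CSV (inverse of :func:`load_atlas`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "name", "abbreviation", "hemisphere", "system"])
        for e in atlas:
            writer.writerow([e.index, e.name, e.abbreviation, e.hemisphere, e.system])


def default_atlas() -> NodeAtlas:
    """The bundled 90-node AAL atlas (45 regions per hemisphere)."""
    ref = resources.files("structconn.data").joinpath("aal90.csv")
    with resources.as_file(ref) as path:
        atlas = load_atlas(path)
    if len(atlas) != 90:
        raise RuntimeError("bundled atlas is corrupt: expected 90 regions")
    return atlas
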