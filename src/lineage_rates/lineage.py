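"""Invariant early-embryo cell lineage of *C. elegans*.

The first five cleavage rounds of the worm embryo are invariant: every
embryo produces the same named cells (Sulston nomenclature: daughters append
a/p/l/r to the parent name) with stereotyped division timing and volumes.
This module represents that lineage — names, topology, stage labels, founder
lineages, volume fractions and timing — and maps DAPI nuclei counts to
developmental time.  It is the coordinate system for every downstream rate
computation: volumes calibrate TPM to absolute molecule counts, and cycle
durations convert per-cycle accumulation into transcripts per minute.

Stage convention: stage labels count cells *within the sampled cohort*, so
the "16-cell stage" denotes the cohort born when the eight AB granddaughters
divide (a ~24-cell embryo), matching the convention of the early-embryo
single-cell dataset this package emulates.

A default lineage (through the 16-cell cohort) and a default nuclei-count
timing table are bundled; both can be overridden with user TSVs.  Volume
fractions beyond the AB/P1 split (0.55/0.45) default to symmetric halving;
the MS cell cycle is fixed at 16 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "CellNode",
    "LineageTree",
    "TimingTable",
    "load_lineage",
    "load_timing",
    "default_tree",
    "default_timing",
]

STAGES = ("1-cell", "2-cell", "4-cell", "8-cell", "16-cell")


@dataclass(frozen=True)
class CellNode:
    """One named cell of the invariant lineage.

    volume_fraction is the fraction of total embryo volume (the embryo
    cleaves reductively inside a constant-volume eggshell, so fractions of
    the two daughters sum to the parent's).  birth_time is minutes after
    first cleavage; cycle_duration is the cell-cycle length in minutes.
    """

    name: str
    parent: str | None
    stage: str
    founder: str
    volume_fraction: float
    birth_time: float
    cycle_duration: float


class LineageTree:
    """Named binary lineage tree with stage, volume and timing annotation."""

    def __init__(self, nodes: Iterable[CellNode], *, validate: bool = True):
        self.nodes: dict[str, CellNode] = {n.name: n for n in nodes}
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root cell, found {len(roots)}")
        self.root = roots[0].name
        self._children: dict[str, list[str]] = {name: [] for name in self.nodes}
        for n in self.nodes.values():
            if n.parent is not None:
                if n.parent not in self.nodes:
                    raise ValueError(f"cell {n.name!r} has unknown parent {n.parent!r}")
                self._children[n.parent].append(n.name)
        for kids in self._children.values():
            kids.sort()
        if validate:
            self.validate()

    # -- structure -------------------------------------------------------

    def __contains__(self, cell: str) -> bool:
        return cell in self.nodes

    def __getitem__(self, cell: str) -> CellNode:
        try:
            return self.nodes[cell]
        except KeyError:
            raise KeyError(f"unknown cell name: {cell!r}") from None

    def parent_of(self, cell: str) -> str | None:
        """Parent cell name, or None for the root (P0)."""
        return self[cell].parent

    def children_of(self, cell: str) -> list[str]:
        self[cell]  # raise on unknown name
        return list(self._children[cell])

    def descendants_of(self, cell: str) -> list[str]:
        """All strict descendants, preorder, deterministic."""
        out: list[str] = []
        stack = list(reversed(self.children_of(cell)))
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(reversed(self._children[c]))
        return out

    def cells_at_stage(self, stage: str) -> list[str]:
        """All cells annotated with the given stage label, sorted by name."""
        if stage not in {n.stage for n in self.nodes.values()}:
            raise ValueError(f"unknown stage label: {stage!r}")
        return sorted(n.name for n in self.nodes.values() if n.stage == stage)

    def edges(self) -> list[tuple[str, str]]:
        """All (parent, daughter) edges, sorted by daughter name."""
        return sorted(
            (n.parent, n.name) for n in self.nodes.values() if n.parent is not None
        )

    def cycle_duration(self, cell: str) -> float:
        return self[cell].cycle_duration

    def volume_fraction(self, cell: str) -> float:
        return self[cell].volume_fraction

    # -- invariants ------------------------------------------------------

    def validate(self, tol: float = 1e-9) -> None:
        """Check volume conservation, timing additivity and binary topology."""
        root = self.nodes[self.root]
        if abs(root.volume_fraction - 1.0) > tol:
            raise ValueError("root volume fraction must be 1.0")
        for name, kids in self._children.items():
            node = self.nodes[name]
            if len(kids) not in (0, 2):
                raise ValueError(f"cell {name!r} has {len(kids)} daughters; tree must be binary")
            if kids:
                vsum = sum(self.nodes[k].volume_fraction for k in kids)
                if abs(vsum - node.volume_fraction) > tol:
                    raise ValueError(
                        f"daughter volumes of {name!r} sum to {vsum}, "
                        f"parent is {node.volume_fraction}"
                    )
                division = node.birth_time + node.cycle_duration
                for k in kids:
                    if abs(self.nodes[k].birth_time - division) > tol:
                        raise ValueError(
                            f"{k!r} birth time {self.nodes[k].birth_time} != "
                            f"division time of {name!r} ({division})"
                        )
        for n in self.nodes.values():
            if n.name != self.root and n.cycle_duration <= 0:
                raise ValueError(f"non-root cell {n.name!r} needs a positive cycle duration")


@dataclass
class TimingTable:
    """Nuclei-count → time intervals for staging fixed embryos.

    Each row gives the interval [start, end) during which the embryo holds
    exactly `nuclei_count` nuclei.  Counts absent from the table (passed
    through instantaneously by simultaneous divisions) resolve to the
    transition time between the flanking tabulated counts.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        t = self.table.sort_values("nuclei_count").reset_index(drop=True)
        if (t["end_min"] < t["start_min"]).any():
            raise ValueError("timing table has end < start")
        if not t["start_min"].is_monotonic_increasing:
            raise ValueError("timing table start times must be non-decreasing in nuclei count")
        self.table = t

    @property
    def max_count(self) -> int:
        return int(self.table["nuclei_count"].max())

    def nuclei_to_time(self, nuclei_count: int) -> float:
        """Midpoint of the interval with that nuclei count, in minutes.

        One nucleus is the time origin (first cleavage) by convention.
        """
        if nuclei_count < 1:
            raise ValueError("nuclei count must be >= 1")
        if nuclei_count > self.max_count:
            raise ValueError(
                f"nuclei count {nuclei_count} above table range "
                f"[1, {self.max_count}]"
            )
        t = self.table
        row = t[t["nuclei_count"] == nuclei_count]
        if len(row):
            return float((row["start_min"].iloc[0] + row["end_min"].iloc[0]) / 2.0)
        # untabulated count: the embryo passes through it at the division
        # event between the flanking rows
        above = t[t["nuclei_count"] > nuclei_count]
        return float(above["start_min"].iloc[0])

    def time_to_nuclei(self, time_min: float) -> int:
        """Nuclei count of an embryo at the given time (inverse lookup)."""
        t = self.table
        inside = t[(t["start_min"] <= time_min) & (time_min < t["end_min"])]
        if len(inside):
            return int(inside["nuclei_count"].iloc[-1])
        if time_min >= t["end_min"].iloc[-1]:
            return int(t["nuclei_count"].iloc[-1])
        if time_min <= 0:
            return 1
        # time falls exactly on a division event: report the post-division count
        after = t[t["start_min"] <= time_min]
        return int(after["nuclei_count"].iloc[-1])


# -- I/O ----------------------------------------------------------------


def load_lineage(path: str | Path) -> LineageTree:
    """Read a lineage TSV (cell, parent, stage, founder, volume_fraction,
    birth_time_min, cycle_min); '-' or empty parent marks the root."""
    df = pd.read_csv(path, sep="\t", dtype={"cell": str, "parent": str})
    required = {"cell", "parent", "stage", "founder",
                "volume_fraction", "birth_time_min", "cycle_min"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lineage TSV missing columns: {sorted(missing)}")
    nodes = []
    for row in df.itertuples(index=False):
        parent = None if (pd.isna(row.parent) or row.parent in ("-", "")) else row.parent
        nodes.append(
            CellNode(
                name=row.cell,
                parent=parent,
                stage=row.stage,
                founder=row.founder,
                volume_fraction=float(row.volume_fraction),
                birth_time=float(row.birth_time_min),
                cycle_duration=float(row.cycle_min),
            )
        )
    return LineageTree(nodes)


def load_timing(path: str | Path) -> TimingTable:
    df = pd.read_csv(path, sep="\t")
    required = {"nuclei_count", "start_min", "end_min"}
    if required - set(df.columns):
        raise ValueError(f"timing TSV must have columns {sorted(required)}")
    return TimingTable(df)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("lineage_rates").joinpath("data", name)))


def default_tree() -> LineageTree:
    """Bundled lineage through the 16-cell cohort (24-cell embryo)."""
    return load_lineage(_data_path("lineage_default.tsv"))


def default_timing() -> TimingTable:
    """Bundled nuclei-count timing table derived from the default lineage."""
    return load_timing(_data_path("timing_default.tsv"))
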