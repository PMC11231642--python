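"""Navigation maps, tags, distance tables and module banks.

A navigation map is a small 3-D grid of cells, the architecture's unit of
representation (a functional model of a neocortical minicolumn).  Cells hold
sensory feature labels, links to other maps, and operational *tags* that the
planning primitives read and write: an action word (e.g. ``"go"``), the
``<"all">`` marker placed on every destination cell, the ``<"back">`` marker
on the cell to return to, and integer visit-order tags ``<0>, <1>, <2>, ...``
assigned by the planner.

A :class:`ModuleBank` holds one "module A" map (the sensory scene) plus an
ordered bank of "module B" slots.  Slot ``n = 0`` is reserved for a safety
copy of the instruction and is never overwritten; slot ``n = 1`` runs the
deterministic nearest-neighbour plan; slots ``n >= 2`` run randomized
variants.
"""

from __future__ import annotations

import copy as _copylib
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Iterator

import numpy as np

from .errors import (
    BoundsError,
    DuplicateCoordinateError,
    ValidationError,
)

Coord = tuple[int, int, int]

#: Grid dimensions used throughout: a 6x6 single-layer grid (z is always 0).
DEFAULT_DIMS: Coord = (6, 6, 1)


class TagKind(str, Enum):
    ACTION_WORD = "action-word"
    ALL_MARKER = "all-marker"
    BACK_MARKER = "back-marker"
    VISIT_ORDER = "visit-order"


@dataclass(frozen=True)
class Tag:
    """A single operational tag on a cell.

    Visit-order tags carry a non-negative integer (the position in the
    planned route, 0 being the start/return cell); all other kinds carry
    text.
    """

    kind: TagKind
    value: str | int

    def __post_init__(self) -> None:
        if self.kind is TagKind.VISIT_ORDER:
            if not isinstance(self.value, int) or isinstance(self.value, bool) or self.value < 0:
                raise ValidationError(
                    f"visit-order tag value must be a non-negative integer, got {self.value!r}"
                )
        elif not isinstance(self.value, str):
            raise ValidationError(f"{self.kind.value} tag value must be text, got {self.value!r}")


@dataclass
class Cell:
    """One grid cell: feature labels, links to other maps, tags, start flag."""

    features: set[str] = field(default_factory=set)
    links: list[tuple[int, Coord]] = field(default_factory=list)
    tags: list[Tag] = field(default_factory=list)
    is_start: bool = False

    def add_tag(self, tag: Tag) -> None:
        """Append *tag*, keeping tags unique per cell (idempotent)."""
        if tag not in self.tags:
            self.tags.append(tag)

    def has_tag(self, kind: TagKind, value: str | int | None = None) -> bool:
        return any(t.kind is kind and (value is None or t.value == value) for t in self.tags)

    def drop_tags(self, kind: TagKind) -> None:
        self.tags = [t for t in self.tags if t.kind is not kind]

    def visit_order(self) -> int | None:
        for t in self.tags:
            if t.kind is TagKind.VISIT_ORDER:
                return int(t.value)
        return None


@dataclass
class NavigationMap:
    """A sparse grid of :class:`Cell` objects within ``dims``."""

    dims: Coord = DEFAULT_DIMS
    cells: dict[Coord, Cell] = field(default_factory=dict)
    map_id: int = 0

    def __post_init__(self) -> None:
        for coord in self.cells:
            self._check_bounds(coord)
        starts = [c for c, cell in self.cells.items() if cell.is_start]
        if len(starts) > 1:
            raise ValidationError(f"at most one start marker allowed, found {len(starts)}")

    def _check_bounds(self, coord: Coord) -> None:
        if len(coord) != 3 or any(not (0 <= c < d) for c, d in zip(coord, self.dims)):
            raise BoundsError(f"coordinate {coord} outside dims {self.dims}")

    def cell(self, coord: Coord) -> Cell:
        """Return the cell at *coord*, creating an empty one if absent."""
        self._check_bounds(coord)
        return self.cells.setdefault(coord, Cell())

    def start_coord(self) -> Coord | None:
        for coord, cell in sorted(self.cells.items()):
            if cell.is_start:
                return coord
        return None

    def object_coords(self) -> list[Coord]:
        """Coordinates of cells carrying sensory features, row-major order."""
        return sorted(c for c, cell in self.cells.items() if cell.features)

    def tagged_coords(self, kind: TagKind, value: str | int | None = None) -> list[Coord]:
        return sorted(c for c, cell in self.cells.items() if cell.has_tag(kind, value))

    # -- JSON serialization ------------------------------------------------
    # Schema: {"dims": [x,y,z], "map_id": int, "cells": {"x,y,z": {
    #   "features": [...], "links": [[map_id, [x,y,z]], ...],
    #   "tags": [{"kind": ..., "value": ...}], "is_start": bool}}}

    def to_dict(self) -> dict[str, Any]:
        return {
            "dims": list(self.dims),
            "map_id": self.map_id,
            "cells": {
                ",".join(map(str, coord)): {
                    "features": sorted(cell.features),
                    "links": [[mid, list(c)] for mid, c in cell.links],
                    "tags": [{"kind": t.kind.value, "value": t.value} for t in cell.tags],
                    "is_start": cell.is_start,
                }
                for coord, cell in sorted(self.cells.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "NavigationMap":
        cells: dict[Coord, Cell] = {}
        for key, cd in d.get("cells", {}).items():
            coord = tuple(int(v) for v in key.split(","))
            cells[coord] = Cell(  # type: ignore[index]
                features=set(cd.get("features", [])),
                links=[(int(mid), tuple(c)) for mid, c in cd.get("links", [])],
                tags=[Tag(TagKind(t["kind"]), t["value"]) for t in cd.get("tags", [])],
                is_start=bool(cd.get("is_start", False)),
            )
        return cls(dims=tuple(d["dims"]), cells=cells, map_id=int(d.get("map_id", 0)))

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "NavigationMap":
        return cls.from_dict(json.loads(text))


def make_map(
    dims: Coord = DEFAULT_DIMS,
    objects: Iterable[tuple[Coord, Iterable[str]]] = (),
    start: Coord | None = None,
) -> NavigationMap:
    """Build an untagged scene map: one featured cell per object plus a start marker.

    Raises
    ------
    BoundsError
        if any coordinate lies outside *dims*.
    DuplicateCoordinateError
        if two objects share a coordinate, or the start coincides with one.
    """
    m = NavigationMap(dims=dims)
    for coord, labels in objects:
        coord = tuple(coord)  # type: ignore[assignment]
        m._check_bounds(coord)
        if coord in m.cells:
            raise DuplicateCoordinateError(f"duplicate object coordinate {coord}")
        m.cells[coord] = Cell(features=set(labels))
    if start is not None:
        start = tuple(start)  # type: ignore[assignment]
        m._check_bounds(start)
        if start in m.cells:
            raise DuplicateCoordinateError(f"start {start} coincides with an object cell")
        m.cells[start] = Cell(is_start=True)
    return m


def copy_map(m: NavigationMap, strip_action_words: bool = False) -> NavigationMap:
    """Deep, independent copy of *m*; optionally drop action-word tags.

    Stripping action words is what the broadcast step does when the scene map
    is copied into the working bank slots: only the tagged destination cells
    are left for the planner.
    """
    out = _copylib.deepcopy(m)
    if strip_action_words:
        for cell in out.cells.values():
            cell.drop_tags(TagKind.ACTION_WORD)
    return out


@dataclass
class DistanceTable:
    """Symmetric pairwise distances between labelled locations.

    ``labels`` fixes the index order (index 0 is conventionally the home /
    start location for city tables; for scene maps the labels are cell
    coordinates).  Units are recorded only as an annotation -- the planner
    deliberately disregards them.
    """

    labels: list[Any]
    d: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError(f"matrix shape {self.d.shape} does not match {n} labels")
        if n != len(set(map(self._key, self.labels))):
            raise ValidationError("duplicate labels")
        if not np.array_equal(self.d, self.d.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValidationError("distances must be non-negative")
        self._index = {self._key(lab): i for i, lab in enumerate(self.labels)}

    @staticmethod
    def _key(label: Any) -> Any:
        return tuple(label) if isinstance(label, (list, tuple)) else label

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: Any) -> int:
        return self._index[self._key(label)]

    def __contains__(self, label: Any) -> bool:
        return self._key(label) in self._index

    def distance(self, a: Any, b: Any) -> float:
        return float(self.d[self.index(a), self.index(b)])

    @classmethod
    def from_pairs(
        cls,
        labels: Iterable[Any],
        pairs: Iterable[tuple[Any, Any, float]],
        units: str = "",
    ) -> "DistanceTable":
        """Build a table from (a, b, distance) entries; missing pairs are an error."""
        labels = list(labels)
        n = len(labels)
        idx = {cls._key(lab): i for i, lab in enumerate(labels)}
        d = np.zeros((n, n))
        seen = np.eye(n, dtype=bool)
        for a, b, dist in pairs:
            i, j = idx[cls._key(a)], idx[cls._key(b)]
            d[i, j] = d[j, i] = dist
            seen[i, j] = seen[j, i] = True
        if not seen.all():
            missing = np.argwhere(~seen)
            i, j = missing[0]
            raise ValidationError(f"missing distance between {labels[i]} and {labels[j]}")
        return cls(labels=labels, d=d, units=units)


@dataclass
class PlanConfig:
    """How a single module constructs its tour.

    ``weight`` is the exponent sharpening the rank-based selection
    probabilities; any weight of 10 or more collapses to the deterministic
    nearest-neighbour rule (the architecture's convention for switching the
    randomness off).
    """

    mode: str = "position-weighted"
    weight: int = 4
    seed: int = 0

    MODES = ("deterministic-nn", "position-weighted", "value-weighted")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise ValidationError(f"mode must be one of {self.MODES}, got {self.mode!r}")
        if not isinstance(self.weight, int) or self.weight < 1:
            raise ValidationError("weight must be a positive integer")


class ModuleBank:
    """One module-A scene map plus ``B`` module-B bank slots.

    Slot ``n = 0`` is reserved (holds the instruction safety copy and the
    TempMap that tracks the running-minimum tour); each slot nominally has
    ``K`` TempMap areas, but only the reserved slot's running minimum is
    functionally used here.
    """

    def __init__(self, module_a: NavigationMap, size: int = 1024, tempmaps_per_module: int = 1024):
        if size < 2:
            raise ValidationError("bank needs at least 2 module-B slots (one reserved, one working)")
        self.module_a = module_a
        self.size = size
        self.tempmaps_per_module = tempmaps_per_module
        self.slots: list[NavigationMap | None] = [None] * size
        self.reserved: set[int] = {0}
        #: running minimum held in the reserved slot's TempMap: (module index, total)
        self.temp_best: tuple[int, float] | None = None

    def __len__(self) -> int:
        return self.size

    def working_indices(self) -> Iterator[int]:
        """Bank indices that planning may overwrite (everything not reserved)."""
        return (n for n in range(self.size) if n not in self.reserved)

    def clear_tempmaps(self) -> None:
        """Reset per-episode temporary state (default policy between episodes)."""
        self.temp_best = None
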