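"""Readers, writers, fixture generation, and built-in datasets.

Distance matrices travel as plain CSV/TSV: a square numeric matrix with an
optional first header row of labels; row/column order defines the location
indices and index 0 is the home (start) city.  Scene files are JSON
(``{"objects": [{"coord", "labels"}], "start", "distances": [{"a","b","d"}]}``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .maps import DistanceTable, NavigationMap, make_map


@dataclass
class FixtureSpec:
    """Recipe for a reproducible random symmetric integer distance matrix."""

    n_locations: int = 13
    distance_range: tuple[int, int] = (50, 2000)
    metric_repair: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 3:
            raise ValidationError("need at least 3 locations")
        low, high = self.distance_range
        if low < 1 or high < low:
            raise ValidationError("distance range must satisfy 1 <= low <= high")


def generate_fixture(spec: FixtureSpec) -> DistanceTable:
    """Seeded symmetric integer matrix; optionally repaired to satisfy the
    triangle inequality by taking the all-pairs shortest-path closure."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_locations
    low, high = spec.distance_range
    d = rng.integers(low, high + 1, size=(n, n)).astype(float)
    d = np.triu(d, k=1)
    d = d + d.T
    if spec.metric_repair:
        for k in range(n):  # Floyd-Warshall closure keeps values integral
            d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return DistanceTable(labels=list(range(n)), d=d)


def read_distance_matrix(path: str | Path, fmt: str | None = None) -> DistanceTable:
    """Read a square symmetric matrix from CSV/TSV, header row optional."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    sep = "\t" if fmt == "tsv" else ","
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str).values
    if raw.shape[0] == 0:
        raise FormatError(f"{path}: empty file")

    n_rows, n_cols = raw.shape
    if n_rows == n_cols + 1:  # first row is the label header
        labels: list[Any] = [str(v) for v in raw[0]]
        body = raw[1:]
    elif n_rows == n_cols:
        labels = list(range(n_cols))
        body = raw
    else:
        raise FormatError(f"{path}: matrix is {n_rows}x{n_cols}, not square")
    try:
        d = body.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from exc
    return DistanceTable(labels=labels, d=d)


def write_distance_matrix(dt: DistanceTable, path: str | Path, fmt: str | None = None) -> None:
    """Write a table back as CSV/TSV with a label header row; round-trip exact."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    sep = "\t" if fmt == "tsv" else ","
    with open(path, "w") as fh:
        fh.write(sep.join(str(lab) for lab in dt.labels) + "\n")
        for row in dt.d:
            fh.write(sep.join(_fmt_num(v) for v in row) + "\n")


def _fmt_num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_scene(path: str | Path) -> tuple[NavigationMap, DistanceTable]:
    """Load a scene JSON file into a map and its pairwise distance table."""
    with open(path) as fh:
        doc = json.load(fh)
    return scene_from_dict(doc)


def scene_from_dict(doc: dict[str, Any]) -> tuple[NavigationMap, DistanceTable]:
    objects = [(tuple(o["coord"]), o["labels"]) for o in doc["objects"]]
    start = tuple(doc["start"])
    dims = tuple(doc.get("dims", (6, 6, 1)))
    m = make_map(dims=dims, objects=objects, start=start)
    labels = sorted([c for c, _ in objects] + [start])
    pairs = [(tuple(e["a"]), tuple(e["b"]), float(e["d"])) for e in doc.get("distances", [])]
    dt = DistanceTable.from_pairs(labels, pairs, units=doc.get("units", ""))
    return m, dt


def builtin_toy_scene() -> tuple[NavigationMap, DistanceTable]:
    """The worked desk example: three objects on a 6x6 grid, distances in cm.

    Start "X" at (0,0,0); white sphere (2,2,0); black sphere (3,0,0); white
    block (4,2,0).  Deterministic nearest neighbour yields the 109 cm tour;
    the best possible tour is 100 cm and the worst 119 cm.
    """
    doc = {
        "objects": [
            {"coord": [2, 2, 0], "labels": ["sphere", "white"]},
            {"coord": [3, 0, 0], "labels": ["sphere", "black"]},
            {"coord": [4, 2, 0], "labels": ["block", "white"]},
        ],
        "start": [0, 0, 0],
        "units": "cm",
        "distances": [
            {"a": [0, 0, 0], "b": [2, 2, 0], "d": 25},
            {"a": [0, 0, 0], "b": [3, 0, 0], "d": 31},
            {"a": [0, 0, 0], "b": [4, 2, 0], "d": 42},
            {"a": [2, 2, 0], "b": [3, 0, 0], "d": 22},
            {"a": [2, 2, 0], "b": [4, 2, 0], "d": 24},
            {"a": [3, 0, 0], "b": [4, 2, 0], "d": 20},
        ],
    }
    return scene_from_dict(doc)


# The classic 13-city intercity road-mileage example distributed with Google
# OR-Tools (city 0 is the home city).  Nearest neighbour from city 0 gives a
# 8,131-mile tour; the exact optimum is 7,293 miles.
_CITIES_13 = [
    [0, 2451, 713, 1018, 1631, 1374, 2408, 213, 2571, 875, 1420, 2145, 1972],
    [2451, 0, 1745, 1524, 831, 1240, 959, 2596, 403, 1589, 1374, 357, 579],
    [713, 1745, 0, 355, 920, 803, 1737, 851, 1858, 262, 940, 1453, 1260],
    [1018, 1524, 355, 0, 700, 862, 1395, 1123, 1584, 466, 1056, 1280, 987],
    [1631, 831, 920, 700, 0, 663, 1021, 1769, 949, 796, 879, 586, 371],
    [1374, 1240, 803, 862, 663, 0, 1681, 1551, 1765, 547, 225, 887, 999],
    [2408, 959, 1737, 1395, 1021, 1681, 0, 2493, 678, 1724, 1891, 1114, 701],
    [213, 2596, 851, 1123, 1769, 1551, 2493, 0, 2699, 1038, 1605, 2300, 2099],
    [2571, 403, 1858, 1584, 949, 1765, 678, 2699, 0, 1744, 1645, 653, 600],
    [875, 1589, 262, 466, 796, 547, 1724, 1038, 1744, 0, 679, 1272, 1162],
    [1420, 1374, 940, 1056, 879, 225, 1891, 1605, 1645, 679, 0, 1017, 1200],
    [2145, 357, 1453, 1280, 586, 887, 1114, 2300, 653, 1272, 1017, 0, 504],
    [1972, 579, 1260, 987, 371, 999, 701, 2099, 600, 1162, 1200, 504, 0],
]


def builtin_cities() -> DistanceTable:
    """The built-in 13-city miles table used by the comparative study."""
    return DistanceTable(labels=list(range(13)), d=np.array(_CITIES_13, dtype=float), units="miles")
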