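"""The ``small_plan()`` primitive: randomized nearest-neighbour tour construction.

Each planning module builds a tour greedily from the start cell over all
tagged destinations.  At every decision point the remaining destinations are
re-sorted by distance from the current location and one is drawn according to
the module's selection rule:

``deterministic-nn``
    always the nearest (classic nearest-neighbour construction);

``position-weighted``
    probability proportional to ``inverse_rank ** weight`` -- depends only on
    each candidate's *position* in the sorted list, never on the distance
    magnitudes.  With the default ``weight = 4`` and five candidates the
    distribution is [64, 26, 8, 2, 0.1]%.  Any ``weight >= 10`` collapses to
    the deterministic rule;

``value-weighted``
    probability from normalized reciprocals of each candidate's distance
    difference from the minimum (differences below 1 count as 1), so the
    actual distance values matter.

A bank runs one deterministic module (slot ``n = 1``) plus many randomized
ones and keeps the plan with the smallest total, which cannot be worse than
plain nearest neighbour.  Probability vectors are plain ``numpy`` arrays
summing to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Any, Sequence

import numpy as np

from .errors import CoverageError, StateError, ValidationError
from .maps import (
    DistanceTable,
    ModuleBank,
    NavigationMap,
    PlanConfig,
    Tag,
    TagKind,
)

#: Weights at or above this value make selection deterministic (nearest only).
DETERMINISTIC_WEIGHT_CUTOFF = 10

#: Default randomness exponent for position-weighted selection.
DEFAULT_WEIGHT = 4

#: Nominal weight used by the deterministic nearest-neighbour rule.
DETERMINISTIC_WEIGHT = 30

MODE_CODES = {"deterministic-nn": 0, "position-weighted": 1, "value-weighted": 2}


@dataclass
class DestinationList:
    """Remaining candidate destinations sorted ascending by distance.

    Rank (``position``) is 1-based: the nearest candidate has position 1 and
    inverse position ``len(list)``.  Ties are broken by the candidate's index
    in the distance table (row-major cell order for scene maps), which keeps
    the deterministic branch fully reproducible.
    """

    ids: list[Any]
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.ids) == 0:
            raise ValidationError("destination list must not be empty")
        if np.any(np.diff(self.distances) < 0):
            raise ValidationError("distances must be sorted ascending")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self) + 1)

    @property
    def inverse_positions(self) -> np.ndarray:
        return np.arange(len(self), 0, -1)


def sort_destinations(current: Any, candidates: Sequence[Any], dt: DistanceTable) -> DestinationList:
    """Sort *candidates* by distance from *current*, ties by table index."""
    try:
        rows = [(dt.distance(current, c), dt.index(c), c) for c in candidates]
    except KeyError as exc:
        raise CoverageError(f"distance table does not cover location {exc}") from exc
    rows.sort(key=lambda r: (r[0], r[1]))
    return DestinationList(ids=[c for _, _, c in rows], distances=[d for d, _, _ in rows])


def _rank_probabilities_direct(length: int, weight: int) -> np.ndarray:
    """Exact position-weighted probabilities for a sorted list of *length*.

    Uses arbitrary-precision integer arithmetic for the powers, so large
    weights cannot overflow; at or beyond the cutoff the vector degenerates
    to [1, 0, ..., 0] (pure nearest neighbour) and no large powers are needed.
    """
    if length < 1:
        raise ValidationError("destination list must not be empty")
    if not isinstance(weight, (int, np.integer)) or weight < 1:
        raise ValidationError("weight must be a positive integer")
    if weight >= DETERMINISTIC_WEIGHT_CUTOFF:
        p = np.zeros(length)
        p[0] = 1.0
        return p
    powers = [int(i) ** int(weight) for i in range(length, 0, -1)]
    total = sum(powers)
    return np.array([pw / total for pw in powers])


@lru_cache(maxsize=None)
def _rank_probabilities_cached(length: int, weight: int) -> np.ndarray:
    p = _rank_probabilities_direct(length, weight)
    p.setflags(write=False)
    return p


def rank_probabilities(length: int, weight: int, use_cache: bool = True) -> np.ndarray:
    """Position-weighted probabilities keyed only by (list length, weight).

    The cached path models the architecture's stored probability
    distributions; it agrees exactly with the direct computation.
    """
    if use_cache:
        return _rank_probabilities_cached(int(length), int(weight))
    return _rank_probabilities_direct(int(length), int(weight))


def position_weighted_probabilities(dl: DestinationList | int, weight: int) -> np.ndarray:
    """Selection probabilities by rank: ``inverse_position**weight``, normalized.

    Depends only on the number of candidates and the weight -- scaling every
    distance leaves the vector unchanged.
    """
    length = dl if isinstance(dl, (int, np.integer)) else len(dl)
    return rank_probabilities(length, weight)


def value_weighted_probabilities(dl: DestinationList | Sequence[float]) -> np.ndarray:
    """Selection probabilities from distance differences.

    Each candidate gets weight ``1 / max(1, distance - min_distance)`` (the
    nominal value 1 applies to differences below 1, including the minimum
    itself), normalized to sum to 1.  Equal distances therefore give a
    uniform vector.
    """
    d = dl.distances if isinstance(dl, DestinationList) else np.asarray(dl, dtype=float)
    if d.size == 0:
        raise ValidationError("destination list must not be empty")
    w = 1.0 / np.maximum(1.0, d - d.min())
    return w / w.sum()


def select_next(p: np.ndarray, draw: float) -> int:
    """Map a uniform draw in [0, 1) through the cumulative distribution.

    Returns the 0-based index of the first candidate whose cumulative
    probability exceeds *draw* (index 0 is the nearest candidate).
    """
    if not (0.0 <= draw < 1.0):
        raise ValidationError(f"draw must lie in [0, 1), got {draw}")
    cum = np.cumsum(np.asarray(p, dtype=float))
    return int(min(np.count_nonzero(cum <= draw), len(cum) - 1))


@dataclass
class PlanResult:
    """One module's constructed tour: destinations in visit order, then home."""

    module_index: int
    visit_order: list[Any]
    leg_distances: list[float]
    total_distance: float
    tag_assignment: dict[Any, int] = field(default_factory=dict)


@dataclass
class BankResult:
    """Per-module totals plus the winning plan (ties go to the lowest index)."""

    per_module_totals: dict[int, float]
    best_index: int
    best_plan: PlanResult


def _plan_locations(m: NavigationMap) -> tuple[Any, list[Any]]:
    start_tagged = m.tagged_coords(TagKind.BACK_MARKER)
    if not start_tagged:
        raise ValidationError("map has no <'back'>-tagged start cell")
    return start_tagged[0], m.tagged_coords(TagKind.ALL_MARKER)


def small_plan(
    m: NavigationMap,
    dt: DistanceTable,
    cfg: PlanConfig,
    rng: np.random.Generator | None = None,
    module_index: int = 1,
) -> PlanResult:
    """Construct one greedy tour on a tagged map and re-tag it with the order.

    Starting from the ``<"back">`` cell, repeatedly sorts the unvisited
    ``<"all">`` cells by distance, draws the next one according to
    ``cfg.mode``, and finally returns home.  Destination cells are re-tagged
    ``<1>, <2>, ...`` in visit order and the start cell ``<0>``.  One uniform
    variate is consumed per decision step regardless of mode, so a given
    generator state yields the same tour whether planned here or by the
    vectorized :func:`construct_tours` engine.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    start, destinations = _plan_locations(m)
    for loc in [start, *destinations]:
        if loc not in dt:
            raise CoverageError(f"distance table does not cover {loc}")

    weight = cfg.weight
    deterministic = cfg.mode == "deterministic-nn" or weight >= DETERMINISTIC_WEIGHT_CUTOFF
    current = start
    remaining = list(destinations)
    order: list[Any] = []
    legs: list[float] = []
    while remaining:
        dl = sort_destinations(current, remaining, dt)
        draw = float(rng.random())
        if deterministic:
            idx = 0
        elif cfg.mode == "position-weighted":
            idx = select_next(rank_probabilities(len(dl), weight), draw)
        else:
            idx = select_next(value_weighted_probabilities(dl), draw)
        nxt = dl.ids[idx]
        legs.append(float(dl.distances[idx]))
        order.append(nxt)
        remaining.remove(nxt)
        current = nxt
    legs.append(dt.distance(current, start) if order else 0.0)

    tags = {loc: i + 1 for i, loc in enumerate(order)}
    tags[start] = 0
    for loc, k in tags.items():
        cell = m.cells[loc]
        cell.drop_tags(TagKind.ALL_MARKER)
        cell.drop_tags(TagKind.BACK_MARKER)
        cell.drop_tags(TagKind.VISIT_ORDER)
        cell.add_tag(Tag(TagKind.VISIT_ORDER, k))
    return PlanResult(
        module_index=module_index,
        visit_order=[*order, start],
        leg_distances=legs,
        total_distance=float(sum(legs)),
        tag_assignment=tags,
    )


def run_bank(
    bank: ModuleBank,
    dt: DistanceTable,
    weight: int = DEFAULT_WEIGHT,
    rng: np.random.Generator | None = None,
    mode: str = "position-weighted",
) -> BankResult:
    """Plan in every working bank slot and select the shortest tour.

    Slot ``n = 1`` always runs the deterministic nearest-neighbour rule;
    higher slots run *mode* at the given *weight*.  The reserved slot's
    TempMap tracks the running minimum as modules finish; the winner (lowest
    index on ties) supplies the move sequence.  The bank's best can never
    exceed the deterministic slot's total, since that slot competes too.
    """
    working = list(bank.working_indices())
    maps = [bank.slots[n] for n in working]
    if any(m is None or not m.tagged_coords(TagKind.ALL_MARKER) for m in maps):
        raise StateError("bank has not been broadcast with a tagged map")
    if rng is None:
        rng = np.random.default_rng(0)
    bank.clear_tempmaps()

    child_rngs = rng.spawn(len(working))
    totals: dict[int, float] = {}
    plans: dict[int, PlanResult] = {}
    for n, child in zip(working, child_rngs):
        cfg = (
            PlanConfig(mode="deterministic-nn", weight=DETERMINISTIC_WEIGHT)
            if n == 1
            else PlanConfig(mode=mode, weight=weight)
        )
        pr = small_plan(bank.slots[n], dt, cfg, rng=child, module_index=n)
        totals[n] = pr.total_distance
        plans[n] = pr
        if bank.temp_best is None or pr.total_distance < bank.temp_best[1]:
            bank.temp_best = (n, pr.total_distance)

    best_index = min(totals, key=lambda n: (totals[n], n))
    return BankResult(per_module_totals=totals, best_index=best_index, best_plan=plans[best_index])


def move_sequence(pr: PlanResult) -> list[tuple[Any, int]]:
    """Locations with their visit-order tags, ascending, ending at ``<0>`` home."""
    ordered = sorted(
        ((loc, k) for loc, k in pr.tag_assignment.items() if k > 0), key=lambda t: t[1]
    )
    home = [(loc, 0) for loc, k in pr.tag_assignment.items() if k == 0]
    return ordered + home


def construct_tours(
    d: np.ndarray,
    start: int,
    modes: np.ndarray,
    weight: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tour construction for many modules at once.

    *d* is a full symmetric distance matrix, *modes* an integer vector (one
    entry per module, see :data:`MODE_CODES`).  All modules advance in
    lockstep: at each decision step one uniform variate per module is drawn
    (in module order), exactly mirroring the per-step draw of
    :func:`small_plan`, so a single-module call reproduces ``small_plan`` on
    the same generator state draw for draw.

    Returns ``(totals, orders)`` where ``orders[m]`` lists the city indices
    module ``m`` visits (the closing leg back to *start* is included in the
    total).
    """
    d = np.asarray(d, dtype=float)
    modes = np.asarray(modes, dtype=int)
    n = d.shape[0]
    m_count = modes.size
    current = np.full(m_count, start)
    visited = np.zeros((m_count, n), dtype=bool)
    visited[:, start] = True
    totals = np.zeros(m_count)
    orders = np.empty((m_count, n - 1), dtype=int)

    all_deterministic = weight >= DETERMINISTIC_WEIGHT_CUTOFF
    for step in range(n - 1):
        k = n - 1 - step
        dist = np.where(visited, np.inf, d[current])
        # stable argsort breaks distance ties by lowest city index
        rank_to_city = np.argsort(dist, axis=1, kind="stable")[:, :k]
        dist_sorted = np.take_along_axis(dist, rank_to_city, axis=1)
        draws = rng.random(m_count)
        pick = np.zeros(m_count, dtype=int)
        if not all_deterministic:
            pos = modes == MODE_CODES["position-weighted"]
            if pos.any():
                cum = np.cumsum(rank_probabilities(k, weight))
                pick[pos] = np.minimum(np.count_nonzero(cum <= draws[pos, None], axis=1), k - 1)
            val = modes == MODE_CODES["value-weighted"]
            if val.any():
                w = 1.0 / np.maximum(1.0, dist_sorted[val] - dist_sorted[val, :1])
                cum = np.cumsum(w, axis=1)
                cum /= cum[:, -1:]
                pick[val] = np.minimum(np.count_nonzero(cum <= draws[val, None], axis=1), k - 1)
        nxt = np.take_along_axis(rank_to_city, pick[:, None], axis=1)[:, 0]
        totals += np.take_along_axis(dist_sorted, pick[:, None], axis=1)[:, 0]
        orders[:, step] = nxt
        visited[np.arange(m_count), nxt] = True
        current = nxt
    totals += d[current, start]
    return totals, orders
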