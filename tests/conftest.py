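"""Shared fixtures and the independent exhaustive tour enumerator."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

import navbank as nb


def enumerate_tours(d: np.ndarray, start: int = 0) -> list[float]:
    """All distinct closed-tour totals by brute enumeration.

    Walks every permutation of the non-start locations, skipping each
    cycle's reversed duplicate, so exactly (n-1)!/2 totals come back (one
    per undirected route).  Deliberately naive: this is the oracle the
    dynamic-programming solver is checked against.
    """
    n = d.shape[0]
    others = [i for i in range(n) if i != start]
    totals = []
    for perm in permutations(others):
        if perm[0] > perm[-1]:  # each cycle appears once per direction
            continue
        tot = d[start, perm[0]] + d[perm[-1], start]
        tot += sum(d[a, b] for a, b in zip(perm, perm[1:]))
        totals.append(float(tot))
    return totals


class ScriptedRng:
    """Stands in for a Generator, returning a fixed sequence of draws."""

    def __init__(self, draws):
        self._draws = list(draws)

    def random(self, size=None):
        if size is None:
            return self._draws.pop(0)
        return np.array([self._draws.pop(0) for _ in range(size)])


@pytest.fixture
def toy_scene():
    return nb.builtin_toy_scene()


@pytest.fixture
def cities():
    return nb.builtin_cities()


@pytest.fixture
def tagged_toy_map(toy_scene):
    """The toy scene map after instruction parsing (tags in place)."""
    m, dt = toy_scene
    bank = nb.ModuleBank(m, size=4)
    nb.load_instruction(nb.Instruction.from_text("go to all objects and go back"), bank)
    tagged, count = nb.parse_goto(bank)
    assert count == 3
    return tagged, dt


def make_toy_bank(size: int = 16):
    m, dt = nb.builtin_toy_scene()
    bank = nb.ModuleBank(m, size=size)
    nb.load_instruction(nb.Instruction.from_text("go to all objects and go back"), bank)
    nb.parse_goto(bank)
    nb.broadcast(bank)
    return bank, dt
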