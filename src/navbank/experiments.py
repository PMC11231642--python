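"""Comparative simulation study harness, exact-tour oracle, and statistics.

The study measures how much a bank of randomized nearest-neighbour planners
improves over a single module on a fixed symmetric travelling-salesperson
instance.  Four variants are compared, each over repeated independent runs
(100 by convention):

``single-nn``
    one module, deterministic nearest neighbour (no run-to-run variation);
``single-random``
    one module, position-weighted randomness;
``bank-position``
    a full bank: slot 1 deterministic, the rest position-weighted;
``bank-value``
    a full bank: slot 1 deterministic, the rest value-weighted.

Bank sizes follow the "1K/4K/16K" convention: ``B`` slots of which slot 0 is
reserved, leaving ``B - 1`` usable planners.  Each run reports the best
(shortest) total across its modules; runs are summarized by mean, sample
standard deviation, and the fraction of runs that hit the exact optimum
computed by :func:`brute_force_shortest`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import DegenerateSamplesError, SizeError, ValidationError
from .maps import DistanceTable
from .planner import (
    DEFAULT_WEIGHT,
    MODE_CODES,
    construct_tours,
)

VARIANTS = ("single-nn", "single-random", "bank-position", "bank-value")

#: Largest instance the dynamic-programming oracle will attempt (2^n states).
MAX_ORACLE_CITIES = 16


@dataclass
class ExperimentConfig:
    """One experiment arm: variant, bank size, weight, run count, master seed."""

    variant: str
    bank_size: int = 1024
    weight: int = DEFAULT_WEIGHT
    runs: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.runs < 1:
            raise ValidationError("runs must be >= 1")
        if self.variant.startswith("bank") and self.bank_size < 2:
            raise ValidationError("bank variants need bank_size >= 2")


@dataclass
class ExperimentResult:
    """Per-run best totals with summary statistics against the oracle optimum."""

    config: ExperimentConfig
    best_per_run: np.ndarray
    optimum: float
    mean: float = field(init=False)
    sd: float = field(init=False)
    sd_defined: bool = field(init=False)
    fraction_optimal: float = field(init=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.best_per_run, dtype=float)
        self.best_per_run = b
        self.mean = float(b.mean())
        self.sd_defined = b.size > 1
        self.sd = float(b.std(ddof=1)) if self.sd_defined else 0.0
        self.fraction_optimal = float(np.mean(np.abs(b - self.optimum) < 1e-9))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"run": np.arange(len(self.best_per_run)), "best_total": self.best_per_run}
        )

    def summary(self) -> dict[str, Any]:
        return {
            "variant": self.config.variant,
            "bank_size": self.config.bank_size,
            "weight": self.config.weight,
            "runs": self.config.runs,
            "mean": self.mean,
            "sd": self.sd,
            "sd_defined": self.sd_defined,
            "fraction_optimal": self.fraction_optimal,
            "optimum": self.optimum,
        }


def brute_force_shortest(dt: DistanceTable, start: Any = None) -> tuple[float, list[Any]]:
    """Exact shortest Hamiltonian cycle from *start* (Held-Karp dynamic program).

    The cycle is undirected -- each of the ``(n-1)!/2`` distinct routes can be
    walked in either direction -- so the DP's directed minimum equals the
    undirected optimum.  Instances beyond ``MAX_ORACLE_CITIES`` are refused.
    """
    n = len(dt)
    if n > MAX_ORACLE_CITIES:
        raise SizeError(f"exact solution limited to {MAX_ORACLE_CITIES} locations, got {n}")
    if n < 2:
        raise ValidationError("need at least 2 locations")
    s = 0 if start is None else dt.index(start)
    others = [i for i in range(n) if i != s]
    m = len(others)
    d = dt.d

    # cost[mask][j] = min cost from s through set `mask` of others, ending at others[j]
    inf = float("inf")
    cost = [[inf] * m for _ in range(1 << m)]
    parent = [[-1] * m for _ in range(1 << m)]
    for j in range(m):
        cost[1 << j][j] = d[s][others[j]]
    for mask in range(1, 1 << m):
        row = cost[mask]
        for j in range(m):
            cj = row[j]
            if cj == inf or not (mask >> j) & 1:
                continue
            dj = d[others[j]]
            for i in range(m):
                if (mask >> i) & 1:
                    continue
                nmask = mask | (1 << i)
                nc = cj + dj[others[i]]
                if nc < cost[nmask][i]:
                    cost[nmask][i] = nc
                    parent[nmask][i] = j
    full = (1 << m) - 1
    best_total, best_j = min(
        ((cost[full][j] + d[others[j]][s], j) for j in range(m)), key=lambda t: t[0]
    )
    # reconstruct
    order_idx = []
    mask, j = full, best_j
    while j >= 0:
        order_idx.append(j)
        mask, j = mask ^ (1 << j), parent[mask][j]
    order_idx.reverse()
    route = [dt.labels[s]] + [dt.labels[others[j]] for j in order_idx] + [dt.labels[s]]
    return float(best_total), route


def _mode_vector(cfg: ExperimentConfig) -> np.ndarray:
    if cfg.variant == "single-nn":
        return np.array([MODE_CODES["deterministic-nn"]])
    if cfg.variant == "single-random":
        return np.array([MODE_CODES["position-weighted"]])
    randomized = "position-weighted" if cfg.variant == "bank-position" else "value-weighted"
    modes = np.full(cfg.bank_size - 1, MODE_CODES[randomized])  # slots n = 1..B-1
    modes[0] = MODE_CODES["deterministic-nn"]  # slot n = 1
    return modes


def run_experiment(
    cfg: ExperimentConfig, dt: DistanceTable, start: Any = None
) -> ExperimentResult:
    """Execute ``cfg.runs`` independent episodes and summarize the best totals.

    Each run gets its own generator seeded from ``(master_seed, run index)``,
    so results are fully reproducible and runs are independent.  The bank's
    parallel modules are simulated sequentially within a run.
    """
    start_idx = 0 if start is None else dt.index(start)
    modes = _mode_vector(cfg)
    best = np.empty(cfg.runs)
    for r in range(cfg.runs):
        rng = np.random.default_rng([cfg.master_seed, r])
        totals, _ = construct_tours(dt.d, start_idx, modes, cfg.weight, rng)
        best[r] = totals.min()
    optimum, _ = brute_force_shortest(dt, start=dt.labels[start_idx])
    return ExperimentResult(config=cfg, best_per_run=best, optimum=optimum)


def weight_sweep(
    weights: Sequence[int],
    dt: DistanceTable,
    bank_size: int = 1024,
    runs: int = 1,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Best totals per weight for the single-module and full-bank variants.

    The single-module arm runs the randomized rule (not the degenerate
    deterministic one) so the weight actually matters; the bank arm runs the
    standard mixed bank.  Returns one row per weight with the mean best total
    of each arm over *runs* episodes.
    """
    rows = []
    for w in weights:
        if not 1 <= w <= 30:
            raise ValidationError("weights must lie in [1, 30]")
        single = run_experiment(
            ExperimentConfig("single-random", weight=w, runs=runs, master_seed=master_seed), dt
        )
        bank = run_experiment(
            ExperimentConfig(
                "bank-position", bank_size=bank_size, weight=w, runs=runs, master_seed=master_seed
            ),
            dt,
        )
        rows.append(
            {"weight": w, "single_module_best": single.mean, "bank_best": bank.mean}
        )
    return pd.DataFrame(rows)


def welch_one_tailed(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test, one-tailed for ``mean(a) < mean(b)``.

    Uses the Welch-Satterthwaite degrees of freedom.  A single zero-variance
    sample is fine (the statistic reduces to a one-sample t-test against that
    constant); both samples constant is degenerate and refused.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise DegenerateSamplesError("both samples have zero variance")
    sea, seb = va / a.size, vb / b.size
    se2 = sea + seb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (sea**2 / (a.size - 1) if va > 0 else 0.0) + (seb**2 / (b.size - 1) if vb > 0 else 0.0)
    )
    p = float(_stats.t.cdf(t, df))
    return float(t), p
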