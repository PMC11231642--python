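# navbank

Tour planning with a bank of duplicated navigation modules.

`navbank` models a planning subsystem of a brain-inspired cognitive
architecture in which the unit of representation is a *navigation map*: a
small spatial grid whose cells hold sensory features, links to other maps,
and operational tags. Planning works by massive duplication rather than by a
clever algorithm: the tagged scene map is copied into a large bank of
planning modules, every module independently builds a greedy tour with a
little randomness injected, and the architecture keeps the shortest tour any
module found. The package implements the map/tag data model, the
instruction-driven `goto()` tagging step, the `small_plan()` randomized
nearest-neighbour planner, an exact dynamic-programming oracle, and a
Monte-Carlo experiment harness that quantifies what the duplication buys on
a travelling-salesperson instance.

## The model

Given a start cell and `k` tagged destination cells with symmetric pairwise
distances, each module builds a tour greedily. At every decision point the
unvisited destinations are sorted by distance from the current location into
a list with 1-based ranks; the next destination is drawn from one of three
rules:

- **deterministic-nn** — always the nearest (the classic nearest-neighbour
  construction);
- **position-weighted** — rank `x` is chosen with probability

  ```
  P(x) = inverse_position(x)^weight / Σ_y inverse_position(y)^weight
  ```

  where `inverse_position(x) = k − rank(x) + 1`. The probabilities depend
  only on the *positions* in the sorted list, never on the distance values:
  with `weight = 4` and five candidates the distribution is
  [64, 26, 8, 2, 0.1]%. Any `weight ≥ 10` collapses to the deterministic
  rule;
- **value-weighted** — each candidate gets weight
  `1 / max(1, d − d_min)`, normalized; here the actual distance values do
  matter (e.g. distances [12, 13, 44] give [49, 49, 2]%).

A bank of `B` module slots reserves slot 0 for a safety copy of the
instruction, runs slot 1 deterministically, and slots 2..B−1 with the
randomized rule, so the bank's best tour can never be worse than plain
nearest neighbour. Visit order is written back onto the map as tags
`<1>, <2>, ..., <0>` that a `move()` step then follows.

## Worked example

Three objects on a 6×6 grid — white sphere at (2,2,0), black sphere at
(3,0,0), white block at (4,2,0) — start at (0,0,0), distances in cm:

```python
import numpy as np
import navbank as nb

scene, distances = nb.builtin_toy_scene()
bank = nb.ModuleBank(scene, size=1024)
nb.load_instruction(nb.Instruction.from_text("go to all objects and go back"), bank)
tagged, n_destinations = nb.parse_goto(bank)   # tags 3 cells <"all">, start <"back">
nb.broadcast(bank)                             # copies the tagged map to slots 1..1023
result = nb.run_bank(bank, distances, weight=4, rng=np.random.default_rng(0))
```

prints, when the pieces are echoed:

```
destinations tagged: 3
totals seen across the bank: [100.0, 109.0, 119.0]
best module: 3 -> total 100.0 cm
  <1> (3, 0, 0)
  <2> (4, 2, 0)
  <3> (2, 2, 0)
  <0> (0, 0, 0)
```

The deterministic slot produces the 109 cm nearest-neighbour tour; the
randomized slots between them realize all three possible routes (100, 109,
119 cm), and the bank returns a 100 cm optimum — here walked in the
direction start → black sphere → white block → white sphere → start.

The same machinery scales to the built-in 13-city miles table (city 0 is
home). Nearest neighbour alone yields 8,131 miles; the exact optimum from
`brute_force_shortest` is 7,293 miles; a 1024-slot position-weighted bank
over 100 runs lands in between:

```python
cities = nb.builtin_cities()
cfg = nb.ExperimentConfig("bank-position", bank_size=1024, runs=100, master_seed=0)
nb.run_experiment(cfg, cities).summary()
# {'variant': 'bank-position', 'bank_size': 1024, 'weight': 4, 'runs': 100,
#  'mean': 7462.85, 'sd': 155.59..., 'sd_defined': True,
#  'fraction_optimal': 0.1, 'optimum': 7293.0}
```

A CLI mirrors the library: `navbank plan`, `navbank experiment`,
`navbank sweep`, `navbank oracle`, `navbank fixture` (see `--help`).

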