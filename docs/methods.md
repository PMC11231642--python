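# Methods

## Representation

A navigation map is a sparse 6×6×1 grid (coordinates are 0-based `(x, y, z)`
with `z = 0` throughout; other dimensions are accepted). Cells carry feature
labels, links to other maps, a start flag, and operational tags of four
kinds: action words (`"go"`), the `<"all">` destination marker, the
`<"back">` return marker, and integer visit-order tags. Pairwise distances
live in one canonical `DistanceTable` — a symmetric, zero-diagonal,
non-negative matrix over labelled locations — rather than in per-cell
distance listings; a per-cell clockwise rendering would be a view of the
same relation, and a single store cannot drift out of sync. Units are kept
as an annotation only: the planner treats distances as pure magnitudes.

A `ModuleBank` is one module-A scene map plus `B` module-B slots. Slot 0 is
reserved for the instruction safety copy; each slot nominally owns `K = 1024`
TempMap areas, but the only TempMap state with behavioural consequences is
the reserved slot's running minimum `(module index, total)`, so only that is
materialized. TempMap contents are cleared at the start of each planning
episode (the persistence policy is an open modelling question; clearing is
the default and `ModuleBank.clear_tempmaps` makes the policy explicit).

## Instruction handling and tagging

Perception and compositional parsing are out of scope; the package emulates
their *outcome*. An instruction is a lowercase token sequence matched by
exact string equality (no fuzzy matching). Only the `"go"` action word is
implemented: `"all"` tags every object cell `<"all">`, a named object
("go to the black sphere") tags exactly the cell whose features include all
non-filler tokens, and `"back"` tags the start cell `<"back">`. The
`<"back">` cell participates only as the forced final leg, not as an
ordinary destination — this matches the `<0>` tag semantics of the worked
examples, where the return home always closes the tour. With at most one
destination the bank is bypassed and a direct move is emitted.

## The planner

`small_plan()` constructs a tour greedily. At each decision point the
unvisited destinations are re-sorted by distance from the current location
(the destination list is rebuilt, and probabilities renormalized, at every
step); distance ties break by the lower table index, i.e. row-major cell
order, which makes the deterministic branch exactly reproducible. Selection
follows the mode:

- position-weighted: `P(rank x) = inv_pos(x)^w / Σ inv_pos^w`, computed with
  arbitrary-precision integer arithmetic for the powers (no overflow at any
  weight) and evaluated as the exact ratio. A memoized lookup keyed by
  (list length, weight) models the architecture's stored probability
  distributions; it agrees bit-for-bit with direct computation and the
  direct path remains the reference.
- value-weighted: normalized `1 / max(1, d − d_min)`; equal distances give a
  uniform vector.
- `weight ≥ 10` forces `P = [1, 0, …, 0]` regardless of mode, so no large
  powers are ever needed in practice.

One uniform variate is consumed per decision step *regardless of mode*, and
a draw maps through the cumulative distribution to the first rank whose
cumulative probability exceeds it. This fixed draw discipline means the
scalar map-level planner and the vectorized experiment engine
(`construct_tours`, which advances thousands of modules in lockstep with one
`rng.random(M)` per step) produce identical tours from identical generator
states — a property the test suite asserts draw for draw.

`run_bank` plans slot 1 deterministically and all higher slots with the
configured randomized rule, tracks the running minimum in the reserved
slot's TempMap, and breaks best-total ties toward the lowest module index.
Per-module generators are spawned from the caller's generator
(`Generator.spawn`), giving reproducible, independent streams without
constructing one generator object per module in the large banks; the
vectorized engine instead draws one uniform per module per step from a
single per-run stream seeded by `(master seed, run index)`. Parallel modules
are always simulated sequentially.

## Experiments and statistics

Four arms are compared on a fixed symmetric instance: `single-nn`,
`single-random` (one position-weighted module), `bank-position` and
`bank-value` (slot 1 deterministic, the rest randomized). Bank sizes follow
the 1K/4K/16K convention — `B` slots, `B − 1` usable because slot 0 is
reserved. Each experiment runs 100 independent episodes by default (the
study's convention), reports each episode's best total, and summarizes with
the mean, the sample (n−1) standard deviation — conventional for
run-to-run summaries — and the fraction of runs hitting the exact optimum.
Runs are unpaired across arms (each arm re-seeds independently), matching
the unpaired Welch comparison.

The exact optimum comes from a Held–Karp dynamic program (exact for the
≤ 16-location instances accepted; each undirected route is one of
`(n−1)!/2`, and the directed DP minimum equals the undirected optimum). The
independent check in the test suite is a naive permutation enumerator with
direction halving, applied to instances of ≤ 8 locations and the 3-route toy
scene.

Welch's unequal-variance t statistic and Welch–Satterthwaite degrees of
freedom are computed in closed form with the p-value from `scipy.stats.t`,
one-tailed for `mean(a) < mean(b)`. When exactly one sample has zero
variance (the deterministic arm), the statistic reduces algebraically to a
one-sample t-test against that constant, which is how the degenerate
comparison is handled; both samples constant is refused.

## Synthetic data

`generate_fixture` draws seeded symmetric integer matrices, uniform over a
configurable range (defaults: 13 locations, 50–2000), optionally repaired to
satisfy the triangle inequality via the all-pairs shortest-path closure.
These fixtures emulate the *shape* of real inter-city tables — symmetry,
integrality, zero diagonal — but not their spatial structure: uniform random
distances are typically non-metric unless repaired and have no planar
embedding, so nearest-neighbour pathologies appear with different frequency
than on road networks. Passing tests on fixtures therefore demonstrate
correctness of the machinery, not performance claims about any particular
geography; performance statements are made only on the built-in 13-city
table.

## Numerical and design choices

- Probabilities are exact ratios of integers; probability vectors sum to 1
  within 1e−12 and the cumulative-draw selection clamps to the last rank to
  be safe against rounding at the boundary.
- Draws are uniform on [0, 1); a draw outside that range is rejected.
- `fraction_optimal` compares totals to the optimum at 1e−9 absolute (totals
  of integer matrices are exact in floats).
- Experiment problem sizes were chosen to keep a full study — five 100-run
  arms up to the 16K bank — in the tens of seconds on one core: the
  vectorized engine makes a 16K×100 study ~1.6 M greedy constructions of a
  13-city tour, dominated by a few hundred `argsort` calls on
  16383×13 arrays.

## Known limitations

- Only the `"go"` pathway is implemented; other action words raise.
- No tour-improvement heuristics (2-opt, ant colony, …) and no asymmetric
  distance support — the planner is deliberately restricted to randomized
  greedy construction, since the object of study is what module duplication
  alone contributes.
- The exact-ratio reading of the position-weighted rule is taken as ground
  truth. An architecture that approximates these probabilities with a small
  table of stored distributions (rounded, or truncated to the first few
  ranks) would inject slightly *milder* randomness on long candidate lists;
  with banks of the sizes studied here this shifts best-of-bank means by a
  fraction of a percent and single-module means by several percent. The
  experiment harness reports whatever the exact-ratio semantics produce.
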