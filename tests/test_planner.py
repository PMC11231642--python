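"""Selection probabilities, small_plan tours, and bank execution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import navbank as nb
from navbank.maps import PlanConfig, TagKind
from navbank.planner import (
    DETERMINISTIC_WEIGHT_CUTOFF,
    MODE_CODES,
    _rank_probabilities_direct,
    construct_tours,
)
from conftest import ScriptedRng, make_toy_bank


class TestPositionWeightedProbabilities:
    def test_five_destinations_weight_4(self):
        p = nb.position_weighted_probabilities(5, 4)
        assert np.array_equal(p, np.array([625, 256, 81, 16, 1]) / 979)

    def test_three_destinations_weight_4(self):
        p = nb.position_weighted_probabilities(3, 4)
        assert np.array_equal(p, np.array([81, 16, 1]) / 98)

    def test_two_destinations_weight_4(self):
        assert np.array_equal(nb.position_weighted_probabilities(2, 4), np.array([16, 1]) / 17)

    @pytest.mark.parametrize("weight", [10, 12, 30])
    def test_large_weight_degenerates(self, weight):
        p = nb.position_weighted_probabilities(6, weight)
        assert p[0] == 1.0 and not p[1:].any()

    def test_single_destination_is_certain(self):
        assert nb.position_weighted_probabilities(1, 7).tolist() == [1.0]

    def test_empty_and_bad_weight_rejected(self):
        with pytest.raises(nb.ValidationError):
            nb.position_weighted_probabilities(0, 4)
        with pytest.raises(nb.ValidationError):
            nb.position_weighted_probabilities(3, 0)

    def test_cached_equals_direct(self):
        for k in range(1, 15):
            for w in (1, 4, 9, 30):
                assert np.array_equal(
                    nb.rank_probabilities(k, w, use_cache=True), _rank_probabilities_direct(k, w)
                )

    def test_depends_only_on_length_not_distances(self):
        """Metamorphic: scaling distances changes value-weighted p, not position-weighted."""
        dl1 = nb.DestinationList(ids=list("abc"), distances=[12.0, 13.0, 44.0])
        dl2 = nb.DestinationList(ids=list("abc"), distances=[120.0, 130.0, 440.0])
        assert np.array_equal(
            nb.position_weighted_probabilities(dl1, 4), nb.position_weighted_probabilities(dl2, 4)
        )
        assert not np.allclose(
            nb.value_weighted_probabilities(dl1), nb.value_weighted_probabilities(dl2)
        )


class TestValueWeightedProbabilities:
    def test_near_tie_distances(self):
        p = nb.value_weighted_probabilities([12.0, 13.0, 44.0])
        assert np.allclose(p, [32 / 65, 32 / 65, 1 / 65])
        assert [round(100 * x) for x in p] == [49, 49, 2]

    def test_dominant_nearest(self):
        p = nb.value_weighted_probabilities([12.0, 42.0, 44.0])
        assert np.allclose(p, np.array([1, 1 / 30, 1 / 32]) / (1 + 1 / 30 + 1 / 32))
        assert [round(100 * x, 1) for x in p] == [93.9, 3.1, 2.9]

    def test_equal_distances_uniform(self):
        assert np.allclose(nb.value_weighted_probabilities([7.0, 7.0, 7.0, 7.0]), 0.25)

    def test_empty_rejected(self):
        with pytest.raises(nb.ValidationError):
            nb.value_weighted_probabilities([])


class TestSelectNext:
    def test_draw_within_first_band(self):
        assert nb.select_next(np.array([0.83, 0.16, 0.01]), 0.55) == 0

    def test_draw_beyond_first_band(self):
        assert nb.select_next(np.array([0.94, 0.06]), 0.95) == 1

    def test_singleton(self):
        assert nb.select_next(np.array([1.0]), 0.999) == 0

    @pytest.mark.parametrize("draw", [-0.1, 1.0, 1.5])
    def test_draw_out_of_range(self, draw):
        with pytest.raises(nb.ValidationError):
            nb.select_next(np.array([1.0]), draw)


@given(
    length=st.integers(1, 20),
    weight=st.integers(1, 30),
    scale=st.floats(0.5, 100.0),
)
@settings(max_examples=120, deadline=None, derandomize=True)
def test_probability_vectors_sum_to_one(length, weight, scale):
    p = nb.position_weighted_probabilities(length, weight)
    assert abs(p.sum() - 1.0) < 1e-12 and (p >= 0).all()
    distances = np.sort(np.arange(length, dtype=float) * scale + 3.0)
    v = nb.value_weighted_probabilities(distances)
    assert abs(v.sum() - 1.0) < 1e-12 and (v >= 0).all()


class TestSmallPlan:
    def test_toy_deterministic_tour_109(self, tagged_toy_map):
        tagged, dt = tagged_toy_map
        pr = nb.small_plan(tagged, dt, PlanConfig(mode="deterministic-nn", weight=30))
        assert pr.visit_order == [(2, 2, 0), (3, 0, 0), (4, 2, 0), (0, 0, 0)]
        assert pr.leg_distances == [25, 22, 20, 42]
        assert pr.total_distance == 109

    def test_toy_forced_draws_give_printed_alternative_100(self, tagged_toy_map):
        """Draws 0.55 then 0.95 pick the second-nearest at step 2 -> 100 cm."""
        tagged, dt = tagged_toy_map
        pr = nb.small_plan(
            tagged, dt, PlanConfig(mode="position-weighted", weight=4),
            rng=ScriptedRng([0.55, 0.95, 0.0]),
        )
        assert pr.visit_order == [(2, 2, 0), (4, 2, 0), (3, 0, 0), (0, 0, 0)]
        assert pr.leg_distances == [25, 24, 20, 31]
        assert pr.total_distance == 100

    def test_retagging(self, tagged_toy_map):
        tagged, dt = tagged_toy_map
        pr = nb.small_plan(tagged, dt, PlanConfig(mode="deterministic-nn", weight=30))
        assert pr.tag_assignment == {(2, 2, 0): 1, (3, 0, 0): 2, (4, 2, 0): 3, (0, 0, 0): 0}
        assert tagged.cells[(2, 2, 0)].visit_order() == 1
        assert tagged.cells[(0, 0, 0)].visit_order() == 0
        assert tagged.tagged_coords(TagKind.ALL_MARKER) == []

    def test_cities_deterministic_8131(self, cities):
        m = nb.make_map(dims=(13, 1, 1), start=(0, 0, 0))
        # city i sits at cell (i,0,0); relabel the table to coordinates
        labels = [(i, 0, 0) for i in range(13)]
        dt = nb.DistanceTable(labels=labels, d=cities.d)
        for i in range(1, 13):
            m.cell((i, 0, 0)).features.add(f"city{i}")
        bank = nb.ModuleBank(m, size=2)
        nb.load_instruction(nb.Instruction.from_text("go to all objects and go back"), bank)
        tagged, count = nb.parse_goto(bank)
        assert count == 12
        pr = nb.small_plan(tagged, dt, PlanConfig(mode="deterministic-nn", weight=30))
        assert pr.total_distance == 8131

    def test_single_destination_out_and_back(self):
        bank = nb.ModuleBank(nb.make_map(objects=[((3, 0, 0), {"a"})], start=(0, 0, 0)), size=2)
        nb.load_instruction(nb.Instruction.from_text("go to all objects and go back"), bank)
        tagged, _ = nb.parse_goto(bank)
        dt = nb.DistanceTable(labels=[(0, 0, 0), (3, 0, 0)], d=np.array([[0.0, 7], [7, 0]]))
        pr = nb.small_plan(tagged, dt, PlanConfig(mode="position-weighted", weight=4))
        assert pr.total_distance == 14
        assert pr.visit_order == [(3, 0, 0), (0, 0, 0)]

    def test_missing_distance_entry(self, tagged_toy_map):
        tagged, _ = tagged_toy_map
        dt = nb.DistanceTable(labels=[(0, 0, 0), (2, 2, 0)], d=np.zeros((2, 2)))
        with pytest.raises(nb.CoverageError):
            nb.small_plan(tagged, dt, PlanConfig())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_weight_cutoff_collapses_to_deterministic(self, seed, tagged_toy_map):
        tagged, dt = tagged_toy_map
        det = nb.small_plan(
            nb.copy_map(tagged), dt, PlanConfig(mode="deterministic-nn", weight=30)
        )
        for w in (DETERMINISTIC_WEIGHT_CUTOFF, 15, 30):
            rnd = nb.small_plan(
                nb.copy_map(tagged), dt,
                PlanConfig(mode="position-weighted", weight=w),
                rng=np.random.default_rng(seed),
            )
            assert rnd.visit_order == det.visit_order

    def test_route_frequencies_match_decision_tree(self, tagged_toy_map):
        """Sampled tour shares agree with the exact per-branch probabilities.

        Start draws over [25, 31, 42] with p = [81, 16, 1]/98, then over the
        remaining two with p = [16, 1]/17 -- so e.g. the printed 100 cm route
        (nearest first, then second-nearest) has probability 81/98 * 1/17.
        """
        tagged, dt = tagged_toy_map
        n = 40_000
        totals, orders = construct_tours(
            dt.d, dt.index((0, 0, 0)),
            np.full(n, MODE_CODES["position-weighted"]), 4, np.random.default_rng(2024),
        )
        p_first = np.array([81, 16, 1]) / 98
        p_second = np.array([16, 1]) / 17
        # first hop: index of visited city by rank among [ws, bs, wb]
        first = orders[:, 0]
        ranks = {dt.index((2, 2, 0)): 0, dt.index((3, 0, 0)): 1, dt.index((4, 2, 0)): 2}
        for city, rank in ranks.items():
            share = (first == city).mean()
            se = np.sqrt(p_first[rank] * (1 - p_first[rank]) / n)
            assert abs(share - p_first[rank]) < 5 * se + 1e-4
        # second hop, conditioned on nearest-first
        mask = first == dt.index((2, 2, 0))
        second_nearest = (orders[mask, 1] == dt.index((4, 2, 0))).mean()
        se = np.sqrt(p_second[1] * (1 - p_second[1]) / mask.sum())
        assert abs(second_nearest - p_second[1]) < 5 * se + 1e-4


class TestTourValidity:
    @given(seed=st.integers(0, 200), mode=st.sampled_from(["position-weighted", "value-weighted"]))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_every_plan_is_a_valid_tour(self, seed, mode):
        dt = nb.generate_fixture(nb.FixtureSpec(n_locations=7, seed=seed))
        totals, orders = construct_tours(
            dt.d, 0, np.array([MODE_CODES[mode]]), 4, np.random.default_rng(seed)
        )
        order = orders[0]
        assert sorted(order) == list(range(1, 7))
        legs = [dt.d[0, order[0]]] + [dt.d[a, b] for a, b in zip(order, order[1:])]
        legs.append(dt.d[order[-1], 0])
        assert totals[0] == pytest.approx(sum(legs))


class TestRunBank:
    def test_toy_bank_finds_100(self):
        bank, dt = make_toy_bank(size=1024)
        res = nb.run_bank(bank, dt, weight=4, rng=np.random.default_rng(0))
        assert res.best_plan.total_distance == 100
        assert set(res.per_module_totals.values()) == {100.0, 109.0, 119.0}
        assert res.per_module_totals[1] == 109  # deterministic slot
        assert bank.temp_best == (res.best_index, 100.0)

    def test_best_never_worse_than_deterministic_slot(self):
        for seed in range(5):
            bank, dt = make_toy_bank(size=32)
            res = nb.run_bank(bank, dt, weight=4, rng=np.random.default_rng(seed))
            assert res.best_plan.total_distance <= res.per_module_totals[1]
            assert res.best_plan.total_distance == min(res.per_module_totals.values())

    def test_two_destination_bank_is_optimal(self):
        """Both possible tours exist in any 2-destination instance; the bank's
        best must equal the enumerated optimum."""
        bank = nb.ModuleBank(
            nb.make_map(objects=[((1, 0, 0), {"a"}), ((2, 0, 0), {"b"})], start=(0, 0, 0)),
            size=64,
        )
        nb.load_instruction(nb.Instruction.from_text("go to all objects and go back"), bank)
        nb.parse_goto(bank)
        nb.broadcast(bank)
        labels = [(0, 0, 0), (1, 0, 0), (2, 0, 0)]
        d = np.array([[0, 9, 2], [9, 0, 4], [2, 4, 0]], float)
        dt = nb.DistanceTable(labels=labels, d=d)
        res = nb.run_bank(bank, dt, weight=4, rng=np.random.default_rng(1))
        # only one undirected tour exists: 9 + 4 + 2
        assert res.best_plan.total_distance == 15

    def test_requires_broadcast(self, toy_scene):
        m, dt = toy_scene
        bank = nb.ModuleBank(m, size=4)
        with pytest.raises(nb.StateError):
            nb.run_bank(bank, dt)


class TestMoveSequence:
    def test_ascending_tags_then_home(self, tagged_toy_map):
        tagged, dt = tagged_toy_map
        pr = nb.small_plan(
            tagged, dt, PlanConfig(mode="position-weighted", weight=4),
            rng=ScriptedRng([0.55, 0.95, 0.0]),
        )
        assert nb.move_sequence(pr) == [
            ((2, 2, 0), 1), ((4, 2, 0), 2), ((3, 0, 0), 3), ((0, 0, 0), 0)
        ]

    def test_empty_plan_start_only(self):
        pr = nb.PlanResult(1, [(0, 0, 0)], [0.0], 0.0, {(0, 0, 0): 0})
        assert nb.move_sequence(pr) == [((0, 0, 0), 0)]


def test_vectorized_engine_matches_small_plan():
    """One vectorized module replays small_plan draw for draw on any instance."""
    for seed in range(6):
        dt_int = nb.generate_fixture(nb.FixtureSpec(n_locations=8, seed=seed))
        labels = [(i, 0, 0) for i in range(8)]
        dt = nb.DistanceTable(labels=labels, d=dt_int.d)
        m = nb.make_map(dims=(8, 1, 1), start=(0, 0, 0))
        for i in range(1, 8):
            m.cell((i, 0, 0)).features.add("c")
        bank = nb.ModuleBank(m, size=2)
        nb.load_instruction(nb.Instruction.from_text("go to all objects and go back"), bank)
        tagged, _ = nb.parse_goto(bank)
        for mode in ("position-weighted", "value-weighted"):
            pr = nb.small_plan(
                nb.copy_map(tagged), dt, PlanConfig(mode=mode, weight=4),
                rng=np.random.default_rng(seed + 100),
            )
            totals, orders = construct_tours(
                dt.d, 0, np.array([MODE_CODES[mode]]), 4, np.random.default_rng(seed + 100)
            )
            assert pr.total_distance == pytest.approx(totals[0])
            assert [labels.index(c) for c in pr.visit_order[:-1]] == orders[0].tolist()
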