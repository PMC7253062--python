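"""Engine mechanics: the staging table, the five steps and whole runs."""

import numpy as np
import pandas as pd
import pytest

from wormcolony import FoodGrid, Genotype, run_colony
from wormcolony.engine import (ColonyState, Stage, feed_step, move_step,
                               reproduce_step, stage_step, survival_step)
from conftest import build_state


class TestStagingTable:
    """Every row of the stage-transition table, one individual at a time."""

    @pytest.mark.parametrize("stage,fed,expected", [
        (Stage.L0, False, Stage.L1),
        (Stage.L0, True, Stage.L1),
        (Stage.L1, True, Stage.L2),
        (Stage.L1, False, Stage.L1_ARRESTED),
        (Stage.L1_ARRESTED, True, Stage.L2),
        (Stage.L1_ARRESTED, False, Stage.L1_ARRESTED),
        (Stage.L2, True, Stage.ADULT),
        (Stage.L2, False, Stage.DAUER),
        (Stage.DAUER, True, Stage.ADULT),
        (Stage.DAUER, False, Stage.DAUER),
        (Stage.ADULT, True, Stage.ADULT),
        (Stage.ADULT, False, Stage.ADULT),
    ])
    def test_transitions(self, genotype, rich_grid, stage, fed, expected):
        state = build_state(genotype, rich_grid,
                            [{"stage": stage, "fed": fed, "starve_days": 1}])
        stage_step(state)
        assert state.n == 1
        assert Stage(state.stage[0]) == expected

    def test_new_adult_starts_at_age_zero(self, genotype, rich_grid):
        state = build_state(genotype, rich_grid,
                            [{"stage": Stage.L2, "fed": True},
                             {"stage": Stage.DAUER, "fed": True},
                             {"stage": Stage.ADULT, "fed": True, "adult_age": 3}])
        stage_step(state)
        assert list(state.adult_age) == [0, 0, 4]

    def test_entering_dauer_counts_once(self, genotype, rich_grid):
        state = build_state(genotype, rich_grid,
                            [{"stage": Stage.L2, "fed": False}])
        stage_step(state)
        assert state.cum_dauers == 1 and state.became_dauer[0]
        # resume to adult and keep the counter unchanged
        state.fed[0] = True
        stage_step(state)
        assert Stage(state.stage[0]) == Stage.ADULT
        assert state.cum_dauers == 1

    def test_arrested_l1_dies_on_sixth_starved_day(self, genotype, rich_grid):
        state = build_state(genotype, rich_grid,
                            [{"stage": Stage.L1_ARRESTED, "fed": False,
                              "starve_days": 5}])
        stage_step(state)  # 6th consecutive starved day: L1s_s reached
        assert state.n == 0
        assert state.deaths["starved_l1_arrested"] == 1

    def test_dauer_dies_at_its_starvation_limit(self, rich_grid):
        g = Genotype(L2s_s=30)
        state = build_state(g, rich_grid,
                            [{"stage": Stage.DAUER, "fed": False,
                              "starve_days": 29}])
        stage_step(state)
        assert state.n == 0 and state.deaths["starved_dauer"] == 1

    def test_arrested_survives_below_limit(self, genotype, rich_grid):
        state = build_state(genotype, rich_grid,
                            [{"stage": Stage.L1_ARRESTED, "fed": False,
                              "starve_days": 2}])
        stage_step(state)
        assert state.n == 1 and state.starve_days[0] == 3


class TestFeedStep:
    def test_lone_adult_empties_its_cell(self, genotype):
        grid = FoodGrid(np.full((3, 3), 1000.0))
        state = build_state(genotype, grid, [{"stage": Stage.ADULT, "x": 1, "y": 1}])
        feed_step(state)
        assert state.fed[0]
        assert grid.cells[1, 1] == 0.0
        assert grid.consumed["adult"] == 1000.0

    def test_two_larvae_share_75_units(self, genotype):
        grid = FoodGrid(np.array([[75.0]]))
        state = build_state(genotype, grid,
                            [{"stage": Stage.L1, "x": 0, "y": 0},
                             {"stage": Stage.L1, "x": 0, "y": 0}])
        feed_step(state)
        # sequential all-or-nothing meals: the first-created larva eats,
        # the second finds only 25 units left
        assert list(state.fed) == [True, False]
        assert grid.cells[0, 0] == 25.0

    def test_resident_adult_eats_before_younger_larva(self, genotype):
        grid = FoodGrid(np.array([[1049.0]]))
        state = build_state(genotype, grid,
                            [{"stage": Stage.ADULT, "x": 0, "y": 0},
                             {"stage": Stage.L1, "x": 0, "y": 0}])
        feed_step(state)
        assert list(state.fed) == [True, False]
        assert grid.cells[0, 0] == 49.0

    def test_eggs_demand_nothing(self, genotype):
        grid = FoodGrid(np.zeros((2, 2)))
        state = build_state(genotype, grid, [{"stage": Stage.L0, "x": 0, "y": 0}])
        feed_step(state)
        assert state.fed[0]  # no demand, unaffected by the empty cell
        assert grid.remaining == 0.0

    def test_arrested_stages_pay_a_larval_meal_to_resume(self, genotype):
        grid = FoodGrid(np.array([[60.0]]))
        state = build_state(genotype, grid,
                            [{"stage": Stage.DAUER, "x": 0, "y": 0}])
        feed_step(state)
        assert state.fed[0]
        assert grid.cells[0, 0] == 10.0
        assert grid.consumed["larva"] == 50.0


class TestSurvivalStep:
    def test_eggs_always_survive(self, rich_grid):
        g = Genotype(m_larva=1.0, m_dauer=1.0, M2=0.5)  # lethal to all others
        state = build_state(g, rich_grid,
                            [{"stage": Stage.L0} for _ in range(200)])
        survival_step(state)
        assert state.n == 200

    def test_larval_mortality_is_binomial(self, rich_grid):
        g = Genotype(m_larva=0.05)
        state = build_state(g, rich_grid, [])
        state.add_individuals(10_000, Stage.L1, 15, 15)
        survival_step(state, rng=np.random.default_rng(7))
        deaths = 10_000 - state.n
        sd = np.sqrt(10_000 * 0.05 * 0.95)
        assert abs(deaths - 500) < 3 * sd

    def test_no_aging_adults_never_die(self, rich_grid):
        g = Genotype(M2=1.0)
        state = build_state(g, rich_grid, [])
        state.add_individuals(5_000, Stage.ADULT, 10, 10)
        state.adult_age[:] = np.arange(5_000) % 40
        survival_step(state, rng=np.random.default_rng(3))
        assert state.n == 5_000


class TestMoveStep:
    def test_zero_scale_is_stationary(self, rich_grid):
        g = Genotype(s_fed=0.0, s_hungry=0.0)
        state = build_state(g, rich_grid, [{"stage": Stage.ADULT, "x": 4, "y": 9}])
        move_step(state)
        assert (state.x[0], state.y[0]) == (4, 9)

    def test_displacement_bounded_by_scale(self, rich_grid):
        g = Genotype(s_fed=0.5, s_hungry=0.9)
        state = build_state(g, rich_grid, [])
        state.add_individuals(500, Stage.ADULT, 15, 15)
        state.fed[:] = True
        move_step(state, rng=np.random.default_rng(0))
        assert np.abs(state.x - 15).max() <= 5
        assert np.abs(state.y - 15).max() <= 5

    def test_overshoot_is_clamped_to_the_edge(self):
        # a worm at the edge whose draw would land outside is set to the limit
        grid = FoodGrid(np.ones((5, 5)))
        g = Genotype(s_fed=0.9, s_hungry=0.9)
        state = build_state(g, grid, [])
        state.add_individuals(300, Stage.DAUER, 4, 4)
        for _ in range(5):
            move_step(state, rng=np.random.default_rng(1))
            assert state.x.min() >= 0 and state.x.max() <= 4
            assert state.y.min() >= 0 and state.y.max() <= 4

    def test_eggs_do_not_move(self, rich_grid, genotype):
        state = build_state(genotype, rich_grid, [])
        state.add_individuals(50, Stage.L0, 12, 12)
        move_step(state, rng=np.random.default_rng(5))
        assert (state.x == 12).all() and (state.y == 12).all()


class TestReproduceStep:
    def test_day1_brood_at_parent_cell(self, rich_grid):
        g = Genotype(F1=4, F2=4.0)
        state = build_state(g, rich_grid,
                            [{"stage": Stage.ADULT, "adult_age": 0,
                              "x": 7, "y": 3}])
        reproduce_step(state)
        assert state.n == 5 and state.births == 4
        assert (state.stage[1:] == Stage.L0).all()
        assert (state.x[1:] == 7).all() and (state.y[1:] == 3).all()

    def test_post_reproductive_adult_lays_nothing(self, rich_grid):
        g = Genotype(F1=4, F2=4.0)
        state = build_state(g, rich_grid,
                            [{"stage": Stage.ADULT, "adult_age": 1}])
        reproduce_step(state)
        assert state.n == 1 and state.births == 0

    def test_larvae_do_not_reproduce(self, rich_grid):
        g = Genotype(F1=50, F2=0.0)
        state = build_state(g, rich_grid, [{"stage": Stage.L2, "fed": True}])
        reproduce_step(state)
        assert state.n == 1


class TestGeometricGrowthOracle:
    def test_five_step_leslie_tally(self, rich_grid):
        """Deathless, food-unlimited growth from one adult matches the
        closed-form age-structured recursion (F1=2, F2=0)."""
        g = Genotype(F1=2, F2=0.0, M2=1.0, m_larva=0.0, m_dauer=0.0,
                     s_fed=0.2, s_hungry=0.2)
        state = build_state(g, rich_grid, [{"stage": Stage.ADULT}])
        # oracle: L0(t)=2*A(t); L1(t)=L0(t-1); L2(t)=L1(t-1); A(t)=A(t-1)+L2(t-1)
        l0 = l1 = l2 = 0
        adults = 1
        for _ in range(5):
            feed_step(state)
            stage_step(state)
            survival_step(state)
            move_step(state)
            reproduce_step(state)
            adults, l2, l1, l0 = adults + l2, l1, l0, 2 * (adults + l2)
            counts = state.stage_counts()
            assert counts[Stage.L0] == l0
            assert counts[Stage.L1] == l1
            assert counts[Stage.L2] == l2
            assert counts[Stage.ADULT] == adults
        assert state.n == 23  # 10 + 6 + 2 + 5


class TestRunColony:
    def test_fixed_seed_is_bit_reproducible(self, small_patch, genotype):
        a = run_colony(genotype, small_patch, seed=11, t_max=60)
        b = run_colony(genotype, small_patch, seed=11, t_max=60)
        pd.testing.assert_frame_equal(a.series, b.series)
        assert a.summary == b.summary

    def test_different_seeds_differ(self, small_patch, genotype):
        a = run_colony(genotype, small_patch, seed=1, t_max=60)
        b = run_colony(genotype, small_patch, seed=2, t_max=60)
        assert not a.series.equals(b.series)

    def test_food_conservation_over_a_run(self, small_patch, genotype):
        result = run_colony(genotype, small_patch, seed=5, t_max=60)
        assert result.summary["food_conservation_error"] < 1e-9
        s = result.series
        total = (s["food_remaining"] + s["food_consumed_adults"]
                 + s["food_consumed_larvae"])
        assert np.allclose(total, small_patch.initial_total)

    def test_cumulative_dauers_monotone_and_peak_bounded(self, small_patch,
                                                         genotype):
        result = run_colony(genotype, small_patch, seed=3, t_max=60)
        cum = result.series["cum_dauers"].to_numpy()
        assert (np.diff(cum) >= 0).all()
        assert result.summary["peak_dauers"] <= result.summary["cum_dauers"]
        assert result.fitness == cum[-1]

    def test_empty_grid_run_is_null(self, genotype):
        grid = FoodGrid(np.zeros((21, 21)))
        result = run_colony(genotype, grid, seed=9)
        assert result.null
        assert result.fitness == 0
        # the founder arrests immediately and starves out within L1s_s days
        assert result.summary["t_end"] <= genotype.L1s_s + 1
        assert result.summary["termination"] in ("extinct", "exhausted")

    def test_sterile_founder_is_not_null(self, rich_grid):
        g = Genotype(F1=0, F2=0.0, m_larva=0.0, M2=0.99, s_fed=0.1)
        result = run_colony(g, rich_grid, seed=4, t_max=25)
        assert result.summary["ever_adults"] >= 1  # the founder matured
        assert not result.null
        assert result.fitness == 0

    def test_boom_produces_thousands_of_dauers(self):
        # demo genotype: no decline, 50 progeny/day, fast dispersal
        result = run_colony(Genotype(), seed=2)
        assert not result.null
        assert result.fitness > 1000
        assert result.summary["termination"] == "exhausted"

    def test_truncation_flagged_at_t_max(self, rich_grid):
        g = Genotype(F1=2, F2=0.0, M2=1.0, m_larva=0.0, s_fed=0.1)
        result = run_colony(g, rich_grid, seed=1, t_max=5)
        assert result.truncated
        assert result.summary["termination"] == "t_max"

    def test_founder_count_and_positions(self, small_patch, genotype):
        result = run_colony(genotype, small_patch, founders=3, seed=8)
        assert result.summary["founders"] == 3
        with pytest.raises(ValueError):
            run_colony(genotype, small_patch, founders=0)
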