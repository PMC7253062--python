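"""The per-timepoint simulation pipeline and colony bookkeeping.

Each timepoint (one day) applies five steps to the whole population, in this
order: feed -> stage -> survive -> move -> reproduce.  Stages follow the
reduced life cycle L0 (egg) -> L1 -> L2 -> adult, with the two arrested
branches L1_arrested (starved L1s, survive up to ``L1s_s`` days) and dauer
(starved L2s, survive up to ``L2s_s`` days).  Colony fitness is the
cumulative number of distinct individuals that ever entered the dauer stage
by the time the food patch is exhausted.

The population is held as struct-of-arrays (one numpy array per attribute)
so a run with tens of thousands of concurrent worms stays fast; the
:class:`Individual` record view exists for inspection and tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .environment import FoodGrid, make_gaussian_patch
from .life_history import Genotype, consumption_vec, fecundity_vec

__all__ = [
    "Stage",
    "Individual",
    "ColonyState",
    "RunResult",
    "feed_step",
    "stage_step",
    "survival_step",
    "move_step",
    "reproduce_step",
    "run_colony",
]


class Stage(IntEnum):
    L0 = 0
    L1 = 1
    L1_ARRESTED = 2
    L2 = 3
    DAUER = 4
    ADULT = 5


_SERIES_COLUMNS = [
    "timepoint", "l0", "l1", "l1_arrested", "l2", "dauer", "adult",
    "cum_dauers", "cum_births", "food_remaining",
    "food_consumed_adults", "food_consumed_larvae",
]


@dataclass(frozen=True)
class Individual:
    """Read-only record view of one worm (for inspection and tests)."""

    id: int
    stage: Stage
    adult_age: int
    x: int
    y: int
    fed: bool
    starve_days: int
    became_dauer: bool


class ColonyState:
    """Population + grid + clock + cumulative counters for one run."""

    def __init__(self, genotype: Genotype, grid: FoodGrid,
                 rng: Optional[np.random.Generator] = None, seed=None,
                 feed_order: str = "creation"):
        if feed_order not in ("creation", "random"):
            raise ValueError("feed_order must be 'creation' or 'random'")
        self.genotype = genotype
        self.grid = grid
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        self.clock = 0
        self.feed_order = feed_order
        # struct-of-arrays population state
        self.stage = np.empty(0, dtype=np.int8)
        self.adult_age = np.empty(0, dtype=np.int32)
        self.x = np.empty(0, dtype=np.int32)
        self.y = np.empty(0, dtype=np.int32)
        self.fed = np.empty(0, dtype=bool)
        self.starve_days = np.empty(0, dtype=np.int32)
        self.became_dauer = np.empty(0, dtype=bool)
        self.ident = np.empty(0, dtype=np.int64)
        self._next_id = 0
        # counters
        self.founders = 0
        self.births = 0
        self.cum_dauers = 0
        self.peak_dauers = 0
        self.ever_adults = 0
        self.deaths = {"larva": 0, "dauer": 0, "adult": 0,
                       "starved_l1_arrested": 0, "starved_dauer": 0}

    # -- population management -------------------------------------------

    @property
    def n(self) -> int:
        return self.stage.size

    @property
    def deaths_total(self) -> int:
        return sum(self.deaths.values())

    def add_individuals(self, n: int, stage: Stage, x, y, *,
                        founders: bool = False) -> None:
        """Append ``n`` live individuals at the given cell(s)."""
        if n <= 0:
            return
        xs = np.broadcast_to(np.asarray(x, dtype=np.int32), (n,))
        ys = np.broadcast_to(np.asarray(y, dtype=np.int32), (n,))
        if (xs < 0).any() or (xs >= self.grid.width).any() \
                or (ys < 0).any() or (ys >= self.grid.height).any():
            raise ValueError("individual position outside grid bounds")
        self.stage = np.concatenate([self.stage, np.full(n, int(stage), dtype=np.int8)])
        self.adult_age = np.concatenate([self.adult_age, np.zeros(n, dtype=np.int32)])
        self.x = np.concatenate([self.x, xs.astype(np.int32)])
        self.y = np.concatenate([self.y, ys.astype(np.int32)])
        self.fed = np.concatenate([self.fed, np.zeros(n, dtype=bool)])
        self.starve_days = np.concatenate([self.starve_days, np.zeros(n, dtype=np.int32)])
        self.became_dauer = np.concatenate([self.became_dauer, np.zeros(n, dtype=bool)])
        self.ident = np.concatenate(
            [self.ident, np.arange(self._next_id, self._next_id + n, dtype=np.int64)])
        self._next_id += n
        if founders:
            self.founders += n
        else:
            self.births += n

    def remove(self, dead: np.ndarray, cause: str) -> None:
        """Drop individuals flagged in the boolean mask ``dead``."""
        k = int(dead.sum())
        if k == 0:
            return
        self.deaths[cause] = self.deaths.get(cause, 0) + k
        self._drop(dead)

    def _drop(self, dead: np.ndarray) -> None:
        keep = ~dead
        for name in ("stage", "adult_age", "x", "y", "fed", "starve_days",
                     "became_dauer", "ident"):
            setattr(self, name, getattr(self, name)[keep])

    def individuals(self) -> list:
        """Materialize the population as :class:`Individual` records."""
        return [Individual(int(self.ident[i]), Stage(int(self.stage[i])),
                           int(self.adult_age[i]), int(self.x[i]), int(self.y[i]),
                           bool(self.fed[i]), int(self.starve_days[i]),
                           bool(self.became_dauer[i]))
                for i in range(self.n)]

    def stage_counts(self) -> np.ndarray:
        return np.bincount(self.stage, minlength=len(Stage))

    @property
    def hatched(self) -> int:
        """All individuals that ever existed, founders included."""
        return self.births + self.founders


# -- the five per-timepoint steps ----------------------------------------

def feed_step(state: ColonyState) -> None:
    """All worms attempt to eat, cell by cell, setting fed flags.

    Demands: ``c_larva`` for every larval stage — L1 and L2, and also the
    arrested stages (L1_arrested, dauer), which eat a larval meal on the day
    they encounter food and resume development; the (possibly age-scheduled)
    adult demand for adults; nothing for eggs.  A worm whose cell holds at
    least its demand eats it (all or nothing) and is flagged fed; otherwise
    it is flagged starved and the cell is untouched.
    """
    n = state.n
    if n == 0:
        return
    g = state.genotype
    demand = np.zeros(n, dtype=np.float64)
    mode = np.zeros(n, dtype=np.int8)

    larv = (state.stage != Stage.L0) & (state.stage != Stage.ADULT)
    demand[larv] = g.c_larva
    mode[larv] = _kernels.MODE_LARVA

    adult = state.stage == Stage.ADULT
    if adult.any():
        demand[adult] = consumption_vec(g, state.adult_age[adult])
        mode[adult] = _kernels.MODE_ADULT

    cell = (state.y.astype(np.int64) * state.grid.width + state.x)
    if state.feed_order == "creation":
        # stable sort keeps creation (= age) order within a cell: the oldest
        # worm on a cell eats first, so a resident adult claims its meal
        # before the larvae crowding around it
        order = np.argsort(cell, kind="stable")
    else:
        perm = state.rng.permutation(n)
        order = perm[np.argsort(cell[perm], kind="stable")]

    fed = np.zeros(n, dtype=np.uint8)
    totals = np.zeros(2, dtype=np.float64)
    _kernels.feed_loop(order.astype(np.int64), cell, demand, mode,
                       state.grid.cells.reshape(-1), fed, totals)
    state.fed = fed.astype(bool)
    state.grid.consumed["larva"] += float(totals[0])
    state.grid.consumed["adult"] += float(totals[1])


def stage_step(state: ColonyState) -> None:
    """Advance every live individual one row through the staging table.

    L0->L1; L1 fed->L2, starved->L1_arrested; L1_arrested fed->L2, starved
    counts starvation days and dies at ``L1s_s``; L2 fed->adult (age 0),
    starved->dauer; dauer fed->adult (age 0), starved counts days and dies
    at ``L2s_s``; adults age by one day.  Entering dauer increments the
    cumulative dauer counter exactly once per individual.
    """
    if state.n == 0:
        return
    g = state.genotype
    st = state.stage
    fed = state.fed
    new = st.copy()
    dead = np.zeros(state.n, dtype=bool)

    new[st == Stage.L0] = Stage.L1

    m = st == Stage.L1
    new[m & fed] = Stage.L2
    entering_arrest = m & ~fed
    new[entering_arrest] = Stage.L1_ARRESTED
    state.starve_days[entering_arrest] = 1

    m = st == Stage.L1_ARRESTED
    resume = m & fed
    new[resume] = Stage.L2
    state.starve_days[resume] = 0
    stay = m & ~fed
    state.starve_days[stay] += 1

    m = st == Stage.L2
    mature = m & fed
    new[mature] = Stage.ADULT
    state.adult_age[mature] = 0
    entering_dauer = m & ~fed
    new[entering_dauer] = Stage.DAUER
    state.starve_days[entering_dauer] = 1
    state.became_dauer[entering_dauer] = True
    state.cum_dauers += int(entering_dauer.sum())

    m = st == Stage.DAUER
    resume = m & fed
    new[resume] = Stage.ADULT
    state.adult_age[resume] = 0
    state.starve_days[resume] = 0
    stay = m & ~fed
    state.starve_days[stay] += 1

    m = st == Stage.ADULT
    state.adult_age[m] += 1

    state.ever_adults += int((new == Stage.ADULT).sum() - (st == Stage.ADULT).sum())
    state.stage = new

    # starvation-limit deaths (checked after the counts were updated, so an
    # individual dies on its L1s_s-th / L2s_s-th consecutive starved day)
    l1a_dead = (state.stage == Stage.L1_ARRESTED) & (state.starve_days >= g.L1s_s)
    dauer_dead = (state.stage == Stage.DAUER) & (state.starve_days >= g.L2s_s)
    state.remove(l1a_dead, "starved_l1_arrested")
    # the mask for dauers must be recomputed after the first removal
    dauer_dead = (state.stage == Stage.DAUER) & (state.starve_days >= g.L2s_s)
    state.remove(dauer_dead, "starved_dauer")


def survival_step(state: ColonyState,
                  rng: Optional[np.random.Generator] = None) -> None:
    """One Bernoulli death draw per live individual.

    Eggs (L0) always survive.  L1, L1_arrested and L2 die with probability
    ``m_larva``, dauers with ``m_dauer``, adults with
    ``1 - M2**(M1 + adult_age)``.
    """
    if state.n == 0:
        return
    if rng is None:
        rng = state.rng
    g = state.genotype
    p = np.zeros(state.n, dtype=np.float64)
    larva = ((state.stage == Stage.L1) | (state.stage == Stage.L1_ARRESTED)
             | (state.stage == Stage.L2))
    p[larva] = g.m_larva
    p[state.stage == Stage.DAUER] = g.m_dauer
    adult = state.stage == Stage.ADULT
    if adult.any():
        p[adult] = np.clip(
            1.0 - g.M2 ** (g.M1 + state.adult_age[adult].astype(np.float64)), 0.0, 1.0)
    dies = rng.random(state.n) < p
    if not dies.any():
        return
    state.deaths["larva"] += int((dies & larva).sum())
    state.deaths["dauer"] += int((dies & (state.stage == Stage.DAUER)).sum())
    state.deaths["adult"] += int((dies & adult).sum())
    state._drop(dies)


def move_step(state: ColonyState,
              rng: Optional[np.random.Generator] = None) -> None:
    """Random walk with fed-status-dependent step size, clamped to the grid.

    Each worm (eggs excepted) draws independent per-axis displacements
    uniformly from the integers ``[-floor(10 s), +floor(10 s)]`` with
    ``s = s_fed`` if fed else ``s_hungry``; positions beyond an edge are set
    to the edge cell.
    """
    if state.n == 0:
        return
    if rng is None:
        rng = state.rng
    g = state.genotype
    kf, kh = int(10 * g.s_fed), int(10 * g.s_hungry)
    k = np.where(state.fed, kf, kh).astype(np.int64)
    k[state.stage == Stage.L0] = 0  # eggs do not move
    dx = rng.integers(-k, k + 1)
    dy = rng.integers(-k, k + 1)
    np.clip(state.x + dx, 0, state.grid.width - 1, out=state.x, casting="unsafe")
    np.clip(state.y + dy, 0, state.grid.height - 1, out=state.y, casting="unsafe")


def reproduce_step(state: ColonyState) -> None:
    """Every live adult lays its age-determined clutch of eggs at its cell.

    Reproduction is clonal and does not require the adult to have fed; the
    clutch size is ``fecundity(adult_age)`` and the L0s appear at the
    parent's position, to be processed from the next timepoint on.
    """
    if state.n == 0:
        return
    adult = state.stage == Stage.ADULT
    if not adult.any():
        return
    counts = fecundity_vec(state.genotype, state.adult_age[adult])
    total = int(counts.sum())
    if total == 0:
        return
    xs = np.repeat(state.x[adult], counts)
    ys = np.repeat(state.y[adult], counts)
    state.add_individuals(total, Stage.L0, xs, ys)


# -- run driver -----------------------------------------------------------

@dataclass
class RunResult:
    """Outcome of one colony simulation.

    ``series`` is a tidy per-timepoint table (stage counts, cumulative
    dauers and births, food remaining and consumed by class); ``summary``
    carries the scalar counters, the termination reason and full seed /
    genotype provenance.  ``fitness`` is the cumulative number of distinct
    individuals that ever entered dauer.
    """

    series: pd.DataFrame
    summary: dict

    @property
    def fitness(self) -> int:
        return self.summary["fitness"]

    @property
    def null(self) -> bool:
        return self.summary["null"]

    @property
    def truncated(self) -> bool:
        return self.summary["truncated"]

    def write(self, outdir) -> None:
        """Write ``series.csv`` and ``summary.json`` into ``outdir``."""
        import json
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.series.to_csv(outdir / "series.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)


def _record_row(state: ColonyState) -> list:
    counts = state.stage_counts()
    return [state.clock, *(int(c) for c in counts), state.cum_dauers,
            state.births, state.grid.remaining,
            state.grid.consumed["adult"], state.grid.consumed["larva"]]


def run_colony(genotype: Genotype, grid: Optional[FoodGrid] = None, *,
               founders: int = 1,
               founder_positions: Optional[Sequence[Tuple[int, int]]] = None,
               seed=None, rng: Optional[np.random.Generator] = None,
               t_max: int = 100, copy_grid: bool = True,
               feed_order: str = "creation") -> RunResult:
    """Simulate one colony from founding larvae to food-patch exhaustion.

    Founders are L1 larvae placed at the centre of the grid (or at
    ``founder_positions``).  The run ends when the population is extinct or
    when the patch is exhausted, plus one settling timepoint so starved L2s
    still in flight enter dauer; exhaustion means no grid cell holds the
    smallest positive meal any stage could ever demand, so nothing can feed
    or resume development again.  The same applies as soon as every survivor
    is arrested (dauer or L1_arrested) and no cell can feed them.  Runs
    reaching ``t_max`` timepoints are recorded as truncated.

    A run is flagged *null* when the founding larva(e) died before any
    reproduction: no eggs laid, no adult matured, no dauer formed.  Null
    runs are excluded from mean-fitness aggregation downstream.
    """
    if founders < 1:
        raise ValueError("founders must be >= 1")
    if grid is None:
        grid = make_gaussian_patch()
    elif copy_grid:
        grid = grid.copy()
    state = ColonyState(genotype, grid, rng=rng, seed=seed, feed_order=feed_order)
    if founder_positions is None:
        cx, cy = grid.width // 2, grid.height // 2
        state.add_individuals(founders, Stage.L1, cx, cy, founders=True)
    else:
        if len(founder_positions) != founders:
            raise ValueError("founder_positions length must equal founders")
        for (fx, fy) in founder_positions:
            state.add_individuals(1, Stage.L1, fx, fy, founders=True)

    # the smallest meal any stage could ever demand: once every cell is below
    # this, no worm can ever feed again and the patch is effectively exhausted
    if genotype.consumption_schedule is None:
        min_adult_demand = genotype.c_adult
    else:
        positive = [f for f in genotype.consumption_schedule if f > 0]
        min_adult_demand = genotype.c_adult * min(positive) if positive else math.inf
    min_demand = min(genotype.c_larva, min_adult_demand)

    rows = [_record_row(state)]
    reason = "t_max"
    truncated = True
    settling = False
    while state.clock < t_max:
        state.clock += 1
        feed_step(state)
        stage_step(state)
        survival_step(state)
        move_step(state)
        if not settling:
            # after exhaustion nothing laid can ever feed; the settling
            # timepoint only converts starved L2s in flight into dauers
            reproduce_step(state)
        counts = state.stage_counts()
        state.peak_dauers = max(state.peak_dauers, int(counts[Stage.DAUER]))
        rows.append(_record_row(state))
        if state.n == 0:
            reason, truncated = "extinct", False
            break
        if settling:
            reason, truncated = "exhausted", False
            break
        fmax = float(state.grid.cells.max())
        if fmax < min_demand:
            settling = True  # one more timepoint: starved L2s become dauers
            continue
        arrested = int(counts[Stage.L1_ARRESTED] + counts[Stage.DAUER])
        if arrested == state.n and fmax < genotype.c_larva:
            reason, truncated = "exhausted", False
            break

    series = pd.DataFrame(rows, columns=_SERIES_COLUMNS)
    null = (state.births == 0 and state.ever_adults == 0 and state.cum_dauers == 0)
    summary = {
        "fitness": state.cum_dauers,
        "null": null,
        "truncated": truncated,
        "termination": reason,
        "t_end": state.clock,
        "cum_dauers": state.cum_dauers,
        "peak_dauers": state.peak_dauers,
        "births": state.births,
        "founders": state.founders,
        "hatched": state.hatched,
        "ever_adults": state.ever_adults,
        "final_population": state.n,
        "deaths": dict(state.deaths),
        "food_initial": state.grid.initial_total,
        "food_remaining": state.grid.remaining,
        "food_consumed_adults": state.grid.consumed["adult"],
        "food_consumed_larvae": state.grid.consumed["larva"],
        "food_conservation_error": state.grid.conservation_error(),
        "genotype": genotype.to_dict(),
        "grid": {"width": grid.width, "height": grid.height,
                 "initial_total": grid.initial_total},
    }
    return RunResult(series=series, summary=summary)
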