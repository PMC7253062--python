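"""Scenario definitions, replicate management and sweep aggregation.

An experiment ("scenario") sweeps a genotype template over an aging-rate
grid (M2 values) crossed with a dispersal-speed grid (cells/day for fed
worms), running seeded replicate colonies in every cell and aggregating
colony fitness (dauer yield) into heatmap matrices, after excluding null
runs in which the founding larva died before establishing a colony.

Replicate seeds derive deterministically from the scenario's base seed and
the (M2 index, dispersal index, replicate index) triple, so sweeps are
reproducible, parallel-safe and independent of execution order.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .engine import RunResult, run_colony
from .environment import DEFAULT_SIGMA, FoodGrid, make_gaussian_patch
from .life_history import (DISPERSAL_GRID, M2_GRID, Genotype,
                           analytic_mean_lifespan)

__all__ = [
    "Scenario",
    "SweepResult",
    "run_sweep",
    "replicate_seed",
    "food_share_series",
    "dauer_fraction",
    "scenario_presets",
    "load_preset",
]

_RUN_COLUMNS = [
    "m2", "dispersal", "replicate", "fitness", "null", "truncated",
    "termination", "t_end", "peak_dauers", "births", "founders", "hatched",
    "ever_adults", "food_consumed_adults", "food_consumed_larvae",
    "adult_share", "dauer_fraction",
]


@dataclass(frozen=True)
class Scenario:
    """A full experiment: genotype template, sweep grids and run settings."""

    name: str
    genotype: Genotype = field(default_factory=Genotype)
    m2_values: tuple = M2_GRID
    dispersal_speeds: tuple = DISPERSAL_GRID
    width: int = 300
    height: int = 300
    total_food: float = 1e6
    sigma: float = DEFAULT_SIGMA
    founders: int = 1
    replicates: int = 100
    base_seed: int = 0
    t_max: int = 100

    def __post_init__(self):
        object.__setattr__(self, "m2_values", tuple(self.m2_values))
        object.__setattr__(self, "dispersal_speeds", tuple(self.dispersal_speeds))
        if not self.m2_values or not self.dispersal_speeds:
            raise ValueError(f"scenario {self.name!r}: sweep lists must be non-empty")
        if self.replicates < 1:
            raise ValueError(f"scenario {self.name!r}: replicates must be >= 1")

    def replace(self, **changes) -> "Scenario":
        return dataclasses.replace(self, **changes)

    def make_grid(self) -> FoodGrid:
        return make_gaussian_patch(self.width, self.height,
                                   self.total_food, self.sigma)

    def cell_genotype(self, m2: float, dispersal: float) -> Genotype:
        """Genotype for one sweep cell: template with M2 and fed-speed set."""
        return self.genotype.replace(M2=m2, s_fed=dispersal / 10.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genotype"] = self.genotype.to_dict()
        d["m2_values"] = list(self.m2_values)
        d["dispersal_speeds"] = list(self.dispersal_speeds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        g = d.get("genotype", {})
        if not isinstance(g, Genotype):
            try:
                d["genotype"] = Genotype.from_dict(g)
            except TypeError as e:
                raise ValueError(f"bad genotype block in scenario config: {e}") from None
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario key(s): {sorted(unknown)}")
        return cls(**d)


def replicate_seed(base_seed: int, m2_index: int, dispersal_index: int,
                   replicate: int) -> np.random.SeedSequence:
    """Deterministic, collision-free seed for one replicate of one cell."""
    return np.random.SeedSequence(base_seed,
                                  spawn_key=(m2_index, dispersal_index, replicate))


def _run_row(result: RunResult, m2: float, dispersal: float, rep: int) -> dict:
    s = result.summary
    consumed = s["food_consumed_adults"] + s["food_consumed_larvae"]
    return {
        "m2": m2, "dispersal": dispersal, "replicate": rep,
        "fitness": s["fitness"], "null": s["null"], "truncated": s["truncated"],
        "termination": s["termination"], "t_end": s["t_end"],
        "peak_dauers": s["peak_dauers"], "births": s["births"],
        "founders": s["founders"], "hatched": s["hatched"],
        "ever_adults": s["ever_adults"],
        "food_consumed_adults": s["food_consumed_adults"],
        "food_consumed_larvae": s["food_consumed_larvae"],
        "adult_share": s["food_consumed_adults"] / consumed if consumed > 0 else math.nan,
        "dauer_fraction": s["fitness"] / s["hatched"] if s["hatched"] > 0 else math.nan,
    }


def _run_cell(scenario: Scenario, i: int, j: int, replicates: int,
              base_grid: Optional[FoodGrid] = None) -> list:
    m2 = scenario.m2_values[i]
    dispersal = scenario.dispersal_speeds[j]
    genotype = scenario.cell_genotype(m2, dispersal)
    if base_grid is None:
        base_grid = scenario.make_grid()
    rows = []
    for r in range(replicates):
        rng = np.random.default_rng(
            replicate_seed(scenario.base_seed, i, j, r))
        result = run_colony(genotype, base_grid, founders=scenario.founders,
                            rng=rng, t_max=scenario.t_max, copy_grid=True)
        rows.append(_run_row(result, m2, dispersal, r))
    return rows


@dataclass
class SweepResult:
    """Per-replicate outcomes of a sweep plus heatmap-style aggregation.

    ``runs`` is a long-format table with one row per replicate per
    (M2, dispersal) cell.  All aggregations average over non-null runs only.
    """

    scenario: Scenario
    runs: pd.DataFrame

    def _nonnull(self) -> pd.DataFrame:
        return self.runs[~self.runs["null"]]

    def _pivot(self, frame: pd.DataFrame, value: str, agg: str) -> pd.DataFrame:
        out = frame.pivot_table(index="m2", columns="dispersal",
                                values=value, aggfunc=agg)
        out = out.reindex(index=list(self.scenario.m2_values),
                          columns=list(self.scenario.dispersal_speeds))
        return out

    def mean_fitness(self) -> pd.DataFrame:
        """Mean dauer yield per cell over non-null replicates (M2 rows,
        dispersal columns); cells whose replicates were all null are NaN."""
        return self._pivot(self._nonnull(), "fitness", "mean")

    def sd_fitness(self) -> pd.DataFrame:
        return self._pivot(self._nonnull(), "fitness", "std")

    def null_counts(self) -> pd.DataFrame:
        return self._pivot(self.runs.assign(is_null=self.runs["null"].astype(int)),
                           "is_null", "sum")

    def mean_adult_share(self) -> pd.DataFrame:
        return self._pivot(self._nonnull(), "adult_share", "mean")

    def mean_dauer_fraction(self) -> pd.DataFrame:
        return self._pivot(self._nonnull(), "dauer_fraction", "mean")

    def all_null_cells(self) -> list:
        """(m2, dispersal) cells in which every replicate was null."""
        m = self.mean_fitness()
        return [(m2, d) for m2 in m.index for d in m.columns
                if pd.isna(m.loc[m2, d])]

    def best_cell(self) -> tuple:
        """(m2, dispersal, mean_fitness) of the fittest heatmap cell."""
        m = self.mean_fitness()
        flat = m.stack()
        if flat.empty:
            raise ValueError("sweep produced no non-null runs")
        (m2, d) = flat.idxmax()
        return (m2, d, float(flat.max()))

    def heatmap_frame(self) -> pd.DataFrame:
        """Mean-fitness matrix with rows labelled by M2 and mean lifespan."""
        m = self.mean_fitness()
        labels = []
        for m2 in m.index:
            g = self.scenario.genotype.replace(M2=m2)
            ls = analytic_mean_lifespan(g)
            labels.append(f"M2={m2:g} ({ls:.1f} d)" if math.isfinite(ls)
                          else f"M2={m2:g} (immortal)")
        out = m.copy()
        out.index = pd.Index(labels, name="aging_rate")
        out.columns = pd.Index([f"dispersal_{d:g}" for d in m.columns])
        return out

    def write(self, outdir) -> None:
        """Write ``runs.csv`` (long) and ``heatmap.csv`` (matrix)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.runs.to_csv(outdir / "runs.csv", index=False)
        self.heatmap_frame().to_csv(outdir / "heatmap.csv")

    def plot_heatmap(self, path) -> None:
        """Render the mean-fitness matrix as a basic heatmap image."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        frame = self.heatmap_frame()
        fig, ax = plt.subplots(figsize=(1 + 0.8 * frame.shape[1],
                                        1 + 0.6 * frame.shape[0]))
        im = ax.imshow(frame.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(frame.shape[1]),
                      [c.replace("dispersal_", "") for c in frame.columns])
        ax.set_yticks(range(frame.shape[0]), frame.index)
        ax.set_xlabel("dispersal speed (cells/day)")
        ax.set_ylabel("aging rate")
        fig.colorbar(im, ax=ax, label="mean dauer yield")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def run_sweep(scenario: Scenario, replicates: Optional[int] = None,
              n_jobs: int = 1, warn_all_null: bool = True) -> SweepResult:
    """Run every (M2, dispersal) cell of a scenario with seeded replicates.

    ``replicates`` overrides the scenario's count (e.g. the fast 20-replicate
    mode).  With ``n_jobs > 1`` cells run in parallel via joblib; outputs are
    identical to the serial ones because each replicate derives its seed from
    (base seed, cell, replicate) alone.
    """
    reps = scenario.replicates if replicates is None else int(replicates)
    if reps < 1:
        raise ValueError("replicates must be >= 1")
    cells = [(i, j) for i in range(len(scenario.m2_values))
             for j in range(len(scenario.dispersal_speeds))]
    if n_jobs != 1:
        from joblib import Parallel, delayed
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(_run_cell)(scenario, i, j, reps) for (i, j) in cells)
    else:
        base_grid = scenario.make_grid()
        chunks = [_run_cell(scenario, i, j, reps, base_grid=base_grid)
                  for (i, j) in cells]
    runs = pd.DataFrame([row for chunk in chunks for row in chunk],
                        columns=_RUN_COLUMNS)
    result = SweepResult(scenario=scenario.replace(replicates=reps), runs=runs)
    if warn_all_null:
        flagged = result.all_null_cells()
        if flagged:
            warnings.warn(f"cells with all-null replicates: {flagged}",
                          stacklevel=2)
    return result


def food_share_series(result: RunResult) -> pd.DataFrame:
    """Per-timepoint adult vs. larval share of cumulative consumed food.

    Shares lie in [0, 1] and sum to 1 wherever any food has been consumed;
    timepoints with nothing consumed yet are NaN (undefined-empty).
    """
    s = result.series
    consumed = s["food_consumed_adults"] + s["food_consumed_larvae"]
    with np.errstate(invalid="ignore", divide="ignore"):
        adult = np.where(consumed > 0, s["food_consumed_adults"] / consumed, np.nan)
    return pd.DataFrame({
        "timepoint": s["timepoint"],
        "adult_share": adult,
        "larva_share": 1.0 - adult,
    })


def dauer_fraction(results: Union[RunResult, Iterable[RunResult]]) -> float:
    """Fraction of all hatched individuals (founders included) that ever
    reached the dauer stage.

    For a single run: ever-dauer count / hatched (NaN when nothing hatched,
    which cannot occur with >= 1 founder).  For an iterable of runs: the mean
    of per-run fractions over non-null runs.
    """
    if isinstance(results, RunResult):
        s = results.summary
        return s["fitness"] / s["hatched"] if s["hatched"] > 0 else math.nan
    fracs = [dauer_fraction(r) for r in results if not r.null]
    fracs = [f for f in fracs if not math.isnan(f)]
    return float(np.mean(fracs)) if fracs else math.nan


# -- named presets --------------------------------------------------------

def _presets_raw() -> dict:
    text = (importlib.resources.files("wormcolony") / "presets" /
            "scenarios.yaml").read_text()
    return yaml.safe_load(text)


def scenario_presets() -> dict:
    """All named experiment configurations, as ``{name: Scenario}``."""
    out = {}
    for name, block in _presets_raw().items():
        block = dict(block)
        block.pop("description", None)
        block.setdefault("name", name)
        out[name] = Scenario.from_dict(block)
    return out


def preset_descriptions() -> dict:
    return {name: block.get("description", "")
            for name, block in _presets_raw().items()}


def load_preset(name: str) -> Scenario:
    """Load one named preset scenario."""
    presets = scenario_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]
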