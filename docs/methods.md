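# Methods

## The model

`wormcolony` simulates a clonal *Caenorhabditis elegans* colony founded by a
single larva on a finite food patch, in discrete daily timepoints on a
W x H cell grid (default 300 x 300). The life cycle is reduced to six
stages: egg (L0), L1, L2, adult, and the two food-arrested branches —
arrested L1s (limited starvation survival, default 6 days) and dauers
(long-lived diapause dispersal larvae, default 30 days of starvation
survival). Colony fitness is the cumulative number of distinct individuals
that ever entered the dauer stage by the time the patch is exhausted: dauers
are the colony's dispersal propagules, so their yield proxies the colony's
capacity to found new colonies (an inclusive-fitness currency, as opposed to
progeny per individual).

Each timepoint applies five steps to the whole population, in order:

1. **Feed.** Worms eat cell by cell in creation order (oldest first; see
   "Within-cell competition" below). A worm whose cell holds at least its
   demand eats it — all or nothing — and is flagged *fed*; otherwise it is
   flagged *starved* and eats nothing. Demands: `c_larva` (default 50
   units/day) for all larval stages, including arrested stages on the day
   they encounter food and resume development; `c_adult` x the optional
   age-dependent consumption schedule (default 1,000 units/day, constant)
   for adults; nothing for eggs. Consumption is ledgered by consumer class
   (adult vs. larva) for the food-share analyses.
2. **Stage.** L0 -> L1. L1 -> L2 if fed, else arrested L1. Arrested L1 ->
   L2 if fed; a starved arrested L1 counts consecutive starved days and dies
   on day `L1s_s`. L2 -> adult (age 0) if fed, else dauer. Dauer -> adult
   (age 0) if fed; a starved dauer dies on starved day `L2s_s`. Adults age
   one day. Entering dauer increments the fitness counter exactly once per
   individual (re-entry is impossible: the post-dauer stage is adult, which
   is absorbing).
3. **Survive.** One Bernoulli draw per worm: eggs never die; L1, arrested
   L1 and L2 die with probability `m_larva` (0.05/day); dauers with
   `m_dauer` (0.005/day); an adult of age *a* with
   `p_death(a) = 1 - M2**(M1 + a)`. With M2 = 1 adults never age.
4. **Move.** Each worm except eggs draws independent per-axis displacements
   uniformly from the integers `[-floor(10 s), +floor(10 s)]`, with
   `s = s_fed` when fed (the dispersal-speed axis of the sweeps, 0.1-0.9 for
   1-9 cells/day) and `s = s_hungry` (0.9) when starved — worms slow down on
   food and roam when hungry. Positions beyond an edge are set to the edge.
5. **Reproduce.** Every live adult of age *a* lays
   `max(0, floor(F1 - F2 * a**2.5))` eggs at its own position, clonally and
   regardless of its fed state. Age counts from 0 on the first adult day,
   so an adult promoted this timepoint lays its full `F1` clutch the same
   day. `F2 = 0` means no reproductive decline;
   `make_schedule(F1, span)` returns the smallest `F2` (= `F1 / span**2.5`)
   whose fecundity is exactly zero from age `span` onward, so
   `(F1, F2) = (n, n)` encodes "n progeny on day 1 only".

The food patch is an isotropic 2D Gaussian centred on the grid, rescaled to
a fixed total (default 1e6 units). Food is conserved exactly: at all times
initial total = remaining + consumed (asserted to 1e-6 relative).

## Termination and null runs

A run ends when (a) the population is extinct, (b) the patch is exhausted —
no cell holds the smallest positive meal any stage could demand, so nothing
can ever feed or resume again — or (c) every survivor is arrested and no
cell can feed them. After detecting exhaustion the engine runs exactly one
settling timepoint *without reproduction*: starved L2s still in flight
become dauers and are counted, but eggs that could never feed are not
created. This pins the hatched-individual denominator of the dauer-fraction
metric to the lifetime of the colony proper. A `t_max` cap (default 100
timepoints) guards non-terminating parameter sets and is recorded as a
truncation. A run is *null* when the founding larva died before anything
was established (no egg laid, no adult matured, no dauer formed); null runs
are excluded from mean-fitness aggregation and reported as counts.

## Mortality and the lifespan estimator

The adult mortality law is shared by the engine and the stand-alone
lifespan estimator, but the day-counting convention is exposed explicitly
because it changes the mean. `estimate_mean_lifespan` defaults to drawing
the first death at exponent `M1 + 1` and counting the day of death as lived;
under M1 = 0.5 this yields mean lifespans of 12.06 days at M2 = 0.99 and
2.41 days at M2 = 0.8 — the two anchor values of the aging-rate grid — and
is the only convention that reproduces both anchors simultaneously (first
draws at `M1 + 0` give 13.0/3.15 or 12.0/2.15 days). Both flags
(`first_draw_age`, `count_death_day`) are parameters and the convention is
echoed in the estimate's metadata. The Monte-Carlo estimate is checked
against the closed-form mean (the summed survival curve
`S(t) = M2**(t*(M1+a0) + t(t-1)/2)`) in the test suite. Inside the colony
engine adults are promoted at age 0 and draw survival from `p_death(0)`
onward, which keeps `fecundity(0) = F1` ("F1 progeny on day 1") consistent
with the staging order.

## Within-cell competition

When several worms share a cell, meals are sequential and all-or-nothing,
so the processing order is a real model choice. The default is creation
order (oldest first): a resident adult claims its 1,000-unit meal before
the larvae crowding around it. This ordering is what gives adult longevity
its cost — sustained adult consumption that starves kin larvae — and with
it the model reproduces the headline yields and their ordering (a
day-1-only brood of 50 out-yields sustained 50/day, ~6,400 vs ~5,800 dauers
at the best grid cell). A randomized order (`feed_order="random"`) is kept
for bias analysis; under it larvae usually strip cells below the adult meal
size before the adults' turns, adult starvation becomes cost-free, and the
fitness landscape loses the short-lifespan optimum.

## The food patch width

The patch width sigma is the one spatial parameter with no published value;
only the grid size and the total are fixed. It is identified from the
reported adult food shares: an adult can only ever eat from cells holding
at least `c_adult`, and the food initially in such cells is
`total - 2*pi*sigma**2*c_adult`. Shares of total consumption by adults up
to ~0.8 under the default rates therefore require sigma ~5 cells on the
1e6-unit patch; at sigma >= 13 the peak cell falls below one adult meal and
adults could never feed at all. The default is sigma = 5.0, with the
flatter/steeper patch variants at x2 and x0.5.

## Experiment harness

A `Scenario` is a genotype template plus the sweep grids: five aging rates
(M2 in {0.99, 0.95, 0.90, 0.85, 0.80}, mean lifespans ~12 to ~2.4 days)
crossed with nine dispersal speeds (1-9 cells/day), 100 replicates per cell
by default (20 in fast mode). Replicate seeds derive from
`SeedSequence(base_seed, spawn_key=(m2_index, dispersal_index, replicate))`,
so sweeps are reproducible, parallel-safe (joblib) and independent of
execution order. Cell means are computed over non-null replicates only;
cells whose replicates were all null are reported as missing and flagged,
never averaged silently. Derived metrics: per-timepoint adult/larval shares
of cumulative consumption, and the dauer fraction — individuals that ever
entered dauer over all individuals hatched, founders included.

Named presets (versioned YAML data, `wormcolony presets`) cover the
scenario families: constant progeny rates 2-50/day; curtailed reproductive
spans (30 progeny over 10 days down to day-1-only broods); day-1-only
broods of 2-50; adult consumption 50-1,000 and larval consumption 25-500;
a precipitous maturational feeding decline (100 % on adult days 1-2, zero
from day 3); and robustness variants (founders 1-7, grids 200-500, patch
halved/x5, patch flattened/steepened).

## Problem sizes and runtime

Full-scale sweeps are 45 cells x 100 replicates per scenario. The package's
own test suite and the acceptance script run the same sweeps at 20
replicates per cell (and the test suite restricts to sub-regions around
each scenario's optimum), which keeps a full scenario sweep to a few
minutes on one core while leaving replicate standard errors of the best
cell mean around 2-4 %. Peak populations reach ~10^5 concurrent worms;
the population is held as struct-of-arrays and the sequential feeding pass
is a numba-compiled kernel over cell-sorted worms, everything else being
vectorized numpy.

## Known limitations

- Within-run variance between replicates is large (single-founder colonies
  are dominated by early stochasticity), so optimum *locations* on the
  heatmap are noisy at 20 replicates even where optimum *values* are
  stable.
- The measured dauer fractions at the most viscous dispersal run below the
  reported reference points (day-1-only ~5-6 % vs 8.5 %; no-decline ~1-2 %
  vs ~3 %). This metric's denominator (every individual ever hatched) is
  highly sensitive to exactly when hatching stops being counted near
  exhaustion; the model counts through the settling timepoint.
- The shift of the optimal aging rate with adult consumption (greed) is
  flat at desk-scale replication for the 4-progeny genotype: with a day-1
  brood, adult longevity has neither strong benefit nor — at 50 units/day —
  strong cost, and the 20-replicate landscape does not separate the rates.
- One genotype per patch: no competition between genotypes, no mutation or
  selection dynamics, no males or outcrossing, no food regrowth, and no
  effect of starvation on adult survival. These are model boundaries, not
  simplifications of implemented features.
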