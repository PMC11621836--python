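# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `hitchsim`, in the order a reader meets them in a run.

## Model and state

The simulator is a discrete-time (one step = one year), individual-based
meta-population model. Individuals carry sex, age, marriage state, a family
handle, a vector of `z` binary neutral cultural variants, and a frozen copy
(`carried_adaptive`) of the adaptive variants of the community they last came
from (set at birth, re-frozen at postmarital migration). Communities carry a
grid cell, three binary adaptive variants shared by all residents, and a
lineage label recording descent from an initial incumbent (A) or migrant (B)
community; the label is inherited unchanged through fission. Dead individuals
remain in the registry (flagged) so end-of-run statistics and genealogical
accounting stay possible.

Internally the population is a growable struct-of-arrays table; the
object-style `Individual` view is materialized on demand. This is purely a
performance choice (runs reach ~10⁴ living individuals) and has no semantic
content.

## Demographic assumptions

* **Mortality** is a piecewise-constant age schedule, loosely shaped on
  ethnographic hunter-gatherer life tables: 0.15/yr for ages 0–5, 0.01 for
  6–40, 0.02 for 41–65, 0.05 for 66–85, and 1 beyond 85. Aging precedes the
  death draw within a step, so a newborn's first draw happens at age 1.
* **Marriage** is strictly exogamous (partners must reside in different
  communities), age-eligible at 18 (read inclusively, to coincide with the
  reproduction window; a strict `>18` reading is available via
  `marriage_age_inclusive=False`), and permanent — widow(er)s never re-enter
  the pool. Matching is a randomized greedy pass: females are shuffled, each
  picks a uniformly random eligible male; unmatched individuals simply try
  again next step. "Community of origin" is read as current residence.
* **Residence** follows `p_location`: the pair settles with the female's
  community at that probability, otherwise the male's; the relocating partner
  freezes `carried_adaptive` to their origin community's current vector at
  departure.
* **Reproduction** gives each married pair with both partners aged 18–45 one
  birth per step with probability `b + Σ f_i·1[a_i=1]` of the residence
  community; `b = 0.3224` reproduces a baseline per-step growth rate of
  roughly 0.008 in this implementation (measured 0.007–0.010 across seeds),
  and `f_i = 0.015` each lifts the all-adaptive lineage to roughly 0.012.
* **Families** are the fission unit: a married pair plus their co-resident
  never-married offspring. Both partners receive a fresh family id at
  marriage; newborns take the mother's. This makes family ids a partition of
  every community.
* **Fission** assigns whole families to two daughters by randomized greedy
  balancing (shuffle families, assign each to the currently smaller daughter,
  ties at random); the larger daughter keeps the parent's cell, the smaller
  takes a uniformly random empty cell, both inherit the adaptive vector and
  lineage. A single indivisible family never splits. With no empty cell the
  run stops (`grid_full`).

## Initialization and burn-in

Initial communities occupy uniformly random distinct cells (no model process
depends on distance; cells are addresses). Individuals get 50:50 random sex
and uniform random integer ages on **[0, 40]**. A wider initial age law (e.g.
uniform to 85) is unworkable here: the first marriage round pairs fertile
adults with elderly partners, remarriage is impossible, and births fall below
deaths before the age structure can equilibrate — communities collapse during
burn-in. A young founding population is also the natural reading of a
colonization scenario; the burn-in owns the final age structure either way.

The 500-step burn-in runs the full demographic machinery — including
exogamous marriage and relocation — but disables resocialization and
adoption, and deletes the new-cell daughter of every fission so the community
count stays at its initial value. Movement during burn-in is culturally null
by construction: at burn-in end every individual's neutral variants and
carried adaptive vector are re-asserted to the founding values of their
community's lineage (all 0 for A, all 1 for B), migration marks are cleared,
counters are zeroed, and the clock resets to 0. A fully closed burn-in
(within-community pairing only) is available via `PhaseConfig`, but in a
10-community world it starves small communities of partners and drifts them
to extinction; it is not used by default.

Even the open burn-in can fail: the population is capped near its initial
size for 500 steps, and initial sex-ratio drift (couples are limited by
`min(females, males)`, and the surplus sex accumulates as an aging
never-married backlog) occasionally spirals a community — or the whole
population — to extinction. The experiment design requires the initial
community set to persist, so `engine.run` conditions on a successful
initialization: on a burn-in extinction it deterministically re-initializes
with a seed derived from `(seed, attempt)`, up to 20 attempts, recording the
count in `RunRecord.burn_in_attempts`. Determinism per `(params, seed)` is
preserved. Roughly a quarter of raw seeds need at least one retry at default
parameters.

## Cultural transmission

Each individual has exactly two learning points: birth and (at most once)
postmarital migration.

* **Vertical**: per trait independently, the newborn copies the mother with
  probability `p_bias`, else the father. Per-trait independence (rather than
  one parent for all traits) is the minimal reading consistent with the
  trait-wise pathway design; at `p_bias ∈ {0,1}` it collapses to strict
  patri-/matrilineal inheritance either way.
* **Resocialization**: per trait with a pathway, independently: with
  probability `p_transmit` the migrant draws a role-model sex (female with
  probability `p_bias`), collects eligible candidates — community members
  within 20 years of age (horizontal) or at least 20 years older (oblique),
  of the drawn sex, excluding the learner — and copies a uniformly chosen
  candidate's variant. An empty candidate set means the migrant keeps the
  natal variant; the event is counted and (optionally) logged. The spouse and
  fellow same-step migrants are eligible like anyone else; same-step migrants
  resocialize in random order, so an earlier-processed migrant can pass on an
  already-updated variant.

The default five-trait set spans the design space: `c1` (no pathway), `c2`
horizontal 0.9, `c3` horizontal 1.0, `c4` oblique 0.9, `c5` oblique 1.0.

## Adoption of adaptive traits

After the migration phase, every community flips each adaptive trait
independently with probability `k^(1−β) / (k^(1−β) + (n−k)^(1−β))`, where `n`
is the living community size and `k` counts residents whose frozen carried
variant disagrees with the community's current one. Decisions within a step
use the censuses taken at the start of the adoption phase.

Numerical care: `k = 0` and `k = n` short-circuit to 0 and 1 before
exponentiation (avoiding `0^(1−β)`), and the interior is evaluated in log
space so `β = −10` cannot overflow; the implementation matches an exact
rational-arithmetic oracle to 12 significant digits up to `n = 10⁴`.

Two deliberate readings, each isolated behind one function so the alternative
is a one-line change: discordance is *cumulative* (every surviving resident
whose frozen vector disagrees counts, not just the step's arrivals — the
community size `n` in the flip probability includes everyone, so `k` is
censused against the same registry), and a community flip does *not*
re-baseline residents' carried vectors, so a flip turns the natal majority
into the discordant class and back-flips are possible. Note the flip
suppression at `β = −10` is a property of the default community scale
(`n_fission = 100`): in toy communities of a few dozen the discordant share
can approach one half, where even `β = −10` flips readily.

## Step order and stopping

Phases run in fixed order: mortality → marriage/migration → resocialization →
adoption → reproduction → fission. The run stops at the first fission attempt
that finds no empty cell (`grid_full`, the normal end of the expansion phase)
or at `max_steps` (default 5000, flagged non-converged; never binding at
default parameters).

## Statistics

* Community types: A = `(0,0,0)`, B = `(1,1,1)`, C = anything partial.
* The hitchhiking signature pools analyzed individuals across communities of
  type A versus type B∪C and reports the per-trait fraction carrying the
  1-variant; at `p_bias = 0` (or 1) only males (females) are analyzed, since
  opposite-sex variants are never transmitted in those regimes. Per-community
  fractions are emitted alongside, so distribution-style summaries remain
  recoverable. End-of-run statistics cover all living individuals at the
  stopping step.
* Growth rates are OLS slopes of log lineage population against time from
  t = 0 to the stop, excluding the final 10% of steps (saturation edge
  effects of the stopping rule).
* The sweep enumerates `β ∈ {−10, 0} × f ∈ {0, 0.005, 0.015} ×
  p_bias ∈ {0, 0.5, 1} × p_location ∈ {0, 0.5}` (36 combinations; the five
  trait pathways are tracked within each run) with per-(combination,
  replicate) seeds derived through `SeedSequence`, so results are invariant
  to execution order and reproducible piecewise. Replicates are summarized by
  medians and interquartile ranges where aggregation is needed.

## Problem sizes used in checks

The test suite and `scripts/acceptance.py` run the full default-scale model
(10×10 grid, 8+2 communities of 70, 500-step burn-in): 5–10 seeds for the
growth-rate estimates and 20 replicates for the lineage-share estimate, with
a handful of reduced worlds (smaller grids, shorter horizons) for mechanical
and determinism checks. A full 125-replicate × 36-combination sweep is a
cluster-scale job and is intentionally not part of the checks.

## What the simulator does and does not show

The model is a theoretical instrument, not a fitted reconstruction: grid
cells carry no geography, there is no carrying capacity (dynamics are studied
during the expansion phase only), migration happens only through exogamous
marriage (no family moves, trade, or drift of whole groups), role models are
chosen uniformly (no conformity, payoff or prestige bias), and adoption of
adaptive traits is symmetric — a community is as likely to drop the
beneficial variant as to gain it at equal discordance. Passing checks
demonstrate the internal logic of hitchhiking under these assumptions; they
say nothing about any particular archaeological case.
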