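"""Run orchestration: per-step phase ordering, burn-in protocol, stopping.

A main-phase step applies, in fixed order: (1) aging & mortality, (2)
marriage-pool formation, pairing and postmarital migration, (3)
resocialization of this step's migrants, (4) community-level adoption of
adaptive traits, (5) reproduction with vertical transmission, (6) fission.
The burn-in protocol disables resocialization and adoption and deletes the
new-cell daughter of every fission so the community count stays fixed;
marriage (with relocation) and reproduction run normally, which keeps the
communities demographically open and stable. Burn-in movement is culturally
null: afterwards all neutral and carried variants are re-asserted from each
community's founding lineage values and the clock resets to zero. (A fully
closed burn-in — pairing within communities only — starves small communities
of partners and drifts them to extinction; it remains available via
``PhaseConfig(migration=False)``.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import adoption, demography, transmission
from .params import SimulationParams
from .world import LINEAGE_A, LINEAGE_B, World, init_world

COMMUNITY_TYPES = ("A", "B", "C")
LINEAGES = (LINEAGE_A, LINEAGE_B)


class BurnInExtinctionError(RuntimeError):
    """A community died out during burn-in; the run cannot be initialized."""


@dataclass(frozen=True)
class PhaseConfig:
    """Which step phases are active (burn-in and diagnostics switch these)."""

    migration: bool = True  # cross-community marriage + relocation
    resocialization: bool = True
    adoption: bool = True
    reproduction: bool = True
    fission: bool = True
    remove_new_on_fission: bool = False  # burn-in: delete the new-cell daughter


MAIN_PHASES = PhaseConfig()
BURN_IN_PHASES = PhaseConfig(
    resocialization=False, adoption=False, remove_new_on_fission=True,
)


@dataclass
class RunRecord:
    """Everything a finished run produced: series, counters, final world."""

    params: SimulationParams
    seed: int
    series: pd.DataFrame
    world: World
    stop_reason: str
    counters: dict[str, int]
    converged: bool
    burn_in_attempts: int = 1

    @property
    def n_steps(self) -> int:
        return int(self.series["t"].iloc[-1]) if len(self.series) else 0


def _community_type(adaptive: np.ndarray) -> str:
    s = int(adaptive.sum())
    if s == 0:
        return "A"
    if s == len(adaptive):
        return "B"
    return "C"


def _series_row(world: World) -> dict:
    p = world.people
    living = world.living_indices()
    comm_of = p.community[living]
    lineage_of = {cid: c.lineage for cid, c in world.communities.items()}
    pop = {lin: 0 for lin in LINEAGES}
    sizes = np.bincount(comm_of, minlength=world._next_community_id) if len(living) else None
    row = {"t": world.t}
    for cid, c in world.communities.items():
        if sizes is not None:
            pop[c.lineage] += int(sizes[cid]) if cid < len(sizes) else 0
    row["pop_linA"] = pop[LINEAGE_A]
    row["pop_linB"] = pop[LINEAGE_B]
    counts = {(ty, lin): 0 for ty in COMMUNITY_TYPES for lin in LINEAGES}
    for c in world.communities.values():
        counts[(_community_type(c.adaptive), c.lineage)] += 1
    for ty in COMMUNITY_TYPES:
        for lin in LINEAGES:
            row[f"comm_{ty}_lin{lin}"] = counts[(ty, lin)]
    return row


def step(world: World, phases: PhaseConfig = MAIN_PHASES) -> None:
    """Advance the world by one time step (see module docstring for order)."""
    if world.stopped:
        raise RuntimeError(f"world already stopped ({world.stopped})")
    rng = world.rng

    demography.step_age_and_mortality(world)

    pool = demography.form_marriage_pool(world)
    pairs = demography.match_pairs(
        pool, world, same_community=not phases.migration
    )
    movers: list[int] = []
    for pair in pairs:
        mover = demography.settle_pair(pair, world)
        if mover is not None:
            movers.append(mover)

    if phases.resocialization and movers:
        order = rng.permutation(len(movers))
        for i in order:
            transmission.resocialize(movers[i], world)

    if phases.adoption:
        adoption.adoption_step(world)

    if phases.reproduction:
        demography.reproduce(world)

    if phases.fission:
        demography.fission_check(
            world, remove_new=phases.remove_new_on_fission
        )

    world.t += 1


def run_burn_in(world: World) -> None:
    """Equilibrate the age/family structure, then reset culture and clock.

    Runs ``burn_in_steps`` restricted steps (no resocialization or adoption;
    new fission daughters removed; marriage and relocation run normally and
    are culturally null). Any community extinction aborts with a diagnostic.
    Afterwards every living
    individual's neutral variants and carried adaptive vector are re-set to
    their community's founding lineage values (all-0 for lineage A, all-1 for
    lineage B), migration marks are cleared, counters zeroed, and t returns
    to 0.
    """
    p = world.people
    for _ in range(world.params.burn_in_steps):
        step(world, BURN_IN_PHASES)
        sizes = world.community_sizes()
        extinct = [cid for cid, s in sizes.items() if s == 0]
        if extinct:
            raise BurnInExtinctionError(
                f"community {extinct} extinct at burn-in step {world.t}"
            )
    by_comm = world.members_by_community()
    for cid, members in by_comm.items():
        c = world.communities[cid]
        founding = 1 if c.lineage == LINEAGE_B else 0
        p.neutral[members] = founding
        p.carried[members] = c.adaptive  # unchanged during burn-in
    p.migrated_at[: p.n] = -1
    world.t = 0
    for k in world.counters:
        world.counters[k] = 0


def _retry_seed(seed: int, attempt: int) -> int:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5EED, attempt])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run(
    params: SimulationParams,
    step_callback: Optional[Callable[[World], None]] = None,
    log_events: bool = False,
    burn_in_attempts: int = 20,
) -> RunRecord:
    """Full protocol: init -> burn-in -> step until the grid fills.

    The experiment conditions on all initial communities surviving burn-in
    (the design requires the initial community set to persist): if a burn-in
    ends in extinction — possible through sex-ratio drift in the small capped
    population — the run deterministically re-initializes with a seed derived
    from (seed, attempt), up to ``burn_in_attempts`` times, then re-raises.
    Identical (params, seed) therefore still yields an identical RunRecord.
    ``step_callback`` is invoked after every main-phase step (for invariant
    monitoring); ``log_events`` keeps the per-event resocialization log on
    the world.
    """
    attempts = 0
    while True:
        attempts += 1
        world_seed = params.seed if attempts == 1 else _retry_seed(params.seed, attempts)
        world = init_world(params.replace(seed=world_seed))
        try:
            run_burn_in(world)
            break
        except BurnInExtinctionError:
            if attempts >= burn_in_attempts:
                raise
    if log_events:
        world.record_events(True)
    rows = [_series_row(world)]
    while not world.stopped and world.t < params.max_steps:
        step(world)
        rows.append(_series_row(world))
        if step_callback is not None:
            step_callback(world)
    stop_reason = world.stopped or "max_steps"
    return RunRecord(
        params=params,
        seed=params.seed,
        series=pd.DataFrame(rows),
        world=world,
        stop_reason=stop_reason,
        counters=dict(world.counters),
        converged=stop_reason == "grid_full",
        burn_in_attempts=attempts,
    )
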