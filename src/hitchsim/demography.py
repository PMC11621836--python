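"""Demographic processes: aging, mortality, marriage, migration, reproduction,
and community fission.

Each time step individuals age by one year and then face an age-dependent
death draw. All never-married adults enter a common marriage pool and are
paired at random with someone of the opposite sex from a different community;
the new pair settles in the female's community with probability ``p_location``
(patrilocality = 0, bilocality = 0.5, matrilocality = 1), the other partner
relocating. Married pairs with both partners aged 18–45 produce one offspring
per step with probability ``b + Σ f_i·1[a_i=1]`` of the residence community.
Communities reaching ``n_fission`` split into two, assigning whole families to
daughters by randomized greedy balancing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import FEMALE, MALE, SimulationParams
from .world import World
from . import transmission


@dataclass
class MarriagePair:
    """An exogamous match before/after residence settlement."""

    female_id: int
    male_id: int
    origin_female: int
    origin_male: int
    residence: Optional[int] = None
    mover_id: Optional[int] = None


def death_probability(age: int, schedule) -> float:
    """Piecewise-constant mortality lookup; bands inclusive of both endpoints."""
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    for upper, p in schedule:
        if upper is None or age <= upper:
            return p
    raise ValueError("death schedule has no open-ended band")


def _death_probs_vector(ages: np.ndarray, schedule) -> np.ndarray:
    uppers = np.array([u for u, _ in schedule[:-1]], dtype=np.int64)
    probs = np.array([p for _, p in schedule], dtype=np.float64)
    idx = np.searchsorted(uppers, ages, side="left")
    return probs[idx]


def step_age_and_mortality(world: World) -> None:
    """Age every living individual by one year, then apply the death draw.

    A decedent's surviving spouse becomes a widow(er): the spouse link is
    cleared but ``ever_married`` stays set — there is no remarriage. The dead
    leave their community's membership but stay in the registry.
    """
    p = world.people
    living = world.living_indices()
    if len(living) == 0:
        return
    p.age[living] += 1
    probs = _death_probs_vector(p.age[living], world.params.death_schedule)
    u = world.rng.random(len(living))
    dead = living[u < probs]
    if len(dead) == 0:
        return
    p.alive[dead] = False
    world.counters["deaths"] += len(dead)
    spouses = p.spouse[dead]
    spouses = spouses[spouses >= 0]
    p.spouse[spouses] = -1  # widow(er)s; covers both-partners-die too
    p.spouse[dead] = -1


def form_marriage_pool(world: World) -> np.ndarray:
    """Living, never-married individuals at or above the marriage age."""
    p = world.people
    prm = world.params
    min_age = prm.marriage_age_min if prm.marriage_age_inclusive else prm.marriage_age_min + 1
    mask = p.alive[: p.n] & ~p.ever_married[: p.n] & (p.age[: p.n] >= min_age)
    return np.flatnonzero(mask)


def match_pairs(
    pool: np.ndarray,
    world: World,
    rng: Optional[np.random.Generator] = None,
    same_community: bool = False,
) -> list[MarriagePair]:
    """Randomized greedy matching of the marriage pool.

    Females are shuffled uniformly; each in turn picks a uniformly random
    eligible male (opposite sex, not yet matched, and — except during burn-in —
    a different current community). Unmatched individuals simply stay in the
    pool for the next step.
    """
    rng = world.rng if rng is None else rng
    p = world.people
    if len(pool) == 0:
        return []
    females = pool[p.sex[pool] == FEMALE]
    males = pool[p.sex[pool] == MALE]
    if len(females) == 0 or len(males) == 0:
        return []
    female_order = females[rng.permutation(len(females))]
    male_comm = p.community[males]
    taken = np.zeros(len(males), dtype=bool)
    pairs: list[MarriagePair] = []
    for f in female_order:
        fc = p.community[f]
        if same_community:
            eligible = np.flatnonzero(~taken & (male_comm == fc))
        else:
            eligible = np.flatnonzero(~taken & (male_comm != fc))
        if len(eligible) == 0:
            continue
        j = eligible[rng.integers(len(eligible))]
        taken[j] = True
        pairs.append(
            MarriagePair(
                female_id=int(f),
                male_id=int(males[j]),
                origin_female=int(fc),
                origin_male=int(male_comm[j]),
            )
        )
    return pairs


def settle_pair(
    pair: MarriagePair, world: World, rng: Optional[np.random.Generator] = None
) -> Optional[int]:
    """Marry the pair and decide residence; returns the mover's id (if any).

    With probability ``p_location`` the pair resides in the female's community
    (the male relocates), otherwise in the male's. The mover leaves their old
    community, freezes ``carried_adaptive`` to the origin community's current
    a-vector at departure, and records ``migrated_at`` for resocialization.
    Both partners join a fresh family unit.
    """
    rng = world.rng if rng is None else rng
    p = world.people
    f, m = pair.female_id, pair.male_id
    if rng.random() < world.params.p_location:
        pair.residence = pair.origin_female
        mover = m
    else:
        pair.residence = pair.origin_male
        mover = f
    p.spouse[f] = m
    p.spouse[m] = f
    p.ever_married[f] = True
    p.ever_married[m] = True
    fid = world.new_family_id()
    p.family[f] = fid
    p.family[m] = fid
    world.counters["marriages"] += 1
    if p.community[mover] == pair.residence:
        pair.mover_id = None
        return None
    origin = world.communities[int(p.community[mover])]
    p.carried[mover] = origin.copy_adaptive()
    p.community[mover] = pair.residence
    p.migrated_at[mover] = world.t
    pair.mover_id = int(mover)
    world.counters["migrations"] += 1
    return int(mover)


def birth_probability(params: SimulationParams, adaptive: np.ndarray) -> float:
    """Per-pair per-step birth probability: b plus the adaptive-trait bonuses."""
    bonus = float(np.dot(np.asarray(adaptive, dtype=float), params.fitness_bonuses))
    return params.b + bonus


def reproduce(world: World, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One birth draw per fertile married pair; returns the newborn ids.

    Fertile = both partners alive and aged within the reproduction window.
    Newborns get random sex, age 0, the pair's family and residence community,
    the community's current a-vector as their carried adaptive variants, and
    neutral variants via per-trait vertical transmission (mother's variant
    with probability ``p_bias``, else father's).
    """
    rng = world.rng if rng is None else rng
    p = world.people
    prm = world.params
    lo, hi = prm.reproduction_age_min, prm.reproduction_age_max

    fem = np.flatnonzero(
        p.alive[: p.n]
        & (p.sex[: p.n] == FEMALE)
        & (p.spouse[: p.n] >= 0)
        & (p.age[: p.n] >= lo)
        & (p.age[: p.n] <= hi)
    )
    if len(fem) == 0:
        return np.empty(0, dtype=np.int64)
    husbands = p.spouse[fem]
    ok = p.alive[husbands] & (p.age[husbands] >= lo) & (p.age[husbands] <= hi)
    fem, husbands = fem[ok], husbands[ok]
    if len(fem) == 0:
        return np.empty(0, dtype=np.int64)

    probs = np.array(
        [birth_probability(prm, world.communities[int(c)].adaptive) for c in p.community[fem]]
    )
    births = rng.random(len(fem)) < probs
    mothers, fathers = fem[births], husbands[births]
    nb = len(mothers)
    if nb == 0:
        return np.empty(0, dtype=np.int64)

    sexes = rng.integers(0, 2, size=nb).astype(np.uint8)
    neutral = transmission.vertical_transmit_batch(
        p.neutral[mothers], p.neutral[fathers], prm.p_bias, rng
    )
    comm = p.community[mothers]
    carried = np.stack([world.communities[int(c)].copy_adaptive() for c in comm])
    ids = p.add(
        nb,
        sex=sexes,
        age=0,
        community=comm,
        natal=comm,
        family=p.family[mothers],
        neutral=neutral,
        carried=carried,
        mother=mothers,
        father=fathers,
    )
    world.counters["births"] += nb
    return ids


def _split_families(
    members: np.ndarray, families: np.ndarray, rng: np.random.Generator
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Randomized greedy balance of whole families into two groups.

    Families are visited in random order and each is assigned to the currently
    smaller group (ties broken at random). Returns (keep, move) member index
    arrays, or None if there are fewer than two families.
    """
    uniq, inverse, counts = np.unique(families, return_inverse=True, return_counts=True)
    if len(uniq) < 2:
        return None
    order = rng.permutation(len(uniq))
    sizes = [0, 0]
    assign = np.zeros(len(uniq), dtype=np.int8)
    for fi in order:
        if sizes[0] < sizes[1]:
            g = 0
        elif sizes[1] < sizes[0]:
            g = 1
        else:
            g = int(rng.integers(2))
        assign[fi] = g
        sizes[g] += int(counts[fi])
    group = assign[inverse]
    g0, g1 = members[group == 0], members[group == 1]
    if len(g0) >= len(g1):
        keep, move = g0, g1
    elif len(g1) > len(g0):
        keep, move = g1, g0
    return keep, move


def fission_check(
    world: World,
    rng: Optional[np.random.Generator] = None,
    remove_new: bool = False,
) -> None:
    """Split every community at or above the fission threshold.

    The larger daughter keeps the parent's cell; the smaller takes a uniformly
    random empty cell, inheriting the parent's adaptive vector and lineage.
    If the grid has no empty cell the simulation stops (``grid_full``) and the
    community stays intact. With ``remove_new`` (burn-in mode) the would-be
    new-cell daughter is deleted instead, holding the community count fixed.
    """
    rng = world.rng if rng is None else rng
    p = world.people
    by_comm = world.members_by_community()
    over = [cid for cid in sorted(by_comm) if len(by_comm[cid]) >= world.params.n_fission]
    if not over:
        return
    over = [over[i] for i in rng.permutation(len(over))]
    for cid in over:
        members = by_comm[cid]
        split = _split_families(members, p.family[members], rng)
        if split is None:
            continue  # a single indivisible family cannot fission
        keep, move = split
        if remove_new:
            p.alive[move] = False
            spouses = p.spouse[move]
            spouses = spouses[spouses >= 0]
            p.spouse[spouses] = -1
            p.spouse[move] = -1
            continue
        empty = world.empty_cells()
        if not empty:
            world.stopped = "grid_full"
            return
        cell = empty[rng.integers(len(empty))]
        parent = world.communities[cid]
        daughter = world.add_community(cell, parent.copy_adaptive(), parent.lineage)
        p.community[move] = daughter.id
        world.counters["fissions"] += 1
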