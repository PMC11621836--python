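"""Cultural transmission of neutral traits.

Two learning points per lifetime: vertical transmission at birth (per trait,
the child copies the mother with probability ``p_bias``, else the father) and
postmarital resocialization for migrants. After relocating, a migrant attempts
— per trait, independently, with probability ``p_transmit`` — to copy the
variant of a role model drawn uniformly from the destination community's
eligible pool: peers within 20 years of age (horizontal) or individuals at
least 20 years older (oblique), filtered to females with probability
``p_bias`` and males otherwise. If no eligible role model of the drawn sex
exists, the migrant keeps the variant learned at birth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import FEMALE, MALE, TraitConfig
from .world import World


@dataclass(frozen=True)
class ResocializationEvent:
    """One per-trait learning attempt by a migrant (kept when logging is on)."""

    t: int
    learner_id: int
    trait_id: int
    pathway: str
    model_sex: int
    outcome: str  # "copied" | "no_candidate"
    source_id: Optional[int]  # role model id when copied


@dataclass(frozen=True)
class RoleModelQuery:
    """A candidate search: who may this learner copy this trait from?"""

    learner_id: int
    trait: TraitConfig
    community_id: int
    sex_filter: str  # "female" | "male" | "any"
    pathway: str  # "horizontal" | "oblique"


def vertical_transmit(
    mother_variants, father_variants, p_bias: float, rng: np.random.Generator
) -> np.ndarray:
    """Newborn's neutral-variant vector: per trait, mother's copy w.p. p_bias."""
    mother = np.asarray(mother_variants, dtype=np.uint8)
    father = np.asarray(father_variants, dtype=np.uint8)
    from_mother = rng.random(mother.shape[-1]) < p_bias
    return np.where(from_mother, mother, father).astype(np.uint8)


def vertical_transmit_batch(
    mothers: np.ndarray, fathers: np.ndarray, p_bias: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized vertical transmission for a batch of births (rows = children)."""
    from_mother = rng.random(mothers.shape) < p_bias
    return np.where(from_mother, mothers, fathers).astype(np.uint8)


def eligible_role_models(query: RoleModelQuery, world: World) -> np.ndarray:
    """Living community members satisfying the pathway's age rule and sex filter.

    Horizontal: absolute age difference below the generation gap (20 y).
    Oblique: at least one generation gap older. The learner is excluded; the
    spouse and fellow same-step migrants are eligible like anyone else.
    """
    p = world.people
    gap = world.params.generation_gap
    cand = world.members(query.community_id)
    cand = cand[cand != query.learner_id]
    if len(cand) == 0:
        return cand
    learner_age = p.age[query.learner_id]
    diff = p.age[cand].astype(np.int64) - int(learner_age)
    if query.pathway == "horizontal":
        cand = cand[np.abs(diff) < gap]
    elif query.pathway == "oblique":
        cand = cand[diff >= gap]
    else:
        raise ValueError(f"unknown pathway {query.pathway!r}")
    if query.sex_filter == "female":
        cand = cand[p.sex[cand] == FEMALE]
    elif query.sex_filter == "male":
        cand = cand[p.sex[cand] == MALE]
    elif query.sex_filter != "any":
        raise ValueError(f"unknown sex filter {query.sex_filter!r}")
    return cand


def resocialize(
    migrant_id: int, world: World, rng: Optional[np.random.Generator] = None
) -> None:
    """Postmarital social learning for one freshly relocated migrant.

    Per trait with a transmission pathway: with probability ``p_transmit``
    draw a role-model sex (female w.p. ``p_bias``), search the destination
    community, and copy a uniformly chosen candidate's variant. Runs at most
    once per lifetime since remarriage is impossible.
    """
    rng = world.rng if rng is None else rng
    p = world.people
    prm = world.params
    community_id = int(p.community[migrant_id])
    for j, trait in enumerate(prm.trait_configs):
        if trait.pathway == "none":
            continue
        if rng.random() >= trait.p_transmit:
            continue
        world.counters["resoc_attempted"] += 1
        model_sex = FEMALE if rng.random() < prm.p_bias else MALE
        query = RoleModelQuery(
            learner_id=migrant_id,
            trait=trait,
            community_id=community_id,
            sex_filter="female" if model_sex == FEMALE else "male",
            pathway=trait.pathway,
        )
        cand = eligible_role_models(query, world)
        if len(cand) == 0:
            world.counters["resoc_no_candidate"] += 1
            if world.event_log is not None:
                world.event_log.append(
                    ResocializationEvent(
                        world.t, int(migrant_id), trait.trait_id, trait.pathway,
                        model_sex, "no_candidate", None,
                    )
                )
            continue
        src = int(cand[rng.integers(len(cand))])
        p.neutral[migrant_id, j] = p.neutral[src, j]
        world.counters["resoc_succeeded"] += 1
        if world.event_log is not None:
            world.event_log.append(
                ResocializationEvent(
                    world.t, int(migrant_id), trait.trait_id, trait.pathway,
                    model_sex, "copied", src,
                )
            )
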