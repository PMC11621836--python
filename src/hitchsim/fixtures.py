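"""Deterministic miniature worlds for tests and demos.

Each fixture is hand-built (no burn-in, fixed ages/sexes) so expected values
are enumerable by inspection. Catalogue:

``two_communities``
    One lineage-A community (all-0 variants) and one lineage-B community
    (all-1), six members each with fixed ages/sexes.
``lonely_migrant``
    A migrant female who is the only living member of her destination
    community — every resocialization attempt finds no role model.
``fission_ready``
    A single community exactly at the fission threshold, partitioned into
    three known four-member families, with empty grid cells available.
"""

from __future__ import annotations

import numpy as np

from .params import FEMALE, MALE, SimulationParams, default_trait_configs
from .world import LINEAGE_A, LINEAGE_B, World

CATALOGUE = ("two_communities", "lonely_migrant", "fission_ready")

_AGES = (10, 25, 30, 45, 50, 70)
_SEXES = (FEMALE, MALE, FEMALE, MALE, FEMALE, MALE)


def _base_params(**kw) -> SimulationParams:
    defaults = dict(
        grid_width=3, grid_height=3, n_incumbent=1, n_migrant=1,
        initial_community_size=6, burn_in_steps=0, n_fission=50, seed=0,
    )
    defaults.update(kw)
    return SimulationParams(**defaults)


def _two_communities() -> World:
    params = _base_params()
    world = World(params)
    for k, (cell, lineage) in enumerate([((0, 0), LINEAGE_A), ((1, 0), LINEAGE_B)]):
        variant = 0 if lineage == LINEAGE_A else 1
        comm = world.add_community(cell, np.full(3, variant, np.uint8), lineage)
        fams = np.array([world.new_family_id() for _ in _AGES], np.int32)
        world.people.add(
            len(_AGES),
            sex=np.array(_SEXES, np.uint8),
            age=np.array(_AGES, np.int32),
            community=comm.id,
            natal=comm.id,
            family=fams,
            neutral=np.full((len(_AGES), params.z), variant, np.uint8),
            carried=np.full((len(_AGES), 3), variant, np.uint8),
        )
    return world


def _lonely_migrant() -> World:
    params = _base_params()
    world = World(params)
    origin = world.add_community((0, 0), np.zeros(3, np.uint8), LINEAGE_A)
    dest = world.add_community((1, 0), np.ones(3, np.uint8), LINEAGE_B)
    # a few stay-at-homes in the origin community
    fams = np.array([world.new_family_id() for _ in range(3)], np.int32)
    world.people.add(
        3,
        sex=np.array([MALE, FEMALE, MALE], np.uint8),
        age=np.array([40, 35, 22], np.int32),
        community=origin.id, natal=origin.id, family=fams,
        neutral=np.zeros((3, params.z), np.uint8),
        carried=np.zeros((3, 3), np.uint8),
    )
    # the migrant: female, 20, alone in the destination community (widowed)
    mid = world.people.add(
        1,
        sex=FEMALE, age=20, community=dest.id, natal=origin.id,
        family=world.new_family_id(),
        neutral=np.zeros((1, params.z), np.uint8),
        carried=np.zeros((1, 3), np.uint8),
    )[0]
    world.people.ever_married[mid] = True
    world.people.migrated_at[mid] = 0
    return world


def _fission_ready() -> World:
    n_fission = 12
    params = _base_params(initial_community_size=8, n_fission=n_fission)
    world = World(params)
    comm = world.add_community((0, 0), np.zeros(3, np.uint8), LINEAGE_A)
    for _ in range(3):  # three families of four
        fid = world.new_family_id()
        world.people.add(
            4,
            sex=np.array([MALE, FEMALE, FEMALE, MALE], np.uint8),
            age=np.array([40, 38, 12, 9], np.int32),
            community=comm.id, natal=comm.id, family=fid,
            neutral=np.zeros((4, params.z), np.uint8),
            carried=np.zeros((4, 3), np.uint8),
        )
    return world


_BUILDERS = {
    "two_communities": _two_communities,
    "lonely_migrant": _lonely_migrant,
    "fission_ready": _fission_ready,
}


def make_fixture(name: str) -> World:
    """Build a catalogue fixture; unknown names raise with the catalogue listed."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; catalogue: {', '.join(CATALOGUE)}"
        ) from None
    return builder()
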