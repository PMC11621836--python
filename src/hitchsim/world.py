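"""World state: communities on a grid and a columnar registry of individuals.

Individuals live in a struct-of-arrays table (``PeopleTable``) for speed;
``World.individual(i)`` materializes a read-only snapshot when object-style
access is convenient (tests, debugging). Dead individuals stay in the registry
(``alive=False``) so end-of-run statistics and genealogies remain available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .params import FEMALE, MALE, SimulationParams, validate_params

LINEAGE_A = "A"
LINEAGE_B = "B"


class ConfigurationError(ValueError):
    """Raised when SimulationParams violate a structural invariant."""


@dataclass
class Community:
    """A grid-located group carrying community-level adaptive variants.

    ``adaptive`` is the shared a-vector (all residents express the same
    variants); ``lineage`` records descent from an initial incumbent (A) or
    migrant (B) community and is inherited unchanged through fission.
    """

    id: int
    location: tuple[int, int]
    adaptive: np.ndarray  # shape (3,), uint8
    lineage: str

    def copy_adaptive(self) -> np.ndarray:
        return self.adaptive.copy()


@dataclass(frozen=True)
class Individual:
    """Read-only snapshot of one individual (see ``World.individual``)."""

    id: int
    sex: int
    age: int
    alive: bool
    community_id: int
    natal_community_id: int
    spouse_id: Optional[int]
    ever_married: bool
    family_id: int
    neutral_variants: tuple
    carried_adaptive: tuple
    migrated_at: Optional[int]
    mother_id: Optional[int]
    father_id: Optional[int]


class PeopleTable:
    """Growable struct-of-arrays store for individuals."""

    _SCALARS = (
        ("sex", np.uint8),
        ("age", np.int32),
        ("alive", np.bool_),
        ("community", np.int32),
        ("natal", np.int32),
        ("spouse", np.int32),
        ("ever_married", np.bool_),
        ("family", np.int32),
        ("migrated_at", np.int32),
        ("mother", np.int32),
        ("father", np.int32),
    )

    def __init__(self, z: int, capacity: int = 1024):
        self.z = z
        self.n = 0
        self._cap = capacity
        for name, dt in self._SCALARS:
            setattr(self, name, np.zeros(capacity, dtype=dt))
        self.neutral = np.zeros((capacity, z), dtype=np.uint8)
        self.carried = np.zeros((capacity, 3), dtype=np.uint8)

    def _ensure(self, extra: int) -> None:
        need = self.n + extra
        if need <= self._cap:
            return
        new_cap = self._cap
        while new_cap < need:
            new_cap *= 2
        for name, _ in self._SCALARS:
            old = getattr(self, name)
            grown = np.zeros(new_cap, dtype=old.dtype)
            grown[: self.n] = old[: self.n]
            setattr(self, name, grown)
        for name in ("neutral", "carried"):
            old = getattr(self, name)
            grown = np.zeros((new_cap, old.shape[1]), dtype=old.dtype)
            grown[: self.n] = old[: self.n]
            setattr(self, name, grown)
        self._cap = new_cap

    def add(self, count, *, sex, age, community, natal, family,
            neutral, carried, mother=-1, father=-1) -> np.ndarray:
        """Append ``count`` individuals; returns their ids (row indices)."""
        self._ensure(count)
        ids = np.arange(self.n, self.n + count)
        self.sex[ids] = sex
        self.age[ids] = age
        self.alive[ids] = True
        self.community[ids] = community
        self.natal[ids] = natal
        self.spouse[ids] = -1
        self.ever_married[ids] = False
        self.family[ids] = family
        self.migrated_at[ids] = -1
        self.mother[ids] = mother
        self.father[ids] = father
        self.neutral[ids] = neutral
        self.carried[ids] = carried
        self.n += count
        return ids


class World:
    """Full simulation state: grid, communities, individuals, clock, RNG."""

    def __init__(self, params: SimulationParams, rng: Optional[np.random.Generator] = None):
        self.params = params
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        self.people = PeopleTable(params.z)
        self.communities: dict[int, Community] = {}
        self.grid: dict[tuple[int, int], int] = {}
        self.t = 0
        self.stopped: Optional[str] = None
        self.counters: dict[str, int] = {
            k: 0
            for k in (
                "births", "deaths", "marriages", "migrations",
                "resoc_attempted", "resoc_succeeded", "resoc_no_candidate",
                "adoptions", "fissions",
            )
        }
        self.event_log: Optional[list] = None  # enable via record_events()
        self._next_community_id = 0
        self._next_family_id = 0

    # -- bookkeeping -----------------------------------------------------
    def record_events(self, on: bool = True) -> None:
        """Switch per-event resocialization logging (learner, trait, outcome)."""
        self.event_log = [] if on else None

    def new_family_id(self) -> int:
        fid = self._next_family_id
        self._next_family_id += 1
        return fid

    def add_community(self, location, adaptive, lineage) -> Community:
        if location in self.grid:
            raise ValueError(f"cell {location} already occupied")
        cid = self._next_community_id
        self._next_community_id += 1
        comm = Community(cid, tuple(location), np.asarray(adaptive, dtype=np.uint8).copy(), lineage)
        self.communities[cid] = comm
        self.grid[comm.location] = cid
        return comm

    def empty_cells(self) -> list[tuple[int, int]]:
        """Unoccupied grid cells in deterministic (row-major) order."""
        p = self.params
        return [
            (x, y)
            for x in range(p.grid_width)
            for y in range(p.grid_height)
            if (x, y) not in self.grid
        ]

    # -- queries ---------------------------------------------------------
    def living_indices(self) -> np.ndarray:
        return np.flatnonzero(self.people.alive[: self.people.n])

    def members(self, community_id: int) -> np.ndarray:
        p = self.people
        mask = p.alive[: p.n] & (p.community[: p.n] == community_id)
        return np.flatnonzero(mask)

    def members_by_community(self) -> dict[int, np.ndarray]:
        """One-pass grouping of living individuals by community id."""
        living = self.living_indices()
        comm = self.people.community[living]
        order = np.argsort(comm, kind="stable")
        living, comm = living[order], comm[order]
        out: dict[int, np.ndarray] = {cid: np.empty(0, dtype=np.int64) for cid in self.communities}
        if len(living):
            cids, starts = np.unique(comm, return_index=True)
            bounds = list(starts) + [len(living)]
            for i, cid in enumerate(cids):
                out[int(cid)] = living[bounds[i]: bounds[i + 1]]
        return out

    def community_sizes(self) -> dict[int, int]:
        return {cid: len(ids) for cid, ids in self.members_by_community().items()}

    def individual(self, i: int) -> Individual:
        p = self.people
        if not (0 <= i < p.n):
            raise KeyError(i)
        return Individual(
            id=i,
            sex=int(p.sex[i]),
            age=int(p.age[i]),
            alive=bool(p.alive[i]),
            community_id=int(p.community[i]),
            natal_community_id=int(p.natal[i]),
            spouse_id=int(p.spouse[i]) if p.spouse[i] >= 0 else None,
            ever_married=bool(p.ever_married[i]),
            family_id=int(p.family[i]),
            neutral_variants=tuple(int(v) for v in p.neutral[i]),
            carried_adaptive=tuple(int(v) for v in p.carried[i]),
            migrated_at=int(p.migrated_at[i]) if p.migrated_at[i] >= 0 else None,
            mother_id=int(p.mother[i]) if p.mother[i] >= 0 else None,
            father_id=int(p.father[i]) if p.father[i] >= 0 else None,
        )

    # -- state dumps (determinism checks, archives) ----------------------
    def individuals_frame(self) -> pd.DataFrame:
        p = self.people
        n = p.n
        df = pd.DataFrame(
            {name: getattr(p, name)[:n].copy() for name, _ in PeopleTable._SCALARS}
        )
        df.insert(0, "id", np.arange(n))
        for j in range(p.z):
            df[f"c{j + 1}"] = p.neutral[:n, j]
        for j in range(3):
            df[f"carried_a{j + 1}"] = p.carried[:n, j]
        return df

    def communities_frame(self) -> pd.DataFrame:
        rows = []
        sizes = self.community_sizes()
        for cid in sorted(self.communities):
            c = self.communities[cid]
            rows.append(
                {
                    "id": c.id,
                    "x": c.location[0],
                    "y": c.location[1],
                    "lineage": c.lineage,
                    "a1": int(c.adaptive[0]),
                    "a2": int(c.adaptive[1]),
                    "a3": int(c.adaptive[2]),
                    "size": sizes.get(cid, 0),
                }
            )
        return pd.DataFrame(rows)


def init_world(params: SimulationParams, rng: Optional[np.random.Generator] = None) -> World:
    """Build the initial world: incumbent (A) and migrant (B) communities.

    A communities start with a=(0,0,0) and all-0 neutral variants; B with
    a=(1,1,1) and all-1 variants. Individuals get random sex (50:50) and random
    integer age uniform on [0, 40] — a young, expanding population; the burn-in
    then equilibrates the age structure. (A wider initial age law, e.g. [0, 85],
    locks fertile adults into marriages with elderly partners — remarriage is
    impossible — and communities crash before the burn-in can stabilize them.)
    Everyone starts unmarried, each founder in their own single-person family
    unit.
    """
    violations = validate_params(params)
    if violations:
        raise ConfigurationError("; ".join(violations))
    world = World(params, rng)
    rng = world.rng

    cells = [
        (x, y) for x in range(params.grid_width) for y in range(params.grid_height)
    ]
    order = rng.permutation(len(cells))
    n_total = params.n_incumbent + params.n_migrant
    chosen = [cells[i] for i in order[:n_total]]

    for k, cell in enumerate(chosen):
        is_migrant = k >= params.n_incumbent
        variant = 1 if is_migrant else 0
        comm = world.add_community(
            cell,
            adaptive=np.full(3, variant, dtype=np.uint8),
            lineage=LINEAGE_B if is_migrant else LINEAGE_A,
        )
        size = params.initial_community_size
        sexes = rng.integers(0, 2, size=size).astype(np.uint8)
        ages = rng.integers(0, 41, size=size).astype(np.int32)
        families = np.array([world.new_family_id() for _ in range(size)], dtype=np.int32)
        world.people.add(
            size,
            sex=sexes,
            age=ages,
            community=comm.id,
            natal=comm.id,
            family=families,
            neutral=np.full((size, params.z), variant, dtype=np.uint8),
            carried=np.full((size, 3), variant, dtype=np.uint8),
        )
    return world
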