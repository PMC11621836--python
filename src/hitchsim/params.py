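"""Simulation parameters, trait configuration, validation, and config file I/O.

The parameter set mirrors the experimental design of a two-population
(incumbent vs. migrant) exogamy model: fixed demographic constants (baseline
fertility ``b``, a piecewise-constant mortality schedule, a fission threshold)
plus the swept knobs — adoption strength ``beta``, reproductive bonuses
``f1..f3`` of the three community-level adaptive traits, sex bias ``p_bias``
in social learning, and the postmarital residence rule ``p_location``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

FEMALE = 0
MALE = 1

PATHWAYS = ("none", "horizontal", "oblique")

#: Mortality schedule: (upper age inclusive, probability) bands; the last band
#: is open-ended. Loosely based on ethnographic hunter-gatherer figures.
DEFAULT_DEATH_SCHEDULE: tuple[tuple[Optional[int], float], ...] = (
    (5, 0.15),
    (40, 0.01),
    (65, 0.02),
    (85, 0.05),
    (None, 1.0),
)


@dataclass(frozen=True)
class TraitConfig:
    """One neutral cultural trait and its postmarital transmission pathway.

    ``p_transmit`` is the probability that a migrant engages in social
    learning of this trait after relocating; ``pathway`` selects the role-model
    pool (peers within 20 years of age for horizontal, individuals at least
    20 years older for oblique). ``pathway == "none"`` iff ``p_transmit == 0``:
    the trait is then only ever transmitted vertically at birth.
    """

    trait_id: int
    p_transmit: float
    pathway: str

    def violations(self) -> list[str]:
        out = []
        if not (0.0 <= self.p_transmit <= 1.0):
            out.append(f"trait c{self.trait_id}: p_transmit={self.p_transmit} not in [0,1]")
        if self.pathway not in PATHWAYS:
            out.append(f"trait c{self.trait_id}: unknown pathway {self.pathway!r}")
        if (self.pathway == "none") != (self.p_transmit == 0):
            out.append(
                f"trait c{self.trait_id}: pathway 'none' must coincide with p_transmit=0"
            )
        return out


def default_trait_configs() -> tuple[TraitConfig, ...]:
    """The canonical five-trait set spanning the pathway/probability design."""
    return (
        TraitConfig(1, 0.0, "none"),
        TraitConfig(2, 0.9, "horizontal"),
        TraitConfig(3, 1.0, "horizontal"),
        TraitConfig(4, 0.9, "oblique"),
        TraitConfig(5, 1.0, "oblique"),
    )


def uniform_trait_configs(p_transmit: float, pathway: str, z: int = 5) -> tuple[TraitConfig, ...]:
    """Helper: ``z`` identical traits (e.g. all-off for pure-demic scenarios)."""
    if p_transmit == 0:
        pathway = "none"
    return tuple(TraitConfig(i + 1, p_transmit, pathway) for i in range(z))


@dataclass
class SimulationParams:
    """Every knob of the simulation experiment.

    Defaults are the fixed values of the experimental design: a 10x10 grid,
    eight incumbent (type A) and two migrant (type B) communities of 70,
    b=0.3224, fission at 100, a 500-step burn-in, and patrilocality.
    """

    grid_width: int = 10
    grid_height: int = 10
    n_incumbent: int = 8
    n_migrant: int = 2
    initial_community_size: int = 70
    burn_in_steps: int = 500

    b: float = 0.3224
    f1: float = 0.0
    f2: float = 0.0
    f3: float = 0.0
    beta: float = 0.0
    p_bias: float = 0.5
    p_location: float = 0.0

    death_schedule: tuple = DEFAULT_DEATH_SCHEDULE
    reproduction_age_min: int = 18
    reproduction_age_max: int = 45
    marriage_age_min: int = 18
    #: inclusive reading of "older than 18" (>=18); set False for strict >18
    marriage_age_inclusive: bool = True
    generation_gap: int = 20
    n_fission: int = 100
    z: int = 5
    trait_configs: tuple[TraitConfig, ...] = field(default_factory=default_trait_configs)
    max_steps: int = 5000
    seed: int = 0

    # -- derived helpers -------------------------------------------------
    @property
    def fitness_bonuses(self):
        return (self.f1, self.f2, self.f3)

    @property
    def grid_cells(self) -> int:
        return self.grid_width * self.grid_height

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["death_schedule"] = [list(band) for band in self.death_schedule]
        d["trait_configs"] = [dataclasses.asdict(t) for t in self.trait_configs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        if "death_schedule" in d:
            d["death_schedule"] = tuple(
                (None if u is None else int(u), float(p)) for u, p in d["death_schedule"]
            )
        if "trait_configs" in d:
            d["trait_configs"] = tuple(
                t if isinstance(t, TraitConfig) else TraitConfig(**t)
                for t in d["trait_configs"]
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def validate_params(params: SimulationParams) -> list[str]:
    """Return a list of invariant violations (empty iff the params are valid).

    Reporting only — callers decide whether to raise.
    """
    v: list[str] = []
    for name in ("b", "f1", "f2", "f3", "p_bias", "p_location"):
        x = getattr(params, name)
        if not (0.0 <= x <= 1.0):
            v.append(f"{name}={x} not in [0,1]")
    for name in ("grid_width", "grid_height", "initial_community_size", "z", "max_steps"):
        if getattr(params, name) < 1:
            v.append(f"{name} must be >= 1")
    for name in ("n_incumbent", "n_migrant", "burn_in_steps"):
        if getattr(params, name) < 0:
            v.append(f"{name} must be >= 0")
    if params.n_incumbent + params.n_migrant < 1:
        v.append("n_incumbent + n_migrant must be >= 1")
    if params.n_incumbent + params.n_migrant > params.grid_cells:
        v.append(
            f"n_incumbent + n_migrant = {params.n_incumbent + params.n_migrant} exceeds "
            f"grid capacity {params.grid_cells}"
        )
    if params.n_fission <= params.initial_community_size:
        v.append(
            f"n_fission={params.n_fission} must exceed "
            f"initial_community_size={params.initial_community_size}"
        )
    sched = params.death_schedule
    if not sched or sched[-1][0] is not None:
        v.append("death_schedule must end with an open-ended (None) band")
    else:
        uppers = [u for u, _ in sched[:-1]]
        if any(u is None for u in uppers) or sorted(uppers) != uppers:
            v.append("death_schedule bands must have increasing finite uppers before the last")
        if any(not (0.0 <= p <= 1.0) for _, p in sched):
            v.append("death_schedule probabilities must be in [0,1]")
    if len(params.trait_configs) != params.z:
        v.append(f"trait_configs has {len(params.trait_configs)} entries, z={params.z}")
    for t in params.trait_configs:
        v.extend(t.violations())
    if not (0 <= params.reproduction_age_min <= params.reproduction_age_max):
        v.append("reproduction age window invalid")
    if params.marriage_age_min < 0:
        v.append("marriage_age_min must be >= 0")
    return v


def load_config(path) -> SimulationParams:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationParams.from_dict(data)


def save_config(params: SimulationParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
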