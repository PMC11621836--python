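"""Summary statistics: community typing, hitchhiking strength, diversity,
growth-rate estimation, and the replicated parameter sweep.

The hitchhiking signature is quantified by the proportion of analyzed
individuals carrying the migrant-associated 1-variant of each neutral trait,
pooled over type A communities and (separately) over type B and C communities
— i.e. communities that adopted the novel technology to some degree. Under a
fully sex-biased transmission regime only the biased-toward sex is analyzed
(males when p_bias=0, females when p_bias=1), since opposite-sex variants are
never transmitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import RunRecord, run
from .params import FEMALE, MALE, SimulationParams
from .world import Community, World

COMMUNITY_TYPES = ("A", "B", "C")
LINEAGES = ("A", "B")


def classify_community(community: Community) -> str:
    """Type A: a=(0,0,0); type B: a=(1,1,1); type C: partial adoption."""
    s = int(np.asarray(community.adaptive).sum())
    if s == 0:
        return "A"
    if s == len(community.adaptive):
        return "B"
    return "C"


def analyzed_sex(p_bias: float) -> Optional[int]:
    """The sex whose variants are analyzed, or None for both (0 < p_bias < 1)."""
    if p_bias == 0:
        return MALE
    if p_bias == 1:
        return FEMALE
    return None


@dataclass
class NeutralProportions:
    """Per-trait 1-variant proportions, pooled by community-type group.

    ``pooled``: DataFrame indexed by group ("A", "BC") with one column per
    trait; NaN where the group has no analyzed individuals.
    ``per_community``: tidy DataFrame (community, type, lineage, trait, prop).
    """

    pooled: pd.DataFrame
    per_community: pd.DataFrame


def neutral_proportions(world: World, p_bias: Optional[float] = None) -> NeutralProportions:
    """Fraction of analyzed individuals with c_i = 1, by community-type group.

    Groups pool individuals across communities (type A vs. type B∪C); the
    per-community breakdown is also returned so distribution-style summaries
    remain recoverable.
    """
    if p_bias is None:
        p_bias = world.params.p_bias
    p = world.people
    z = world.params.z
    sex = analyzed_sex(p_bias)
    by_comm = world.members_by_community()

    trait_cols = [f"c{j + 1}" for j in range(z)]
    sums = {g: np.zeros(z) for g in ("A", "BC")}
    counts = {g: 0 for g in ("A", "BC")}
    rows = []
    for cid in sorted(world.communities):
        comm = world.communities[cid]
        members = by_comm[cid]
        if sex is not None:
            members = members[p.sex[members] == sex]
        ctype = classify_community(comm)
        group = "A" if ctype == "A" else "BC"
        row = {"community": cid, "type": ctype, "lineage": comm.lineage,
               "n_analyzed": len(members)}
        if len(members):
            props = p.neutral[members].mean(axis=0)
            sums[group] += p.neutral[members].sum(axis=0)
            counts[group] += len(members)
        else:
            props = np.full(z, np.nan)
        for j, col in enumerate(trait_cols):
            row[col] = props[j]
        rows.append(row)

    pooled = pd.DataFrame(
        {
            col: [
                sums[g][j] / counts[g] if counts[g] else np.nan
                for g in ("A", "BC")
            ]
            for j, col in enumerate(trait_cols)
        },
        index=pd.Index(["A", "BC"], name="group"),
    )
    return NeutralProportions(pooled=pooled, per_community=pd.DataFrame(rows))


def lineage_type_counts(world: World) -> pd.DataFrame:
    """2x3 table: communities cross-classified by lineage and current type."""
    table = pd.DataFrame(
        0, index=pd.Index(LINEAGES, name="lineage"),
        columns=pd.Index(COMMUNITY_TYPES, name="type"),
    )
    for comm in world.communities.values():
        table.loc[comm.lineage, classify_community(comm)] += 1
    return table


def growth_rate(t: Sequence[float], population: Sequence[float]) -> float:
    """Per-step exponential growth rate: OLS slope of log population vs. t."""
    t = np.asarray(t, dtype=float)
    pop = np.asarray(population, dtype=float)
    if len(t) < 10:
        raise ValueError(f"need >= 10 points, got {len(t)}")
    if np.any(pop <= 0):
        raise ValueError("population must be positive throughout the window")
    return float(np.polyfit(t, np.log(pop), 1)[0])


def lineage_growth_rates(record: RunRecord, drop_tail: float = 0.1) -> dict[str, float]:
    """Per-lineage growth rates over the expansion phase of a finished run.

    Fits from t=0 up to the grid-fill step, excluding the final ``drop_tail``
    fraction of steps (edge effects of the stopping rule). Lineages whose
    population hits zero in the window report NaN.
    """
    s = record.series
    n_keep = max(10, int(math.floor(len(s) * (1.0 - drop_tail))))
    window = s.iloc[:n_keep]
    out = {}
    for lin in LINEAGES:
        pop = window[f"pop_lin{lin}"].to_numpy()
        try:
            out[lin] = growth_rate(window["t"].to_numpy(), pop)
        except ValueError:
            out[lin] = float("nan")
    return out


@dataclass
class RunSummary:
    """Per-run statistics: type/lineage counts, hitchhiking proportions, rates."""

    seed: int
    stop_reason: str
    n_steps: int
    type_counts: pd.DataFrame  # lineage x type
    proportions: NeutralProportions
    growth_rates: dict[str, float]
    counters: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: one row per trait x community-type group."""
        rows = []
        z = self.proportions.pooled.shape[1]
        for group in self.proportions.pooled.index:
            for j in range(z):
                rows.append(
                    {
                        "seed": self.seed,
                        "stop_reason": self.stop_reason,
                        "n_steps": self.n_steps,
                        "group": group,
                        "trait": f"c{j + 1}",
                        "prop_1": self.proportions.pooled.iloc[
                            self.proportions.pooled.index.get_loc(group), j
                        ],
                        "growth_rate_linA": self.growth_rates.get("A"),
                        "growth_rate_linB": self.growth_rates.get("B"),
                    }
                )
        return pd.DataFrame(rows)


def summarize_run(record: RunRecord) -> RunSummary:
    return RunSummary(
        seed=record.seed,
        stop_reason=record.stop_reason,
        n_steps=record.n_steps,
        type_counts=lineage_type_counts(record.world),
        proportions=neutral_proportions(record.world),
        growth_rates=lineage_growth_rates(record),
        counters=dict(record.counters),
    )


# ---------------------------------------------------------------------------
# Parameter sweep
# ---------------------------------------------------------------------------

SWEEP_BETAS = (-10.0, 0.0)
SWEEP_FS = (0.0, 0.005, 0.015)
SWEEP_P_BIAS = (0.0, 0.5, 1.0)
SWEEP_P_LOCATION = (0.0, 0.5)


def build_sweep_grid(
    betas: Iterable[float] = SWEEP_BETAS,
    fs: Iterable[float] = SWEEP_FS,
    p_biases: Iterable[float] = SWEEP_P_BIAS,
    p_locations: Iterable[float] = SWEEP_P_LOCATION,
) -> list[dict]:
    """The experiment grid (trait pathways are all tracked within each run)."""
    grid = []
    for beta in betas:
        for f in fs:
            for p_bias in p_biases:
                for p_location in p_locations:
                    grid.append(
                        {"beta": beta, "f": f, "p_bias": p_bias, "p_location": p_location}
                    )
    return grid


def derive_seed(base_seed: int, combo_index: int, rep_index: int) -> int:
    """Stable per-(combination, replicate) seed; order-invariant across the sweep."""
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, combo_index, rep_index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def apply_combo(base: SimulationParams, combo: dict) -> SimulationParams:
    kw = dict(combo)
    if "f" in kw:
        f = kw.pop("f")
        kw.update(f1=f, f2=f, f3=f)
    return base.replace(**kw)


def sweep(
    base_params: Optional[SimulationParams] = None,
    grid: Optional[list[dict]] = None,
    n_reps: int = 1,
    base_seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Run grid x replicates; one tidy row per run x trait x group.

    Seeds derive from (base_seed, combination index, replicate index), so the
    result is invariant to execution order and reproducible piecewise.
    """
    base = base_params if base_params is not None else SimulationParams()
    grid = build_sweep_grid() if grid is None else grid
    frames = []
    for ci, combo in enumerate(grid):
        for rep in range(n_reps):
            seed = derive_seed(base_seed, ci, rep)
            params = apply_combo(base, combo).replace(seed=seed)
            record = run(params)
            summ = summarize_run(record)
            df = summ.to_frame()
            df.insert(0, "combo", ci)
            df.insert(1, "rep", rep)
            for key, val in combo.items():
                df[key] = val
            tc = summ.type_counts
            for lin in LINEAGES:
                for ty in COMMUNITY_TYPES:
                    df[f"n_comm_{ty}_lin{lin}"] = tc.loc[lin, ty]
            frames.append(df)
            if progress:
                print(f"combo {ci + 1}/{len(grid)} rep {rep + 1}/{n_reps} done")
    return pd.concat(frames, ignore_index=True)
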