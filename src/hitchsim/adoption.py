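"""Frequency-dependent community-level adoption of adaptive traits.

The three adaptive traits are community-level: all residents share the same
variant. After the migration phase of each step, every community may flip each
trait independently with probability

    p = k^(1-beta) / (k^(1-beta) + (n-k)^(1-beta)),

where ``n`` is the community size including migrants and ``k`` is the number
of residents whose frozen carried variant for that trait differs from the
community's current one. ``beta = 0`` reduces to the discordant proportion
k/n; strongly negative ``beta`` (e.g. -10) makes adoption essentially
impossible for any minority of migrants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .world import Community, World


@dataclass(frozen=True)
class AdoptionState:
    """Per-community discordance census at the start of an adoption phase."""

    community_id: int
    k: tuple[int, ...]  # per-trait discordant counts
    n: int  # living community size including migrants


def adoption_probability(k: int, n: int, beta: float) -> float:
    """Probability that a community flips one adaptive trait.

    Degenerate censuses are fixed before exponentiation: k=0 -> 0 exactly and
    k=n -> 1 exactly, avoiding 0^(1-beta) ambiguity. The interior is evaluated
    in log space so strongly negative beta cannot overflow.
    """
    if n < 1:
        raise ValueError(f"community size n must be >= 1, got {n}")
    if not (0 <= k <= n):
        raise ValueError(f"discordant count k={k} outside [0, {n}]")
    if k == 0:
        return 0.0
    if k == n:
        return 1.0
    e = 1.0 - beta
    la = e * np.log(k)
    lb = e * np.log(n - k)
    m = max(la, lb)
    ea, eb = np.exp(la - m), np.exp(lb - m)
    return float(ea / (ea + eb))


def count_discordant(community: Community, trait_index: int, world: World) -> int:
    """Residents whose frozen carried variant differs from the community's.

    ``trait_index`` is 0-based (0..2). Discordance is cumulative over all
    surviving migrants — anyone whose carried vector (frozen at birth or at
    their migration) disagrees with the community's current variant counts,
    not just this step's arrivals.
    """
    if not (0 <= trait_index < 3):
        raise ValueError(f"trait_index must be in 0..2, got {trait_index}")
    members = world.members(community.id)
    if len(members) == 0:
        return 0
    carried = world.people.carried[members, trait_index]
    return int(np.count_nonzero(carried != community.adaptive[trait_index]))


def adoption_state(community: Community, world: World) -> AdoptionState:
    members = world.members(community.id)
    carried = world.people.carried[members]
    k = tuple(
        int(np.count_nonzero(carried[:, j] != community.adaptive[j])) for j in range(3)
    )
    return AdoptionState(community.id, k, len(members))


def adoption_step(world: World, rng: Optional[np.random.Generator] = None) -> None:
    """One adoption phase: every community, every trait, independent flips.

    Flip decisions within a step use the k and a values censused at the start
    of the phase; carried vectors are never re-baselined by a flip, so a flip
    turns the natal majority into the discordant class (back-flips possible).
    """
    rng = world.rng if rng is None else rng
    p = world.people
    by_comm = world.members_by_community()
    for cid in sorted(world.communities):
        members = by_comm[cid]
        n = len(members)
        if n == 0:
            continue
        comm = world.communities[cid]
        carried = p.carried[members]
        u = rng.random(3)
        flips = np.zeros(3, dtype=bool)
        for j in range(3):
            k = int(np.count_nonzero(carried[:, j] != comm.adaptive[j]))
            flips[j] = u[j] < adoption_probability(k, n, world.params.beta)
        if flips.any():
            comm.adaptive[flips] ^= 1
            world.counters["adoptions"] += int(flips.sum())
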