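"""Shared fixtures: miniature hand-built worlds and session-scoped full runs."""

import numpy as np
import pytest
from hypothesis import settings

import hitchsim as hs

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture
def two_communities():
    return hs.make_fixture("two_communities")


@pytest.fixture
def lonely_migrant():
    return hs.make_fixture("lonely_migrant")


@pytest.fixture
def fission_ready():
    return hs.make_fixture("fission_ready")


def tiny_params(**kw):
    """Small-but-complete world for fast end-to-end runs."""
    defaults = dict(
        grid_width=4, grid_height=4, n_incumbent=2, n_migrant=1,
        initial_community_size=30, n_fission=45, burn_in_steps=60,
        max_steps=200, seed=0,
    )
    defaults.update(kw)
    return hs.SimulationParams(**defaults)


# ---------------------------------------------------------------------------
# Expensive shared runs (session scope)
# ---------------------------------------------------------------------------

DEMIC_GROWTH_PARAMS = dict(
    beta=-10.0, f1=0.015, f2=0.015, f3=0.015, p_location=0.0, p_bias=0.0,
)


@pytest.fixture(scope="session")
def demic_growth_records():
    """Five no-social-learning runs with the full adaptive growth advantage."""
    records = []
    for seed in range(1, 6):
        params = hs.SimulationParams(
            **DEMIC_GROWTH_PARAMS,
            trait_configs=hs.uniform_trait_configs(0.0, "none"),
            seed=seed,
        )
        records.append(hs.run(params))
    return records


@pytest.fixture(scope="session")
def pure_demic_record():
    """One pure-demic run (five default traits, male-only transmission) with a
    per-step monitor of community adaptive vectors.

    Returns (record, flips) where flips lists any observed change of any
    community's adaptive vector during the run.
    """
    params = hs.SimulationParams(**DEMIC_GROWTH_PARAMS, seed=7)
    seen: dict[int, tuple] = {}
    flips: list[tuple] = []

    def monitor(world):
        for cid, comm in world.communities.items():
            vec = tuple(int(v) for v in comm.adaptive)
            if cid in seen and seen[cid] != vec:
                flips.append((world.t, cid, seen[cid], vec))
            seen[cid] = vec

    record = hs.run(params, step_callback=monitor)
    return record, flips


@pytest.fixture(scope="session")
def oblique_record():
    """Matrilineal oblique-resocialization run with the event log retained."""
    params = hs.SimulationParams(
        beta=-10.0, f1=0.015, f2=0.015, f3=0.015,
        p_location=0.0, p_bias=1.0, seed=5,
    )
    return hs.run(params, log_events=True)


@pytest.fixture(scope="session")
def lineage_share_records():
    """Twenty neutral-adoption runs (f=0, beta=0) for the lineage-ratio check."""
    records = []
    for seed in range(20):
        params = hs.SimulationParams(
            beta=0.0, f1=0.0, f2=0.0, f3=0.0, p_location=0.0, p_bias=0.5,
            seed=seed,
        )
        records.append(hs.run(params))
    return records
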