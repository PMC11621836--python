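"""Mortality schedule, marriage market, reproduction, and fission."""

import numpy as np
import pytest

import hitchsim as hs
from hitchsim import demography
from hitchsim.params import DEFAULT_DEATH_SCHEDULE, FEMALE, MALE
from hitchsim.world import World


@pytest.mark.parametrize(
    "age, expected",
    [
        (0, 0.15), (3, 0.15), (5, 0.15),
        (6, 0.01), (40, 0.01),
        (41, 0.02), (50, 0.02), (65, 0.02),
        (66, 0.05), (85, 0.05),
        (86, 1.0), (90, 1.0),
    ],
)
def test_death_schedule_bands(age, expected):
    assert demography.death_probability(age, DEFAULT_DEATH_SCHEDULE) == expected


def test_negative_age_rejected():
    with pytest.raises(ValueError):
        demography.death_probability(-1, DEFAULT_DEATH_SCHEDULE)


def _marry(world, a, b):
    p = world.people
    p.spouse[a], p.spouse[b] = b, a
    p.ever_married[a] = p.ever_married[b] = True


def test_certain_death_past_schedule_and_widowhood(two_communities):
    world = two_communities
    p = world.people
    # ids 0..5 in community 0 with ages (10, 25, 30, 45, 50, 70)
    p.age[5] = 90  # will age to 91 -> dies with certainty
    _marry(world, 4, 5)
    demography.step_age_and_mortality(world)
    assert not p.alive[5]
    assert p.spouse[4] == -1 and p.ever_married[4]
    # the widow never re-enters the pool
    assert 4 not in demography.form_marriage_pool(world)


def test_mortality_on_empty_world():
    world = World(hs.SimulationParams())
    demography.step_age_and_mortality(world)  # no-op, no error
    assert len(world.living_indices()) == 0


def test_marriage_pool_age_threshold(two_communities):
    world = two_communities
    p = world.people
    p.age[[0, 1, 2]] = [17, 18, 30]
    pool = set(demography.form_marriage_pool(world))
    assert 0 not in pool and {1, 2} <= pool
    # strict reading excludes exact-18
    world.params = world.params.replace(marriage_age_inclusive=False)
    pool = set(demography.form_marriage_pool(world))
    assert 1 not in pool and 2 in pool


def test_no_pairs_within_one_community(two_communities):
    world = two_communities
    pool = np.array([0, 1])  # female 10y? ages irrelevant: both community 0
    pairs = demography.match_pairs(pool, world)
    assert pairs == []


def test_forced_cross_community_pair(two_communities):
    world = two_communities
    # female id 2 (community 0), male id 7 (community 1)
    pairs = demography.match_pairs(np.array([2, 7]), world)
    assert len(pairs) == 1
    assert pairs[0].female_id == 2 and pairs[0].male_id == 7
    assert pairs[0].origin_female != pairs[0].origin_male


def test_two_males_one_female_uniform_choice(two_communities):
    world = two_communities
    # males 1, 3 live in community 0; female 6 lives in community 1
    pool = np.array([1, 3, 6])
    counts = {1: 0, 3: 0}
    for seed in range(10_000):
        rng = np.random.default_rng(seed)
        pairs = demography.match_pairs(pool, world, rng=rng)
        assert len(pairs) == 1
        counts[pairs[0].male_id] += 1
    # binomial(10000, 0.5) 3-sigma band
    assert abs(counts[1] - 5000) < 3 * np.sqrt(10_000 * 0.25)


@pytest.mark.parametrize("p_location, expect_female_side", [(0.0, False), (1.0, True)])
def test_residence_rule_limits(two_communities, p_location, expect_female_side):
    world = two_communities
    world.params = world.params.replace(p_location=p_location)
    pairs = demography.match_pairs(np.array([2, 7]), world)
    mover = demography.settle_pair(pairs[0], world)
    pair = pairs[0]
    if expect_female_side:
        assert pair.residence == pair.origin_female and mover == pair.male_id
    else:
        assert pair.residence == pair.origin_male and mover == pair.female_id
    p = world.people
    assert p.community[mover] == pair.residence
    assert p.spouse[pair.female_id] == pair.male_id
    assert p.spouse[pair.male_id] == pair.female_id
    assert p.family[pair.female_id] == p.family[pair.male_id]
    assert p.migrated_at[mover] == world.t
    # carried variants frozen to the origin community's vector at departure
    origin = pair.origin_female if mover == pair.female_id else pair.origin_male
    assert (p.carried[mover] == world.communities[origin].adaptive).all()


def test_bilocality_binomial():
    female_side = 0
    n = 10_000
    for seed in range(n):
        world = hs.make_fixture("two_communities")
        world.params = world.params.replace(p_location=0.5)
        world.rng = np.random.default_rng(seed)
        pairs = demography.match_pairs(np.array([2, 7]), world)
        demography.settle_pair(pairs[0], world)
        if pairs[0].residence == pairs[0].origin_female:
            female_side += 1
    assert abs(female_side - n / 2) < 3 * np.sqrt(n * 0.25)


def test_birth_probability_values():
    params = hs.SimulationParams()
    assert demography.birth_probability(params, np.zeros(3)) == pytest.approx(0.3224)
    params = params.replace(f1=0.015, f2=0.015, f3=0.015)
    assert demography.birth_probability(params, np.ones(3)) == pytest.approx(0.3674)


def _paired_world(n_pairs, adaptive, **param_kw):
    """One community of n_pairs married couples aged 30/32."""
    params = hs.SimulationParams(
        grid_width=3, grid_height=3, n_incumbent=1, n_migrant=0,
        initial_community_size=2, n_fission=10_000, seed=0, **param_kw
    )
    world = World(params)
    comm = world.add_community((0, 0), np.asarray(adaptive, np.uint8), "A")
    for _ in range(n_pairs):
        fid = world.new_family_id()
        ids = world.people.add(
            2, sex=np.array([FEMALE, MALE], np.uint8),
            age=np.array([30, 32], np.int32),
            community=comm.id, natal=comm.id, family=fid,
            neutral=np.zeros((2, params.z), np.uint8),
            carried=np.tile(np.asarray(adaptive, np.uint8), (2, 1)),
        )
        _marry(world, ids[0], ids[1])
    return world


@pytest.mark.parametrize(
    "adaptive, f, expected",
    [((0, 0, 0), 0.0, 0.3224), ((1, 1, 1), 0.015, 0.3674)],
)
def test_reproduction_frequency_matches_birth_probability(adaptive, f, expected):
    world = _paired_world(50, adaptive, f1=f, f2=f, f3=f)
    world.rng = np.random.default_rng(99)
    trials, births = 200, 0
    for _ in range(trials):
        newborns = demography.reproduce(world)
        births += len(newborns)
        world.people.alive[newborns] = False  # keep the pair census fixed
    n = trials * 50
    assert abs(births / n - expected) < 3 * np.sqrt(expected * (1 - expected) / n)


def test_no_reproduction_outside_age_window():
    world = _paired_world(1, (0, 0, 0))
    world.people.age[1] = 46  # husband just past the window
    for seed in range(50):
        world.rng = np.random.default_rng(seed)
        assert len(demography.reproduce(world)) == 0


def test_newborn_state(two_communities):
    world = two_communities
    pairs = demography.match_pairs(np.array([2, 7]), world)
    demography.settle_pair(pairs[0], world)
    world.rng = np.random.default_rng(1)
    newborns = []
    for _ in range(30):
        newborns.extend(demography.reproduce(world))
    assert newborns
    p = world.people
    i = newborns[0]
    assert p.age[i] == 0
    assert p.natal[i] == p.community[i] == pairs[0].residence
    assert p.family[i] == p.family[pairs[0].female_id]
    assert (p.carried[i] == world.communities[pairs[0].residence].adaptive).all()
    assert p.mother[i] == pairs[0].female_id and p.father[i] == pairs[0].male_id


def test_fission_balances_families():
    # 25 four-member families in one community of 100 at the threshold
    params = hs.SimulationParams(
        grid_width=2, grid_height=2, n_incumbent=1, n_migrant=0,
        initial_community_size=99, n_fission=100, seed=0,
    )
    world = World(params)
    comm = world.add_community((0, 0), np.array([0, 1, 0], np.uint8), "B")
    for _ in range(25):
        fid = world.new_family_id()
        world.people.add(
            4, sex=np.array([MALE, FEMALE, FEMALE, MALE], np.uint8),
            age=np.array([40, 38, 10, 8], np.int32),
            community=comm.id, natal=comm.id, family=fid,
            neutral=np.zeros((4, params.z), np.uint8),
            carried=np.zeros((4, 3), np.uint8),
        )
    members_before = set(world.members(comm.id).tolist())
    world.rng = np.random.default_rng(5)
    demography.fission_check(world)
    assert len(world.communities) == 2
    sizes = world.community_sizes()
    assert sum(sizes.values()) == 100
    assert abs(sizes[0] - sizes[1]) <= 4  # greedy balance of equal families
    # families never split; daughters partition the parent
    p = world.people
    union = set()
    for cid in world.communities:
        ids = world.members(cid)
        union.update(ids.tolist())
        fams = p.family[ids]
        for other in world.communities:
            if other != cid:
                assert not set(fams.tolist()) & set(p.family[world.members(other)].tolist())
    assert union == members_before
    # adaptive vector and lineage inherited; parent keeps its cell
    daughter = world.communities[1]
    assert (daughter.adaptive == np.array([0, 1, 0])).all()
    assert daughter.lineage == "B"
    assert world.communities[0].location == (0, 0)
    assert sizes[0] >= sizes[1]


def test_no_fission_below_threshold(fission_ready):
    world = fission_ready
    world.params = world.params.replace(n_fission=13)  # size is 12
    demography.fission_check(world)
    assert len(world.communities) == 1


def test_fission_on_full_grid_stops_simulation():
    params = hs.SimulationParams(
        grid_width=1, grid_height=2, n_incumbent=1, n_migrant=1,
        initial_community_size=8, n_fission=12, seed=0,
    )
    world = World(params)
    for k, cell in enumerate([(0, 0), (0, 1)]):
        comm = world.add_community(cell, np.full(3, k, np.uint8), "AB"[k])
        for _ in range(3):
            fid = world.new_family_id()
            world.people.add(
                4, sex=np.array([MALE, FEMALE, FEMALE, MALE], np.uint8),
                age=np.array([40, 38, 10, 8], np.int32),
                community=comm.id, natal=comm.id, family=fid,
                neutral=np.full((4, params.z), k, np.uint8),
                carried=np.full((4, 3), k, np.uint8),
            )
    before = world.community_sizes()
    demography.fission_check(world)
    assert world.stopped == "grid_full"
    assert len(world.communities) == 2
    assert world.community_sizes() == before  # community left intact


def test_conservation_and_spouse_symmetry_through_steps():
    from hitchsim import engine

    world = hs.init_world(hs.SimulationParams(seed=6))
    for _ in range(40):
        before = len(world.living_indices())
        b0, d0 = world.counters["births"], world.counters["deaths"]
        engine.step(world)
        after = len(world.living_indices())
        db = world.counters["births"] - b0
        dd = world.counters["deaths"] - d0
        assert after == before + db - dd
        p = world.people
        living = world.living_indices()
        spoused = living[p.spouse[living] >= 0]
        assert (p.spouse[p.spouse[spoused]] == spoused).all()
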