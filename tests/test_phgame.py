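"""Public health game: payoffs, transmission, recovery, imitation, runs.

One-step behavior is checked against an independent brute-force oracle that
walks the 3x3 torus with plain Python loops.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epigames.networks import build_grid_lattice
from epigames.phgame import (
    HealthState,
    PHGConfig,
    Trajectory,
    compute_payoffs,
    imitate_best,
    initialize_population,
    progress_infection,
    run,
    state_grid,
    step,
    transmit_infection,
)

# ---------------------------------------------------------------------------
# brute-force oracle on the 3x3 torus (complete graph on 9 nodes)
# ---------------------------------------------------------------------------


def torus_neighbors(side):
    nbrs = {}
    for r in range(side):
        for c in range(side):
            out = set()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    out.add(((r + dr) % side) * side + (c + dc) % side)
            out.discard(r * side + c)
            nbrs[r * side + c] = sorted(out)
    return nbrs


def oracle_payoffs(protect, remaining, nbrs, b, c):
    n = len(protect)
    healthy = [remaining[i] == 0 for i in range(n)]
    pay = []
    for i in range(n):
        locals_ = [i] + nbrs[i]
        benefit = b * sum(1 for j in locals_ if healthy[j])
        cost = c * len(nbrs[i]) if protect[i] else 0.0
        pay.append(benefit - cost)
    return pay


def oracle_imitate(protect, pay, nbrs):
    out = list(protect)
    for i in range(len(protect)):
        locals_ = [i] + nbrs[i]
        own = max(pay[j] for j in locals_ if protect[j] == protect[i])
        other_vals = [pay[j] for j in locals_ if protect[j] != protect[i]]
        if other_vals and max(other_vals) > own:
            out[i] = not protect[i]
    return out


def oracle_step(protect, remaining, nbrs, b, c, beta, duration):
    """Full round with deterministic transmission (beta must be 0 or 1)."""
    assert beta in (0, 1)
    n = len(protect)
    infected0 = [remaining[i] > 0 for i in range(n)]
    rem = list(remaining)
    newly = [False] * n
    if beta == 1:
        for i in range(n):
            if not protect[i] and rem[i] == 0 and any(infected0[j] for j in nbrs[i]):
                newly[i] = True
    for i in range(n):
        if newly[i]:
            rem[i] = duration
        elif infected0[i]:
            rem[i] -= 1
    pay = oracle_payoffs(protect, rem, nbrs, b, c)
    return oracle_imitate(protect, pay, nbrs), rem


def make_state(protect, remaining):
    return HealthState(
        protect=np.asarray(protect, dtype=bool),
        remaining_infection=np.asarray(remaining, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


class TestInitialization:
    def test_exact_counts_at_default_fractions(self, grid61, rng):
        state = initialize_population(grid61, PHGConfig(benefit=5), rng)
        assert int(state.protect.sum()) == 1861  # round-half-up of 1860.5
        assert int(state.infected.sum()) == 372
        assert np.all(state.remaining_infection[state.infected] == 5)

    def test_zero_infection_fraction(self, grid5, rng):
        cfg = PHGConfig(benefit=5, init_infect_frac=0.0)
        state = initialize_population(grid5, cfg, rng)
        assert not state.infected.any()

    def test_behavior_and_infection_independent(self, grid5):
        # pooled over 200 seeds the infected fraction among protectors should
        # match the infected fraction among defectors
        cfg = PHGConfig(benefit=5)
        inf_p = inf_d = n_p = n_d = 0
        for seed in range(200):
            s = initialize_population(grid5, cfg, np.random.default_rng(seed))
            inf_p += int((s.protect & s.infected).sum())
            inf_d += int((~s.protect & s.infected).sum())
            n_p += int(s.protect.sum())
            n_d += int((~s.protect).sum())
        rate_p, rate_d = inf_p / n_p, inf_d / n_d
        assert abs(rate_p - rate_d) < 0.03


# ---------------------------------------------------------------------------
# payoffs
# ---------------------------------------------------------------------------


class TestPayoffs:
    def _uniform_state(self, net, protect_node, infect=()):
        protect = np.zeros(net.n_nodes, dtype=bool)
        protect[list(protect_node)] = True
        rem = np.zeros(net.n_nodes, dtype=np.int64)
        rem[list(infect)] = 5
        return make_state(protect, rem)

    def test_healthy_protector_all_healthy_neighbors(self, grid5):
        state = self._uniform_state(grid5, protect_node=[0])
        pay = compute_payoffs(state, grid5, PHGConfig(benefit=5, cost=1))
        assert pay[0] == 5 * 9 - 8  # 37

    def test_healthy_defector_all_healthy_neighbors(self, grid5):
        state = self._uniform_state(grid5, protect_node=[])
        pay = compute_payoffs(state, grid5, PHGConfig(benefit=5, cost=1))
        assert pay[12] == 45

    def test_infected_defector_excludes_self(self, grid5):
        # node 12's neighbors: infect 5 of 8, and node 12 itself
        adj = grid5.adjacency()
        nbrs = adj.indices[adj.indptr[12] : adj.indptr[13]]
        state = self._uniform_state(grid5, protect_node=[], infect=[12, *nbrs[:5]])
        pay = compute_payoffs(state, grid5, PHGConfig(benefit=5, cost=1))
        assert pay[12] == 5 * 3  # 3 healthy neighbors, infected self not counted

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        protect=st.lists(st.booleans(), min_size=9, max_size=9),
        remaining=st.lists(st.integers(0, 5), min_size=9, max_size=9),
        b=st.floats(0, 10, allow_nan=False),
        c=st.floats(0, 3, allow_nan=False),
    )
    def test_matches_oracle_on_3x3(self, protect, remaining, b, c):
        net = build_grid_lattice(3)
        nbrs = torus_neighbors(3)
        state = make_state(protect, remaining)
        pay = compute_payoffs(state, net, PHGConfig(benefit=b, cost=c))
        expected = oracle_payoffs(protect, remaining, nbrs, b, c)
        assert np.allclose(pay, expected)


# ---------------------------------------------------------------------------
# transmission and recovery
# ---------------------------------------------------------------------------


class TestInfectionDynamics:
    def test_certain_transmission_to_defector(self, grid5, rng):
        rem = np.zeros(25, dtype=np.int64)
        rem[0] = 3
        state = make_state(np.zeros(25, dtype=bool), rem)
        cfg = PHGConfig(benefit=5, infectivity=1.0)
        out = transmit_infection(state, grid5, cfg, rng)
        adj = grid5.adjacency()
        nbrs = adj.indices[adj.indptr[0] : adj.indptr[1]]
        assert out.infected[nbrs].all()
        assert np.all(out.remaining_infection[nbrs] == 5)

    def test_zero_infectivity_never_transmits(self, grid5, rng):
        rem = np.zeros(25, dtype=np.int64)
        rem[:10] = 5
        state = make_state(np.zeros(25, dtype=bool), rem)
        out = transmit_infection(state, grid5, PHGConfig(benefit=5, infectivity=0.0), rng)
        assert int(out.infected.sum()) == 10

    def test_protector_immune_even_when_surrounded(self, grid3, rng):
        protect = np.zeros(9, dtype=bool)
        protect[4] = True
        rem = np.full(9, 5, dtype=np.int64)
        rem[4] = 0
        state = make_state(protect, rem)
        out = transmit_infection(state, grid3, PHGConfig(benefit=5, infectivity=1.0), rng)
        assert not out.infected[4]

    def test_infected_protector_transmits(self, grid3, rng):
        # the shield blocks incoming infection, not outgoing
        protect = np.zeros(9, dtype=bool)
        protect[0] = True
        rem = np.zeros(9, dtype=np.int64)
        rem[0] = 5
        state = make_state(protect, rem)
        out = transmit_infection(state, grid3, PHGConfig(benefit=5, infectivity=1.0), rng)
        assert out.infected[1:].all()

    def test_progression_decrements_and_recovers(self):
        state = make_state([False, False], [5, 1])
        cfg = PHGConfig(benefit=5)
        out = progress_infection(state, cfg)
        assert list(out.remaining_infection) == [4, 0]
        assert out.healthy[1]

    def test_recovery_after_exactly_duration_steps(self, grid5):
        # with beta=0 a node infected at step 0 is healthy exactly at step 5
        cfg = PHGConfig(benefit=5, infectivity=0.0)
        rem = np.zeros(25, dtype=np.int64)
        rem[7] = 5
        state = make_state(np.zeros(25, dtype=bool), rem)
        rng = np.random.default_rng(0)
        for t in range(1, 6):
            state = step(state, grid5, cfg, rng)
            if t < 5:
                assert state.infected[7], f"should still be infected at step {t}"
        assert not state.infected.any()


# ---------------------------------------------------------------------------
# imitation
# ---------------------------------------------------------------------------


class TestImitation:
    def test_switches_to_strictly_better_behavior(self, grid3):
        protect = np.zeros(9, dtype=bool)
        protect[1] = True
        state = make_state(protect, np.zeros(9, dtype=np.int64))
        pay = np.full(9, 10.0)
        pay[1] = 12.0
        out = imitate_best(state, grid3, pay)
        assert out.protect.all()  # everyone copies the protector earning 12

    def test_tie_favors_incumbent(self, grid3):
        protect = np.zeros(9, dtype=bool)
        protect[1] = True
        state = make_state(protect, np.zeros(9, dtype=np.int64))
        pay = np.full(9, 10.0)  # all payoffs equal
        out = imitate_best(state, grid3, pay)
        assert np.array_equal(out.protect, protect)

    def test_uniform_behavior_never_changes(self, grid3):
        state = make_state(np.ones(9, dtype=bool), np.zeros(9, dtype=np.int64))
        pay = np.arange(9, dtype=float)
        out = imitate_best(state, grid3, pay)
        assert out.protect.all()

    def test_never_touches_infection(self, grid3):
        rem = np.array([5, 0, 3, 0, 0, 1, 0, 0, 2], dtype=np.int64)
        state = make_state(np.zeros(9, dtype=bool), rem)
        out = imitate_best(state, grid3, np.random.default_rng(0).random(9))
        assert np.array_equal(out.remaining_infection, rem)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        protect=st.lists(st.booleans(), min_size=9, max_size=9),
        pay=st.lists(st.integers(-5, 40), min_size=9, max_size=9),
    )
    def test_matches_oracle_on_3x3(self, protect, pay):
        net = build_grid_lattice(3)
        nbrs = torus_neighbors(3)
        state = make_state(protect, np.zeros(9, dtype=np.int64))
        out = imitate_best(state, net, np.asarray(pay, dtype=float))
        expected = oracle_imitate(protect, pay, nbrs)
        assert list(out.protect) == expected


# ---------------------------------------------------------------------------
# full rounds and runs
# ---------------------------------------------------------------------------


class TestStepAndRun:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        protect=st.lists(st.booleans(), min_size=9, max_size=9),
        remaining=st.lists(st.integers(0, 5), min_size=9, max_size=9),
        b=st.sampled_from([1.0, 3.0, 5.0]),
        beta=st.sampled_from([0, 1]),
    )
    def test_one_step_matches_oracle_on_3x3(self, protect, remaining, b, beta):
        net = build_grid_lattice(3)
        nbrs = torus_neighbors(3)
        cfg = PHGConfig(benefit=b, infectivity=float(beta))
        state = make_state(protect, remaining)
        out = step(state, net, cfg, np.random.default_rng(0))
        exp_protect, exp_rem = oracle_step(protect, remaining, nbrs, b, 1.0, beta, 5)
        assert list(out.protect) == exp_protect
        assert list(out.remaining_infection) == exp_rem

    def test_absorbing_all_protectors_no_infection(self, grid5):
        cfg = PHGConfig(benefit=5, infectivity=0.0, init_infect_frac=0.0,
                        init_protect_frac=1.0, n_steps=10)
        state = make_state(np.ones(25, dtype=bool), np.zeros(25, dtype=np.int64))
        rng = np.random.default_rng(0)
        for _ in range(5):
            state = step(state, grid5, cfg, rng)
        assert state.protect.all()
        assert not state.infected.any()

    def test_count_conservation(self, grid5):
        cfg = PHGConfig(benefit=4, n_steps=60)
        traj, _ = run(grid5, cfg, np.random.default_rng(3))
        totals = (
            traj.n_protect_healthy + traj.n_protect_infected
            + traj.n_defect_healthy + traj.n_defect_infected
        )
        assert np.all(totals == 25)

    def test_beta_zero_extinction_by_duration(self, grid5):
        cfg = PHGConfig(benefit=5, infectivity=0.0, n_steps=20)
        traj, _ = run(grid5, cfg, np.random.default_rng(4))
        infected = traj.n_protect_infected + traj.n_defect_infected
        assert infected[0] == 3  # round-half-up of 25 * 0.10 = 2.5
        assert np.all(infected[5:] == 0)

    def test_no_protector_newly_infected_during_run(self, grid5):
        # track transitions: a node that protects and is healthy before a
        # round must not be infected after transmission
        cfg = PHGConfig(benefit=4, infectivity=0.8)
        rng = np.random.default_rng(5)
        state = initialize_population(grid5, cfg, rng)
        for _ in range(40):
            protected_healthy = state.protect & state.healthy
            after = transmit_infection(state, grid5, cfg, rng)
            assert not (protected_healthy & after.infected).any()
            newly = after.infected & ~state.infected
            after = progress_infection(after, cfg, newly_infected=newly)
            pay = compute_payoffs(after, grid5, cfg)
            state = imitate_best(after, grid5, pay)

    def test_run_is_deterministic_given_seed(self, grid5):
        cfg = PHGConfig(benefit=5, infectivity=0.7, n_steps=50)
        t1, s1 = run(grid5, cfg, np.random.default_rng(99))
        t2, s2 = run(grid5, cfg, np.random.default_rng(99))
        assert np.array_equal(t1.n_defect_infected, t2.n_defect_infected)
        assert s1 == s2

    def test_trajectory_dataframe_shape(self, grid5):
        cfg = PHGConfig(benefit=5, n_steps=12)
        traj, _ = run(grid5, cfg, np.random.default_rng(1))
        df = traj.to_dataframe()
        assert len(df) == 13
        assert list(df.columns) == [
            "step", "n_protect_healthy", "n_protect_infected",
            "n_defect_healthy", "n_defect_infected",
        ]

    def test_state_grid_codes(self, grid3):
        state = make_state(
            [True, True, False, False, False, False, False, False, False],
            [0, 5, 0, 5, 0, 0, 0, 0, 0],
        )
        grid = state_grid(state, grid3)
        assert grid.shape == (3, 3)
        assert grid[0, 0] == 0  # healthy protector
        assert grid[0, 1] == 1  # infected protector
        assert grid[0, 2] == 2  # healthy defector
        assert grid[1, 0] == 3  # infected defector


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"benefit": -1},
            {"benefit": 5, "infectivity": 1.5},
            {"benefit": 5, "init_infect_frac": -0.1},
            {"benefit": 5, "infection_duration": 0},
            {"benefit": 5, "n_steps": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PHGConfig(**kwargs)
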