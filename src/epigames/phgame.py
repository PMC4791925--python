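"""The public health protection game with SIS infection on a network.

Each individual either protects (pays a per-neighbor cost, cannot be infected)
or defects (pays nothing, susceptible).  Everyone earns a benefit ``b`` per
healthy person in their closed neighborhood (self plus neighbors).  Infection
spreads from infected individuals to each non-protecting healthy neighbor with
probability ``beta`` per contact per step and lasts a fixed number of steps,
after which the individual is susceptible again (SIS — no immunity).  After
infection spread, recovery, and payoff calculation, everyone synchronously
imitates the best: an individual switches behavior only if some member of its
closed neighborhood with the *other* behavior strictly out-earns every member
(including self) with its *own* behavior.

The canonical round is: transmit, recover, compute payoffs, imitate.  Payoffs
therefore reflect the newest health states, and newly infected individuals do
not transmit within the round that infected them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._neigh import neighbor_max_where, neighbor_sum
from .networks import Network

__all__ = [
    "PHGConfig",
    "HealthState",
    "Trajectory",
    "RunSummary",
    "initialize_population",
    "compute_payoffs",
    "transmit_infection",
    "progress_infection",
    "imitate_best",
    "step",
    "run",
]


@dataclass(frozen=True)
class PHGConfig:
    """Parameters of the public health game.

    Attributes
    ----------
    benefit:
        Payoff units earned per healthy person in the closed neighborhood
        (the ``b`` in the benefit-to-cost ratio).
    cost:
        Payoff units a protector pays per neighbor (``c``; default 1, so
        ``benefit`` doubles as the benefit-to-cost ratio).
    infectivity:
        Per-step probability of transmission across each infected-neighbor
        contact, in [0, 1].
    infection_duration:
        Number of steps an infection lasts before the individual is
        susceptible again.
    init_protect_frac:
        Initial fraction of protectors (default 0.5).
    init_infect_frac:
        Initial fraction infected (default 0.10), independent of behavior.
    n_steps:
        Number of rounds per run (default 500).
    burn_in:
        Steps discarded before computing run-level means (default 0: the
        mean is taken over the whole run including the transient).
    """

    benefit: float
    cost: float = 1.0
    infectivity: float = 1.0
    infection_duration: int = 5
    init_protect_frac: float = 0.5
    init_infect_frac: float = 0.10
    n_steps: int = 500
    burn_in: int = 0

    def __post_init__(self) -> None:
        if self.benefit < 0 or self.cost < 0:
            raise ValueError("benefit and cost must be non-negative")
        if not 0.0 <= self.infectivity <= 1.0:
            raise ValueError("infectivity must lie in [0, 1]")
        for name in ("init_protect_frac", "init_infect_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.infection_duration < 1:
            raise ValueError("infection_duration must be a positive integer")
        if self.n_steps < 1:
            raise ValueError("n_steps must be a positive integer")


@dataclass
class HealthState:
    """Per-node behavior and infection state.

    ``protect`` is a boolean array; ``remaining_infection`` counts the steps
    of infection left (0 means healthy and susceptible).
    """

    protect: np.ndarray
    remaining_infection: np.ndarray

    @property
    def infected(self) -> np.ndarray:
        return self.remaining_infection > 0

    @property
    def healthy(self) -> np.ndarray:
        return self.remaining_infection == 0

    def copy(self) -> "HealthState":
        return HealthState(self.protect.copy(), self.remaining_infection.copy())

    def counts(self) -> tuple[int, int, int, int]:
        """(healthy protectors, infected protectors, healthy defectors,
        infected defectors)."""
        h, p = self.healthy, self.protect
        return (
            int(np.sum(p & h)),
            int(np.sum(p & ~h)),
            int(np.sum(~p & h)),
            int(np.sum(~p & ~h)),
        )


@dataclass
class Trajectory:
    """Per-step compartment counts, row 0 being the initial state."""

    n_protect_healthy: np.ndarray
    n_protect_infected: np.ndarray
    n_defect_healthy: np.ndarray
    n_defect_infected: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.n_protect_healthy) - 1

    @property
    def n_nodes(self) -> int:
        return int(
            self.n_protect_healthy[0]
            + self.n_protect_infected[0]
            + self.n_defect_healthy[0]
            + self.n_defect_infected[0]
        )

    def prop_infected(self) -> np.ndarray:
        return (self.n_protect_infected + self.n_defect_infected) / self.n_nodes

    def prop_protecting(self) -> np.ndarray:
        return (self.n_protect_healthy + self.n_protect_infected) / self.n_nodes

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(len(self.n_protect_healthy)),
                "n_protect_healthy": self.n_protect_healthy,
                "n_protect_infected": self.n_protect_infected,
                "n_defect_healthy": self.n_defect_healthy,
                "n_defect_infected": self.n_defect_infected,
            }
        )


@dataclass(frozen=True)
class RunSummary:
    mean_prop_infected: float
    mean_prop_protecting: float
    protection_survived: bool
    burn_in: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def initialize_population(
    network: Network, config: PHGConfig, rng: np.random.Generator
) -> HealthState:
    """Random initial state: exact protector and infected counts.

    Exactly ``round(N * init_protect_frac)`` nodes protect and exactly
    ``round(N * init_infect_frac)`` nodes start infected with a full duration
    counter; both subsets are drawn uniformly and independently of each other,
    so initial infection is not restricted to either behavior.
    """
    n = network.n_nodes
    protect = np.zeros(n, dtype=bool)
    n_protect = _round_half_up(n * config.init_protect_frac)
    protect[rng.choice(n, size=n_protect, replace=False)] = True
    remaining = np.zeros(n, dtype=np.int64)
    n_infect = _round_half_up(n * config.init_infect_frac)
    remaining[rng.choice(n, size=n_infect, replace=False)] = config.infection_duration
    return HealthState(protect=protect, remaining_infection=remaining)


def compute_payoffs(
    state: HealthState, network: Network, config: PHGConfig
) -> np.ndarray:
    """Payoff per node: ``b * (healthy in closed neighborhood) - c * degree``
    for protectors, no cost term for defectors.

    Infection does not gate *receipt* of benefit: an infected individual still
    collects ``b`` per healthy local person, it just never counts itself.
    """
    adj = network.adjacency()
    healthy = state.healthy
    closed_healthy = neighbor_sum(adj, healthy.astype(np.float64)) + healthy
    payoff = config.benefit * closed_healthy
    deg = network.degrees()
    payoff[state.protect] -= config.cost * deg[state.protect]
    return payoff


def transmit_infection(
    state: HealthState,
    network: Network,
    config: PHGConfig,
    rng: np.random.Generator,
) -> HealthState:
    """Spread infection to healthy defectors.

    Each currently infected node — protector or defector, the shield blocks
    incoming but not outgoing transmission — independently infects each
    healthy defecting neighbor with probability ``infectivity``, so a defector
    with ``k`` infected neighbors escapes with ``(1 - infectivity)**k``.
    Newly infected nodes receive the full duration counter and transmit only
    from the next round on.
    """
    adj = network.adjacency()
    infected = state.infected
    k = neighbor_sum(adj, infected.astype(np.float64))
    p = 1.0 - (1.0 - config.infectivity) ** k
    at_risk = (~state.protect) & state.healthy
    new_inf = at_risk & (rng.random(state.protect.shape[0]) < p)
    out = state.copy()
    out.remaining_infection[new_inf] = config.infection_duration
    return out


def progress_infection(
    state: HealthState, config: PHGConfig, newly_infected: np.ndarray | None = None
) -> HealthState:
    """Decrement the infection counter of everyone infected before this round
    (nodes in ``newly_infected`` keep their full counter); at zero the node is
    healthy and fully susceptible again."""
    out = state.copy()
    old = out.remaining_infection > 0
    if newly_infected is not None:
        old &= ~newly_infected
    out.remaining_infection[old] -= 1
    return out


def imitate_best(
    state: HealthState, network: Network, payoffs: np.ndarray
) -> HealthState:
    """Synchronous imitate-the-best behavior update.

    A node switches to the other behavior iff the best payoff among
    closed-neighborhood holders of the other behavior strictly exceeds the
    best payoff among closed-neighborhood holders of its own behavior
    (self included).  Ties favor the incumbent behavior, and a node whose
    whole closed neighborhood shares its behavior never changes.  Infection
    status is untouched.
    """
    adj = network.adjacency()
    protect = state.protect
    best_protect = neighbor_max_where(adj, payoffs, protect)
    best_defect = neighbor_max_where(adj, payoffs, ~protect)
    own = np.where(protect, best_protect, best_defect)
    own = np.maximum(own, payoffs)  # self always holds its own behavior
    other = np.where(protect, best_defect, best_protect)
    out = state.copy()
    out.protect = protect ^ (other > own)
    return out


def step(
    state: HealthState,
    network: Network,
    config: PHGConfig,
    rng: np.random.Generator,
) -> HealthState:
    """One canonical round: transmit, recover, compute payoffs, imitate."""
    infected_before = state.infected
    state = transmit_infection(state, network, config, rng)
    newly = state.infected & ~infected_before
    state = progress_infection(state, config, newly_infected=newly)
    payoffs = compute_payoffs(state, network, config)
    return imitate_best(state, network, payoffs)


def run(
    network: Network,
    config: PHGConfig,
    rng: np.random.Generator,
) -> tuple[Trajectory, RunSummary]:
    """Run the game for ``config.n_steps`` rounds from a fresh initialization.

    The trajectory records compartment counts at step 0 (initial state) and
    after every round; summary means are taken over steps ``burn_in`` onward.
    """
    state = initialize_population(network, config, rng)
    rows = np.empty((config.n_steps + 1, 4), dtype=np.int64)
    rows[0] = state.counts()
    for t in range(1, config.n_steps + 1):
        state = step(state, network, config, rng)
        rows[t] = state.counts()
    traj = Trajectory(rows[:, 0], rows[:, 1], rows[:, 2], rows[:, 3])
    sel = slice(config.burn_in, None)
    summary = RunSummary(
        mean_prop_infected=float(traj.prop_infected()[sel].mean()),
        mean_prop_protecting=float(traj.prop_protecting()[sel].mean()),
        protection_survived=bool(traj.prop_protecting()[-1] > 0),
        burn_in=config.burn_in,
    )
    return traj, summary


def state_grid(state: HealthState, network: Network) -> np.ndarray:
    """Side x side matrix of state codes for spatial inspection.

    Codes: 0 healthy protector, 1 infected protector, 2 healthy defector,
    3 infected defector.  Requires a grid-derived network.
    """
    if network.side is None:
        raise ValueError("state_grid requires a grid-derived network")
    code = np.where(
        state.protect,
        np.where(state.healthy, 0, 1),
        np.where(state.healthy, 2, 3),
    )
    return code.reshape(network.side, network.side)
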