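"""Three-strain cyclic-dominance ("rock-paper-scissors") microbial game.

Three E. coli strategy types compete on a contact network: an antibiotic
*producer* kills the antibiotic-sensitive fast *grower*; a *resister*
withstands the antibiotic and outcompetes the producer; the grower outgrows
the resister.  Each round every cell scores one point per neighbor it beats
(the producer's win over a grower succeeds only with probability
``attack_rate`` per encounter), pays its strain's flat per-round cost, and
then everyone synchronously adopts the strain of the highest-scoring member
of its closed neighborhood — the same imitate-the-best rule as the public
health game, with the incumbent strain winning ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._neigh import neighbor_max_where, neighbor_sum
from .networks import Network

__all__ = [
    "PRODUCER",
    "RESISTER",
    "GROWER",
    "STRAIN_NAMES",
    "RPSConfig",
    "RPSSummary",
    "initialize_strains",
    "compute_rps_payoffs",
    "rps_step",
    "rps_run",
]

PRODUCER, RESISTER, GROWER = 0, 1, 2
STRAIN_NAMES = ("producer", "resister", "grower")
# prey[s] is the strain that s beats: producer beats grower, resister beats
# producer, grower beats resister
_PREY = np.array([GROWER, PRODUCER, RESISTER])


@dataclass(frozen=True)
class RPSConfig:
    """Parameters of the three-strain game.

    ``attack_rate`` is the probability that a producer gains its point per
    grower neighbor per round (1.0 = always wins the encounter, 0.0 = never).
    Costs are flat per-round payoff deductions per strain; the base game sets
    them to zero, and because a uniform cost shift cannot change any
    imitate-the-best comparison, setting all three costs equal reproduces the
    zero-cost dynamics exactly.
    """

    attack_rate: float = 1.0
    cost_producer: float = 0.0
    cost_resister: float = 0.0
    cost_grower: float = 0.0
    n_steps: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.attack_rate <= 1.0:
            raise ValueError("attack_rate must lie in [0, 1]")
        if min(self.cost_producer, self.cost_resister, self.cost_grower) < 0:
            raise ValueError("costs must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be a positive integer")

    @property
    def costs(self) -> np.ndarray:
        return np.array([self.cost_producer, self.cost_resister, self.cost_grower])


@dataclass(frozen=True)
class RPSSummary:
    """Run-level summary: time-averaged strain proportions (over all recorded
    steps including the initial state), whether one strain occupies every node
    at the final step, and the first step at which each strain hit zero
    (None if it never went extinct)."""

    mean_prop: tuple[float, float, float]
    dominated: bool
    dominant_strain: int | None
    first_extinction_step: tuple[int | None, int | None, int | None]


def initialize_strains(network: Network, rng: np.random.Generator) -> np.ndarray:
    """Assign strains by a random permutation of an as-equal-as-possible
    multiset (counts differ by at most 1), one third of nodes per strain."""
    n = network.n_nodes
    base, extra = divmod(n, 3)
    counts = np.full(3, base)
    counts[rng.permutation(3)[:extra]] += 1
    strains = np.repeat(np.arange(3), counts)
    return strains[rng.permutation(n)]


def compute_rps_payoffs(
    strains: np.ndarray,
    network: Network,
    config: RPSConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One point per beaten neighbor, minus the strain's flat cost.

    Resister-vs-producer and grower-vs-resister wins are deterministic counts;
    each producer's wins against its grower neighbors are a fresh
    ``Binomial(k, attack_rate)`` draw each round (independent Bernoulli per
    directed producer-grower encounter).
    """
    adj = network.adjacency()
    n_by_strain = np.stack(
        [neighbor_sum(adj, (strains == s).astype(np.float64)) for s in range(3)]
    )
    prey_count = n_by_strain[_PREY[strains], np.arange(strains.shape[0])]
    wins = prey_count.copy()
    producer_mask = strains == PRODUCER
    k_grower = prey_count * producer_mask  # grower neighbors, producers only
    draws = rng.binomial(k_grower.astype(np.int64), config.attack_rate)
    wins[producer_mask] = draws[producer_mask]
    return wins - config.costs[strains]


def rps_step(
    strains: np.ndarray,
    network: Network,
    config: RPSConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synchronous imitate-the-best strain update.

    Each node adopts the strain of the maximum-payoff member of its closed
    neighborhood.  If the maximum is attained by a holder of the node's own
    strain (itself included), the node keeps its strain; when two other
    strains tie at a strictly higher value the node picks one uniformly at
    random.
    """
    adj = network.adjacency()
    payoffs = compute_rps_payoffs(strains, network, config, rng)
    n = strains.shape[0]
    best = np.stack(
        [neighbor_max_where(adj, payoffs, strains == s) for s in range(3)], axis=1
    )
    idx = np.arange(n)
    best[idx, strains] = np.maximum(best[idx, strains], payoffs)
    overall = best.max(axis=1)
    keep = best[idx, strains] >= overall
    at_max = best == overall[:, None]
    first = at_max.argmax(axis=1)
    last = 2 - at_max[:, ::-1].argmax(axis=1)
    pick = np.where(rng.random(n) < 0.5, first, last)
    return np.where(keep, strains, pick)


def strain_counts(strains: np.ndarray) -> np.ndarray:
    return np.bincount(strains, minlength=3)


def rps_run(
    network: Network,
    config: RPSConfig,
    rng: np.random.Generator,
    strains: np.ndarray | None = None,
) -> tuple[pd.DataFrame, RPSSummary]:
    """Run the game for ``config.n_steps`` rounds.

    Returns the per-step strain counts (row 0 = initial state) and a summary.
    An explicit initial ``strains`` array may be supplied; by default the
    equal-thirds random initialization is used.
    """
    if strains is None:
        strains = initialize_strains(network, rng)
    else:
        strains = np.asarray(strains)
    rows = np.empty((config.n_steps + 1, 3), dtype=np.int64)
    rows[0] = strain_counts(strains)
    for t in range(1, config.n_steps + 1):
        strains = rps_step(strains, network, config, rng)
        rows[t] = strain_counts(strains)
    props = rows / network.n_nodes
    mean_prop = tuple(float(x) for x in props.mean(axis=0))
    final = rows[-1]
    dominated = bool(np.max(final) == network.n_nodes)
    dominant = int(np.argmax(final)) if dominated else None
    first_ext = []
    for s in range(3):
        zero = np.flatnonzero(rows[:, s] == 0)
        first_ext.append(int(zero[0]) if zero.size else None)
    traj = pd.DataFrame(
        {
            "step": np.arange(config.n_steps + 1),
            "n_producer": rows[:, 0],
            "n_resister": rows[:, 1],
            "n_grower": rows[:, 2],
        }
    )
    summary = RPSSummary(
        mean_prop=mean_prop,
        dominated=dominated,
        dominant_strain=dominant,
        first_extinction_step=tuple(first_ext),
    )
    return traj, summary


def strain_grid(strains: np.ndarray, network: Network) -> np.ndarray:
    """Side x side matrix of strain codes (0 producer, 1 resister, 2 grower)."""
    if network.side is None:
        raise ValueError("strain_grid requires a grid-derived network")
    return np.asarray(strains).reshape(network.side, network.side)
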