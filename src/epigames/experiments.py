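"""Parameter sweeps and threshold/bimodality detectors.

Every sweep runs one fresh, independently initialized simulation per
(parameter value, replicate) pair and returns a tidy table with one row per
run.  Per-run seeds are derived deterministically from a single master seed
together with the sweep name, value index, and replicate index, so a whole
sweep is reproducible end-to-end from the master seed while runs remain
statistically independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .networks import (
    Network,
    build_grid_lattice,
    build_random_network,
    rewire_network,
)
from .phgame import PHGConfig, run
from .rpsgame import STRAIN_NAMES, RPSConfig, rps_run

__all__ = [
    "derive_seed",
    "build_network",
    "sweep_benefit",
    "sweep_infectivity",
    "sweep_rewiring",
    "sweep_attack_rate",
    "sweep_producer_cost",
    "find_survival_threshold",
    "ThresholdResult",
    "classify_bimodal",
    "BimodalResult",
]


def derive_seed(master_seed: int, name: str, value_index: int, replicate: int) -> int:
    """Deterministic per-run seed from a master seed and run coordinates."""
    ss = np.random.SeedSequence(
        [int(master_seed), zlib.crc32(name.encode()), value_index, replicate]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def build_network(spec: dict, rng: np.random.Generator | None = None) -> Network:
    """Build a network from a declarative spec dict.

    Keys: ``kind`` (grid | random | rewired_grid), ``side`` (grid-derived),
    ``n_nodes`` and ``mean_degree`` (random), ``n_rewired_edges`` or
    ``fraction_rewired`` plus optional ``method`` (rewired_grid).
    """
    kind = spec["kind"]
    if kind == "grid":
        return build_grid_lattice(spec["side"])
    if kind == "random":
        return build_random_network(
            spec["n_nodes"], spec.get("mean_degree", 8.0), rng=rng
        )
    if kind == "rewired_grid":
        grid = build_grid_lattice(spec["side"])
        if "n_rewired_edges" in spec:
            n_rewired = int(spec["n_rewired_edges"])
        else:
            n_rewired = round(spec["fraction_rewired"] * grid.n_edges)
        return rewire_network(
            grid, n_rewired, rng=rng, method=spec.get("method", "degree_preserving_swap")
        )
    raise ValueError(f"unknown network kind: {kind!r}")


def _phg_rows(
    network_spec: dict,
    configs: Sequence[tuple[str, float, PHGConfig]],
    reps: int,
    master_seed: int,
    sweep_name: str,
) -> pd.DataFrame:
    rows = []
    for i, (param, value, config) in enumerate(configs):
        for r in range(reps):
            seed = derive_seed(master_seed, sweep_name, i, r)
            rng = np.random.default_rng(seed)
            net = build_network(network_spec, rng)
            _, summary = run(net, config, rng)
            rows.append(
                {
                    "parameter": param,
                    "value": value,
                    "replicate": r,
                    "seed": seed,
                    "mean_prop_infected": summary.mean_prop_infected,
                    "mean_prop_protecting": summary.mean_prop_protecting,
                    "protection_survived": summary.protection_survived,
                }
            )
    return pd.DataFrame(rows)


def sweep_benefit(
    network_spec: dict,
    b_values: Sequence[float],
    base_config: PHGConfig,
    reps: int = 5,
    master_seed: int = 0,
) -> pd.DataFrame:
    """One fresh run per (benefit value, replicate); records mean proportion
    infected and whether protection survived to the final step."""
    if len(b_values) == 0:
        raise ValueError("b_values must be non-empty")
    configs = [("benefit", b, replace(base_config, benefit=b)) for b in b_values]
    return _phg_rows(network_spec, configs, reps, master_seed, "benefit")


def sweep_infectivity(
    b: float,
    infectivity_values: Sequence[float],
    reps: int = 10,
    network_spec: dict | None = None,
    base_config: PHGConfig | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Per-level, per-replicate mean proportion infected at fixed benefit.

    Averaging the replicate column per level gives the hill-shaped
    infectivity-response curve of the coexistence regime.
    """
    if network_spec is None:
        network_spec = {"kind": "grid", "side": 61}
    if base_config is None:
        base_config = PHGConfig(benefit=b)
    configs = [
        ("infectivity", v, replace(base_config, benefit=b, infectivity=v))
        for v in infectivity_values
    ]
    return _phg_rows(network_spec, configs, reps, master_seed, "infectivity")


def _rps_row(summary, extras: dict) -> dict:
    row = dict(extras)
    for s, name in enumerate(STRAIN_NAMES):
        row[f"mean_prop_{name}"] = summary.mean_prop[s]
    row["dominated"] = summary.dominated
    row["dominant_strain"] = (
        STRAIN_NAMES[summary.dominant_strain]
        if summary.dominant_strain is not None
        else None
    )
    return row


def sweep_rewiring(
    fractions: Sequence[float],
    rps_config: RPSConfig,
    reps: int = 5,
    side: int = 61,
    master_seed: int = 0,
    method: str = "degree_preserving_swap",
) -> pd.DataFrame:
    """Three-strain game on progressively rewired lattices.

    ``fractions`` are the fractions of lattice edges rewired (a fresh
    rewiring per replicate).  Records time-averaged and final strain
    proportions and whether a single strain had taken over by the final step.
    """
    rows = []
    for i, frac in enumerate(fractions):
        for r in range(reps):
            seed = derive_seed(master_seed, "rewiring", i, r)
            rng = np.random.default_rng(seed)
            grid = build_grid_lattice(side)
            net = rewire_network(grid, round(frac * grid.n_edges), rng, method=method)
            traj, summary = rps_run(net, rps_config, rng)
            final = traj.iloc[-1]
            row = _rps_row(
                summary,
                {"parameter": "fraction_rewired", "value": frac, "replicate": r, "seed": seed},
            )
            for s, name in enumerate(STRAIN_NAMES):
                row[f"final_prop_{name}"] = final[f"n_{name}"] / net.n_nodes
            rows.append(row)
    return pd.DataFrame(rows)


def sweep_attack_rate(
    a_values: Sequence[float],
    rps_config: RPSConfig,
    reps: int = 5,
    side: int = 61,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Three-strain game on the unrewired grid across producer attack rates."""
    rows = []
    for i, a in enumerate(a_values):
        for r in range(reps):
            seed = derive_seed(master_seed, "attack_rate", i, r)
            rng = np.random.default_rng(seed)
            net = build_grid_lattice(side)
            _, summary = rps_run(net, replace(rps_config, attack_rate=a), rng)
            rows.append(
                _rps_row(
                    summary,
                    {"parameter": "attack_rate", "value": a, "replicate": r, "seed": seed},
                )
            )
    return pd.DataFrame(rows)


def sweep_producer_cost(
    reduction_fractions: Sequence[float],
    rps_config: RPSConfig | None = None,
    reps: int = 10,
    side: int = 61,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Reduce the producer's per-round cost below the common unit cost.

    Starts from all three strains paying cost 1 and lowers the producer's
    cost by each fraction in ``reduction_fractions`` (0 = all equal,
    1 = producer pays nothing).
    """
    if rps_config is None:
        rps_config = RPSConfig(cost_producer=1.0, cost_resister=1.0, cost_grower=1.0)
    rows = []
    for i, red in enumerate(reduction_fractions):
        cfg = replace(rps_config, cost_producer=rps_config.cost_producer * (1.0 - red))
        for r in range(reps):
            seed = derive_seed(master_seed, "producer_cost", i, r)
            rng = np.random.default_rng(seed)
            net = build_grid_lattice(side)
            _, summary = rps_run(net, cfg, rng)
            rows.append(
                _rps_row(
                    summary,
                    {
                        "parameter": "cost_reduction",
                        "value": red,
                        "replicate": r,
                        "seed": seed,
                    },
                )
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdResult:
    """Smallest parameter value at which an outcome holds in a majority of
    replicates.  ``warning`` flags a non-monotone majority pattern;
    ``degenerate`` flags sweeps where the outcome held at every level."""

    value: float | None
    warning: bool = False
    degenerate: bool = False


def find_survival_threshold(
    table: pd.DataFrame,
    outcome: str = "protection_survived",
    param_col: str = "value",
) -> ThresholdResult:
    """Detect the tipping value of a sweep via a per-level majority vote.

    Requires at least two parameter levels.  Returns ``value=None`` when the
    outcome never reaches a majority.  If majorities are non-monotone in the
    parameter, the smallest qualifying value is still returned, flagged with
    ``warning``; if every level qualifies, the smallest value is returned
    flagged ``degenerate``.
    """
    levels = table.groupby(param_col)[outcome].agg(["sum", "count"]).sort_index()
    if len(levels) < 2:
        raise ValueError("threshold detection needs at least two parameter levels")
    majority = levels["sum"] * 2 > levels["count"]
    if not majority.any():
        return ThresholdResult(value=None)
    first = majority.idxmax()
    hit = majority.values
    start = int(np.argmax(hit))
    monotone = bool(np.all(hit[start:]))
    return ThresholdResult(
        value=float(first), warning=not monotone, degenerate=bool(majority.all())
    )


@dataclass(frozen=True)
class BimodalResult:
    lower_mode: float
    upper_mode: float | None
    n_lower: int
    n_upper: int
    bimodal: bool


def classify_bimodal(run_means: Sequence[float], gap: float = 0.2) -> BimodalResult:
    """Split run-level means at the largest gap in their sorted order.

    If the largest adjacent gap exceeds ``gap``, the values are partitioned
    there and each cluster's mean and size is reported (lower mode first);
    otherwise a single mode (the overall mean) is reported.
    """
    values = np.sort(np.asarray(run_means, dtype=float))
    if values.size < 4:
        raise ValueError("bimodality classification needs at least 4 run means")
    gaps = np.diff(values)
    k = int(np.argmax(gaps))
    if gaps[k] <= gap:
        return BimodalResult(
            lower_mode=float(values.mean()),
            upper_mode=None,
            n_lower=int(values.size),
            n_upper=0,
            bimodal=False,
        )
    lower, upper = values[: k + 1], values[k + 1 :]
    return BimodalResult(
        lower_mode=float(lower.mean()),
        upper_mode=float(upper.mean()),
        n_lower=int(lower.size),
        n_upper=int(upper.size),
        bimodal=True,
    )
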