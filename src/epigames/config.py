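"""Declarative run configuration: schema, validation, YAML round-trip.

A config file names the game, the network, the game parameters, and the seed.
Unknown keys are rejected, invalid values are reported with their key path,
and a loaded config dumps back to an equivalent file (load -> dump -> load is
the identity on the validated model).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .experiments import build_network
from .phgame import PHGConfig, run
from .rpsgame import RPSConfig, rps_run

__all__ = ["RunConfigFile", "load_config", "dump_config", "run_from_config"]


class NetworkSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["grid", "random", "rewired_grid"]
    side: Optional[int] = Field(default=None, ge=3)
    n_nodes: Optional[int] = Field(default=None, ge=9)
    mean_degree: float = Field(default=8.0, gt=0)
    fraction_rewired: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    method: Literal["degree_preserving_swap", "delete_and_replace"] = (
        "degree_preserving_swap"
    )

    @model_validator(mode="after")
    def _check_fields(self) -> "NetworkSpec":
        if self.kind in ("grid", "rewired_grid") and self.side is None:
            raise ValueError(f"network.side is required for kind={self.kind}")
        if self.kind == "random" and self.n_nodes is None:
            raise ValueError("network.n_nodes is required for kind=random")
        if self.kind == "rewired_grid" and self.fraction_rewired is None:
            raise ValueError(
                "network.fraction_rewired is required for kind=rewired_grid"
            )
        return self


class PHGameParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    benefit: float = Field(ge=0)  # required: the b/c ratio drives everything
    cost: float = Field(default=1.0, ge=0)
    infectivity: float = Field(default=1.0, ge=0.0, le=1.0)
    infection_duration: int = Field(default=5, ge=1)
    init_protect_frac: float = Field(default=0.5, ge=0.0, le=1.0)
    init_infect_frac: float = Field(default=0.10, ge=0.0, le=1.0)
    n_steps: int = Field(default=500, ge=1)
    burn_in: int = Field(default=0, ge=0)

    def to_config(self) -> PHGConfig:
        return PHGConfig(**self.model_dump())


class RPSParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    attack_rate: float = Field(default=1.0, ge=0.0, le=1.0)
    cost_producer: float = Field(default=0.0, ge=0)
    cost_resister: float = Field(default=0.0, ge=0)
    cost_grower: float = Field(default=0.0, ge=0)
    n_steps: int = Field(default=500, ge=1)

    def to_config(self) -> RPSConfig:
        return RPSConfig(**self.model_dump())


class RunConfigFile(BaseModel):
    model_config = ConfigDict(extra="forbid")

    game: Literal["phgame", "rps"]
    network: NetworkSpec
    phgame: Optional[PHGameParams] = None
    rps: Optional[RPSParams] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check_game_section(self) -> "RunConfigFile":
        if self.game == "phgame" and self.phgame is None:
            raise ValueError("phgame section (with benefit) is required for game=phgame")
        if self.game == "rps" and self.rps is None:
            raise ValueError("rps section is required for game=rps")
        return self


def load_config(path) -> RunConfigFile:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return RunConfigFile.model_validate(raw)


def dump_config(config: RunConfigFile, path) -> None:
    """Write a validated configuration back to YAML with defaults filled."""
    data = config.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def run_from_config(config: RunConfigFile) -> pd.DataFrame:
    """Execute the run a configuration describes; returns the trajectory table.

    All randomness (network construction and game dynamics) flows from a
    single generator seeded with ``config.seed``, so the result is a pure
    function of the configuration.
    """
    rng = np.random.default_rng(config.seed)
    net = build_network(config.network.model_dump(exclude_none=True), rng)
    if config.game == "phgame":
        traj, _ = run(net, config.phgame.to_config(), rng)
        return traj.to_dataframe()
    traj, _ = rps_run(net, config.rps.to_config(), rng)
    return traj
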