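"""Validated run configuration, output writing, and random fixture generation.

JSON is the canonical config dialect (bit-exact round-tripping); YAML is
accepted read-only.  Every output file embeds the SHA-256 hash of the
canonical config plus the seed, so any run can be reproduced exactly
from its artefacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .altruism import EncounterConfig
from .equilibrium import EquilibriumResult, IdentityDiagnostic
from .dynamics import Trajectory
from .games import (
    ContestRules,
    GameValidationError,
    GeneralizedMigraineGame,
    MigraineGameParams,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_config",
    "write_outputs",
    "config_hash",
    "generate_random_scenario",
]


class ConfigError(ValueError):
    """Configuration file failed validation; message names the JSON path."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ContestRulesBlock(_Strict):
    win_value: float
    loss_value: float
    injury_value: float
    time_cost: float

    def build(self) -> ContestRules:
        return ContestRules(**self.model_dump())


class MigraineParamsBlock(_Strict):
    c_m: float
    c_n: float
    d_m_prime: float
    d_m_base: float = 1.0

    def build(self) -> MigraineGameParams:
        return MigraineGameParams(**self.model_dump())


class GeneralizedGameBlock(_Strict):
    f_n: float
    f_m: float
    d_m: float
    d_n: float
    d_m_prime: Optional[float] = None

    def build(self) -> GeneralizedMigraineGame:
        d = self.model_dump()
        if d["d_m_prime"] is None:
            del d["d_m_prime"]
        return GeneralizedMigraineGame(**d)


class DynamicsBlock(_Strict):
    p0: float = 0.5
    dt: float = 0.01
    t_max: float = 1e4
    tol: float = 1e-8
    N: int = 1000
    generations: int = 500
    intensity: float = 0.1
    mutation_rate: float = 0.0


class AbmBlock(_Strict):
    n_agents: int = 24
    migraineur_fraction: float = 0.14
    n_rounds: int = 1000
    predator_prob: float = 0.2
    attack_prob: float = 0.25
    defect_prob: float = 0.0
    agreement: bool = True
    repeat_interaction: bool = True
    recognition: bool = True
    memory: bool = True

    def build(self, game: GeneralizedMigraineGame, seed: int) -> EncounterConfig:
        return EncounterConfig(game=game, seed=seed, **self.model_dump())


class SweepBlock(_Strict):
    parameter: str
    start: float
    stop: float
    steps: int = 11
    form: Literal["generalized", "printed"] = "generalized"

    def grid(self) -> list[float]:
        return list(np.linspace(self.start, self.stop, self.steps))


class RunConfig(_Strict):
    """Full run description: exactly one game-parameter block plus options."""

    subcommand: Optional[str] = None
    contest_rules: Optional[ContestRulesBlock] = None
    migraine_params: Optional[MigraineParamsBlock] = None
    generalized_game: Optional[GeneralizedGameBlock] = None
    dynamics: DynamicsBlock = DynamicsBlock()
    abm: AbmBlock = AbmBlock()
    sweep: Optional[SweepBlock] = None
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_parameter_block(self) -> "RunConfig":
        blocks = [
            b
            for b in (self.contest_rules, self.migraine_params, self.generalized_game)
            if b is not None
        ]
        if len(blocks) != 1:
            raise ValueError(
                "exactly one of contest_rules / migraine_params / "
                f"generalized_game must be given, found {len(blocks)}"
            )
        return self


def _format_pydantic_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        path = ".".join(str(x) for x in err["loc"]) or "<root>"
        parts.append(f"{path}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON (or YAML, read-only) config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_pydantic_error(exc)) from exc
    # surface game-parameter ordering violations at load time, with the block name
    for name in ("contest_rules", "migraine_params", "generalized_game"):
        block = getattr(cfg, name)
        if block is not None:
            try:
                block.build()
            except GameValidationError as exc:
                raise ConfigError(f"{name}: {exc}") from exc
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(canonical_json(cfg) + "\n")


def canonical_json(cfg: RunConfig) -> str:
    return json.dumps(cfg.model_dump(), sort_keys=True, separators=(",", ":"))


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 of the canonical JSON form; enables exact rerun audits."""
    return hashlib.sha256(canonical_json(cfg).encode()).hexdigest()


def _result_to_dict(result: Any) -> dict:
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        return dataclasses.asdict(result)
    raise TypeError(f"unsupported result type {type(result)!r}")


def write_outputs(
    result: Any,
    path: str | Path,
    cfg: RunConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Write a module result to disk with provenance embedded.

    ``EquilibriumResult`` / ``IdentityDiagnostic`` become JSON;
    ``Trajectory`` and DataFrames (ledgers, sweep tables) become CSV
    with '#'-prefixed provenance lines and 12-significant-digit floats.
    """
    path = Path(path)
    meta = {
        "config_hash": config_hash(cfg) if cfg is not None else None,
        "seed": seed if seed is not None else (cfg.seed if cfg is not None else None),
    }
    if isinstance(result, (EquilibriumResult, IdentityDiagnostic)):
        payload = {**_result_to_dict(result), **meta}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path
    if isinstance(result, Trajectory):
        frame = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        frame = result
    else:
        raise TypeError(f"unsupported result type {type(result)!r}")
    with path.open("w") as fh:
        fh.write(f"# config_hash={meta['config_hash']}\n# seed={meta['seed']}\n")
        frame.to_csv(fh, index=False, float_format="%.12g")
    return path


def generate_random_scenario(
    seed: int | np.random.SeedSequence,
    form: Literal["hawk_dove", "migraine_general", "migraine_printed"],
):
    """Draw a random parameter set guaranteed to satisfy its invariants.

    Parameters are drawn uniformly within documented ranges, ordered by
    construction so no rejection is needed; reproducible by seed.

    Ranges: hawk_dove draws win in [10, 100], loss in [-20, win),
    injury in [loss-200, loss-10), time_cost in [-30, 0]; the migraine
    forms draw fitness gaps in [0.05, 0.3] above a base d_n in
    [0.6, 0.9] (generalized) or costs c_n in [0.05, 0.4] with
    c_m - c_n in [0.01, 0.4] (printed).
    """
    rng = np.random.default_rng(seed)
    if form == "hawk_dove":
        win = rng.uniform(10.0, 100.0)
        loss = rng.uniform(-20.0, win)
        injury = rng.uniform(loss - 200.0, loss - 10.0)
        time_cost = rng.uniform(-30.0, 0.0)
        return ContestRules(win, loss, injury, time_cost)
    if form == "migraine_general":
        d_n = rng.uniform(0.6, 0.9)
        g1, g2, g3 = rng.uniform(0.05, 0.3, size=3)
        d_m = d_n + g1
        f_m = d_m + g2
        f_n = f_m + g3
        d_m_prime = rng.uniform(max(0.0, d_n - 0.3), d_n)
        return GeneralizedMigraineGame(f_n, f_m, d_m, d_n, d_m_prime)
    if form == "migraine_printed":
        c_n = rng.uniform(0.05, 0.4)
        c_m = c_n + rng.uniform(0.01, 0.4)
        d_m_prime = rng.uniform(0.0, max(1e-9, 1.0 - c_m - 1e-6))
        return MigraineGameParams(c_m=c_m, c_n=c_n, d_m_prime=d_m_prime)
    raise ValueError(f"unknown scenario form {form!r}")
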