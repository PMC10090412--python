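"""Comparative statics: equilibrium migraineur fraction versus model parameters.

On the constant-fitness game the interior equilibrium has closed form
``p* = (d_m - d_n) / ((d_m - d_n) + (f_n - f_m))``, so the qualitative
predictions are immediate: lowering the unaided non-migraineur fitness
``d_n`` (a population with more vulnerable members) raises the
equilibrium migraineur fraction, and widening the migraineur's
maintenance gap ``f_n - f_m`` lowers it.  The sweep machinery evaluates
these directions numerically on a parameter grid, flagging grid points
where the fitness ordering breaks instead of silently dropping them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import pandas as pd

from .equilibrium import mixed_equilibrium
from .games import (
    GameValidationError,
    GeneralizedMigraineGame,
    MigraineGameParams,
    migraine_game_generalized,
    migraine_game_printed,
)

__all__ = ["SweepSpec", "MonotonicityResult", "sweep_equilibrium", "monotonicity_test"]

_GENERAL_PARAMS = ("d_n", "f_m", "f_n", "d_m", "d_m_prime")
_PRINTED_PARAMS = ("c_m", "c_n", "d_m_prime")


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter grid sweep over one of the two game forms."""

    parameter: str
    grid: Sequence[float]
    fixed: GeneralizedMigraineGame | MigraineGameParams
    form: Literal["generalized", "printed"] = "generalized"

    def __post_init__(self) -> None:
        allowed = _GENERAL_PARAMS if self.form == "generalized" else _PRINTED_PARAMS
        if self.parameter not in allowed:
            raise ValueError(
                f"parameter {self.parameter!r} not sweepable for form "
                f"{self.form!r}; expected one of {allowed}"
            )
        if len(self.grid) == 0:
            raise ValueError("sweep grid is empty")


def sweep_equilibrium(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the mixed equilibrium at each grid point.

    Returns a table with columns ``param_value, p_star, payoff, stable,
    status``; grid points whose parameters violate the game's ordering
    invariants get ``status='skipped: <reason>'`` and NaN values.
    """
    rows = []
    for value in spec.grid:
        try:
            params = replace(spec.fixed, **{spec.parameter: value})
            game = (
                migraine_game_generalized(params)
                if spec.form == "generalized"
                else migraine_game_printed(params)
            )
            res = mixed_equilibrium(game)
            rows.append((value, res.p_star, res.payoff_at_eq, res.stable, res.status))
        except GameValidationError as exc:
            rows.append((value, math.nan, math.nan, False, f"skipped: {exc}"))
    return pd.DataFrame(
        rows, columns=["param_value", "p_star", "payoff", "stable", "status"]
    )


@dataclass(frozen=True)
class MonotonicityResult:
    status: Literal["pass", "fail", "inconclusive"]
    first_violation: tuple[float, float] | None = None  # (param_value_i, param_value_j)

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def monotonicity_test(
    table: pd.DataFrame,
    parameter: str,
    expected_direction: Literal["increasing", "decreasing"],
) -> MonotonicityResult:
    """Check that p_star moves monotonically with the swept parameter.

    The table must be sorted by ``param_value`` (ascending); adjacent
    *valid* rows are compared in the stated direction.  Fewer than two
    valid rows is inconclusive.
    """
    values = table["param_value"].to_numpy()
    if any(values[i] > values[i + 1] for i in range(len(values) - 1)):
        raise ValueError("table must be sorted ascending by param_value")
    valid = table[~table["status"].astype(str).str.startswith("skipped")]
    if len(valid) < 2:
        return MonotonicityResult(status="inconclusive")
    ps = valid["p_star"].to_numpy()
    vals = valid["param_value"].to_numpy()
    for i in range(len(ps) - 1):
        ok = ps[i + 1] > ps[i] if expected_direction == "increasing" else ps[i + 1] < ps[i]
        if not ok:
            return MonotonicityResult(
                status="fail", first_violation=(float(vals[i]), float(vals[i + 1]))
            )
    return MonotonicityResult(status="pass")
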