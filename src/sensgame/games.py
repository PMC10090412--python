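"""Two-strategy evolutionary games built from contest or cost parameters.

Two families of games are provided:

* The classic Hawk-Dove contest, scored from four primitives (win, loss,
  injury, time-wasting).  Symmetric contests (hawk-hawk, dove-dove) are
  settled by a fair coin flip, so their cells are expected values over
  both outcomes.
* A migraineur/non-migraineur cooperation game in which hypersensitive
  individuals ("migraineurs") detect predators early and warn partners at
  a cost, and less sensitive partners repay by rescuing migraineurs who
  are incapacitated by an attack.  The game exists in two forms: the
  frequency-dependent "printed" form parameterised by the two costs
  (c_m, c_n), and a constant-fitness generalisation parameterised by the
  four fitness levels f_n > f_m > d_m > d_n directly.

All games are symmetric 2x2 games exposed through :class:`StaticGame`,
whose payoff is a function ``payoff(actor, partner, p)`` where ``p`` is
always the frequency of the *focal* strategy (dove, or migraineur).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

__all__ = [
    "GameValidationError",
    "ContestRules",
    "StaticGame",
    "MigraineGameParams",
    "GeneralizedMigraineGame",
    "CostBenefitRecord",
    "hawk_dove_game",
    "migraine_game_printed",
    "migraine_game_generalized",
    "derive_costs_benefits",
]


class GameValidationError(ValueError):
    """A game parameter set violates one of its ordering invariants."""


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise GameValidationError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ContestRules:
    """Scoring primitives for the Hawk-Dove contest.

    Parameters
    ----------
    win_value
        Points for winning the contested resource.
    loss_value
        Points for conceding.
    injury_value
        Points for serious injury or death (typically large and negative).
    time_cost
        Signed points for a drawn-out display contest (e.g. -10).
    """

    win_value: float
    loss_value: float
    injury_value: float
    time_cost: float

    def __post_init__(self) -> None:
        for name in ("win_value", "loss_value", "injury_value", "time_cost"):
            _require_finite(name, getattr(self, name))
        if not self.injury_value < self.loss_value:
            raise GameValidationError(
                "invariant injury_value < loss_value violated: "
                f"{self.injury_value} >= {self.loss_value}"
            )
        if not self.loss_value <= self.win_value:
            raise GameValidationError(
                "invariant loss_value <= win_value violated: "
                f"{self.loss_value} > {self.win_value}"
            )


@dataclass(frozen=True)
class StaticGame:
    """A symmetric 2x2 game, possibly with frequency-dependent cells.

    ``payoff(actor, partner, p)`` returns the payoff to ``actor`` when
    paired with ``partner`` while the focal strategy has population
    frequency ``p``.  For frequency-independent games the ``p`` argument
    is ignored.
    """

    focal_label: str
    other_label: str
    payoff: Callable[[str, str, float], float]
    frequency_dependent: bool = False

    @property
    def strategies(self) -> tuple[str, str]:
        return (self.focal_label, self.other_label)

    def payoff_matrix(self, p: float = 0.5):
        """Return the 2x2 cell array [[a_ff, a_fo], [a_of, a_oo]] at ``p``.

        Rows index the actor (focal first), columns the partner.
        """
        f, o = self.focal_label, self.other_label
        return [
            [self.payoff(f, f, p), self.payoff(f, o, p)],
            [self.payoff(o, f, p), self.payoff(o, o, p)],
        ]

    def validate(self, n_grid: int = 11) -> None:
        """Check that every cell is finite across a grid of frequencies."""
        for k in range(n_grid):
            p = k / (n_grid - 1)
            for row in self.payoff_matrix(p):
                for v in row:
                    _require_finite("payoff cell", v)


def _constant_game(
    focal: str, other: str, a_ff: float, a_fo: float, a_of: float, a_oo: float
) -> StaticGame:
    cells = {
        (focal, focal): a_ff,
        (focal, other): a_fo,
        (other, focal): a_of,
        (other, other): a_oo,
    }

    def payoff(actor: str, partner: str, p: float = 0.0) -> float:
        try:
            return cells[(actor, partner)]
        except KeyError:
            raise KeyError(f"unknown strategy pair ({actor!r}, {partner!r})") from None

    return StaticGame(focal, other, payoff, frequency_dependent=False)


def hawk_dove_game(rules: ContestRules) -> StaticGame:
    """Build the Hawk-Dove game from contest scoring primitives.

    Symmetric contests are won by either party with probability 1/2, so
    hawk-hawk averages the win and injury outcomes and dove-dove averages
    win and loss, with both doves paying the time cost.  The focal
    strategy is *dove*: in all downstream computations ``p`` is the dove
    frequency.
    """
    a_hh = (rules.win_value + rules.injury_value) / 2.0
    a_hd = rules.win_value
    a_dh = rules.loss_value
    a_dd = (rules.win_value + rules.loss_value) / 2.0 + rules.time_cost
    return _constant_game("dove", "hawk", a_dd, a_dh, a_hd, a_hh)


@dataclass(frozen=True)
class MigraineGameParams:
    """Cost parameterisation of the migraineur/non-migraineur game.

    The baseline fitness of a rescued migraineur, ``d_m_base``, is fixed
    at 1; all other fitness levels are measured around it (rescaling is
    multiplicative).  Derived levels:

    * ``f_n = 1 + c_n`` -- non-migraineur warned by a migraineur,
    * ``d_n = 1 - (c_m - c_n)`` -- non-migraineur among non-migraineurs,
    * ``f_m(p) = 1 + c_n - (1-p) p (c_m - c_n)`` -- migraineur among
      migraineurs, with the frequency-dependent gap below ``f_n``,
    * ``b_m = 1 - d_m_prime`` -- value of a rescue versus betrayal.

    ``c_m == c_n`` is allowed as the degenerate equal-cost boundary where
    the gap term vanishes and the game loses its frequency dependence.
    """

    c_m: float
    c_n: float
    d_m_prime: float
    d_m_base: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c_m", "c_n", "d_m_prime", "d_m_base"):
            _require_finite(name, getattr(self, name))
        if self.c_m < self.c_n:
            raise GameValidationError(
                f"invariant c_m >= c_n violated: c_m={self.c_m} < c_n={self.c_n} "
                "(the fitness ordering f_n > d_m > d_n collapses)"
            )
        if not self.c_n > 0:
            raise GameValidationError(f"invariant c_n > 0 violated: c_n={self.c_n}")
        if not self.d_m_prime < self.d_m_base:
            raise GameValidationError(
                "invariant d_m_prime < d_m_base violated: "
                f"{self.d_m_prime} >= {self.d_m_base}"
            )
        if not self.d_m_base - self.d_m_prime > self.c_m:
            raise GameValidationError(
                "invariant d_m_base - d_m_prime > c_m (i.e. b_m - c_m > 0) "
                f"violated: {self.d_m_base} - {self.d_m_prime} <= {self.c_m}"
            )

    # Derived fitness levels (baseline d_m = d_m_base = 1 normalisation).
    @property
    def f_n(self) -> float:
        return self.d_m_base + self.c_n

    @property
    def d_m(self) -> float:
        return self.d_m_base

    @property
    def d_n(self) -> float:
        return self.d_m_base - (self.c_m - self.c_n)

    @property
    def b_m(self) -> float:
        return self.d_m - self.d_m_prime

    @property
    def b_n(self) -> float:
        return self.f_n - self.d_n

    def f_m(self, p: float) -> float:
        """Migraineur-meets-migraineur fitness at migraineur frequency p."""
        return self.d_m_base + self.c_n - (1.0 - p) * p * (self.c_m - self.c_n)


def migraine_game_printed(params: MigraineGameParams) -> StaticGame:
    """Frequency-dependent migraineur game with the published cell forms.

    Cells (actor, partner), with p the migraineur frequency:

    * (m, m) = 1 + c_n - (1-p) p (c_m - c_n)
    * (m, n) = 1
    * (n, m) = 1 + c_n
    * (n, n) = 1 - (c_m - c_n)

    The (m, m) cell carries the frequency-dependent gap below f_n; it
    closes at p = 0 and p = 1 and when c_m = c_n.
    """
    base = params.d_m_base
    c_m, c_n = params.c_m, params.c_n

    def payoff(actor: str, partner: str, p: float) -> float:
        if actor == "migraineur":
            if partner == "migraineur":
                return base + c_n - (1.0 - p) * p * (c_m - c_n)
            if partner == "non_migraineur":
                return base
        elif actor == "non_migraineur":
            if partner == "migraineur":
                return base + c_n
            if partner == "non_migraineur":
                return base - (c_m - c_n)
        raise KeyError(f"unknown strategy pair ({actor!r}, {partner!r})")

    return StaticGame(
        "migraineur",
        "non_migraineur",
        payoff,
        frequency_dependent=(c_m != c_n),
    )


@dataclass(frozen=True)
class GeneralizedMigraineGame:
    """Constant-fitness generalisation of the migraineur game.

    The four pairing fitness levels must satisfy the crossing-lines
    ordering f_n > f_m > d_m > d_n; the betrayal level d_m_prime sits
    below d_m (by default below d_n as well, but that is a modelling
    choice, not an invariant).
    """

    f_n: float
    f_m: float
    d_m: float
    d_n: float
    d_m_prime: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if math.isnan(self.d_m_prime):
            object.__setattr__(self, "d_m_prime", self.d_n - 0.1)
        for name in ("f_n", "f_m", "d_m", "d_n", "d_m_prime"):
            _require_finite(name, getattr(self, name))
        pairs = [
            ("f_n > f_m", self.f_n, self.f_m),
            ("f_m > d_m", self.f_m, self.d_m),
            ("d_m > d_n", self.d_m, self.d_n),
        ]
        for label, hi, lo in pairs:
            if not hi > lo:
                raise GameValidationError(
                    f"invariant {label} violated: {hi} <= {lo}"
                )
        if not self.d_m_prime < self.d_m:
            raise GameValidationError(
                f"invariant d_m_prime < d_m violated: {self.d_m_prime} >= {self.d_m}"
            )


def migraine_game_generalized(g: GeneralizedMigraineGame) -> StaticGame:
    """Constant 2x2 game with cells (m,m)=f_m, (m,n)=d_m, (n,m)=f_n, (n,n)=d_n."""
    return _constant_game(
        "migraineur", "non_migraineur", g.f_m, g.d_m, g.f_n, g.d_n
    )


@dataclass(frozen=True)
class CostBenefitRecord:
    """Costs and benefits of the reciprocal exchange, read off the fitness levels.

    Definitions follow the model's published reading of the fitness
    diagram verbatim: c_n = f_n - d_m, b_n = f_n - d_n, b_m = d_m -
    d_m_prime, and c_m = f_n - d_n.  Note that c_m and b_n are defined as
    the *same* span (f_n - d_n) read from different sides of the
    exchange; this record reports both without reconciling them.
    """

    c_m: float
    c_n: float
    b_m: float
    b_n: float
    migraineur_gain_positive: bool  # b_m - c_m > 0
    non_migraineur_gain_positive: bool  # b_n - c_n > 0


def derive_costs_benefits(g: GeneralizedMigraineGame) -> CostBenefitRecord:
    """Derive the exchange costs/benefits from a generalised game.

    Never raises: the standing viability constraints b_m - c_m > 0 and
    b_n - c_n > 0 are reported as flags rather than enforced.
    """
    c_n = g.f_n - g.d_m
    b_n = g.f_n - g.d_n
    c_m = g.f_n - g.d_n
    b_m = g.d_m - g.d_m_prime
    return CostBenefitRecord(
        c_m=c_m,
        c_n=c_n,
        b_m=b_m,
        b_n=b_n,
        migraineur_gain_positive=bool(b_m - c_m > 0),
        non_migraineur_gain_positive=bool(b_n - c_n > 0),
    )
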