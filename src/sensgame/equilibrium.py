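"""Expected payoffs, mixed evolutionarily stable states, and diagnostics.

The central object is the *payoff gap* ``g(p) = EV_focal(p) - EV_other(p)``
at focal frequency ``p``.  An interior mixed equilibrium is a root of
``g``; it is evolutionarily stable when the gap changes sign from + to -
across the root, so that each strategy is favoured when rare.  For
constant games the gap is linear in ``p`` and the root has the closed
form ``p* = g(0) / (g(0) - g(1))``; frequency-dependent games are
handled by a sign-change scan with bracketed root refinement.

The module also audits the published algebraic identity for the
frequency-dependent migraineur game: the non-migraineur's expected
payoff equals ``1 - c_m (1 - p) + c_n`` exactly, while the migraineur's
differs by ``(1-p)^2 (1+p) (c_m - c_n)``; the diagnostic reports both
residuals rather than deciding which form was intended.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .games import MigraineGameParams, StaticGame, migraine_game_printed

__all__ = [
    "EquilibriumResult",
    "IdentityDiagnostic",
    "expected_payoffs",
    "payoff_gap",
    "mixed_equilibrium",
    "population_mean_payoff",
    "invasion_payoff",
    "verify_paper_identity",
    "classify_stability",
]

#: Default half-width of the window used to probe the gap's sign around a root.
STABILITY_EPS = 1e-6
#: Default grid step for locating sign changes of a frequency-dependent gap.
GRID_STEP = 1e-3
#: Default root-refinement tolerance.
ROOT_TOL = 1e-10


def _check_p(p: float) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frequency p must lie in [0, 1], got {p}")
    return float(p)


def expected_payoffs(game: StaticGame, p: float) -> tuple[float, float]:
    """Expected payoff of each strategy in a well-mixed population.

    ``EV_s = p * payoff(s, focal, p) + (1 - p) * payoff(s, other, p)``,
    i.e. partners are drawn at the population frequencies (self-pairing
    ignored, infinite population).
    """
    p = _check_p(p)
    f, o = game.focal_label, game.other_label
    ev_focal = p * game.payoff(f, f, p) + (1.0 - p) * game.payoff(f, o, p)
    ev_other = p * game.payoff(o, f, p) + (1.0 - p) * game.payoff(o, o, p)
    return ev_focal, ev_other


def payoff_gap(game: StaticGame, p: float) -> float:
    """EV_focal(p) - EV_other(p); its roots are candidate mixed equilibria."""
    ev_f, ev_o = expected_payoffs(game, p)
    return ev_f - ev_o


def population_mean_payoff(game: StaticGame, p: float) -> float:
    """Mean payoff over the whole population, p*EV_focal + (1-p)*EV_other."""
    p = _check_p(p)
    ev_f, ev_o = expected_payoffs(game, p)
    return p * ev_f + (1.0 - p) * ev_o


def invasion_payoff(game: StaticGame, invader: str, resident_p: float) -> float:
    """Expected payoff of a vanishingly rare invader against the residents.

    Implemented as an exact evaluation at the resident composition (the
    invader itself has measure zero), not a small-epsilon approximation.
    """
    resident_p = _check_p(resident_p)
    if invader not in game.strategies:
        raise KeyError(
            f"unknown strategy {invader!r}; expected one of {game.strategies}"
        )
    ev_f, ev_o = expected_payoffs(game, resident_p)
    return ev_f if invader == game.focal_label else ev_o


def classify_stability(
    game: StaticGame, p_star: float, eps: float = STABILITY_EPS
) -> bool:
    """True when the equilibrium resists invasion by either strategy.

    Interior roots are stable when the payoff gap changes sign from + to
    - as ``p`` crosses ``p_star`` (each strategy does better when rare).
    Boundary points are classified by the one-sided invasion direction.
    """
    p_star = _check_p(p_star)
    if p_star <= eps:  # boundary at 0: stable iff rare focal does worse
        return payoff_gap(game, min(eps, 1.0)) < 0
    if p_star >= 1.0 - eps:  # boundary at 1: stable iff rare other does worse
        return payoff_gap(game, max(1.0 - eps, 0.0)) > 0
    return payoff_gap(game, p_star - eps) > 0 > payoff_gap(game, p_star + eps)


@dataclass(frozen=True)
class EquilibriumResult:
    """A mixed (or boundary, or degenerate) equilibrium of a 2x2 game.

    ``p_star`` is the focal-strategy frequency; ``residual`` is the
    absolute payoff gap there.  ``all_roots`` lists every interior root
    found, with its stability flag; ``p_star`` is the first stable root
    when one exists.
    """

    p_star: float
    payoff_at_eq: float
    stable: bool
    method: Literal["analytic", "root_scan"]
    residual: float
    status: Literal["interior", "boundary", "degenerate"] = "interior"
    all_roots: tuple[tuple[float, bool], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_star <= 1.0:
            raise ValueError(f"p_star out of [0, 1]: {self.p_star}")


def _boundary_result(game: StaticGame, method: str) -> EquilibriumResult:
    # no interior root: the gap keeps one sign; the favoured boundary absorbs
    g_mid = payoff_gap(game, 0.5)
    if g_mid == 0.0:
        # pick by the sign nearest a boundary (gap may vanish at one end)
        g_mid = payoff_gap(game, 0.25) + payoff_gap(game, 0.75)
    p_star = 1.0 if g_mid > 0 else 0.0
    ev_f, ev_o = expected_payoffs(game, p_star)
    payoff = ev_f if p_star == 1.0 else ev_o
    return EquilibriumResult(
        p_star=p_star,
        payoff_at_eq=payoff,
        stable=classify_stability(game, p_star),
        method=method,  # type: ignore[arg-type]
        residual=abs(payoff_gap(game, p_star)),
        status="boundary",
    )


def mixed_equilibrium(
    game: StaticGame,
    grid_step: float = GRID_STEP,
    tol: float = ROOT_TOL,
) -> EquilibriumResult:
    """Solve EV_focal(p) = EV_other(p) for the mixed equilibrium.

    Constant games use the closed form on the linear gap; frequency-
    dependent games are scanned on a grid of step ``grid_step`` and each
    sign-change bracket is refined with Brent's method to ``tol``.  When
    no interior root exists the result sits at the dominating boundary;
    a gap that vanishes identically yields ``status='degenerate'`` with
    ``p_star=0.5`` as a conventional representative.
    """
    if not game.frequency_dependent:
        g0 = payoff_gap(game, 0.0)
        g1 = payoff_gap(game, 1.0)
        if g0 == 0.0 and g1 == 0.0:
            return EquilibriumResult(
                p_star=0.5,
                payoff_at_eq=expected_payoffs(game, 0.5)[0],
                stable=False,
                method="analytic",
                residual=0.0,
                status="degenerate",
            )
        if (g0 > 0 > g1) or (g0 < 0 < g1):
            p_star = g0 / (g0 - g1)
            ev_f, _ = expected_payoffs(game, p_star)
            return EquilibriumResult(
                p_star=p_star,
                payoff_at_eq=ev_f,
                stable=g0 > 0 > g1,
                method="analytic",
                residual=abs(payoff_gap(game, p_star)),
                status="interior",
                all_roots=((p_star, g0 > 0 > g1),),
            )
        return _boundary_result(game, "analytic")

    # frequency-dependent: sign-change scan + bracketed refinement
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    grid[-1] = 1.0
    gaps = np.array([payoff_gap(game, p) for p in grid])
    scale = float(np.max(np.abs(gaps)))
    if scale < 1e-14:
        return EquilibriumResult(
            p_star=0.5,
            payoff_at_eq=expected_payoffs(game, 0.5)[0],
            stable=False,
            method="root_scan",
            residual=float(abs(payoff_gap(game, 0.5))),
            status="degenerate",
        )
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = grid[i], grid[i + 1]
        ga, gb = gaps[i], gaps[i + 1]
        if ga == 0.0 and 0.0 < a < 1.0:
            roots.append(float(a))
        elif ga * gb < 0:
            r = brentq(lambda p: payoff_gap(game, p), a, b, xtol=tol)
            if 0.0 < r < 1.0:
                roots.append(float(r))
    # deduplicate near-coincident roots
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or r - uniq[-1] > 10 * max(tol, 1e-12):
            uniq.append(r)
    if not uniq:
        return _boundary_result(game, "root_scan")
    flagged = tuple((r, classify_stability(game, r)) for r in uniq)
    primary = next((fr for fr in flagged if fr[1]), flagged[0])
    p_star = primary[0]
    ev_f, _ = expected_payoffs(game, p_star)
    return EquilibriumResult(
        p_star=p_star,
        payoff_at_eq=ev_f,
        stable=primary[1],
        method="root_scan",
        residual=float(abs(payoff_gap(game, p_star))),
        status="interior",
        all_roots=flagged,
    )


@dataclass(frozen=True)
class IdentityDiagnostic:
    """Audit of the claimed common equilibrium payoff 1 - c_m(1-p) + c_n.

    ``residual_n`` is zero to floating precision for every input (the
    identity is algebraically exact for the non-migraineur), while
    ``residual_m`` equals ``(1-p)^2 (1+p) (c_m - c_n)`` and vanishes only
    at p = 1 or c_m = c_n.  The diagnostic reports, it never corrects.
    """

    p: float
    c_m: float
    c_n: float
    ev_m: float
    ev_n: float
    claimed: float
    residual_m: float
    residual_n: float


def verify_paper_identity(params: MigraineGameParams, p: float) -> IdentityDiagnostic:
    """Compare both expected payoffs against the claimed common value."""
    p = _check_p(p)
    game = migraine_game_printed(params)
    ev_m, ev_n = expected_payoffs(game, p)
    claimed = params.d_m_base - params.c_m * (1.0 - p) + params.c_n
    return IdentityDiagnostic(
        p=p,
        c_m=params.c_m,
        c_n=params.c_n,
        ev_m=ev_m,
        ev_n=ev_n,
        claimed=claimed,
        residual_m=ev_m - claimed,
        residual_n=ev_n - claimed,
    )
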