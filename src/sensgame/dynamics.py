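"""Deterministic and stochastic frequency dynamics for 2x2 games.

Two complementary views of how the focal-strategy frequency evolves:

* Replicator dynamics, ``dp/dt = p (1 - p) (EV_focal(p) - EV_other(p))``,
  integrated with a fixed-step classical Runge-Kutta scheme.  For any
  game with a single stable interior equilibrium, interior trajectories
  converge to it monotonically provided the step is below ~1/L where L
  bounds the derivative of dp/dt in p (for the Hawk-Dove payoffs L ~ 31,
  so the default dt = 0.01 is comfortably monotone).
* A Moran birth-death process in a finite population of N individuals:
  each elementary step one individual reproduces with probability
  proportional to exp(intensity * payoff) and one uniformly chosen
  individual dies.  The exponential payoff-to-fitness map keeps fitness
  positive for arbitrarily negative payoffs (e.g. the hawk-hawk -25).
  One recorded generation comprises N elementary steps.

Constant-payoff games dispatch the Moran inner loop to a compiled
(numba) kernel; frequency-dependent games take a pure-Python path with
cells re-evaluated at the current frequency every step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .equilibrium import expected_payoffs, payoff_gap
from .games import StaticGame

__all__ = [
    "Trajectory",
    "replicator_derivative",
    "simulate_replicator",
    "simulate_moran",
]

logger = logging.getLogger(__name__)

DEFAULT_DT = 0.01
DEFAULT_T_MAX = 1e4
DEFAULT_TOL = 1e-8
DEFAULT_INTENSITY = 0.1


@dataclass(frozen=True)
class Trajectory:
    """Time series of the focal-strategy frequency and payoffs."""

    t: np.ndarray
    p: np.ndarray
    ev_focal: np.ndarray
    ev_other: np.ndarray
    mean_payoff: np.ndarray
    converged: bool
    final_p: float

    def __post_init__(self) -> None:
        if np.any((self.p < -1e-12) | (self.p > 1 + 1e-12)):
            raise ValueError("trajectory frequency left [0, 1]")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "p": self.p,
                "ev_focal": self.ev_focal,
                "ev_other": self.ev_other,
                "mean_payoff": self.mean_payoff,
            }
        )


def replicator_derivative(game: StaticGame, p: float) -> float:
    """dp/dt = p (1-p) (EV_focal - EV_other) at focal frequency p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frequency p must lie in [0, 1], got {p}")
    return p * (1.0 - p) * payoff_gap(game, p)


def _gap_fn(game: StaticGame):
    """Return a fast scalar gap function g(p)."""
    if not game.frequency_dependent:
        g0 = payoff_gap(game, 0.0)
        g1 = payoff_gap(game, 1.0)
        slope = g1 - g0
        return lambda p: g0 + slope * p
    return lambda p: payoff_gap(game, p)


def _traj_from_samples(game: StaticGame, t, p, converged) -> Trajectory:
    t = np.asarray(t, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    evs = np.array([expected_payoffs(game, pi) for pi in p])
    mean = p * evs[:, 0] + (1.0 - p) * evs[:, 1]
    return Trajectory(
        t=t,
        p=p,
        ev_focal=evs[:, 0],
        ev_other=evs[:, 1],
        mean_payoff=mean,
        converged=converged,
        final_p=float(p[-1]),
    )


def simulate_replicator(
    game: StaticGame,
    p0: float,
    t_max: float = DEFAULT_T_MAX,
    dt: float = DEFAULT_DT,
    tol: float = DEFAULT_TOL,
    max_samples: int = 2000,
) -> Trajectory:
    """Integrate the replicator ODE with fixed-step RK4.

    Stops early (``converged=True``) once |dp/dt| < ``tol``.  At most
    ``max_samples`` interior samples are recorded, plus the endpoints.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    gap = _gap_fn(game)

    def f(p: float) -> float:
        return p * (1.0 - p) * gap(p)

    n_steps = int(math.ceil(t_max / dt))
    stride = max(1, n_steps // max_samples)
    ts = [0.0]
    ps = [float(p0)]
    p = float(p0)
    t = 0.0
    converged = abs(f(p)) < tol
    step = 0
    while step < n_steps and not converged:
        k1 = f(p)
        k2 = f(min(max(p + 0.5 * dt * k1, 0.0), 1.0))
        k3 = f(min(max(p + 0.5 * dt * k2, 0.0), 1.0))
        k4 = f(min(max(p + dt * k3, 0.0), 1.0))
        p += (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        p = min(max(p, 0.0), 1.0)
        t += dt
        step += 1
        if step % stride == 0:
            ts.append(t)
            ps.append(p)
        if abs(f(p)) < tol:
            converged = True
    if ts[-1] != t and t > 0.0:
        ts.append(t)
        ps.append(p)
    return _traj_from_samples(game, ts, ps, converged)


@njit(cache=True)
def _moran_constant_kernel(rng, i0, N, generations, beta, a_ff, a_fo, a_of, a_oo, mu):
    counts = np.empty(generations + 1, dtype=np.int64)
    counts[0] = i0
    i = i0
    for g in range(generations):
        for _ in range(N):
            if mu == 0.0 and (i == 0 or i == N):
                continue
            p = i / N
            ev_f = a_ff * p + a_fo * (1.0 - p)
            ev_o = a_of * p + a_oo * (1.0 - p)
            # normalise inside exp for numerical safety
            m = max(ev_f, ev_o)
            w_f = math.exp(beta * (ev_f - m))
            w_o = math.exp(beta * (ev_o - m))
            tot = i * w_f + (N - i) * w_o
            birth_focal = rng.random() < (i * w_f) / tot
            if mu > 0.0 and rng.random() < mu:
                birth_focal = not birth_focal
            death_focal = rng.random() < i / N
            i += int(birth_focal) - int(death_focal)
        counts[g + 1] = i
    return counts


def _moran_python(rng, game, i0, N, generations, beta, mu):
    counts = np.empty(generations + 1, dtype=np.int64)
    counts[0] = i0
    i = i0
    for g in range(generations):
        for _ in range(N):
            if mu == 0.0 and (i == 0 or i == N):
                continue
            p = i / N
            ev_f, ev_o = expected_payoffs(game, p)
            m = max(ev_f, ev_o)
            w_f = math.exp(beta * (ev_f - m))
            w_o = math.exp(beta * (ev_o - m))
            tot = i * w_f + (N - i) * w_o
            birth_focal = rng.random() < (i * w_f) / tot
            if mu > 0.0 and rng.random() < mu:
                birth_focal = not birth_focal
            death_focal = rng.random() < i / N
            i += int(birth_focal) - int(death_focal)
        counts[g + 1] = i
    return counts


def simulate_moran(
    game: StaticGame,
    N: int,
    p0: float,
    generations: int,
    intensity: float = DEFAULT_INTENSITY,
    seed: int | np.random.SeedSequence | None = None,
    mutation_rate: float = 0.0,
) -> Trajectory:
    """Simulate a Moran birth-death process; one generation = N steps.

    Reproduction probability is proportional to ``exp(intensity *
    payoff)``; ``mutation_rate`` (off by default) symmetrically flips the
    offspring's strategy, which keeps long runs off the absorbing
    boundaries.  Fully reproducible given ``seed``.
    """
    if N < 2:
        raise ValueError(f"population size N must be >= 2, got {N}")
    if generations <= 0:
        raise ValueError(f"generations must be positive, got {generations}")
    if intensity < 0:
        raise ValueError(f"selection intensity must be >= 0, got {intensity}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    exact = N * p0
    i0 = int(round(exact))
    if abs(exact - i0) > 1e-9:
        logger.warning("N*p0 = %s is not an integer; rounded to %d", exact, i0)
    rng = np.random.default_rng(seed)
    beta = float(intensity)
    mu = float(mutation_rate)
    if not game.frequency_dependent:
        (a_ff, a_fo), (a_of, a_oo) = game.payoff_matrix(0.0)
        counts = _moran_constant_kernel(
            rng, i0, N, generations, beta, a_ff, a_fo, a_of, a_oo, mu
        )
    else:
        counts = _moran_python(rng, game, i0, N, generations, beta, mu)
    t = np.arange(generations + 1, dtype=float)
    # generation index as time; offset by tiny amount not needed (strictly increasing)
    return _traj_from_samples(game, t, counts / N, converged=False)


def time_averaged_frequency(traj: Trajectory, burn_in: int = 0) -> float:
    """Mean focal frequency over the trajectory after ``burn_in`` samples."""
    return float(np.mean(traj.p[burn_in:]))
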