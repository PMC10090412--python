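"""Expected payoffs, mixed ESS solving, and the equilibrium-payoff identity audit."""

import numpy as np
import pytest
from scipy.optimize import brentq

import sensgame as sg
from conftest import random_general_games

ESS_DOVE = 5.0 / 12.0


def grid_scan_root(game, step=1e-3, xtol=1e-12):
    """Independent oracle for constant games: grid-scan the payoff gap
    for a sign change, then refine the bracket with Brent's method."""
    ps = np.arange(0.0, 1.0 + step / 2, step)
    (a_ff, a_fo), (a_of, a_oo) = game.payoff_matrix(0.0)
    gaps = (a_ff * ps + a_fo * (1 - ps)) - (a_of * ps + a_oo * (1 - ps))
    sign_change = np.nonzero(gaps[:-1] * gaps[1:] < 0)[0]
    if len(sign_change) == 0:
        return None
    i = int(sign_change[0])
    return brentq(lambda p: sg.payoff_gap(game, p), ps[i], ps[i + 1], xtol=xtol)


class TestExpectedPayoffs:
    def test_hawk_dove_at_ess(self, hawk_dove):
        ev_dove, ev_hawk = sg.expected_payoffs(hawk_dove, ESS_DOVE)
        assert ev_dove == pytest.approx(6.25, abs=1e-12)
        assert ev_hawk == pytest.approx(6.25, abs=1e-12)

    def test_pure_hawk_column(self, hawk_dove):
        ev_dove, ev_hawk = sg.expected_payoffs(hawk_dove, 0.0)
        assert (ev_hawk, ev_dove) == (-25.0, 0.0)

    def test_printed_migraine_game(self, printed_params):
        game = sg.migraine_game_printed(printed_params)
        ev_m, ev_n = sg.expected_payoffs(game, 0.5)
        assert ev_m == pytest.approx(1.0875)
        assert ev_n == pytest.approx(1.05)

    @pytest.mark.parametrize("p", [-0.1, 1.5, np.nan])
    def test_domain_error(self, hawk_dove, p):
        with pytest.raises(ValueError):
            sg.expected_payoffs(hawk_dove, p)


class TestMixedEquilibrium:
    def test_hawk_dove_ess(self, hawk_dove):
        res = sg.mixed_equilibrium(hawk_dove)
        assert res.p_star == pytest.approx(ESS_DOVE, abs=1e-12)
        assert res.payoff_at_eq == pytest.approx(6.25, abs=1e-10)
        assert res.stable and res.status == "interior"
        assert res.residual <= 1e-10

    def test_generalized_closed_form(self, gen_game):
        res = sg.mixed_equilibrium(sg.migraine_game_generalized(gen_game))
        # p* = (d_m - d_n) / ((d_m - d_n) + (f_n - f_m))
        assert res.p_star == pytest.approx(0.5, abs=1e-12)
        assert res.stable

    def test_degenerate_game(self):
        game = sg.StaticGame("a", "b", lambda s, t, p: 1.0, frequency_dependent=False)
        res = sg.mixed_equilibrium(game)
        assert res.status == "degenerate"
        assert not res.stable

    def test_closed_form_agrees_with_grid_scan_on_random_games(self):
        for g in random_general_games(1000):
            game = sg.migraine_game_generalized(g)
            res = sg.mixed_equilibrium(game)
            expected = (g.d_m - g.d_n) / ((g.d_m - g.d_n) + (g.f_n - g.f_m))
            assert abs(res.p_star - expected) <= 1e-9
            oracle = grid_scan_root(game)
            assert oracle is not None
            assert abs(res.p_star - oracle) <= 1e-9

    def test_ordering_guarantees_unique_stable_interior_root(self):
        for g in random_general_games(200, entropy=7):
            res = sg.mixed_equilibrium(sg.migraine_game_generalized(g))
            assert res.status == "interior"
            assert 0.0 < res.p_star < 1.0
            assert res.stable
            assert len(res.all_roots) == 1

    def test_printed_game_has_no_interior_root(self, printed_params):
        # the frequency-dependent gap (1-p)^2 (1+p)(c_m - c_n) never
        # changes sign: migraineurs are (weakly) favoured everywhere and
        # the solver honestly reports the absorbing boundary at p = 1
        res = sg.mixed_equilibrium(sg.migraine_game_printed(printed_params))
        assert res.status == "boundary"
        assert res.p_star == 1.0

    def test_equal_cost_printed_game_is_degenerate(self):
        params = sg.MigraineGameParams(c_m=0.2, c_n=0.2, d_m_prime=0.5)
        res = sg.mixed_equilibrium(sg.migraine_game_printed(params))
        assert res.status == "degenerate"

    def test_anti_ordered_interior_root_is_unstable(self):
        # reversing the crossing (focal favoured when common) flips stability
        game = sg.StaticGame(
            "a",
            "b",
            lambda s, t, p: {("a", "a"): 1.2, ("a", "b"): 0.9, ("b", "a"): 1.0, ("b", "b"): 1.1}[(s, t)],
        )
        res = sg.mixed_equilibrium(game)
        assert res.status == "interior"
        assert not res.stable


class TestPopulationMeanPayoff:
    @pytest.mark.parametrize(
        "p, expected", [(1.0, 15.0), (ESS_DOVE, 6.25), (0.0, -25.0)]
    )
    def test_group_versus_ess_comparison(self, hawk_dove, p, expected):
        assert sg.population_mean_payoff(hawk_dove, p) == pytest.approx(expected)

    def test_mean_equals_both_evs_at_equilibrium_on_random_games(self):
        for g in random_general_games(50, entropy=9):
            game = sg.migraine_game_generalized(g)
            res = sg.mixed_equilibrium(game)
            ev_f, ev_o = sg.expected_payoffs(game, res.p_star)
            mean = sg.population_mean_payoff(game, res.p_star)
            assert abs(mean - ev_f) <= 1e-9
            assert abs(mean - ev_o) <= 1e-9


class TestInvasionPayoff:
    def test_hawk_invading_doves(self, hawk_dove):
        assert sg.invasion_payoff(hawk_dove, "hawk", 1.0) == 50.0

    def test_dove_invading_hawks(self, hawk_dove):
        assert sg.invasion_payoff(hawk_dove, "dove", 0.0) == 0.0

    def test_invader_at_equilibrium_earns_equilibrium_payoff(self, hawk_dove):
        res = sg.mixed_equilibrium(hawk_dove)
        for s in hawk_dove.strategies:
            assert sg.invasion_payoff(hawk_dove, s, res.p_star) == pytest.approx(
                res.payoff_at_eq
            )

    def test_unknown_strategy(self, hawk_dove):
        with pytest.raises(KeyError):
            sg.invasion_payoff(hawk_dove, "owl", 0.5)


class TestStability:
    def test_hawk_dove_interior_stable(self, hawk_dove):
        assert sg.classify_stability(hawk_dove, ESS_DOVE)

    def test_boundary_with_rare_migraineur_advantage_is_unstable(self, gen_game):
        # at p = 0 the gap is d_m - d_n > 0: migraineurs invade
        game = sg.migraine_game_generalized(gen_game)
        assert not sg.classify_stability(game, 0.0)

    def test_sign_pattern_oracle_on_linear_gap(self):
        # stable iff the linear gap crosses from + to -
        game = sg.StaticGame(
            "a",
            "b",
            lambda s, t, p: {("a", "a"): 0.9, ("a", "b"): 1.1, ("b", "a"): 1.0, ("b", "b"): 1.0}[(s, t)],
        )
        res = sg.mixed_equilibrium(game)
        g_lo = sg.payoff_gap(game, res.p_star - 1e-6)
        g_hi = sg.payoff_gap(game, res.p_star + 1e-6)
        assert res.stable == (g_lo > 0 > g_hi)


class TestIdentityAudit:
    def test_residual_n_is_exactly_zero_on_10000_random_triples(self):
        rng = np.random.default_rng(11)
        for _ in range(10_000):
            c_n = rng.uniform(0.01, 0.5)
            c_m = c_n + rng.uniform(0.0, 0.4)
            p = rng.uniform(0.0, 1.0)
            params = sg.MigraineGameParams(c_m=c_m, c_n=c_n, d_m_prime=-0.5)
            d = sg.verify_paper_identity(params, p)
            assert abs(d.residual_n) <= 1e-12

    def test_residual_m_matches_symbolic_closed_form(self):
        # independently expand EV_m - (1 - c_m(1-p) + c_n) with sympy
        sympy = pytest.importorskip("sympy")
        p, cm, cn = sympy.symbols("p c_m c_n")
        ev_m = (1 + cn - (1 - p) * p * (cm - cn)) * p + 1 * (1 - p)
        claimed = 1 - cm * (1 - p) + cn
        closed = sympy.factor(sympy.expand(ev_m - claimed))
        reference = (1 - p) ** 2 * (1 + p) * (cm - cn)
        assert sympy.simplify(closed - reference) == 0
        # and the numeric diagnostic agrees with the closed form
        rng = np.random.default_rng(13)
        for _ in range(200):
            c_n_v = rng.uniform(0.01, 0.4)
            c_m_v = c_n_v + rng.uniform(0.0, 0.4)
            p_v = rng.uniform(0.0, 1.0)
            d = sg.verify_paper_identity(
                sg.MigraineGameParams(c_m=c_m_v, c_n=c_n_v, d_m_prime=-0.5), p_v
            )
            expected = (1 - p_v) ** 2 * (1 + p_v) * (c_m_v - c_n_v)
            assert d.residual_m == pytest.approx(expected, abs=1e-12)

    def test_known_point(self):
        d = sg.verify_paper_identity(
            sg.MigraineGameParams(c_m=0.3, c_n=0.2, d_m_prime=0.5), 0.5
        )
        assert d.residual_n == pytest.approx(0.0, abs=1e-15)
        assert d.residual_m == pytest.approx(0.0375)

    @pytest.mark.parametrize("p", [0.0, 0.3, 1.0])
    def test_equal_costs_make_both_residuals_vanish(self, p):
        d = sg.verify_paper_identity(
            sg.MigraineGameParams(c_m=0.2, c_n=0.2, d_m_prime=0.5), p
        )
        assert d.residual_m == pytest.approx(0.0, abs=1e-12)
        assert d.residual_n == pytest.approx(0.0, abs=1e-12)

    def test_residual_m_vanishes_at_p_one(self):
        d = sg.verify_paper_identity(
            sg.MigraineGameParams(c_m=0.4, c_n=0.1, d_m_prime=0.3), 1.0
        )
        assert d.residual_m == pytest.approx(0.0, abs=1e-12)
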