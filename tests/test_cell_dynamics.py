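"""Single-cell kinetics, steady states, and leak-advantage detection."""

import numpy as np
import pytest

from crossfeed import (
    EnvironmentParams,
    fixture,
    generate_random_network,
    growth_rate,
    growth_vs_leakiness_scan,
    leak_advantage_chemicals,
    reaction_fluxes,
    solve_isolated_steady_state,
)
from crossfeed._kinetics import CompiledCell
from crossfeed.cell_dynamics import cell_rhs
from crossfeed.networks import CellSpecies, s1_clamped_environment

from oracles import brute_force_F, brute_force_mu


class TestReactionFluxes:
    def test_fig2_leaker_printed_equations_forced_values(self, leaker):
        x = np.array([1.0, 0.0, 0.0, 1.0, 0.0])  # S=1, E=1, rest 0
        F = reaction_fluxes(leaker.network, x)
        assert F[1] == pytest.approx(1.0)   # M1 made at kS_M1 * xS * xE
        assert F[4] == pytest.approx(1.0)   # M2 made at kS_M2 * xS
        assert F[0] == pytest.approx(-2.0)  # S consumed by both branches

    def test_zero_state_gives_zero_fluxes(self):
        net = generate_random_network(12, 2, 2, 3)
        assert np.all(reaction_fluxes(net, np.zeros(12)) == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_loop(self, seed):
        rng = np.random.default_rng(seed)
        net = generate_random_network(15, 2, 3, seed)
        for _ in range(4):
            x = rng.uniform(0, 2, size=15)
            assert np.allclose(reaction_fluxes(net, x),
                               brute_force_F(net, x), atol=1e-12)

    def test_s1_matches_brute_force(self):
        net = fixture("s1_minimal").network
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(0, 1, size=net.n)
            assert np.allclose(reaction_fluxes(net, x),
                               brute_force_F(net, x), atol=1e-12)

    def test_dimension_mismatch_raises(self, leaker):
        with pytest.raises(ValueError):
            reaction_fluxes(leaker.network, np.zeros(4))


class TestGrowthRate:
    def test_fig2_direct_substitution(self, leaker):
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0])  # E=1, M2=1
        assert growth_rate(leaker.network, x) == pytest.approx(0.01)

    def test_s1_product_of_precursors(self):
        net = fixture("s1_minimal").network
        names = dict(zip(net.names, range(net.n)))
        x = np.zeros(net.n)
        x[names["Nucleotides"]] = 0.2
        x[names["Alanine"]] = 0.3
        assert growth_rate(net, x) == pytest.approx(0.06)

    def test_enzyme_total_rule_zero_when_substrates_absent(self):
        net = generate_random_network(10, 2, 2, 1,
                                      growth_rule="enzyme_synthesis_total")
        x = np.zeros(10)
        x[0] = 5.0  # nutrient alone drives nothing without catalysts
        enzyme_feeders = {rx.substrate for rx in net.reactions
                         if rx.product in set(net.enzyme_indices)}
        assert growth_rate(net, x) == (0.0 if 0 not in enzyme_feeders
                                       else pytest.approx(0.0))

    @pytest.mark.parametrize("seed", [0, 5])
    @pytest.mark.parametrize("rule", ["designated_growth_reactions",
                                      "enzyme_synthesis_total"])
    def test_matches_brute_force(self, seed, rule):
        net = generate_random_network(12, 2, 2, seed, growth_rule=rule)
        rng = np.random.default_rng(seed)
        for _ in range(5):
            x = rng.uniform(0, 2, size=12)
            assert growth_rate(net, x) == pytest.approx(
                brute_force_mu(net, x), abs=1e-13)

    def test_nonnegative_on_random_states(self):
        net = generate_random_network(10, 2, 2, 9)
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert growth_rate(net, rng.uniform(0, 3, size=10)) >= 0.0


class TestCellRhs:
    def test_closed_cell_equals_F_minus_dilution(self, leaker):
        closed = CellSpecies("closed", leaker.network, np.zeros(5), D_S=0.0,
                             adaptation_groups=leaker.adaptation_groups)
        x = np.array([0.4, 0.3, 0.2, 0.1, 0.5])
        rhs = cell_rhs(closed, x, np.ones(5))
        mu = growth_rate(leaker.network, x)
        expected = reaction_fluxes(leaker.network, x) - mu * x
        assert np.allclose(rhs, expected, atol=1e-14)

    def test_exchange_sign_convention(self, leaker):
        # leakage: cell concentration above the environment drains the cell
        sp = leaker.with_D(np.array([1.0, 2.0, 0, 0, 0]))
        x = np.array([0.0, 0.5, 0.0, 0.0, 0.0])
        x_env = np.array([0.0, 0.1, 0.0, 0.0, 0.0])
        base = cell_rhs(leaker, x, x_env)
        with_leak = cell_rhs(sp, x, x_env)
        assert with_leak[1] - base[1] == pytest.approx(2.0 * (0.1 - 0.5))

    def test_fig2_rhs_is_the_printed_equations(self, leaker):
        """Term-for-term identity with the five written-out equations on
        random states."""
        rng = np.random.default_rng(42)
        sp = leaker.with_D(np.array([1.0, 2.0, 0, 0, 0]))
        for _ in range(10):
            x = rng.uniform(0, 1.5, size=5)
            e = rng.uniform(0, 1.5, size=5)
            S, M1, rb, E, M2 = x
            mu = 0.01 * M2 * E
            hand = np.array([
                -S * E - S + 1.0 * (e[0] - S) - mu * S,
                S * E - 2.0 * M1 * rb + 2.0 * (e[1] - M1) - mu * M1,
                M1 * rb - mu * rb,
                M1 * rb - mu * E,
                S - 0.01 * M2 * E - mu * M2,
            ])
            assert np.allclose(cell_rhs(sp, x, e), hand, atol=1e-13)

    def test_analytic_jacobian_matches_finite_differences(self):
        net = generate_random_network(12, 2, 2, 8)
        D = np.zeros(12)
        D[0] = 1.0
        D[5] = 0.7
        cell = CompiledCell(CellSpecies("j", net, D, 1.0))
        rng = np.random.default_rng(1)
        x = rng.uniform(0.05, 1.0, size=12)
        x_env = rng.uniform(0, 0.5, size=12)
        _, J = cell.rhs_jac(x, x_env)
        num = np.zeros_like(J)
        h = 1e-7
        for j in range(12):
            dx = np.zeros(12)
            dx[j] = h
            num[:, j] = (cell.rhs(x + dx, x_env) - cell.rhs(x - dx, x_env)) / (2 * h)
        assert np.allclose(J, num, atol=1e-6)


class TestSteadyStates:
    def test_s1_isolated_growth_reproducible(self, fig2_env, solver):
        sp = fixture("s1_minimal")
        res = solve_isolated_steady_state(sp, fig2_env, clamp_env=True,
                                          clamp_values=s1_clamped_environment(),
                                          config=solver)
        assert res.converged
        # regression pin for the synthetic minimal bioreaction model
        assert res.mu == pytest.approx(0.04660723, rel=1e-5)
        # residual is a genuine steady state
        assert np.max(np.abs(cell_rhs(sp, res.x, res.x_env))) < 1e-8

    def test_no_nutrient_uptake_means_no_growth(self, fig2_env, solver):
        lk = fixture("fig2_leaker")
        dead = CellSpecies("dead", lk.network, np.zeros(5), D_S=0.0,
                           adaptation_groups=lk.adaptation_groups)
        res = solve_isolated_steady_state(dead, fig2_env, clamp_env=True,
                                          config=solver)
        assert res.mu == pytest.approx(0.0, abs=1e-9)

    def test_dynamic_and_clamped_environments_differ(self, fig2_env, solver, leaker):
        sp = leaker.with_D(np.array([1.0, 2.0, 0, 0, 0]))
        dyn = solve_isolated_steady_state(sp, fig2_env, clamp_env=False,
                                          config=solver)
        clamped = solve_isolated_steady_state(sp, fig2_env, clamp_env=True,
                                              config=solver)
        assert dyn.converged and clamped.converged
        # the perfect sink lets the cell leak more, so it grows faster
        assert clamped.mu > dyn.mu

    def test_warm_start_newton_agrees_with_integration(self, fig2_env, solver, leaker):
        cold = solve_isolated_steady_state(leaker, fig2_env, clamp_env=False,
                                           config=solver)
        warm = solve_isolated_steady_state(leaker, fig2_env, clamp_env=False,
                                           config=solver,
                                           warm_start=(cold.x, cold.x_env))
        assert warm.converged and warm.message == "newton"
        assert warm.mu == pytest.approx(cold.mu, rel=1e-8)

    def test_nonnegative_concentrations(self, fig2_env, solver, leaker):
        res = solve_isolated_steady_state(leaker, fig2_env, clamp_env=False,
                                          config=solver)
        assert np.min(res.x) >= 0.0 and np.min(res.x_env) >= 0.0


class TestLeakAdvantage:
    def test_fig2_leaker_M1_is_leak_advantage(self, fig2_env, solver, leaker):
        la = leak_advantage_chemicals(leaker, fig2_env, config=solver)
        assert 1 in la  # M1

    def test_consumer_M1_is_not(self, fig2_env, solver, consumer):
        la = leak_advantage_chemicals(consumer, fig2_env, config=solver)
        assert 1 not in la

    def test_s1_terminal_products_are_neutral(self, fig2_env, solver):
        sp = fixture("s1_minimal")
        names = dict(zip(sp.network.names, range(sp.network.n)))
        la = leak_advantage_chemicals(sp, fig2_env, config=solver,
                                      clamp_values=s1_clamped_environment())
        for terminal in ("CO2", "NH4", "Lactate"):
            assert names[terminal] not in la
        # nutrients are never candidates
        assert names["Glucose"] not in la and names["Glutamine"] not in la
        # the synthetic reconstruction does exhibit a leak advantage
        assert la

    def test_epsilon_must_be_positive(self, fig2_env, leaker):
        with pytest.raises(ValueError):
            leak_advantage_chemicals(leaker, fig2_env, epsilon=0.0)


class TestLeakinessScan:
    def test_single_point_scan_equals_steady_solve(self, fig2_env, solver, leaker):
        frame = growth_vs_leakiness_scan(leaker, fig2_env, 1, [0.0],
                                         config=solver)
        res = solve_isolated_steady_state(leaker, fig2_env, clamp_env=True,
                                          config=solver)
        assert len(frame) == 1
        assert frame.mu.iloc[0] == pytest.approx(res.mu, rel=1e-9)

    def test_interior_maximum_under_sink_protocol(self, fig2_env, solver, leaker):
        frame = growth_vs_leakiness_scan(leaker, fig2_env, 1,
                                         np.linspace(0, 10, 11), config=solver)
        mu = frame.mu.to_numpy()
        peak = int(np.argmax(mu))
        assert 0 < peak < len(mu) - 1
        assert mu[peak] > mu[0]

    def test_reversible_leaker_loses_the_interior_optimum(self, solver):
        """With strongly reversible reactions the leak advantage of M1
        disappears: growth only falls as leakiness rises."""
        env = EnvironmentParams(S_env=1.0, V_env=1.0, R_deg=0.1, D_S_env=10.0)
        sp = fixture("s2_reversible_leaker", r=1.0)
        frame = growth_vs_leakiness_scan(sp, env, 1, np.linspace(0, 2, 9),
                                         config=solver)
        mu = frame.mu.to_numpy()
        assert int(np.argmax(mu)) == 0

    def test_negative_grid_rejected(self, fig2_env, leaker):
        with pytest.raises(ValueError):
            growth_vs_leakiness_scan(leaker, fig2_env, 1, [-1.0])
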