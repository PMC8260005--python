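"""Flux bookkeeping, leakage entropies, classification, removal stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossfeed import CommunityState, fixture, integrate_community
from crossfeed.community_dynamics import SteadyCommunity, empty_environment
from crossfeed.ecosystem_analysis import (
    MUTUALISM,
    NONCOEXISTENCE,
    classify_interaction,
    compute_flux_table,
    multiple_correlation,
    removal_experiment,
    resilience_statistics,
)


def make_community(species, X, x_env, p, mu=None, converged=True):
    state = CommunityState(species, X, x_env, p)
    mu = np.asarray(mu if mu is not None else np.full(len(species), 0.01))
    return SteadyCommunity(state=state, mu=mu, mu_star=float(p @ mu),
                           converged=converged, time_to_converge=1.0)


@pytest.fixture()
def two_leakers(leaker, consumer):
    """Hand-built steady community where both species leak M1 equally."""
    lk = leaker.with_D(np.array([1.0, 2.0, 0, 0, 0]))
    cs = consumer.with_D(np.array([1.0, 2.0, 0, 0, 0]))
    X = np.array([[0.5, 0.6, 0.1, 0.1, 0.2],
                  [0.5, 0.6, 0.1, 0.1, 0.2]])
    x_env = np.array([0.9, 0.1, 0.0, 0.0, 0.0])
    return make_community([lk, cs], X, x_env, np.array([0.5, 0.5]))


class TestFluxTable:
    def test_even_two_species_leakage_gives_ln2(self, two_leakers):
        table = compute_flux_table(two_leakers)
        assert table.defined
        assert table.P_Leak == pytest.approx([0.5, 0.5])
        assert table.S_Cell == pytest.approx(math.log(2))
        # only M1 leaks: a single leaked chemical has zero entropy
        assert table.S_Chem == pytest.approx(0.0)

    def test_single_leaking_species_zero_entropy(self, leaker, consumer):
        lk = leaker.with_D(np.array([1.0, 2.0, 0, 0, 0]))
        cs = consumer.with_D(np.array([1.0, 0.0, 0, 0, 0]))  # no exchange
        X = np.array([[0.5, 0.6, 0.1, 0.1, 0.2],
                      [0.5, 0.6, 0.1, 0.1, 0.2]])
        x_env = np.array([0.9, 0.1, 0.0, 0.0, 0.0])
        com = make_community([lk, cs], X, x_env, np.array([0.5, 0.5]))
        table = compute_flux_table(com)
        assert table.S_Cell == pytest.approx(0.0)

    def test_closed_form_three_way_split(self):
        # shares (0.5, 0.25, 0.25) -> 1.5 ln 2
        shares = np.array([0.5, 0.25, 0.25])
        entropy = -(shares * np.log(shares)).sum()
        assert entropy == pytest.approx(1.5 * math.log(2))

    def test_uptake_never_counts_as_leakage(self, leaker, consumer):
        lk = leaker.with_D(np.array([1.0, 2.0, 0, 0, 0]))
        cs = consumer.with_D(np.array([1.0, 2.0, 0, 0, 0]))
        X = np.array([[0.5, 0.6, 0.1, 0.1, 0.2],   # cell above env: leaks
                      [0.5, 0.02, 0.1, 0.1, 0.2]])  # cell below env: uptake
        x_env = np.array([0.9, 0.1, 0.0, 0.0, 0.0])
        com = make_community([lk, cs], X, x_env, np.array([0.5, 0.5]))
        table = compute_flux_table(com)
        assert table.leak[1, 1] == 0.0
        assert table.f[1, 1] > 0.0  # inflow is positive by convention
        assert table.P_Leak == pytest.approx([1.0, 0.0])

    def test_no_leakage_flagged_undefined(self, leaker):
        com = make_community([leaker], np.full((1, 5), 0.1),
                             np.zeros(5) + 0.1, np.array([1.0]))
        table = compute_flux_table(com)
        assert not table.defined and math.isnan(table.S_Cell)

    def test_nonconverged_rejected(self, two_leakers):
        two_leakers.converged = False
        with pytest.raises(ValueError):
            compute_flux_table(two_leakers)

    def test_frame_has_species_times_chemicals_rows(self, two_leakers):
        frame = compute_flux_table(two_leakers).to_frame()
        assert len(frame) == 2 * 5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_entropy_bounds_and_share_normalization(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(1, 6), rng.integers(2, 8)
        leak = rng.uniform(0, 1, size=(m, n)) * (rng.uniform(size=(m, n)) < 0.6)
        if leak.sum() == 0:
            return
        L = leak.sum()
        P_leak = leak.sum(axis=1) / L
        P_leaked = leak.sum(axis=0) / L
        assert P_leak.sum() == pytest.approx(1.0)
        assert P_leaked.sum() == pytest.approx(1.0)
        s_cell = -(P_leak[P_leak > 0] * np.log(P_leak[P_leak > 0])).sum()
        leaking_species = int((leak.sum(axis=1) > 0).sum())
        assert -1e-12 <= s_cell <= math.log(max(leaking_species, 1)) + 1e-12


class TestClassification:
    def test_single_survivor_is_noncoexistence(self, leaker, fig2_env):
        com = make_community([leaker], np.full((1, 5), 0.1),
                             empty_environment(5, fig2_env), np.array([1.0]))
        assert classify_interaction(com, fig2_env) == NONCOEXISTENCE

    def test_mutualistic_pair_from_dynamics(self, leaker, consumer, fig2_env,
                                            community_config):
        lk = leaker.with_D(np.array([1.0, 3.0, 0, 0, 0]))
        cs = consumer.with_D(np.array([1.0, 3.0, 0, 0, 0]))
        state = CommunityState([lk, cs], np.full((2, 5), 0.1),
                               empty_environment(5, fig2_env),
                               np.array([0.5, 0.5]))
        com = integrate_community(state, fig2_env, community_config)
        assert classify_interaction(com, fig2_env) == MUTUALISM

    def test_invariant_under_relabeling(self, leaker, consumer, fig2_env,
                                        community_config):
        lk = leaker.with_D(np.array([1.0, 3.0, 0, 0, 0]))
        cs = consumer.with_D(np.array([1.0, 3.0, 0, 0, 0]))

        def run(order):
            state = CommunityState(list(order), np.full((2, 5), 0.1),
                                   empty_environment(5, fig2_env),
                                   np.array([0.5, 0.5]))
            com = integrate_community(state, fig2_env, community_config)
            return classify_interaction(com, fig2_env)

        assert run([lk, cs]) == run([cs.with_D(cs.D, "c2"),
                                     lk.with_D(lk.D, "l2")])

    def test_strict_mode_flags_nonconverged(self, two_leakers, fig2_env):
        two_leakers.converged = False
        assert classify_interaction(two_leakers, fig2_env) == "UNRESOLVED"


class TestRemoval:
    @pytest.fixture()
    def steady_pair(self, leaker, consumer, fig2_env, community_config):
        lk = leaker.with_D(np.array([1.0, 3.0, 0, 0, 0]))
        cs = consumer.with_D(np.array([1.0, 3.0, 0, 0, 0]))
        state = CommunityState([lk, cs], np.full((2, 5), 0.1),
                               empty_environment(5, fig2_env),
                               np.array([0.5, 0.5]))
        return integrate_community(state, fig2_env, community_config)

    def test_two_species_removal_always_survives(self, steady_pair, fig2_env,
                                                 community_config):
        for target in ("fig2_leaker", "fig2_consumer"):
            out = removal_experiment(steady_pair, target, fig2_env,
                                     community_config)
            assert out.survival_ratio == 1.0
            assert out.cascade_extinctions == []
            assert out.final.state.p == pytest.approx([1.0])

    def test_absent_target_raises(self, steady_pair, fig2_env):
        with pytest.raises(KeyError):
            removal_experiment(steady_pair, "ghost", fig2_env)

    def test_survival_ratio_in_unit_interval(self, steady_pair, fig2_env,
                                             community_config):
        out = removal_experiment(steady_pair, "fig2_leaker", fig2_env,
                                 community_config)
        assert 0.0 < out.survival_ratio <= 1.0


class TestResilienceStatistics:
    def test_multiple_correlation_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        y = 0.7 * X[:, 0] - 0.2 * X[:, 1] + rng.normal(scale=0.3, size=12)
        # brute-force: solve the 2-predictor normal equations directly
        A = np.column_stack([np.ones(12), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        resid = y - A @ beta
        R = math.sqrt(1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum())
        assert multiple_correlation(y, X) == pytest.approx(R, abs=1e-12)

    def test_perfectly_linear_survival_gives_unit_correlation(self):
        y = np.array([0.2, 0.4, 0.6, 0.8])
        X = np.column_stack([y, np.array([1.0, 0.0, 1.0, 0.0])])
        assert multiple_correlation(y, X) == pytest.approx(1.0)

    def test_too_few_samples_flagged(self, leaker, consumer, fig2_env,
                                     community_config):
        lk = leaker.with_D(np.array([1.0, 3.0, 0, 0, 0]))
        cs = consumer.with_D(np.array([1.0, 3.0, 0, 0, 0]))
        state = CommunityState([lk, cs], np.full((2, 5), 0.1),
                               empty_environment(5, fig2_env),
                               np.array([0.5, 0.5]))
        com = integrate_community(state, fig2_env, community_config)
        stats = resilience_statistics([com], fig2_env, community_config)
        assert stats["flagged"]
        assert math.isnan(stats["multiple_correlation"])

    def test_identical_samples_have_degenerate_correlations(
            self, leaker, consumer, fig2_env, community_config):
        lk = leaker.with_D(np.array([1.0, 3.0, 0, 0, 0]))
        cs = consumer.with_D(np.array([1.0, 3.0, 0, 0, 0]))
        state = CommunityState([lk, cs], np.full((2, 5), 0.1),
                               empty_environment(5, fig2_env),
                               np.array([0.5, 0.5]))
        com = integrate_community(state, fig2_env, community_config)
        stats = resilience_statistics([com, com, com], fig2_env,
                                      community_config)
        assert stats["flagged"]  # zero variance across identical samples
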