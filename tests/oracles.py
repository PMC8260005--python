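"""Independent oracles used by the test suite.

These deliberately avoid the package's kinetics engine and solvers:

- an explicit-Euler integrator for the five-chemical leaker/consumer
  cell written out equation by equation (numba-jitted, dt = 1e-4),
  in clamped-environment and dynamic-environment variants;
- brute-force loop evaluations of the net synthesis vector and the
  environment balance, summing term by term over the reaction list and
  the (species, chemical) grid.
"""

from __future__ import annotations

import numpy as np
from numba import njit


# ---------------------------------------------------------------------------
# Explicit-Euler oracle for the 5-chemical leaker/consumer cell
# x = (S, M1, rb, E, M2); rate constants k = (kS_M1, kM1_rb, kM1_E, kS_M2, kBM)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _euler_clamped(k, D_S, D_M1, xenv_S, xenv_M1, dt, t_max, tol):
    x = np.full(5, 0.1)
    n_steps = int(t_max / dt)
    check = int(1.0 / dt)
    for step in range(n_steps):
        S, M1, rb, E, M2 = x[0], x[1], x[2], x[3], x[4]
        mu = k[4] * M2 * E
        dS = -k[0] * S * E - k[3] * S + D_S * (xenv_S - S) - mu * S
        dM1 = k[0] * S * E - (k[1] + k[2]) * M1 * rb + D_M1 * (xenv_M1 - M1) - mu * M1
        drb = k[1] * M1 * rb - mu * rb
        dE = k[2] * M1 * rb - mu * E
        dM2 = k[3] * S - k[4] * M2 * E - mu * M2
        x[0] += dt * dS
        x[1] += dt * dM1
        x[2] += dt * drb
        x[3] += dt * dE
        x[4] += dt * dM2
        for i in range(5):
            if x[i] < 0.0:
                x[i] = 0.0
        if step % check == 0 and step > 0:
            m = 0.0
            for d, xi in ((dS, x[0]), (dM1, x[1]), (drb, x[2]),
                          (dE, x[3]), (dM2, x[4])):
                r = abs(d) / max(xi, 1e-6)
                if r > m:
                    m = r
            if m < tol:
                break
    return x


@njit(cache=True)
def _euler_dynamic(k, D_S, D_M1, S_env, D_S_env, V_env, R_deg, dt, t_max, tol):
    x = np.full(5, 0.1)
    eS = 0.0
    eM1 = 0.0
    n_steps = int(t_max / dt)
    check = int(1.0 / dt)
    for step in range(n_steps):
        S, M1, rb, E, M2 = x[0], x[1], x[2], x[3], x[4]
        mu = k[4] * M2 * E
        dS = -k[0] * S * E - k[3] * S + D_S * (eS - S) - mu * S
        dM1 = k[0] * S * E - (k[1] + k[2]) * M1 * rb + D_M1 * (eM1 - M1) - mu * M1
        drb = k[1] * M1 * rb - mu * rb
        dE = k[2] * M1 * rb - mu * E
        dM2 = k[3] * S - k[4] * M2 * E - mu * M2
        deS = D_S * (S - eS) / V_env - R_deg * eS + D_S_env * (S_env - eS)
        deM1 = D_M1 * (M1 - eM1) / V_env - R_deg * eM1
        x[0] += dt * dS
        x[1] += dt * dM1
        x[2] += dt * drb
        x[3] += dt * dE
        x[4] += dt * dM2
        eS += dt * deS
        eM1 += dt * deM1
        for i in range(5):
            if x[i] < 0.0:
                x[i] = 0.0
        if eS < 0.0:
            eS = 0.0
        if eM1 < 0.0:
            eM1 = 0.0
        if step % check == 0 and step > 0:
            m = abs(deS) / max(eS, 1e-6)
            r = abs(deM1) / max(eM1, 1e-6)
            if r > m:
                m = r
            for d, xi in ((dS, x[0]), (dM1, x[1]), (drb, x[2]),
                          (dE, x[3]), (dM2, x[4])):
                r = abs(d) / max(xi, 1e-6)
                if r > m:
                    m = r
            if m < tol:
                break
    return x, eS, eM1


LEAKER_K = np.array([1.0, 1.0, 1.0, 1.0, 0.01])
CONSUMER_K = np.array([0.4, 2.0, 2.0, 2.0, 0.01])


def euler_mu_iso_clamped(k, D_M1, xenv_S=10.0 / 11.0, xenv_M1=0.0,
                         D_S=1.0, dt=1e-4, t_max=4000.0, tol=1e-7):
    """Steady growth of the five-chemical cell, perfect-sink protocol."""
    x = _euler_clamped(np.asarray(k, dtype=float), D_S, D_M1,
                       xenv_S, xenv_M1, dt, t_max, tol)
    return k[4] * x[4] * x[3]


def euler_mu_iso_dynamic(k, D_M1, S_env=1.0, D_S_env=10.0, V_env=1.0,
                         R_deg=1.0, D_S=1.0, dt=1e-4, t_max=4000.0, tol=1e-7):
    """Steady growth of the five-chemical cell cultured alone against
    its own dynamic environment."""
    x, _, _ = _euler_dynamic(np.asarray(k, dtype=float), D_S, D_M1, S_env,
                             D_S_env, V_env, R_deg, dt, t_max, tol)
    return k[4] * x[4] * x[3]


# ---------------------------------------------------------------------------
# Brute-force loop oracles
# ---------------------------------------------------------------------------

def brute_force_F(network, x):
    """Net synthesis, summed reaction by reaction in plain Python."""
    x = np.asarray(x, dtype=float)
    F = np.zeros(network.n)
    for rx in network.reactions:
        rate = rx.k * max(x[rx.substrate], 0.0)
        if rx.catalyst is not None:
            rate *= max(x[rx.catalyst], 0.0)
        for idx, _ in rx.co_substrates:
            rate *= max(x[idx], 0.0)
        if rx.r > 0:
            rev = rx.r * rx.k * max(x[rx.product], 0.0)
            if rx.catalyst is not None:
                rev *= max(x[rx.catalyst], 0.0)
            rate -= rev
        F[rx.substrate] -= rx.substrate_coef * rate
        for idx, coef in rx.co_substrates:
            F[idx] -= coef * rate
        if rx.product is not None:
            F[rx.product] += rx.product_coef * rate
        for idx, coef in rx.byproducts:
            F[idx] += coef * rate
    return F


def brute_force_mu(network, x):
    """Growth rate, by direct summation under the network's rule."""
    x = np.asarray(x, dtype=float)
    mu = 0.0
    enz = set(network.enzyme_indices)
    for rx in network.reactions:
        rate = rx.k * max(x[rx.substrate], 0.0)
        if rx.catalyst is not None:
            rate *= max(x[rx.catalyst], 0.0)
        for idx, _ in rx.co_substrates:
            rate *= max(x[idx], 0.0)
        if rx.r > 0:
            rev = rx.r * rx.k * max(x[rx.product], 0.0)
            if rx.catalyst is not None:
                rev *= max(x[rx.catalyst], 0.0)
            rate -= rev
        if network.growth_rule == "designated_growth_reactions":
            if rx.product is None:
                mu += rate
        else:
            if rx.product in enz:
                mu += rx.product_coef * rate
            for idx, coef in rx.byproducts:
                if idx in enz:
                    mu += coef * rate
    return max(mu, 0.0)


def brute_force_env_rhs(species_list, X, x_env, p, env):
    """Environment balance, looped over every (species, chemical) pair."""
    n = len(x_env)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for a, sp in enumerate(species_list):
            acc += p[a] * sp.D[i] * (X[a][i] - x_env[i])
        out[i] = acc / env.V_env - env.R_deg * x_env[i]
    for i in species_list[0].network.nutrient_indices:
        out[i] += env.D_S_env * (env.S_env - x_env[i])
    return out
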