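"""Vectorized evaluation of reaction kinetics, growth and exchange.

Internal module.  A :class:`CompiledCell` flattens one species' reaction
list into index arrays so that rates, net synthesis, growth rate and the
analytic Jacobian are a handful of numpy operations; a
:class:`CompiledCommunity` concatenates several species plus the shared
environment and the population-fraction vector into one flat ODE
right-hand side for the coupled multi-level system.

Rate law: each reaction's forward rate is ``k`` times the product of up
to ``MAXF`` concentration factors (substrate, optional catalyst,
co-substrates); the reverse rate of a reversible reaction is ``r*k``
times product and catalyst concentrations.  Concentrations are clamped
at zero inside rate evaluations so that tiny negative integrator
excursions cannot feed back as negative rates.
"""

from __future__ import annotations

import numpy as np

from .networks import CellSpecies, EnvironmentParams, ReactionNetwork

MAXF = 4  # max concentration factors per rate law


def _factor_table(network: ReactionNetwork):
    """Build (R, MAXF) forward/reverse factor index tables.

    Index ``n`` is a pseudo-chemical with constant concentration 1.0 used
    to pad unused factor slots.
    """
    n = network.n
    R = len(network.reactions)
    fwd = np.full((R, MAXF), n, dtype=np.intp)
    rev = np.full((R, MAXF), n, dtype=np.intp)
    k = np.empty(R)
    rk = np.zeros(R)
    for j, rx in enumerate(network.reactions):
        factors = [rx.substrate]
        if rx.catalyst is not None:
            factors.append(rx.catalyst)
        factors.extend(i for i, _ in rx.co_substrates)
        if len(factors) > MAXF:
            raise ValueError("too many concentration factors in one reaction")
        fwd[j, :len(factors)] = factors
        k[j] = rx.k
        if rx.r > 0:
            rfac = [rx.product]
            if rx.catalyst is not None:
                rfac.append(rx.catalyst)
            rev[j, :len(rfac)] = rfac
            rk[j] = rx.r * rx.k
    return fwd, rev, k, rk


def _stoich(network: ReactionNetwork) -> np.ndarray:
    """Dense (n, R) net stoichiometric matrix (catalysts cancel)."""
    n, R = network.n, len(network.reactions)
    S = np.zeros((n, R))
    for j, rx in enumerate(network.reactions):
        S[rx.substrate, j] -= rx.substrate_coef
        for i, c in rx.co_substrates:
            S[i, j] -= c
        if rx.product is not None:
            S[rx.product, j] += rx.product_coef
        for i, c in rx.byproducts:
            S[i, j] += c
    return S


def _mu_weights(network: ReactionNetwork) -> np.ndarray:
    R = len(network.reactions)
    w = np.zeros(R)
    if network.growth_rule == "designated_growth_reactions":
        for j, rx in enumerate(network.reactions):
            if rx.is_growth:
                w[j] = 1.0
    else:  # enzyme_synthesis_total
        enz = set(network.enzyme_indices)
        for j, rx in enumerate(network.reactions):
            if rx.product in enz:
                w[j] += rx.product_coef
            w[j] += sum(c for i, c in rx.byproducts if i in enz)
    return w


class CompiledCell:
    """Flattened kinetics of one species (network + diffusion vector)."""

    def __init__(self, species: CellSpecies):
        self.species = species
        net = species.network
        self.n = net.n
        self.fwd, self.rev, self.k, self.rk = _factor_table(net)
        self.S = _stoich(net)
        self.w = _mu_weights(net)
        self.clip_mu = net.growth_rule == "enzyme_synthesis_total"
        self.D = species.D.astype(float).copy()

    def with_D(self, D: np.ndarray) -> "CompiledCell":
        """Cheap copy sharing the kinetic tables, with new diffusion."""
        other = object.__new__(CompiledCell)
        other.__dict__.update(self.__dict__)
        other.D = np.asarray(D, dtype=float).copy()
        return other

    # -- kinetics ---------------------------------------------------------

    def net_rates(self, x: np.ndarray) -> np.ndarray:
        xx = np.append(np.maximum(x, 0.0), 1.0)
        rf = self.k * xx[self.fwd].prod(axis=1)
        rb = self.rk * xx[self.rev].prod(axis=1)
        return rf - rb

    def F_mu(self, x: np.ndarray):
        """Net synthesis vector F and growth rate mu at state ``x``."""
        net = self.net_rates(x)
        mu = float(self.w @ net)
        if self.clip_mu and mu < 0.0:
            mu = 0.0
        return self.S @ net, mu

    def rhs(self, x: np.ndarray, x_env: np.ndarray) -> np.ndarray:
        """dx/dt = F + D*(x_env - x) - mu*x."""
        F, mu = self.F_mu(x)
        return F + self.D * (x_env - x) - mu * x

    # -- analytic derivatives --------------------------------------------

    def _rate_jacobian(self, x: np.ndarray) -> np.ndarray:
        """(R, n) derivative of net rates w.r.t. concentrations."""
        xx = np.append(np.maximum(x, 0.0), 1.0)
        R = len(self.k)
        J = np.zeros((R, self.n + 1))
        rows = np.arange(R)
        for table, kk in ((self.fwd, self.k), (self.rev, -self.rk)):
            vals = xx[table]  # (R, MAXF)
            for s in range(MAXF):
                others = np.delete(vals, s, axis=1).prod(axis=1)
                np.add.at(J, (rows, table[:, s]), kk * others)
        J = J[:, :-1]
        # zero sensitivity where the concentration is clamped at 0 from below
        J[:, np.asarray(x) < 0.0] = 0.0
        return J

    def F_mu_grad(self, x: np.ndarray):
        """F, mu, dF/dx and dmu/dx at ``x``."""
        net = self.net_rates(x)
        Jr = self._rate_jacobian(x)
        mu = float(self.w @ net)
        gmu = self.w @ Jr
        if self.clip_mu and mu < 0.0:
            mu, gmu = 0.0, np.zeros(self.n)
        return self.S @ net, mu, self.S @ Jr, gmu

    def rhs_jac(self, x: np.ndarray, x_env: np.ndarray):
        """Right-hand side and its analytic Jacobian (clamped env)."""
        F, mu, JF, gmu = self.F_mu_grad(x)
        rhs = F + self.D * (x_env - x) - mu * x
        J = JF - np.diag(self.D + mu) - np.outer(x, gmu)
        return rhs, J


class CompiledCommunity:
    """Flat ODE system for m species + shared environment + fractions.

    State layout: ``z = [x^(1), ..., x^(m), x_env, p]`` with each block of
    length ``n`` and ``p`` of length ``m``.
    """

    def __init__(self, cells: list[CompiledCell], env: EnvironmentParams):
        if not cells:
            raise ValueError("community needs at least one species")
        n = cells[0].n
        if any(c.n != n for c in cells):
            raise ValueError("all species must share the chemical index space")
        self.cells = cells
        self.env = env
        self.m = len(cells)
        self.n = n
        self.dim = self.m * n + n + self.m
        self.D_mat = np.stack([c.D for c in cells])  # (m, n)
        self.nutrients = cells[0].species.network.nutrient_indices

    # -- layout helpers ---------------------------------------------------

    def pack(self, X: np.ndarray, x_env: np.ndarray, p: np.ndarray) -> np.ndarray:
        return np.concatenate([np.asarray(X, float).ravel(), x_env, p])

    def unpack(self, z: np.ndarray):
        m, n = self.m, self.n
        X = z[: m * n].reshape(m, n)
        x_env = z[m * n: m * n + n]
        p = z[m * n + n:]
        return X, x_env, p

    # -- dynamics ---------------------------------------------------------

    def mu_all(self, X: np.ndarray) -> np.ndarray:
        return np.array([c.F_mu(X[a])[1] for a, c in enumerate(self.cells)])

    def env_rhs(self, X: np.ndarray, x_env: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Environment balance: exchange with every cell, degradation,
        and reservoir supply of the nutrient(s)."""
        ex = (p[:, None] * self.D_mat * (X - x_env[None, :])).sum(axis=0)
        dxe = ex / self.env.V_env - self.env.R_deg * x_env
        for i in self.nutrients:
            dxe[i] += self.env.D_S_env * (self.env.S_env - x_env[i])
        return dxe

    def rhs(self, t: float, z: np.ndarray) -> np.ndarray:
        X, x_env, p = self.unpack(z)
        out = np.empty_like(z)
        mu = np.empty(self.m)
        m, n = self.m, self.n
        for a, c in enumerate(self.cells):
            F, mu_a = c.F_mu(X[a])
            out[a * n:(a + 1) * n] = F + c.D * (x_env - X[a]) - mu_a * X[a]
            mu[a] = mu_a
        out[m * n: m * n + n] = self.env_rhs(X, x_env, p)
        pc = np.maximum(p, 0.0)
        mu_bar = float(pc @ mu) / max(pc.sum(), 1e-300)
        out[m * n + n:] = (mu - mu_bar) * p
        return out

    def jac(self, t: float, z: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs` (dense)."""
        X, x_env, p = self.unpack(z)
        m, n = self.m, self.n
        env = self.env
        J = np.zeros((self.dim, self.dim))
        mu = np.empty(m)
        gmu = np.empty((m, n))
        ie, ip = m * n, m * n + n
        for a, c in enumerate(self.cells):
            _, mu_a, JF, g = c.F_mu_grad(X[a])
            mu[a] = mu_a
            gmu[a] = g
            rows = slice(a * n, (a + 1) * n)
            J[rows, rows] = JF - np.diag(c.D + mu_a) - np.outer(X[a], g)
            J[rows, ie:ip] = np.diag(c.D)
            # environment rows, cell columns
            J[ie:ip, rows] = (p[a] / env.V_env) * np.diag(c.D)
            # environment rows, fraction columns
            J[ie:ip, ip + a] = c.D * (X[a] - x_env) / env.V_env
        denv = -(p[:, None] * self.D_mat).sum(axis=0) / env.V_env - env.R_deg
        sup = np.zeros(n)
        sup[list(self.nutrients)] = env.D_S_env
        J[ie:ip, ie:ip] = np.diag(denv - sup)
        # replicator rows
        s = max(float(np.maximum(p, 0.0).sum()), 1e-300)
        mu_bar = float(np.maximum(p, 0.0) @ mu) / s
        for a in range(m):
            row = ip + a
            for b in range(m):
                cols = slice(b * n, (b + 1) * n)
                term = -p[a] * (p[b] / s) * gmu[b]
                if a == b:
                    term = term + p[a] * gmu[a]
                J[row, cols] = term
                J[row, ip + b] = -p[a] * (mu[b] - mu_bar) / s
            J[row, ip + a] += mu[a] - mu_bar
        return J
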