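"""Coupled community dynamics: cells + shared environment + fractions.

The full multi-level system integrates, simultaneously,

- every species' intracellular concentrations (mass action, exchange,
  dilution),
- the shared environment, which aggregates all species' exchange fluxes
  weighted by their population fractions, degrades its contents at
  ``R_deg`` and receives nutrient from an external reservoir, and
- the population fractions under replicator dynamics
  ``dp_a/dt = (mu_a - mu_bar) p_a``,

with extinction pruning: a species whose fraction falls below ``p_min``
is removed and the remaining fractions renormalized.  At a converged
multi-species state the replicator equation forces all survivors onto a
common growth rate mu*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from ._kinetics import CompiledCell, CompiledCommunity
from .cell_dynamics import DEFAULT_SOLVER, SolverConfig
from .networks import CellSpecies, EnvironmentParams

__all__ = [
    "CommunityConfig",
    "CommunityState",
    "SteadyCommunity",
    "environment_rhs",
    "replicator_rhs",
    "integrate_community",
    "introduce_invader",
    "empty_environment",
]

P_MIN_DEFAULT = 2.5e-4


@dataclass(frozen=True)
class CommunityConfig:
    """Policy for community relaxation.

    ``p_min``: extinction threshold on population fractions.
    ``tol_mu``: relative spread allowed between survivor growth rates at
    a converged coexistence state.  ``mode="nested"`` relaxes cells and
    environment at frozen fractions and steps the replicator equation
    between relaxations (a quasi-steady-state cross-check of the default
    fully coupled integration).
    """

    p_min: float = P_MIN_DEFAULT
    tol_mu: float = 1e-5
    p_rate_tol: float = 1e-8
    solver: SolverConfig = field(default_factory=SolverConfig)
    polish: bool = True
    mode: str = "coupled"


DEFAULT_COMMUNITY = CommunityConfig()


@dataclass
class CommunityState:
    """Roster of species with their intracellular states, the shared
    environment vector, and the population-fraction vector."""

    species: list[CellSpecies]
    X: np.ndarray
    x_env: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.x_env = np.asarray(self.x_env, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        m = len(self.species)
        n = self.species[0].network.n if m else len(self.x_env)
        if any(s.network.n != n for s in self.species):
            raise ValueError("species must share one chemical index space")
        if self.X.shape != (m, n) or self.p.shape != (m,):
            raise ValueError("inconsistent community state shapes")
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species_id in roster")

    def copy(self) -> "CommunityState":
        return CommunityState(list(self.species), self.X.copy(),
                              self.x_env.copy(), self.p.copy())


@dataclass
class SteadyCommunity:
    """A relaxed community: survivors, their common growth rate, and
    convergence metadata."""

    state: CommunityState
    mu: np.ndarray
    mu_star: float
    converged: bool
    time_to_converge: float
    extinctions: list[str] = field(default_factory=list)
    message: str = ""

    @property
    def survivors(self) -> list[CellSpecies]:
        return self.state.species

    @property
    def roster_size(self) -> int:
        return len(self.state.species)


def empty_environment(n: int, env: EnvironmentParams,
                      nutrient_indices=(0,)) -> np.ndarray:
    """Cell-free environment equilibrium: nutrient at its supply/degradation
    balance, everything else absent."""
    x_env = np.zeros(n)
    for i in nutrient_indices:
        x_env[i] = env.D_S_env * env.S_env / (env.D_S_env + env.R_deg)
    return x_env


def environment_rhs(state: CommunityState, env: EnvironmentParams) -> np.ndarray:
    """Environment balance: population-weighted exchange with every cell,
    degradation, and reservoir supply of the nutrient(s)."""
    compiled = CompiledCommunity([CompiledCell(s) for s in state.species], env)
    return compiled.env_rhs(state.X, state.x_env, state.p)


def replicator_rhs(p: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """dp_a/dt = (mu_a - mu_bar) p_a with mu_bar = sum_a p_a mu_a.

    The fraction total is conserved identically (sum of the output is 0
    whenever sum(p) = 1)."""
    p = np.asarray(p, dtype=float)
    mu = np.asarray(mu, dtype=float)
    mu_bar = float(p @ mu)
    return (mu - mu_bar) * p


def introduce_invader(state: CommunityState, invader: CellSpecies,
                      p_init: float = 0.01,
                      x0_value: float = 0.1) -> CommunityState:
    """Append an invader at inoculum fraction ``p_init``.

    Resident fractions are rescaled by ``1 - p_init`` so the total stays
    exactly 1; the invader's intracellular state starts at the standard
    initial condition."""
    if any(s.species_id == invader.species_id for s in state.species):
        raise ValueError(f"duplicate species_id {invader.species_id!r}")
    n = invader.network.n
    if state.species and state.species[0].network.n != n:
        raise ValueError("invader must share the chemical index space")
    if not 0.0 <= p_init < 1.0:
        raise ValueError("p_init must be in [0, 1)")
    x0 = np.full(n, x0_value)
    if not state.species:
        return CommunityState([invader], x0[None, :], state.x_env.copy(),
                              np.array([1.0]))
    X = np.vstack([state.X, x0])
    p = np.concatenate([state.p * (1.0 - p_init), [p_init]])
    return CommunityState(state.species + [invader], X, state.x_env.copy(), p)


# ---------------------------------------------------------------------------
# Relaxation to a steady community
# ---------------------------------------------------------------------------

def _steady_metrics(compiled: CompiledCommunity, z: np.ndarray):
    dz = compiled.rhs(0.0, z)
    k = compiled.m * compiled.n + compiled.n
    chem = float(np.max(np.abs(dz[:k]) / np.maximum(np.abs(z[:k]), 1e-6)))
    prate = float(np.max(np.abs(dz[k:]))) if compiled.m else 0.0
    return chem, prate


def _prune(state: CommunityState, p_min: float, extinct: list[str]) -> CommunityState:
    keep = state.p >= p_min
    if keep.all() or keep.sum() == 0:
        if keep.sum() == 0:
            # keep the least-doomed species; a lone species has p = 1
            keep[int(np.argmax(state.p))] = True
        if keep.all():
            return state
    extinct.extend(s.species_id for s, k in zip(state.species, keep) if not k)
    species = [s for s, k in zip(state.species, keep) if k]
    p = state.p[keep]
    return CommunityState(species, state.X[keep], state.x_env.copy(), p / p.sum())


def _polish(compiled: CompiledCommunity, z: np.ndarray,
            config: CommunityConfig) -> np.ndarray | None:
    """Newton polish of a coexistence state on the simplex.

    Unknowns are the concentrations plus the first m-1 fractions (the
    last is 1 minus their sum); the replicator equations are replaced by
    equal-growth conditions.  The result is accepted only if it is
    feasible and linearly stable under the full dynamics."""
    m, n = compiled.m, compiled.n
    k = m * n + n

    def residual(u):
        z_full = np.empty(compiled.dim)
        z_full[:k] = u[:k]
        pm = 1.0 - u[k:].sum()
        z_full[k:] = np.concatenate([u[k:], [pm]])
        dz = compiled.rhs(0.0, z_full)
        X = z_full[:m * n].reshape(m, n)
        mu = compiled.mu_all(X)
        return np.concatenate([dz[:k], mu[:-1] - mu[-1]])

    u0 = np.concatenate([z[:k], z[k:k + m - 1]])
    sol = root(residual, u0, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(residual(sol.x))) > 1e-9:
        return None
    p_last = 1.0 - sol.x[k:].sum()
    p = np.concatenate([sol.x[k:], [p_last]])
    if np.min(p) < 1e-12 or np.max(p) > 1.0 + 1e-9:
        return None
    z_new = np.concatenate([sol.x[:k], p])
    if np.min(z_new[:k]) < -1e-9:
        return None
    lam = np.linalg.eigvals(compiled.jac(0.0, z_new))
    if np.max(lam.real) > 1e-6:
        return None
    z_new[:k] = np.maximum(z_new[:k], 0.0)
    return z_new


def integrate_community(
    state: CommunityState,
    env: EnvironmentParams,
    config: CommunityConfig | None = None,
    record: list | None = None,
) -> SteadyCommunity:
    """Relax a community to its steady state with extinction pruning.

    Integrates cells, environment and fractions as one coupled stiff
    system in growing time chunks; species dropping below ``p_min`` are
    eliminated (and the fractions renormalized) at chunk boundaries;
    near-steady states are polished by a Newton solve that enforces
    equal survivor growth exactly.  If ``record`` is a list, a snapshot
    dict (time, fractions, environment, growth rates) is appended at
    every chunk boundary.

    Hitting the time cap returns ``converged=False`` with the last state
    attached rather than raising.
    """
    config = config or DEFAULT_COMMUNITY
    if config.mode not in ("coupled", "nested"):
        raise ValueError(f"unknown mode {config.mode!r}")
    scfg = config.solver
    extinct: list[str] = []
    state = _prune(state.copy(), config.p_min, extinct)
    t = 0.0
    chunk = 20.0

    def snapshot(compiled, z, t_now):
        if record is None:
            return
        X, x_env, p = compiled.unpack(z)
        record.append({
            "t": t_now,
            "p": {s.species_id: float(pa) for s, pa in zip(state.species, p)},
            "x_env": x_env.copy(),
            "mu": {s.species_id: float(m) for s, m in
                   zip(state.species, compiled.mu_all(X))},
        })

    while True:
        compiled = CompiledCommunity([CompiledCell(s) for s in state.species], env)
        z = compiled.pack(state.X, state.x_env, state.p)
        snapshot(compiled, z, t)
        if t >= scfg.t_cap:
            return _finish(state, compiled, z, env, config, t, False, extinct,
                           f"no steady state within t={scfg.t_cap:g}")
        if config.mode == "nested":
            # keep the frozen-growth replicator map from overshooting the
            # frequency-dependent balance
            chunk = min(chunk, 500.0)
        span = min(chunk, scfg.t_cap - t)
        if config.mode == "nested":
            z_end = _nested_step(compiled, z, span, scfg)
            sol_ok = z_end is not None
            elapsed = span
        else:
            # terminal events: extinction is enforced the moment any
            # fraction crosses the threshold, not at chunk boundaries —
            # marginal invaders lose the race against a slow environment
            events = _extinction_events(compiled, config.p_min)
            sol = solve_ivp(compiled.rhs, (0.0, span), z, method="LSODA",
                            jac=compiled.jac, rtol=scfg.rtol, atol=scfg.atol,
                            t_eval=[span], events=events)
            sol_ok = sol.success
            elapsed = span
            z_end = z
            if sol.success:
                if sol.status == 1:  # an extinction event fired
                    for arr, te in zip(sol.y_events, sol.t_events):
                        if len(arr):
                            z_end = arr[-1]
                            elapsed = float(te[-1])
                            break
                elif sol.y.shape[1]:
                    z_end = sol.y[:, -1]
        if not sol_ok:
            return _finish(state, compiled, z, env, config, t,
                           False, extinct, "integrator failure")
        z = np.asarray(z_end, dtype=float)
        k = compiled.m * compiled.n + compiled.n
        z[:k] = np.maximum(z[:k], 0.0)
        z[k:] = np.maximum(z[k:], 0.0)
        t += elapsed
        X, x_env, p = compiled.unpack(z)
        state = CommunityState(list(state.species), X, x_env, p / p.sum())
        pruned = _prune(state, config.p_min, extinct)
        if len(pruned.species) != len(state.species):
            state = pruned
            chunk = max(chunk / 2.0, 20.0)
            continue
        chem, prate = _steady_metrics(compiled, z)
        if chem < scfg.ss_tol and prate < config.p_rate_tol:
            return _finish(state, compiled, z, env, config, t, True, extinct)
        if config.polish and chem < scfg.polish_threshold:
            z_pol = _polish(compiled, z, config)
            if z_pol is not None:
                Xp, xep, pp = compiled.unpack(z_pol)
                state = CommunityState(list(state.species), Xp, xep, pp)
                if np.min(pp) < config.p_min:
                    state = _prune(state, config.p_min, extinct)
                    continue
                return _finish(state, compiled, z_pol, env, config, t,
                               True, extinct, "newton")
        if t >= scfg.t_cap:
            return _finish(state, compiled, z, env, config, t, False, extinct,
                           f"no steady state within t={scfg.t_cap:g}")
        chunk = min(chunk * 2.0, 25000.0)


def _extinction_events(compiled: CompiledCommunity, p_min: float):
    """One terminal event per species, firing when its fraction falls
    through the extinction threshold (with a small margin so a freshly
    pruned roster does not re-trigger at t = 0)."""
    k = compiled.m * compiled.n + compiled.n
    if compiled.m <= 1:
        return None  # a lone species holds p = 1
    events = []
    for a in range(compiled.m):
        def ev(t, zz, a=a):
            return zz[k + a] - 0.9 * p_min
        ev.terminal = True
        ev.direction = -1.0
        events.append(ev)
    return events


def _nested_step(compiled: CompiledCommunity, z: np.ndarray, span: float,
                 scfg: SolverConfig) -> np.ndarray | None:
    """Quasi-steady-state alternative: relax chemistry at frozen
    fractions, then apply the replicator map over the same interval."""
    k = compiled.m * compiled.n + compiled.n
    p = z[k:].copy()

    def rhs_frozen(t, zz):
        out = compiled.rhs(t, np.concatenate([zz, p]))
        return out[:k]

    sol = solve_ivp(rhs_frozen, (0.0, span), z[:k], method="LSODA",
                    rtol=scfg.rtol, atol=scfg.atol, t_eval=[span])
    if not sol.success:
        return None
    chem = np.maximum(sol.y[:, -1], 0.0)
    X = chem[:compiled.m * compiled.n].reshape(compiled.m, compiled.n)
    mu = compiled.mu_all(X)
    w = p * np.exp((mu - mu.max()) * span)
    return np.concatenate([chem, w / w.sum()])


def _finish(state: CommunityState, compiled: CompiledCommunity, z: np.ndarray,
            env: EnvironmentParams, config: CommunityConfig, t: float,
            converged: bool, extinct: list[str],
            message: str = "") -> SteadyCommunity:
    X, x_env, p = compiled.unpack(z)
    mu = compiled.mu_all(X)
    mu_star = float(p @ mu / p.sum())
    if converged and len(mu) > 1 and mu_star > 0:
        spread = (mu.max() - mu.min()) / mu_star
        if spread > config.tol_mu:
            message = (message + "; " if message else "") + (
                f"survivor growth spread {spread:.2e} exceeds tol_mu")
    final = CommunityState(list(state.species), X, x_env, p / p.sum())
    return SteadyCommunity(state=final, mu=mu, mu_star=mu_star,
                           converged=converged, time_to_converge=t,
                           extinctions=list(extinct), message=message)


def trajectory_frame(record: list) -> pd.DataFrame:
    """Flatten an ``integrate_community`` record list into a tidy frame."""
    rows = []
    for snap in record:
        for sid, pv in snap["p"].items():
            rows.append({"t": snap["t"], "series": f"p[{sid}]", "value": pv})
        for sid, m in snap["mu"].items():
            rows.append({"t": snap["t"], "series": f"mu[{sid}]", "value": m})
        for i, v in enumerate(snap["x_env"]):
            rows.append({"t": snap["t"], "series": f"x_env[{i}]", "value": float(v)})
    return pd.DataFrame(rows)
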