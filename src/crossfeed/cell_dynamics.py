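"""Single-cell dynamics: fluxes, growth, steady states, leak advantage.

The intracellular state of a species obeys

    dx_i/dt = F_i(x) + D_i * (x_env_i - x_i) - mu(x) * x_i

where ``F`` is the net mass-action synthesis, the middle term is passive
exchange with the environment, and the last term is dilution by volume
growth.  Isolated steady states are found by stiff integration from a
standard initial condition (all concentrations 0.1) with an optional
Newton polish; warm starts make the finite-difference probes used for
leak-advantage detection and leakiness optimization cheap.

A chemical has a *leak advantage* when an infinitesimal increase of its
diffusion coefficient — with the environment acting as a perfect sink
for it — raises the cell's steady growth rate.  That counterintuitive
benefit arises from flux control in autocatalytic parts of the network:
draining an over-accumulating intermediate can speed up the cycle that
makes it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from ._kinetics import CompiledCell
from .networks import CellSpecies, EnvironmentParams, ReactionNetwork

__all__ = [
    "SolverConfig",
    "SteadyState",
    "reaction_fluxes",
    "growth_rate",
    "cell_rhs",
    "solve_isolated_steady_state",
    "leak_advantage_chemicals",
    "growth_vs_leakiness_scan",
]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical policy for steady-state solves.

    ``x0_value``: standard initial intracellular concentration (every
    chemical starts at this value so the autocatalytic core can
    bootstrap).  ``ss_tol``: steady-state criterion, pointwise
    ``|dx/dt| / max(x, 1e-6) < ss_tol`` sustained over ``ss_window`` time
    units.  ``t_cap``: hard cap on integrated time; hitting it flags the
    result as non-converged (e.g. a limit cycle) with a time-averaged
    growth rate attached.
    """

    x0_value: float = 0.1
    rtol: float = 1e-8
    atol: float = 1e-10
    ss_tol: float = 1e-7
    ss_window: float = 10.0
    t_cap: float = 1e5
    newton_tol: float = 1e-10
    polish_threshold: float = 1e-3
    check_stability: bool = True


DEFAULT_SOLVER = SolverConfig()


@dataclass
class SteadyState:
    """Converged (or flagged) single-species steady state."""

    x: np.ndarray
    x_env: np.ndarray
    mu: float
    converged: bool
    t: float
    message: str = ""


def reaction_fluxes(network: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """Net synthesis vector F: production minus consumption per chemical,
    including substrate consumption by designated biomass reactions."""
    x = np.asarray(x, dtype=float)
    if x.shape != (network.n,):
        raise ValueError(f"state must have length {network.n}")
    return CompiledCell(_bare_species(network)).F_mu(x)[0]


def growth_rate(network: ReactionNetwork, x: np.ndarray) -> float:
    """Growth rate mu(x) under the network's growth rule (always >= 0)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (network.n,):
        raise ValueError(f"state must have length {network.n}")
    return CompiledCell(_bare_species(network)).F_mu(x)[1]


def _bare_species(network: ReactionNetwork) -> CellSpecies:
    D = np.zeros(network.n)
    return CellSpecies(species_id="_bare", network=network, D=D, D_S=0.0)


def cell_rhs(species: CellSpecies, x: np.ndarray, x_env: np.ndarray) -> np.ndarray:
    """Time derivative of the intracellular state at fixed environment."""
    x = np.asarray(x, dtype=float)
    x_env = np.asarray(x_env, dtype=float)
    if x.shape != (species.network.n,) or x_env.shape != (species.network.n,):
        raise ValueError("state and environment must have length n")
    return CompiledCell(species).rhs(x, x_env)


# ---------------------------------------------------------------------------
# Steady-state machinery
# ---------------------------------------------------------------------------

def _default_clamp(species: CellSpecies, env: EnvironmentParams) -> np.ndarray:
    """Clamped-environment default: perfect sink for every non-nutrient
    metabolite, nutrients at the cell-free reservoir equilibrium."""
    x_env = np.zeros(species.network.n)
    s_star = env.D_S_env * env.S_env / (env.D_S_env + env.R_deg)
    for i in species.network.nutrient_indices:
        x_env[i] = s_star
    return x_env


def _env_start(species: CellSpecies, env: EnvironmentParams) -> np.ndarray:
    return _default_clamp(species, env)


class _IsoSystem:
    """Coupled cell + dynamic environment for a lone species (p = 1)."""

    def __init__(self, cell: CompiledCell, env: EnvironmentParams):
        self.cell = cell
        self.env = env
        n = cell.n
        self.n = n
        self.supply = np.zeros(n)
        self.supply[list(cell.species.network.nutrient_indices)] = env.D_S_env

    def rhs(self, t, z):
        n = self.n
        x, x_env = z[:n], z[n:]
        dx = self.cell.rhs(x, x_env)
        dxe = (self.cell.D * (x - x_env) / self.env.V_env
               - self.env.R_deg * x_env
               + self.supply * (self.env.S_env - x_env))
        return np.concatenate([dx, dxe])

    def jac(self, t, z):
        n = self.n
        x, x_env = z[:n], z[n:]
        _, Jcell = self.cell.rhs_jac(x, x_env)
        J = np.zeros((2 * n, 2 * n))
        J[:n, :n] = Jcell
        J[:n, n:] = np.diag(self.cell.D)
        J[n:, :n] = np.diag(self.cell.D) / self.env.V_env
        J[n:, n:] = (-np.diag(self.cell.D) / self.env.V_env
                     - np.diag(self.env.R_deg + self.supply))
        return J


class _ResponseSystem:
    """One focal species coupled to the environment, with every other
    community member frozen: the focal cell sees the environment respond
    to its own exchange (weighted by its fraction ``p_self``) on top of
    the others' constant contribution.

    ``source[i] = sum_b p_b D_b_i x_b_i`` and
    ``drain[i] = sum_b p_b D_b_i`` over the frozen species b.
    """

    def __init__(self, cell: CompiledCell, env: EnvironmentParams,
                 p_self: float, source: np.ndarray, drain: np.ndarray):
        self.cell = cell
        self.env = env
        self.p_self = float(p_self)
        self.source = np.asarray(source, dtype=float)
        self.drain = np.asarray(drain, dtype=float)
        n = cell.n
        self.n = n
        self.supply = np.zeros(n)
        self.supply[list(cell.species.network.nutrient_indices)] = env.D_S_env

    def rhs(self, t, z):
        n = self.n
        x, x_env = z[:n], z[n:]
        dx = self.cell.rhs(x, x_env)
        dxe = ((self.p_self * self.cell.D * (x - x_env)
                + self.source - self.drain * x_env) / self.env.V_env
               - self.env.R_deg * x_env
               + self.supply * (self.env.S_env - x_env))
        return np.concatenate([dx, dxe])

    def jac(self, t, z):
        n = self.n
        x, x_env = z[:n], z[n:]
        _, Jcell = self.cell.rhs_jac(x, x_env)
        J = np.zeros((2 * n, 2 * n))
        J[:n, :n] = Jcell
        J[:n, n:] = np.diag(self.cell.D)
        J[n:, :n] = self.p_self * np.diag(self.cell.D) / self.env.V_env
        J[n:, n:] = -np.diag(
            (self.p_self * self.cell.D + self.drain) / self.env.V_env
            + self.env.R_deg + self.supply)
        return J


def solve_response_steady_state(
    species: CellSpecies,
    env: EnvironmentParams,
    p_self: float,
    source: np.ndarray,
    drain: np.ndarray,
    config: SolverConfig | None = None,
    warm_start: tuple[np.ndarray, np.ndarray | None] | None = None,
) -> SteadyState:
    """Steady state of one species against an environment that responds
    to its own exchange while the rest of the community is frozen
    (constant ``source``/``drain`` contributions).  With an empty
    community this reduces to the dynamic isolated solve."""
    config = config or DEFAULT_SOLVER
    cell = CompiledCell(species)
    n = cell.n
    system = _ResponseSystem(cell, env, p_self, source, drain)
    if warm_start is not None:
        xw, xew = warm_start
        z0 = np.concatenate([xw, xew if xew is not None
                             else _env_start(species, env)])
        polished = _try_newton(system, np.asarray(z0, dtype=float), config)
        if polished is not None:
            x = np.maximum(polished[:n], 0.0)
            return SteadyState(x=x, x_env=np.maximum(polished[n:], 0.0),
                               mu=cell.F_mu(x)[1], converged=True, t=0.0,
                               message="newton")
        z_start = np.asarray(z0, dtype=float)
    else:
        z_start = np.concatenate([np.full(n, config.x0_value),
                                  _env_start(species, env)])
    z, t, ok, mu_trace = _relax(system, z_start, config)
    x, xe = np.maximum(z[:n], 0.0), np.maximum(z[n:], 0.0)
    if ok:
        return SteadyState(x=x, x_env=xe, mu=cell.F_mu(x)[1],
                           converged=True, t=t)
    mu_avg = float(np.nanmean(mu_trace)) if len(mu_trace) else float("nan")
    if not np.isfinite(mu_avg):
        mu_avg = cell.F_mu(x)[1]
    return SteadyState(x=x, x_env=xe, mu=mu_avg, converged=False, t=t,
                       message="no steady state (time-averaged growth)")


class _ClampedSystem:
    def __init__(self, cell: CompiledCell, x_env: np.ndarray):
        self.cell = cell
        self.x_env = np.asarray(x_env, dtype=float)
        self.n = cell.n

    def rhs(self, t, z):
        return self.cell.rhs(z, self.x_env)

    def jac(self, t, z):
        return self.cell.rhs_jac(z, self.x_env)[1]


def _try_newton(system, z0: np.ndarray, config: SolverConfig) -> np.ndarray | None:
    """Newton polish; returns the steady point or None if unacceptable."""
    sol = root(lambda z: system.rhs(0.0, z), z0,
               jac=lambda z: system.jac(0.0, z), method="hybr",
               tol=config.newton_tol)
    z = sol.x
    if not sol.success:
        return None
    if np.min(z) < -1e-9:
        return None
    res = system.rhs(0.0, z)
    if np.max(np.abs(res)) > 1e-9:
        return None
    if config.check_stability:
        lam = np.linalg.eigvals(system.jac(0.0, z))
        if np.max(lam.real) > 1e-6:
            return None
    return np.maximum(z, 0.0)


def _steady_metric(system, z: np.ndarray) -> float:
    dz = system.rhs(0.0, z)
    return float(np.max(np.abs(dz) / np.maximum(np.abs(z), 1e-6)))


def _relax(system, z0: np.ndarray, config: SolverConfig):
    """Chunked stiff integration until the steady criterion holds.

    Returns ``(z, t, converged, mu_trace)`` where ``mu_trace`` samples the
    last chunk (used for the time-averaged growth rate of non-converged,
    e.g. oscillatory, solves).
    """
    t = 0.0
    z = z0.copy()
    chunk = 20.0
    mu_samples: list[float] = [np.nan]
    while t < config.t_cap:
        span = min(chunk, config.t_cap - t)
        t_probe = max(span - config.ss_window, span * 0.5)
        sol = solve_ivp(system.rhs, (0.0, span), z, method="LSODA",
                        jac=system.jac, rtol=config.rtol, atol=config.atol,
                        t_eval=[t_probe, span], dense_output=False)
        if not sol.success:
            return z, t, False, mu_samples
        z_probe = np.maximum(sol.y[:, 0], 0.0)
        z = np.maximum(sol.y[:, -1], 0.0)
        t += span
        if (_steady_metric(system, z) < config.ss_tol
                and _steady_metric(system, z_probe) < config.ss_tol):
            return z, t, True, mu_samples
        if _steady_metric(system, z) < config.polish_threshold:
            polished = _try_newton(system, z, config)
            if polished is not None:
                return polished, t, True, mu_samples
        chunk = min(chunk * 2.0, 25000.0)
        mu_samples = [self_mu(system, sol.y[:, j]) for j in range(sol.y.shape[1])]
    return z, t, False, mu_samples


def self_mu(system, z: np.ndarray) -> float:
    n = system.n
    return system.cell.F_mu(np.maximum(z[:n], 0.0))[1]


def solve_isolated_steady_state(
    species: CellSpecies,
    env: EnvironmentParams,
    clamp_env: bool = True,
    clamp_values: np.ndarray | None = None,
    config: SolverConfig | None = None,
    warm_start: tuple[np.ndarray, np.ndarray | None] | None = None,
) -> SteadyState:
    """Steady state and growth rate of a lone species (p = 1).

    With ``clamp_env=True`` the environment vector is held fixed at
    ``clamp_values`` (default: perfect sink for non-nutrient metabolites,
    nutrients at the cell-free reservoir equilibrium).  With
    ``clamp_env=False`` the environment obeys its own balance equation —
    supply of the nutrient(s), exchange with the cell, degradation — and
    is solved jointly with the cell.

    ``warm_start=(x, x_env)`` seeds a Newton solve first (used by the
    finite-difference and optimizer loops); integration from the
    standard initial condition is the fallback.  Non-convergence within
    the time cap is reported via ``converged=False`` (with a
    time-averaged growth rate), never as an exception.
    """
    config = config or DEFAULT_SOLVER
    cell = CompiledCell(species)
    n = cell.n

    if clamp_env:
        x_env = (_default_clamp(species, env) if clamp_values is None
                 else np.asarray(clamp_values, dtype=float))
        system = _ClampedSystem(cell, x_env)
        pack = lambda x: x
        unpack = lambda z: (np.maximum(z, 0.0), x_env)
    else:
        system = _IsoSystem(cell, env)
        pack = lambda x: np.concatenate([x, _env_start(species, env)])
        unpack = lambda z: (np.maximum(z[:n], 0.0), np.maximum(z[n:], 0.0))

    if warm_start is not None:
        xw, xew = warm_start
        z0 = xw if clamp_env else np.concatenate(
            [xw, xew if xew is not None else _env_start(species, env)])
        polished = _try_newton(system, np.asarray(z0, dtype=float), config)
        if polished is not None:
            x, xe = unpack(polished)
            return SteadyState(x=x, x_env=xe, mu=cell.F_mu(x)[1],
                               converged=True, t=0.0, message="newton")
        z_start = np.asarray(z0, dtype=float)
    else:
        z_start = pack(np.full(n, config.x0_value))

    z, t, ok, mu_trace = _relax(system, z_start, config)
    x, xe = unpack(z)
    if ok:
        return SteadyState(x=x, x_env=xe, mu=cell.F_mu(x)[1],
                           converged=True, t=t)
    mu_avg = float(np.nanmean(mu_trace)) if len(mu_trace) else float("nan")
    if not np.isfinite(mu_avg):
        mu_avg = cell.F_mu(x)[1]
    return SteadyState(x=x, x_env=xe, mu=mu_avg, converged=False, t=t,
                       message=f"no steady state within t={config.t_cap:g} "
                               "(time-averaged growth rate reported)")


# ---------------------------------------------------------------------------
# Leak advantage
# ---------------------------------------------------------------------------

def leak_advantage_chemicals(
    species: CellSpecies,
    env: EnvironmentParams,
    epsilon: float = 1e-3,
    tol: float = 1e-9,
    clamp_values: np.ndarray | None = None,
    config: SolverConfig | None = None,
) -> set[int]:
    """Non-nutrient metabolites whose leakage raises the isolated growth.

    Protocol: the tested chemical's environmental concentration is
    clamped at 0 (a perfect sink, so leakage is never throttled by
    accumulation), every other diffusion coefficient keeps its current
    value, and the steady growth rate with ``D_i = epsilon`` is compared
    against ``D_i = 0``.  Chemicals whose growth gain exceeds ``tol``
    are returned.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    config = config or DEFAULT_SOLVER
    net = species.network
    if clamp_values is None:
        clamp_values = _default_clamp(species, env)
        if any(species.D[i] > 0 for i in net.non_nutrient_metabolites):
            # nutrient level in the clamp tracks the species' own isolated
            # culture when it already leaks something
            base_dyn = solve_isolated_steady_state(species, env, clamp_env=False,
                                                   config=config)
            for i in net.nutrient_indices:
                clamp_values[i] = base_dyn.x_env[i]
    clamp_values = np.asarray(clamp_values, dtype=float)

    base_cache: dict[float, SteadyState] = {}

    def mu_at(D_i_zero: bool, i: int, warm: SteadyState | None) -> SteadyState:
        D = species.D.copy()
        D[i] = 0.0 if D_i_zero else epsilon
        probe = species.with_D(D)
        ws = (warm.x, None) if warm is not None and warm.converged else None
        return solve_isolated_steady_state(probe, env, clamp_env=True,
                                           clamp_values=clamp_values,
                                           config=config, warm_start=ws)

    shared_base: SteadyState | None = None
    result: set[int] = set()
    for i in net.non_nutrient_metabolites:
        if species.D[i] == 0.0:
            if shared_base is None:
                shared_base = solve_isolated_steady_state(
                    species, env, clamp_env=True, clamp_values=clamp_values,
                    config=config)
            base = shared_base
        else:
            base = mu_at(True, i, shared_base)
        if not base.converged:
            continue
        probe = mu_at(False, i, base)
        if probe.converged and probe.mu > base.mu + tol:
            result.add(i)
    return result


def growth_vs_leakiness_scan(
    species: CellSpecies,
    env: EnvironmentParams,
    chemical: int,
    D_grid,
    clamp_env: bool = True,
    clamp_values: np.ndarray | None = None,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Isolated growth rate as a function of one diffusion coefficient.

    Returns a frame with columns ``chemical, D, mu, converged`` evaluated
    pointwise over ``D_grid`` (warm-starting each point from the
    previous one).  The default protocol matches the leak-advantage
    definition — the environment is a clamped perfect sink for the
    scanned chemical — so the curve exposes the interior growth optimum
    of a leak-advantage chemical; ``clamp_env=False`` cultures the
    species against its own dynamic environment instead (where leakage
    is throttled by accumulation and the curve typically saturates).
    """
    D_grid = np.asarray(D_grid, dtype=float)
    if np.any(D_grid < 0):
        raise ValueError("diffusion coefficients must be nonnegative")
    config = config or DEFAULT_SOLVER
    rows = []
    warm: SteadyState | None = None
    for D_val in D_grid:
        D = species.D.copy()
        D[chemical] = D_val
        probe = species.with_D(D)
        ws = None
        if warm is not None and warm.converged:
            ws = (warm.x, warm.x_env if not clamp_env else None)
        res = solve_isolated_steady_state(probe, env, clamp_env=clamp_env,
                                          clamp_values=clamp_values,
                                          config=config, warm_start=ws)
        warm = res
        rows.append({"chemical": chemical, "D": float(D_val),
                     "mu": res.mu, "converged": res.converged})
    return pd.DataFrame(rows)
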