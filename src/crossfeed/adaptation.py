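"""Cell-level adaptation of metabolite leakiness.

Two adaptation modes drive the assembly protocol:

- *invasion-time optimization*: a newcomer tunes its non-nutrient
  diffusion coefficients to maximize its own steady growth rate against
  the frozen pre-invasion environment (a derivative-free multi-start
  coordinate hill climb with shrinking steps);
- *gradual resident adaptation*: after the community has re-equilibrated,
  every survivor simultaneously takes small finite-difference ascent
  steps on its own frozen-environment growth rate, after which the whole
  community is relaxed back to a steady state (with extinction pruning).

Both respect the bounds [0, D_max] and the species' adaptation grouping:
all metabolites in one group share a single coefficient (the leakage
"specificity").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cell_dynamics import (
    DEFAULT_SOLVER,
    SolverConfig,
    SteadyState,
    solve_isolated_steady_state,
    solve_response_steady_state,
)
from .community_dynamics import (
    CommunityConfig,
    CommunityState,
    SteadyCommunity,
    integrate_community,
)
from .networks import CellSpecies, EnvironmentParams

__all__ = ["AdaptationConfig", "optimize_invader_D", "adapt_residents"]


@dataclass(frozen=True)
class AdaptationConfig:
    """Tunables of both adaptation modes.

    ``eta``: ascent step size (D units per unit growth gradient);
    ``fd_epsilon``: finite-difference probe on D; ``n_rounds``: resident
    adaptation events per phase; ``D_max``: upper bound of any adapted
    coefficient; ``n_restarts``: random restarts of the invasion-time
    hill climb besides the D = 0 start; ``step_init``/``step_min``: the
    climb's initial and final coordinate step.  ``adapt_interval`` is
    the nominal relaxation period between resident events (the community
    is re-relaxed to steady state after each event, which covers any
    interval at least this long).
    """

    eta: float = 0.1
    fd_epsilon: float = 1e-3
    mu_tol: float = 1e-9
    adapt_interval: float = 100.0
    n_rounds: int = 50
    D_max: float = 10.0
    n_restarts: int = 3
    step_init: float = 1.0
    step_min: float = 0.02
    max_evals: int = 400
    solver: SolverConfig = field(default_factory=SolverConfig)


DEFAULT_ADAPTATION = AdaptationConfig()


class _FrozenObjective:
    """Steady growth rate of one species against a frozen environment,
    as a function of its grouped diffusion coefficients."""

    def __init__(self, species: CellSpecies, x_env: np.ndarray,
                 env: EnvironmentParams, scfg: SolverConfig):
        self.species = species
        self.groups = species.free_groups()
        self.x_env = np.asarray(x_env, dtype=float)
        self.env = env
        self.scfg = scfg
        self.evals = 0

    def D_from_groups(self, v: np.ndarray) -> np.ndarray:
        D = self.species.D.copy()
        for g, val in zip(self.groups, v):
            for i in g:
                D[i] = val
        return D

    def group_values(self, D: np.ndarray) -> np.ndarray:
        return np.array([D[g[0]] for g in self.groups], dtype=float)

    def __call__(self, v: np.ndarray, warm: SteadyState | None = None
                 ) -> SteadyState:
        self.evals += 1
        probe = self.species.with_D(self.D_from_groups(v))
        ws = (warm.x, None) if warm is not None and warm.converged else None
        return solve_isolated_steady_state(
            probe, self.env, clamp_env=True, clamp_values=self.x_env,
            config=self.scfg, warm_start=ws)


class _ResponseObjective:
    """A resident's steady growth as a function of its grouped
    coefficients, with the environment responding to its own exchange
    and the rest of the community frozen (constant source/drain)."""

    def __init__(self, species: CellSpecies, env: EnvironmentParams,
                 p_self: float, source: np.ndarray, drain: np.ndarray,
                 scfg: SolverConfig):
        self.species = species
        self.groups = species.free_groups()
        self.env = env
        self.p_self = p_self
        self.source = source
        self.drain = drain
        self.scfg = scfg

    def D_from_groups(self, v: np.ndarray) -> np.ndarray:
        D = self.species.D.copy()
        for g, val in zip(self.groups, v):
            for i in g:
                D[i] = val
        return D

    def group_values(self, D: np.ndarray) -> np.ndarray:
        return np.array([D[g[0]] for g in self.groups], dtype=float)

    def __call__(self, v: np.ndarray, warm: SteadyState | None = None
                 ) -> SteadyState:
        probe = self.species.with_D(self.D_from_groups(v))
        ws = ((warm.x, warm.x_env) if warm is not None and warm.converged
              else None)
        return solve_response_steady_state(
            probe, self.env, self.p_self, self.source, self.drain,
            config=self.scfg, warm_start=ws)


def _hill_climb(obj: _FrozenObjective, v0: np.ndarray,
                config: AdaptationConfig):
    """Coordinate-wise ascent with shrinking steps from one start."""
    v = np.clip(v0, 0.0, config.D_max)
    best = obj(v)
    if not best.converged:
        return v, best
    step = config.step_init
    while step >= config.step_min and obj.evals < config.max_evals:
        improved = False
        for j in range(len(v)):
            for delta in (step, -step):
                vj = np.clip(v[j] + delta, 0.0, config.D_max)
                if vj == v[j]:
                    continue
                trial = v.copy()
                trial[j] = vj
                res = obj(trial, warm=best)
                if res.converged and res.mu > best.mu + 1e-12:
                    v, best = trial, res
                    improved = True
                if obj.evals >= config.max_evals:
                    break
            if obj.evals >= config.max_evals:
                break
        if not improved:
            step /= 2.0
    return v, best


def optimize_invader_D(
    invader: CellSpecies,
    x_env_frozen: np.ndarray,
    env: EnvironmentParams,
    config: AdaptationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, float]:
    """Diffusion coefficients maximizing an invader's growth against the
    frozen pre-invasion environment.

    Runs the coordinate hill climb from D = 0 and from ``n_restarts``
    random points in [0, D_max] (seeded, hence deterministic), keeping
    the best converged optimum.  Returns ``(D_star, mu_star)``; the
    growth at ``D_star`` is never below the growth at the D = 0 start.
    """
    config = config or DEFAULT_ADAPTATION
    rng = np.random.default_rng(rng)
    obj = _FrozenObjective(invader, x_env_frozen, env, config.solver)
    g = len(obj.groups)
    starts = [np.zeros(g)]
    starts += [rng.uniform(0.0, config.D_max, size=g)
               for _ in range(config.n_restarts)]
    best_v, best_res = None, None
    for v0 in starts:
        obj.evals = 0
        v, res = _hill_climb(obj, v0, config)
        if res.converged and (best_res is None or res.mu > best_res.mu):
            best_v, best_res = v, res
    if best_res is None:  # even the D = 0 start failed to converge
        return invader.D.copy(), float("nan")
    return obj.D_from_groups(best_v), best_res.mu


def adapt_residents(
    community: SteadyCommunity,
    env: EnvironmentParams,
    config: AdaptationConfig | None = None,
    community_config: CommunityConfig | None = None,
    log: list | None = None,
) -> SteadyCommunity:
    """Gradual, simultaneous leakiness adaptation of all survivors.

    Per event: each survivor moves every free coefficient group by
    ``eta`` (in D-units) along the sign of the finite-difference
    gradient of its own steady growth rate, evaluated with the
    environment responding to the survivor's own exchange while every
    other species is frozen at the current community state (all species
    use the same snapshot, hence "simultaneous").  The self-consistent
    environment matters: it lets a leaker feel its own secretion
    saturating the medium and a consumer feel its own uptake depleting
    it, the feedbacks that keep adaptation from running every valve to
    a bound.  A step that would lower the species' growth under its own
    objective is halved until it improves or is dropped, so accepted
    steps are monotone against their snapshot by construction.  The
    full community is then re-relaxed with pruning.  A failed
    re-relaxation rolls the event back with a halved step size; repeated
    failure aborts the phase, returning the last good community.
    """
    config = config or DEFAULT_ADAPTATION
    ccfg = community_config or CommunityConfig(solver=config.solver)
    eta = config.eta
    failures = 0
    for event in range(config.n_rounds):
        if eta <= 0 or community.roster_size == 0:
            break
        st = community.state
        x_env = st.x_env.copy()
        D_all = np.stack([s.D for s in st.species])
        new_species: list[CellSpecies] = []
        any_change = False
        for row, sp in enumerate(st.species):
            mask = np.arange(len(st.species)) != row
            source = (st.p[mask, None] * D_all[mask] * st.X[mask]).sum(axis=0) \
                if mask.any() else np.zeros(st.X.shape[1])
            drain = (st.p[mask, None] * D_all[mask]).sum(axis=0) \
                if mask.any() else np.zeros(st.X.shape[1])
            obj = _ResponseObjective(sp, env, float(st.p[row]), source,
                                     drain, config.solver)
            v0 = obj.group_values(sp.D)
            base = obj(v0, warm=SteadyState(
                x=st.X[row], x_env=x_env, mu=0.0, converged=True, t=0.0))
            if not base.converged:
                new_species.append(sp)
                continue
            direction = np.zeros_like(v0)
            for j in range(len(v0)):
                probe = v0.copy()
                probe[j] = min(probe[j] + config.fd_epsilon, config.D_max)
                if probe[j] == v0[j]:  # pinned at the bound: probe downward
                    probe[j] = v0[j] - config.fd_epsilon
                res = obj(probe, warm=base)
                # dead band: a growth response within the detection
                # tolerance is noise, not a signal to move the valve
                if res.converged and abs(res.mu - base.mu) > config.mu_tol:
                    direction[j] = np.sign((res.mu - base.mu)
                                           * (probe[j] - v0[j]))
            # eta is a step in D-units: move each responsive group by eta
            # along its growth gradient's sign
            scale = eta
            accepted = v0
            mu_after = base.mu
            while scale >= eta / 16.0 and np.any(direction != 0.0):
                trial = np.clip(v0 + scale * direction, 0.0, config.D_max)
                if np.allclose(trial, v0):
                    break
                res = obj(trial, warm=base)
                if res.converged and res.mu > base.mu + 1e-12:
                    accepted, mu_after = trial, res.mu
                    break
                scale /= 2.0
            if not np.array_equal(accepted, v0):
                any_change = True
                if log is not None:
                    for j, grp in enumerate(obj.groups):
                        if accepted[j] != v0[j]:
                            log.append({"event": event, "species": sp.species_id,
                                        "group": grp, "D_before": float(v0[j]),
                                        "D_after": float(accepted[j]),
                                        "mu_before": base.mu,
                                        "mu_frozen": mu_after})
            new_species.append(sp.with_D(obj.D_from_groups(accepted)))
        if not any_change:
            break
        trial_state = CommunityState(new_species, community.state.X.copy(),
                                     community.state.x_env.copy(),
                                     community.state.p.copy())
        relaxed = integrate_community(trial_state, env, ccfg)
        if "integrator failure" in relaxed.message:
            failures += 1  # roll back the event, halve the step
            eta /= 2.0
            if failures >= 3:
                break
        else:
            community = relaxed
            failures = 0
    return community
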