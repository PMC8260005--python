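"""Ecosystem assembly by sequential invasion, and the sweep experiments.

The assembly protocol adds a pool of candidate species to the shared
environment one by one.  Each newcomer first optimizes its leakiness
against the frozen pre-invasion environment, is inoculated at a small
fraction, and the community is relaxed to a steady state with
extinction pruning; the survivors then go through a phase of gradual
simultaneous leakiness adaptation.  Controls run the same protocol with
adaptation disabled and diffusion coefficients fixed by a policy
(uniform random, or random with every leak-advantage chemical's
coefficient forced to zero).

Sweeps repeat assemblies over a parameter axis (community size n,
environment volume, nutrient supply, degradation rate, leakage
specificity, or the fixed-D upper bound) with independent seeded pools,
and tabulate how many species end up coexisting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adaptation import AdaptationConfig, adapt_residents, optimize_invader_D
from .cell_dynamics import SolverConfig, solve_isolated_steady_state
from .community_dynamics import (
    CommunityConfig,
    CommunityState,
    SteadyCommunity,
    empty_environment,
    integrate_community,
    introduce_invader,
)
from .ecosystem_analysis import classify_interaction
from .networks import (
    CellSpecies,
    EnvironmentParams,
    generate_species_pool,
)

__all__ = [
    "AssemblyConfig",
    "AssemblyResult",
    "SweepResult",
    "run_assembly",
    "run_fixed_D_assembly",
    "coexistence_sweep",
    "two_species_phase_diagram",
]


@dataclass(frozen=True)
class AssemblyConfig:
    """Knobs of one assembly run (inoculum, adaptation, relaxation)."""

    p_init: float = 0.01
    adaptation: AdaptationConfig = field(default_factory=AdaptationConfig)
    community: CommunityConfig = field(default_factory=CommunityConfig)
    adapt: bool = True


DEFAULT_ASSEMBLY = AssemblyConfig()


@dataclass
class AssemblyResult:
    """Full log of one sequential-invasion run."""

    invasion_log: list[dict]
    final_community: SteadyCommunity
    params: dict
    seed: int | None = None

    @property
    def roster_size(self) -> int:
        return self.final_community.roster_size


@dataclass
class SweepResult:
    """Roster-size statistics over a parameter axis.

    ``records``: one row per (value, replicate) with the final roster
    size; ``frequency``: for each axis value, the fraction of replicates
    ending with k coexisting species (a proper distribution per value).
    """

    axis: str
    records: pd.DataFrame
    failures: list[dict] = field(default_factory=list)

    @property
    def frequency(self) -> pd.DataFrame:
        counts = (self.records.groupby(["value", "roster"]).size()
                  .rename("count").reset_index())
        totals = counts.groupby("value")["count"].transform("sum")
        counts["frequency"] = counts["count"] / totals
        return counts

    def mean_roster(self) -> pd.Series:
        return self.records.groupby("value")["roster"].mean()


def _empty_state(n: int, env: EnvironmentParams, nutrient_indices) -> CommunityState:
    return CommunityState([], np.zeros((0, n)),
                          empty_environment(n, env, nutrient_indices),
                          np.zeros(0))


def _run_protocol(pool: list[CellSpecies], env: EnvironmentParams,
                  config: AssemblyConfig, seed: int | None,
                  optimize: bool, adapt: bool,
                  D_override: list[np.ndarray] | None = None) -> AssemblyResult:
    if not pool:
        raise ValueError("species pool must be nonempty")
    n = pool[0].network.n
    if any(sp.network.n != n for sp in pool):
        raise ValueError("pool must share one chemical index space")
    rng = np.random.default_rng(seed)
    state = _empty_state(n, env, pool[0].network.nutrient_indices)
    community: SteadyCommunity | None = None
    log: list[dict] = []
    for idx, invader in enumerate(pool):
        x_env = state.x_env if community is None else community.state.x_env
        if optimize:
            D_star, mu_star = optimize_invader_D(
                invader, x_env, env, config.adaptation, rng)
        else:
            D_star, mu_star = D_override[idx], float("nan")
        entry = {"invasion": idx, "invader": invader.species_id,
                 "D_star": np.asarray(D_star, dtype=float).tolist(),
                 "mu_frozen": mu_star}
        invader = invader.with_D(D_star)
        base = community.state if community is not None else state
        try:
            state_new = introduce_invader(base, invader, p_init=config.p_init)
            community = integrate_community(state_new, env, config.community)
            if adapt:
                community = adapt_residents(community, env, config.adaptation,
                                            config.community)
        except Exception as exc:
            raise RuntimeError(f"assembly failed at invasion {idx} "
                               f"({invader.species_id})") from exc
        roster = [s.species_id for s in community.survivors]
        entry.update({
            "accepted": invader.species_id in roster,
            "roster": roster,
            "mu": {s.species_id: float(m)
                   for s, m in zip(community.survivors, community.mu)},
            "converged": community.converged,
        })
        log.append(entry)
    params = {"p_init": config.p_init, "adapt": adapt, "optimize": optimize,
              "env": vars(env).copy(), "pool": [sp.species_id for sp in pool]}
    return AssemblyResult(invasion_log=log, final_community=community,
                          params=params, seed=seed)


def run_assembly(pool: list[CellSpecies], env: EnvironmentParams,
                 config: AssemblyConfig | None = None,
                 seed: int | None = 0) -> AssemblyResult:
    """Sequential invasion with invasion-time optimization and resident
    adaptation — the full adaptive assembly protocol.  Deterministic
    given the seed and the pool order."""
    config = config or DEFAULT_ASSEMBLY
    return _run_protocol(pool, env, config, seed,
                         optimize=True, adapt=config.adapt)


def run_fixed_D_assembly(pool: list[CellSpecies], env: EnvironmentParams,
                         config: AssemblyConfig | None = None,
                         D_policy: str = "uniform_random",
                         D_max: float = 1.0,
                         seed: int | None = 0) -> AssemblyResult:
    """Assembly control with adaptation disabled and D fixed by policy.

    ``uniform_random``: every non-nutrient metabolite coefficient drawn
    once from U[0, D_max].  ``zero_leak_advantage_random``: the same,
    but chemicals that confer a leak advantage in isolation get D = 0 —
    leakage is then never beneficial to the leaker."""
    config = config or DEFAULT_ASSEMBLY
    if D_policy not in ("uniform_random", "zero_leak_advantage_random"):
        raise ValueError(f"unknown D policy {D_policy!r}")
    rng = np.random.default_rng(seed)
    overrides = []
    for sp in pool:
        D = sp.D.copy()
        free = list(sp.network.non_nutrient_metabolites)
        D[free] = rng.uniform(0.0, D_max, size=len(free))
        if D_policy == "zero_leak_advantage_random":
            from .cell_dynamics import leak_advantage_chemicals
            la = leak_advantage_chemicals(sp, env,
                                          config=config.adaptation.solver)
            D[list(la)] = 0.0
        overrides.append(D)
    return _run_protocol(pool, env, config, seed,
                         optimize=False, adapt=False, D_override=overrides)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepBase:
    """Baseline pool/assembly parameters for a sweep (one axis varies)."""

    n: int = 20
    rho: float = 2.0
    n_enzyme: int | None = None  # default n // 5
    N: int = 50
    env: EnvironmentParams = field(default_factory=lambda: EnvironmentParams(
        S_env=0.03, V_env=3.0, R_deg=5e-5, D_S_env=20.0))
    D_S: float = 1.0
    specificity: int | None = None
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    protocol: str = "adaptive"  # or "fixed_random", "fixed_zero_leak_advantage"
    D_max_fixed: float = 1.0
    mu_floor: float = 1e-6


SWEEP_AXES = ("n", "V_env", "S_env", "R_deg", "specificity", "D_max")


def coexistence_sweep(axis: str, values, replicates: int,
                      base: SweepBase | None = None,
                      seed: int = 0) -> SweepResult:
    """Final-roster-size statistics along one parameter axis.

    For every axis value, ``replicates`` independent constraint-
    satisfying species pools are generated (seeded) and assembled with
    the configured protocol; per-replicate failures are logged and
    counted rather than fatal.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"axis must be one of {SWEEP_AXES}")
    values = list(values)
    if not values or replicates < 1:
        raise ValueError("need at least one value and one replicate")
    base = base or SweepBase()
    records = []
    failures = []
    for vi, value in enumerate(values):
        for rep in range(replicates):
            rep_seed = seed + 1000 * vi + rep
            try:
                result = _sweep_one(axis, value, base, rep_seed)
                records.append({"value": value, "replicate": rep,
                                "seed": rep_seed,
                                "roster": result.roster_size,
                                "mu_star": result.final_community.mu_star,
                                "converged": result.final_community.converged})
            except Exception as exc:  # logged, not fatal
                failures.append({"value": value, "replicate": rep,
                                 "seed": rep_seed, "error": str(exc)})
    return SweepResult(axis=axis, records=pd.DataFrame(records),
                       failures=failures)


def _sweep_one(axis: str, value, base: SweepBase, seed: int) -> AssemblyResult:
    n = base.n
    env = base.env
    specificity = base.specificity
    D_max_fixed = base.D_max_fixed
    if axis == "n":
        n = int(value)
    elif axis == "V_env":
        env = replace(env, V_env=float(value))
    elif axis == "S_env":
        env = replace(env, S_env=float(value))
    elif axis == "R_deg":
        env = replace(env, R_deg=float(value))
    elif axis == "specificity":
        specificity = int(value)
    elif axis == "D_max":
        D_max_fixed = float(value)
    n_enzyme = base.n_enzyme if base.n_enzyme is not None else max(1, n // 5)
    pool = generate_species_pool(
        n=n, rho=base.rho, n_enzyme=n_enzyme, N=base.N, env=env,
        rng_seed=seed * 131 + 7, D_S=base.D_S, mu_floor=base.mu_floor,
        specificity=specificity,
        solver_config=base.assembly.adaptation.solver)
    if axis == "D_max" or base.protocol == "fixed_random":
        return run_fixed_D_assembly(pool, env, base.assembly,
                                    D_policy="uniform_random",
                                    D_max=D_max_fixed, seed=seed)
    if base.protocol == "fixed_zero_leak_advantage":
        return run_fixed_D_assembly(pool, env, base.assembly,
                                    D_policy="zero_leak_advantage_random",
                                    D_max=D_max_fixed, seed=seed)
    return run_assembly(pool, env, base.assembly, seed=seed)


# ---------------------------------------------------------------------------
# Two-species phase diagram
# ---------------------------------------------------------------------------

PHASE_AXES = ("D_M1_leaker", "D_M1_consumer", "R_deg", "V_env")


def two_species_phase_diagram(leaker: CellSpecies, consumer: CellSpecies,
                              axis1: str, axis2: str, grid1, grid2,
                              env: EnvironmentParams,
                              config: CommunityConfig | None = None,
                              exchanged_chemical: int = 1) -> pd.DataFrame:
    """Interaction label and common growth over a 2-D parameter grid.

    Axes may move either species' diffusion coefficient of the exchanged
    metabolite or the environment parameters (R_deg, V_env).  Each grid
    point relaxes the two-species community from equal inocula and
    labels it by comparing the common growth with the survivors'
    isolated growth rates.  Points that only hit the time cap keep a
    finite-horizon label from their time-averaged growth (with
    ``converged=False`` recorded); integrator failures are UNRESOLVED.
    """
    for ax in (axis1, axis2):
        if ax not in PHASE_AXES:
            raise ValueError(f"axis must be one of {PHASE_AXES}")
    rows = []
    for v1 in np.asarray(grid1, dtype=float):
        for v2 in np.asarray(grid2, dtype=float):
            lk, cs, env_pt = leaker, consumer, env
            for ax, val in ((axis1, v1), (axis2, v2)):
                if ax == "D_M1_leaker":
                    D = lk.D.copy()
                    D[exchanged_chemical] = val
                    lk = lk.with_D(D)
                elif ax == "D_M1_consumer":
                    D = cs.D.copy()
                    D[exchanged_chemical] = val
                    cs = cs.with_D(D)
                elif ax == "R_deg":
                    env_pt = replace(env_pt, R_deg=val)
                else:
                    env_pt = replace(env_pt, V_env=val)
            n = lk.network.n
            state = CommunityState(
                [lk, cs], np.full((2, n), 0.1),
                empty_environment(n, env_pt, lk.network.nutrient_indices),
                np.array([0.5, 0.5]))
            community = integrate_community(state, env_pt, config)
            label = classify_interaction(community, env_pt, strict=False)
            rows.append({axis1: float(v1), axis2: float(v2), "label": label,
                         "mu_star": community.mu_star,
                         "roster": community.roster_size,
                         "converged": community.converged,
                         "survivors": [s.species_id for s in community.survivors]})
    return pd.DataFrame(rows)
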