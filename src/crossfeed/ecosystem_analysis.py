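"""Ecosystem-level analyses of steady communities.

Covers the leakage/uptake flux bookkeeping, the Shannon-type diversity
indices of leakage (how evenly total leakage is spread over species,
``S_Cell``, and over chemicals, ``S_Chem``), interaction classification
(mutualism / parasitism / noncoexistence relative to the best survivor's
isolated growth), and the removal/resilience experiments with their
correlation statistics.

Sign convention: the exchange flux ``f_i = D_i (x_env_i - x_i)`` is
positive into the cell; *leakage* is unambiguously the cell-to-
environment direction, so the leakage flux used throughout is
``l_i = p_a * max(0, D_i (x_i - x_env_i))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_dynamics import SolverConfig, solve_isolated_steady_state
from .community_dynamics import (
    CommunityConfig,
    CommunityState,
    SteadyCommunity,
    integrate_community,
)
from .networks import EnvironmentParams

__all__ = [
    "FluxTable",
    "RemovalOutcome",
    "compute_flux_table",
    "classify_interaction",
    "removal_experiment",
    "resilience_statistics",
    "MUTUALISM",
    "PARASITISM",
    "NONCOEXISTENCE",
    "BORDERLINE",
]

MUTUALISM = "MUTUALISM"
PARASITISM = "PARASITISM"
NONCOEXISTENCE = "NONCOEXISTENCE"
BORDERLINE = "BORDERLINE"
UNRESOLVED = "UNRESOLVED"


@dataclass
class FluxTable:
    """Steady-state exchange fluxes and leakage diversity indices.

    ``f[a, i]``: exchange flux of chemical i into species a (per unit of
    that species' volume); ``leak[a, i]``: population-weighted leakage
    flux; ``P_Leak[a]`` / ``P_Leaked[i]``: each species' / chemical's
    share of the total leakage ``L_tot``; ``S_Cell`` / ``S_Chem``: the
    Shannon entropies of those shares (natural log by default).  If
    nothing leaks (``L_tot = 0``) the shares and entropies are undefined
    and ``defined`` is False.
    """

    species_ids: list[str]
    f: np.ndarray
    leak: np.ndarray
    L_tot: float
    P_Leak: np.ndarray
    P_Leaked: np.ndarray
    S_Cell: float
    S_Chem: float
    defined: bool
    log_base: float = math.e

    def to_frame(self) -> pd.DataFrame:
        """One row per (species, chemical) with exchange and leakage."""
        rows = []
        for a, sid in enumerate(self.species_ids):
            for i in range(self.f.shape[1]):
                rows.append({"species": sid, "chemical": i,
                             "f": float(self.f[a, i]),
                             "leak": float(self.leak[a, i])})
        return pd.DataFrame(rows)


def _entropy(shares: np.ndarray, log_base: float) -> float:
    pos = shares[shares > 0]
    return float(-(pos * np.log(pos)).sum() / math.log(log_base) + 0.0)


def compute_flux_table(community: SteadyCommunity,
                       log_base: float = math.e) -> FluxTable:
    """Leakage/uptake bookkeeping of a converged community."""
    if not community.converged:
        raise ValueError("flux table requires a converged community")
    st = community.state
    D = np.stack([s.D for s in st.species])
    f = D * (st.x_env[None, :] - st.X)
    leak = st.p[:, None] * np.maximum(0.0, -f)
    L_tot = float(leak.sum())
    m, n = leak.shape
    if L_tot <= 0.0:
        return FluxTable([s.species_id for s in st.species], f, leak, 0.0,
                         np.full(m, np.nan), np.full(n, np.nan),
                         float("nan"), float("nan"), defined=False,
                         log_base=log_base)
    P_Leak = leak.sum(axis=1) / L_tot
    P_Leaked = leak.sum(axis=0) / L_tot
    return FluxTable([s.species_id for s in st.species], f, leak, L_tot,
                     P_Leak, P_Leaked,
                     _entropy(P_Leak, log_base), _entropy(P_Leaked, log_base),
                     defined=True, log_base=log_base)


def classify_interaction(community: SteadyCommunity,
                         env: EnvironmentParams,
                         rel_tol: float = 1e-3,
                         solver_config: SolverConfig | None = None,
                         strict: bool = True) -> str:
    """Label a steady community MUTUALISM / PARASITISM / NONCOEXISTENCE.

    A lone survivor is NONCOEXISTENCE.  Otherwise each survivor's
    isolated growth rate is computed alone against its own dynamic
    environment, keeping its in-community diffusion coefficients;
    coexistence whose common growth exceeds the best such isolated rate
    is mutualism, below it parasitism, and within ``rel_tol`` (relative)
    of it BORDERLINE.

    In the default strict mode non-converged input is labelled
    UNRESOLVED.  With ``strict=False`` a time-capped community that
    still carries several species is labelled from its time-averaged
    growth — the finite-horizon reading of a slowly collapsing
    over-leaky pair, which presents as parasitic coexistence.
    """
    if not community.converged and (strict or "failure" in community.message):
        return UNRESOLVED
    if community.roster_size <= 1:
        return NONCOEXISTENCE
    mu_isos = []
    any_iso_steady = False
    for row, sp in enumerate(community.state.species):
        # benchmark each survivor alone from the standard initial
        # condition; warm-starting is safe only from a converged state
        ws = ((community.state.X[row], None) if community.converged
              else None)
        res = solve_isolated_steady_state(
            sp, env, clamp_env=False, config=solver_config, warm_start=ws)
        # a species that cannot reach a steady state alone (e.g. it dies
        # out while a byproduct accumulates) contributes its time-averaged
        # growth rate, which is the meaningful isolated benchmark
        mu_isos.append(res.mu)
        any_iso_steady = any_iso_steady or res.converged
    if not community.converged and not any_iso_steady:
        # neither the community nor any member alone persists: the roster
        # is a transient of a collective collapse, not coexistence
        return NONCOEXISTENCE
    best = max(mu_isos)
    tol = rel_tol * max(abs(best), abs(community.mu_star), 1e-12)
    if community.mu_star > best + tol:
        return MUTUALISM
    if community.mu_star < best - tol:
        return PARASITISM
    return BORDERLINE


@dataclass
class RemovalOutcome:
    """Result of deleting one species from a steady community."""

    removed: str
    cascade_extinctions: list[str]
    survival_ratio: float
    final: SteadyCommunity


def removal_experiment(community: SteadyCommunity, target: str,
                       env: EnvironmentParams,
                       config: CommunityConfig | None = None) -> RemovalOutcome:
    """Remove ``target``, re-relax, and report the extinction cascade.

    The survival ratio is the number of species surviving the
    re-equilibration divided by the roster size right after the removal
    (before any cascade); 1 means the removal triggered no further
    extinction.  A lone remaining species always survives (its fraction
    is identically 1 under replicator dynamics)."""
    st = community.state
    ids = [s.species_id for s in st.species]
    if target not in ids:
        raise KeyError(f"species {target!r} not in roster")
    if len(ids) < 2:
        raise ValueError("removal needs a roster of at least 2")
    keep = [i for i, sid in enumerate(ids) if sid != target]
    p = st.p[keep]
    reduced = CommunityState([st.species[i] for i in keep], st.X[keep],
                             st.x_env.copy(), p / p.sum())
    final = integrate_community(reduced, env, config)
    cascade = [sid for sid in final.extinctions]
    return RemovalOutcome(
        removed=target, cascade_extinctions=cascade,
        survival_ratio=final.roster_size / len(keep), final=final)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def multiple_correlation(y: np.ndarray, X: np.ndarray) -> float:
    """sqrt(R^2) of the least-squares fit of y on the columns of X
    (with intercept)."""
    y = np.asarray(y, dtype=float)
    A = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    return math.sqrt(max(r2, 0.0))


def resilience_statistics(samples: list[SteadyCommunity],
                          env: EnvironmentParams,
                          config: CommunityConfig | None = None,
                          log_base: float = math.e) -> dict:
    """Removal resilience versus leakage diversity, across communities.

    For each sample community: its ``S_Cell`` and ``S_Chem``, the
    survival ratio averaged over removal of every member in turn, and
    the leakage share of each removed species.  Returns the per-sample
    table plus Pearson correlations (survival vs S_Cell, survival vs
    S_Chem, S_Cell vs S_Chem) and the multiple correlation coefficient
    of survival on (S_Cell, S_Chem).  With fewer than 3 usable samples
    or degenerate variance the correlations are NaN and flagged.
    """
    rows = []
    removals = []
    for idx, community in enumerate(samples):
        if not community.converged or community.roster_size < 2:
            raise ValueError("resilience samples must be converged with >= 2 species")
        table = compute_flux_table(community, log_base=log_base)
        ratios = []
        for a, sp in enumerate(community.state.species):
            out = removal_experiment(community, sp.species_id, env, config)
            ratios.append(out.survival_ratio)
            removals.append({"sample": idx, "removed": sp.species_id,
                             "P_Leak": float(table.P_Leak[a]) if table.defined else np.nan,
                             "survival_ratio": out.survival_ratio,
                             "n_cascade": len(out.cascade_extinctions)})
        rows.append({"sample": idx, "roster": community.roster_size,
                     "S_Cell": table.S_Cell, "S_Chem": table.S_Chem,
                     "mean_survival_ratio": float(np.mean(ratios))})
    frame = pd.DataFrame(rows)
    stats: dict = {"samples": frame, "removals": pd.DataFrame(removals)}
    ok = len(frame) >= 3 and frame[["S_Cell", "S_Chem"]].notna().all().all()
    if ok:
        y = frame["mean_survival_ratio"].to_numpy()
        sc = frame["S_Cell"].to_numpy()
        sx = frame["S_Chem"].to_numpy()
        stats.update({
            "r_survival_S_Cell": _pearson(y, sc),
            "r_survival_S_Chem": _pearson(y, sx),
            "r_S_Cell_S_Chem": _pearson(sc, sx),
            "multiple_correlation": multiple_correlation(y, np.column_stack([sc, sx])),
            "flagged": False,
        })
        if any(np.isnan(v) for k, v in stats.items()
               if k.startswith(("r_", "multiple"))):
            stats["flagged"] = True
    else:
        stats.update({"r_survival_S_Cell": float("nan"),
                      "r_survival_S_Chem": float("nan"),
                      "r_S_Cell_S_Chem": float("nan"),
                      "multiple_correlation": float("nan"),
                      "flagged": True})
    return stats
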