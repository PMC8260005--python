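"""Configuration, serialization, and reproducibility plumbing.

A :class:`RunConfig` gathers every tunable of the simulator — environment
parameters, solver tolerances, community policy, adaptation and assembly
settings, pool parameters and seeds — with two scale presets:

- ``paper``: the headline study conditions (n = 20, rho = 2,
  S_env = 0.03, V_env = 3, D_S_env = 20, D_S = 1, R_deg = 5e-5,
  n_enzyme = n/5, p_min = 2.5e-4, pools of N = 50 species, 50 sweep
  replicates);
- ``desk``: the same model at workstation scale (small pools, few
  replicates, shorter adaptation phases and time caps) for tests and
  exploratory runs.

Configs load from YAML (JSON being a YAML subset works too); unknown
keys are rejected with their field path.  Results serialize to JSON with
a version stamp and embed a config echo so any output can be
regenerated from the file alone.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .adaptation import AdaptationConfig
from .assembly_experiments import (
    AssemblyConfig,
    AssemblyResult,
    SweepBase,
    SweepResult,
)
from .cell_dynamics import SolverConfig
from .community_dynamics import CommunityConfig, SteadyCommunity, CommunityState
from .ecosystem_analysis import FluxTable, RemovalOutcome
from .networks import (
    CellSpecies,
    EnvironmentParams,
    network_from_json,
    network_to_json,
)

__all__ = ["RunConfig", "load_config", "save_config", "serialize_result",
           "load_result", "RESULT_VERSION"]

RESULT_VERSION = 1


@dataclass(frozen=True)
class PoolParams:
    """Species-pool parameters (size, network shape, viability floor)."""

    n: int = 20
    rho: float = 2.0
    n_enzyme: int | None = None  # default n // 5
    N: int = 50
    D_S: float = 1.0
    specificity: int | None = None
    mu_floor: float = 1e-6
    growth_rule: str = "designated_growth_reactions"


@dataclass(frozen=True)
class RunConfig:
    """Complete, seedable description of a simulation run."""

    scale: str = "desk"
    seed: int = 0
    env: EnvironmentParams = field(default_factory=lambda: EnvironmentParams(
        S_env=0.03, V_env=3.0, R_deg=5e-5, D_S_env=20.0))
    pool: PoolParams = field(default_factory=PoolParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    community: CommunityConfig = field(default_factory=CommunityConfig)
    adaptation: AdaptationConfig = field(default_factory=AdaptationConfig)
    p_init: float = 0.01
    replicates: int = 10

    def assembly_config(self) -> AssemblyConfig:
        return AssemblyConfig(p_init=self.p_init, adaptation=self.adaptation,
                              community=self.community)

    def sweep_base(self, protocol: str = "adaptive") -> SweepBase:
        return SweepBase(n=self.pool.n, rho=self.pool.rho,
                         n_enzyme=self.pool.n_enzyme, N=self.pool.N,
                         env=self.env, D_S=self.pool.D_S,
                         specificity=self.pool.specificity,
                         assembly=self.assembly_config(), protocol=protocol,
                         mu_floor=self.pool.mu_floor)


def _preset(scale: str) -> RunConfig:
    if scale == "paper":
        solver = SolverConfig()
        return RunConfig(
            scale="paper",
            pool=PoolParams(N=50),
            solver=solver,
            community=CommunityConfig(solver=solver),
            adaptation=AdaptationConfig(n_rounds=50, solver=solver),
            replicates=50,
        )
    if scale == "desk":
        solver = SolverConfig(t_cap=1e4)
        return RunConfig(
            scale="desk",
            pool=PoolParams(N=6),
            solver=solver,
            community=CommunityConfig(solver=solver),
            adaptation=AdaptationConfig(n_rounds=4, eta=0.5, n_restarts=1,
                                        max_evals=200, step_min=0.1,
                                        solver=solver),
            replicates=10,
        )
    raise ValueError(f"unknown scale preset {scale!r}")


_SUBCONFIGS: dict[type, dict[str, type]] = {
    RunConfig: {"env": EnvironmentParams, "pool": PoolParams,
                "solver": SolverConfig, "community": CommunityConfig,
                "adaptation": AdaptationConfig},
    CommunityConfig: {"solver": SolverConfig},
    AdaptationConfig: {"solver": SolverConfig},
}


def _check_keys(cls, data: dict, path: str = "") -> None:
    names = {f.name for f in dataclasses.fields(cls)}
    subs = _SUBCONFIGS.get(cls, {})
    for key, value in data.items():
        if key not in names:
            raise ValueError(f"unknown config key {path}{key}")
        if key in subs and isinstance(value, dict):
            _check_keys(subs[key], value, f"{path}{key}.")


def _deep_merge(base: dict, upd: dict) -> dict:
    out = dict(base)
    for key, value in upd.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _build(cls, data: dict):
    subs = _SUBCONFIGS.get(cls, {})
    kwargs = {}
    for key, value in data.items():
        if key in subs and isinstance(value, dict):
            kwargs[key] = _build(subs[key], value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML/JSON, filling defaults from the preset.

    The optional ``scale`` key ("paper" or "desk", default "desk")
    selects the preset that supplies every unspecified field; any other
    key overrides it (deep-merged).  A top-level ``solver`` section also
    applies to the community and adaptation solvers unless those
    override it explicitly.  Unknown keys are rejected with their full
    path.  An empty (or missing) file yields the pure desk preset.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else {}
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config root must be a mapping")
        data = loaded
    if overrides:
        data = _deep_merge(data, overrides)
    scale = data.pop("scale", "desk")
    base = _preset(scale)
    if not data:
        return base
    _check_keys(RunConfig, data)
    if "solver" in data:  # one solver section governs all levels by default
        for section in ("community", "adaptation"):
            sec = data.setdefault(section, {})
            if isinstance(sec, dict):
                sec["solver"] = _deep_merge(data["solver"],
                                            sec.get("solver", {}))
    merged = _deep_merge(_to_plain(base), data)
    merged.pop("scale", None)
    cfg = _build(RunConfig, merged)
    return replace(cfg, scale=scale)


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def config_roundtrip_equal(a: RunConfig, b: RunConfig) -> bool:
    return _to_plain(a) == _to_plain(b)


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def _species_doc(sp: CellSpecies) -> dict:
    return {"species_id": sp.species_id,
            "network": json.loads(network_to_json(sp.network)),
            "D": sp.D.tolist(), "D_S": sp.D_S,
            "adaptation_groups": [list(g) for g in sp.adaptation_groups]}


def _species_from_doc(doc: dict) -> CellSpecies:
    return CellSpecies(
        species_id=doc["species_id"],
        network=network_from_json(json.dumps(doc["network"])),
        D=np.asarray(doc["D"], dtype=float), D_S=doc["D_S"],
        adaptation_groups=tuple(tuple(g) for g in doc["adaptation_groups"]))


def _community_doc(com: SteadyCommunity) -> dict:
    return {"species": [_species_doc(s) for s in com.state.species],
            "X": com.state.X.tolist(), "x_env": com.state.x_env.tolist(),
            "p": com.state.p.tolist(), "mu": com.mu.tolist(),
            "mu_star": com.mu_star, "converged": com.converged,
            "time_to_converge": com.time_to_converge,
            "extinctions": com.extinctions, "message": com.message}


def _community_from_doc(doc: dict) -> SteadyCommunity:
    state = CommunityState([_species_from_doc(d) for d in doc["species"]],
                           np.asarray(doc["X"], dtype=float),
                           np.asarray(doc["x_env"], dtype=float),
                           np.asarray(doc["p"], dtype=float))
    return SteadyCommunity(state=state, mu=np.asarray(doc["mu"], dtype=float),
                           mu_star=doc["mu_star"], converged=doc["converged"],
                           time_to_converge=doc["time_to_converge"],
                           extinctions=list(doc["extinctions"]),
                           message=doc["message"])


def serialize_result(result, path: str | Path,
                     config: RunConfig | None = None) -> None:
    """Write a result object to versioned JSON (lossless round-trip).

    Supported: AssemblyResult, SweepResult, FluxTable, RemovalOutcome,
    SteadyCommunity.  A config echo is embedded when provided.
    """
    doc: dict[str, Any] = {"result_version": RESULT_VERSION}
    if config is not None:
        doc["config"] = _to_plain(config)
    if isinstance(result, AssemblyResult):
        doc["kind"] = "assembly"
        doc["data"] = {"invasion_log": _to_plain(result.invasion_log),
                       "final_community": _community_doc(result.final_community),
                       "params": _to_plain(result.params), "seed": result.seed}
    elif isinstance(result, SweepResult):
        doc["kind"] = "sweep"
        doc["data"] = {"axis": result.axis,
                       "records": result.records.to_dict(orient="list"),
                       "failures": result.failures}
    elif isinstance(result, FluxTable):
        doc["kind"] = "flux_table"
        doc["data"] = {"species_ids": result.species_ids,
                       "f": result.f.tolist(), "leak": result.leak.tolist(),
                       "L_tot": result.L_tot,
                       "P_Leak": result.P_Leak.tolist(),
                       "P_Leaked": result.P_Leaked.tolist(),
                       "S_Cell": result.S_Cell, "S_Chem": result.S_Chem,
                       "defined": result.defined, "log_base": result.log_base}
    elif isinstance(result, RemovalOutcome):
        doc["kind"] = "removal"
        doc["data"] = {"removed": result.removed,
                       "cascade_extinctions": result.cascade_extinctions,
                       "survival_ratio": result.survival_ratio,
                       "final": _community_doc(result.final)}
    elif isinstance(result, SteadyCommunity):
        doc["kind"] = "community"
        doc["data"] = _community_doc(result)
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    Path(path).write_text(json.dumps(_sanitize(doc), indent=1))


def _sanitize(obj):
    """JSON-safe: numpy scalars to python, NaN kept (json allows it)."""
    return _to_plain(obj)


def load_result(path: str | Path):
    """Read a result file back into its object.

    Files written by an older schema version load with a warning;
    files from a newer version are an error.
    """
    import pandas as pd

    doc = json.loads(Path(path).read_text())
    version = doc.get("result_version", 0)
    if version > RESULT_VERSION:
        raise ValueError(f"result written by newer schema version {version}")
    if version < RESULT_VERSION:
        warnings.warn(f"result written by older schema version {version}; "
                      "loading with defaults", stacklevel=2)
    kind = doc["kind"]
    data = doc["data"]
    if kind == "assembly":
        return AssemblyResult(invasion_log=data["invasion_log"],
                              final_community=_community_from_doc(data["final_community"]),
                              params=data["params"], seed=data["seed"])
    if kind == "sweep":
        return SweepResult(axis=data["axis"],
                           records=pd.DataFrame(data["records"]),
                           failures=data["failures"])
    if kind == "flux_table":
        return FluxTable(species_ids=data["species_ids"],
                         f=np.asarray(data["f"]), leak=np.asarray(data["leak"]),
                         L_tot=data["L_tot"],
                         P_Leak=np.asarray(data["P_Leak"]),
                         P_Leaked=np.asarray(data["P_Leaked"]),
                         S_Cell=data["S_Cell"], S_Chem=data["S_Chem"],
                         defined=data["defined"], log_base=data["log_base"])
    if kind == "removal":
        return RemovalOutcome(removed=data["removed"],
                              cascade_extinctions=data["cascade_extinctions"],
                              survival_ratio=data["survival_ratio"],
                              final=_community_from_doc(data["final"]))
    if kind == "community":
        return _community_from_doc(data)
    raise ValueError(f"unknown result kind {kind!r}")
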