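"""Reaction networks, cell species, and network generation.

A cell is a well-stirred bag of ``n`` chemicals (a single externally
supplied nutrient, a set of non-diffusible enzymes, and diffusible
metabolites) coupled by mass-action conversion reactions, almost all of
the two-body catalytic form ``i + k -> j + k``.  Growth converts
precursors into biomass and dilutes every intracellular concentration.

This module defines the static description of such a cell — the network
topology and rate constants (:class:`ReactionNetwork`), and the species'
exchange parameters (:class:`CellSpecies`) — plus a seeded random-network
generator, a species-pool generator for assembly experiments, and the
built-in worked example networks (:func:`fixture`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "CellSpecies",
    "EnvironmentParams",
    "generate_random_network",
    "generate_species_pool",
    "fixture",
    "FIXTURE_NAMES",
    "s1_clamped_environment",
    "default_groups",
    "network_to_json",
    "network_from_json",
    "network_to_graphml",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Reaction:
    """One mass-action conversion reaction.

    The canonical form is ``substrate (+ catalyst) -> product (+ catalyst)``
    with forward rate ``k * x_substrate * x_catalyst`` (or ``k * x_substrate``
    when uncatalyzed).  ``product=None`` designates a biomass sink: the
    reaction rate contributes to the growth rate and consumes its
    substrate(s), but produces no chemical.

    ``co_substrates`` and ``byproducts`` extend the canonical form for
    coarse-grained bioreaction models: co-substrates enter the rate law
    (one concentration factor each) and are consumed ``coef`` per event;
    byproducts are produced ``coef`` per event without entering the rate
    law.  Reversibility (``r > 0``, reverse rate ``r*k*x_product*x_catalyst``)
    is supported only for plain one-substrate/one-product reactions.
    """

    substrate: int
    product: int | None
    catalyst: int | None = None
    k: float = 1.0
    r: float = 0.0
    substrate_coef: float = 1.0
    product_coef: float = 1.0
    co_substrates: tuple[tuple[int, float], ...] = ()
    byproducts: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"rate constant must be positive, got {self.k}")
        if self.r < 0:
            raise ValueError(f"reversibility must be nonnegative, got {self.r}")
        if self.r > 0 and (self.co_substrates or self.byproducts or self.product is None):
            raise ValueError("reversible reactions must be plain substrate->product")
        if self.product == self.substrate:
            raise ValueError("substrate and product must differ")

    @property
    def is_growth(self) -> bool:
        return self.product is None

    def key(self) -> tuple:
        """Identity triple used to forbid duplicate reactions."""
        return (self.substrate, self.product, self.catalyst)


@dataclass(frozen=True)
class ReactionNetwork:
    """A catalytic reaction network over ``n`` chemicals.

    Index layout for randomly generated networks: the nutrient is
    chemical 0, enzymes are chemicals ``1..n_enzyme``, and the remaining
    chemicals ``n_enzyme+1..n-1`` are non-nutrient metabolites.  Built-in
    example networks may use a different layout (recorded in
    ``enzyme_indices`` / ``nutrient_indices`` / ``names``).

    ``growth_rule`` selects how the growth rate mu is defined:

    - ``"designated_growth_reactions"``: mu is the summed rate of the
      biomass-sink reactions (``product=None``), which also consume their
      substrates at that rate.
    - ``"enzyme_synthesis_total"``: mu is the summed net rate of every
      reaction whose product is an enzyme; enzymes double as the biomass
      machinery and no extra consumption is added.
    """

    n: int
    n_enzyme: int
    reactions: tuple[Reaction, ...]
    enzyme_indices: tuple[int, ...]
    nutrient_indices: tuple[int, ...] = (0,)
    growth_rule: str = "enzyme_synthesis_total"
    names: tuple[str, ...] | None = None

    GROWTH_RULES = ("designated_growth_reactions", "enzyme_synthesis_total")

    def __post_init__(self) -> None:
        if self.growth_rule not in self.GROWTH_RULES:
            raise ValueError(f"unknown growth_rule {self.growth_rule!r}")
        if len(self.enzyme_indices) != self.n_enzyme:
            raise ValueError("enzyme_indices length must equal n_enzyme")
        enz = set(self.enzyme_indices)
        nut = set(self.nutrient_indices)
        if enz & nut:
            raise ValueError("a chemical cannot be both enzyme and nutrient")
        if not all(0 <= i < self.n for i in enz | nut):
            raise ValueError("chemical index out of range")
        if self.names is not None and len(self.names) != self.n:
            raise ValueError("names must have length n")
        seen = set()
        for rx in self.reactions:
            for idx, _ in ((rx.substrate, 1),) + rx.co_substrates:
                if not 0 <= idx < self.n:
                    raise ValueError("substrate index out of range")
            if rx.substrate in enz:
                raise ValueError("an enzyme cannot be a reaction substrate")
            if rx.product is not None:
                if not 0 <= rx.product < self.n:
                    raise ValueError("product index out of range")
                if rx.product in nut:
                    raise ValueError("the nutrient is never a reaction product")
            if rx.catalyst is not None and rx.catalyst not in enz:
                raise ValueError("catalyst must be an enzyme")
            if rx.key() in seen:
                raise ValueError(f"duplicate reaction {rx.key()}")
            seen.add(rx.key())
        if self.growth_rule == "designated_growth_reactions" and not any(
            rx.is_growth for rx in self.reactions
        ):
            raise ValueError("designated growth rule requires a biomass reaction")

    @property
    def nutrient_index(self) -> int:
        """Primary nutrient (chemical 0 for random networks)."""
        return self.nutrient_indices[0]

    @property
    def metabolite_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n) if i not in set(self.enzyme_indices))

    @property
    def non_nutrient_metabolites(self) -> tuple[int, ...]:
        excl = set(self.enzyme_indices) | set(self.nutrient_indices)
        return tuple(i for i in range(self.n) if i not in excl)

    def name_of(self, i: int) -> str:
        return self.names[i] if self.names is not None else str(i)


@dataclass(frozen=True)
class CellSpecies:
    """A reaction network plus its per-chemical exchange coefficients.

    ``D[i]`` (units 1/time) is the passive-diffusion coefficient of
    chemical ``i`` across this species' membrane: exchange flux into the
    cell is ``D[i] * (x_env_i - x_i)``.  Enzymes never diffuse (D = 0);
    nutrient uptake is fixed at ``D_S`` and is never adapted; the
    coefficients of non-nutrient metabolites are the species' adaptable
    trait, partitioned into ``adaptation_groups`` that each share one
    value (group count = the leakage "specificity").
    """

    species_id: str
    network: ReactionNetwork
    D: np.ndarray
    D_S: float = 1.0
    adaptation_groups: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (self.network.n,):
            raise ValueError("D must have length n")
        if np.any(D < 0):
            raise ValueError("diffusion coefficients must be nonnegative")
        if any(D[i] != 0.0 for i in self.network.enzyme_indices):
            raise ValueError("enzymes are not diffusible (D must be 0)")
        for i in self.network.nutrient_indices:
            if D[i] != self.D_S:
                raise ValueError("nutrient D must equal D_S")
        free = set(self.network.non_nutrient_metabolites)
        flat = [i for g in self.adaptation_groups for i in g]
        if len(flat) != len(set(flat)) or not set(flat) <= free:
            raise ValueError("adaptation groups must partition non-nutrient metabolites")
        for g in self.adaptation_groups:
            if len({float(D[i]) for i in g}) > 1:
                raise ValueError("group members must share one D value")
        object.__setattr__(self, "D", D)

    def with_D(self, D: np.ndarray, species_id: str | None = None) -> "CellSpecies":
        return replace(self, D=np.asarray(D, dtype=float),
                       species_id=species_id or self.species_id)

    def free_groups(self) -> tuple[tuple[int, ...], ...]:
        """Adaptable index groups (defaults to one group per metabolite)."""
        if self.adaptation_groups:
            return self.adaptation_groups
        return tuple((i,) for i in self.network.non_nutrient_metabolites)


@dataclass(frozen=True)
class EnvironmentParams:
    """Shared-environment parameters.

    ``S_env``: nutrient concentration of the external reservoir;
    ``V_env``: environment-to-total-cell-volume ratio (dimensionless);
    ``R_deg``: degradation/outflow rate of environmental chemicals (1/time);
    ``D_S_env``: diffusion coefficient of nutrient supply from the
    reservoir into the environment (1/time).
    """

    S_env: float = 1.0
    V_env: float = 1.0
    R_deg: float = 1.0
    D_S_env: float = 10.0

    def __post_init__(self) -> None:
        if min(self.S_env, self.R_deg, self.D_S_env) < 0 or self.V_env <= 0:
            raise ValueError("invalid environment parameters")


def default_groups(network: ReactionNetwork, specificity: int | None = None
                   ) -> tuple[tuple[int, ...], ...]:
    """Partition the non-nutrient metabolites into ``specificity`` groups.

    ``specificity=None`` (or the metabolite count) gives fully independent
    coefficients; ``specificity=1`` a single shared leakiness.  Groups are
    contiguous runs of equal size, so ``specificity`` must divide the
    metabolite count.
    """
    free = network.non_nutrient_metabolites
    if specificity is None or specificity >= len(free):
        return tuple((i,) for i in free)
    if specificity < 1 or len(free) % specificity:
        raise ValueError(
            f"specificity {specificity} must divide the {len(free)} "
            "non-nutrient metabolites into equal groups")
    size = len(free) // specificity
    return tuple(tuple(free[j * size:(j + 1) * size]) for j in range(specificity))


def _legal_reaction_count(n: int, n_enzyme: int) -> int:
    n_metab = n - n_enzyme  # nutrient + non-nutrient metabolites
    # products: any non-nutrient chemical except the substrate itself
    per_sub_nutrient = (n - 1) * n_enzyme
    per_sub_other = (n - 2) * n_enzyme
    return per_sub_nutrient + (n_metab - 1) * per_sub_other


def generate_random_network(n: int, rho: float, n_enzyme: int,
                            rng_seed: int | np.random.Generator,
                            growth_rule: str = "designated_growth_reactions",
                            ) -> ReactionNetwork:
    """Draw a random catalytic network with ``round(rho*n)`` conversion
    reactions.

    Substrates are drawn uniformly from the metabolites (the nutrient,
    chemical 0, included), products uniformly from the non-nutrient
    chemicals (metabolites or enzymes) excluding the substrate, and
    catalysts uniformly from the enzymes; duplicate
    (substrate, product, catalyst) triples are rejected.  All rate
    constants are 1 and reactions are irreversible.  Bit-for-bit
    reproducible for a fixed integer seed.

    Under the default ``designated_growth_reactions`` rule, one biomass
    reaction (a uniformly drawn non-nutrient metabolite converted to
    biomass by a uniformly drawn enzyme, k = 1) is appended beyond the
    ``rho*n`` conversion reactions.  This separation of the growth drain
    from the autocatalytic enzyme loop is what lets a sizeable fraction
    of random networks exhibit leak advantage; with
    ``growth_rule="enzyme_synthesis_total"`` (growth = total enzyme
    synthesis rate, no biomass reaction) leakage of intermediates is
    essentially never advantageous.
    """
    if n < 5:
        raise ValueError("n must be at least 5")
    if not 1 <= n_enzyme < n:
        raise ValueError("need 1 <= n_enzyme < n")
    m = int(round(rho * n))
    if m > _legal_reaction_count(n, n_enzyme):
        raise ValueError(
            f"{m} reactions requested but only {_legal_reaction_count(n, n_enzyme)} "
            "distinct legal reactions exist")
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, (int, np.integer)) else rng_seed
    metabolites = [0] + list(range(n_enzyme + 1, n))
    enzymes = list(range(1, n_enzyme + 1))
    chosen: dict[tuple, Reaction] = {}
    while len(chosen) < m:
        sub = metabolites[rng.integers(len(metabolites))]
        prod = int(rng.integers(1, n))
        if prod == sub:
            continue
        cat = enzymes[rng.integers(len(enzymes))]
        key = (sub, prod, cat)
        if key in chosen:
            continue
        chosen[key] = Reaction(substrate=sub, product=prod, catalyst=cat, k=1.0)
    reactions = tuple(chosen.values())
    if growth_rule == "designated_growth_reactions":
        non_nut = [i for i in metabolites if i != 0]
        bm_sub = non_nut[rng.integers(len(non_nut))]
        bm_cat = enzymes[rng.integers(len(enzymes))]
        reactions += (Reaction(substrate=bm_sub, product=None,
                               catalyst=bm_cat, k=1.0),)
    return ReactionNetwork(
        n=n, n_enzyme=n_enzyme, reactions=reactions,
        enzyme_indices=tuple(enzymes), nutrient_indices=(0,),
        growth_rule=growth_rule)


def generate_species_pool(n: int, rho: float, n_enzyme: int, N: int,
                          env: EnvironmentParams,
                          rng_seed: int,
                          D_S: float = 1.0,
                          mu_floor: float = 1e-6,
                          specificity: int | None = None,
                          growth_rule: str = "designated_growth_reactions",
                          max_resample_rounds: int = 50,
                          max_network_draws: int = 2000,
                          solver_config=None,
                          log: list | None = None) -> list[CellSpecies]:
    """Generate a pool of ``N`` viable candidate species for assembly.

    Each species is a random network with all non-nutrient diffusion
    coefficients at 0, kept only if its isolated steady growth rate
    exceeds ``mu_floor``.  The pool must satisfy the study constraint
    that the species with the fastest isolated growth has at least one
    leak-advantage chemical; otherwise the entire pool is discarded and
    resampled from the next seed.  Rejection counts and resample rounds
    are appended to ``log`` (a list of dicts) when given.
    """
    from . import cell_dynamics as cd  # deferred: avoids a module cycle

    if N < 1:
        raise ValueError("pool size must be >= 1")
    for round_idx in range(max_resample_rounds):
        seed = rng_seed + round_idx
        rng = np.random.default_rng(seed)
        pool: list[CellSpecies] = []
        mu_isos: list[float] = []
        rejected = 0
        draws = 0
        while len(pool) < N:
            if draws >= max_network_draws:
                raise RuntimeError(
                    f"exhausted {max_network_draws} network draws with only "
                    f"{len(pool)}/{N} viable species (mu_floor={mu_floor})")
            draws += 1
            net = generate_random_network(n, rho, n_enzyme, rng,
                                          growth_rule=growth_rule)
            D = np.zeros(n)
            D[0] = D_S
            sp = CellSpecies(
                species_id=f"sp{seed}-{draws:04d}", network=net, D=D, D_S=D_S,
                adaptation_groups=default_groups(net, specificity))
            res = cd.solve_isolated_steady_state(sp, env, clamp_env=False,
                                                 config=solver_config)
            if res.converged and res.mu > mu_floor:
                pool.append(sp)
                mu_isos.append(res.mu)
            else:
                rejected += 1
        best = int(np.argmax(mu_isos))
        la = cd.leak_advantage_chemicals(pool[best], env, config=solver_config)
        entry = {"seed": seed, "round": round_idx, "rejected": rejected,
                 "draws": draws, "best_mu_iso": mu_isos[best],
                 "best_leak_advantage": sorted(la)}
        if log is not None:
            log.append(entry)
        if la:
            return pool
    raise RuntimeError(
        f"no pool satisfied the leak-advantage constraint in "
        f"{max_resample_rounds} resampling rounds")


# ---------------------------------------------------------------------------
# Built-in example networks
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("fig2_leaker", "fig2_consumer", "s1_minimal",
                 "s2_reversible_leaker", "s2_reversible_consumer")

_FIG2_NAMES = ("S", "M1", "rb", "E", "M2")
FIG2_S, FIG2_M1, FIG2_RB, FIG2_E, FIG2_M2 = range(5)


def _leaker_consumer(k_s_m1: float, k_m1: float, k_s_m2: float,
                     r: float, species_id: str) -> CellSpecies:
    """Five-chemical leaker/consumer network: S, M1, rb, E, M2.

    The enzyme E converts nutrient S into M1; the ribosome-like catalyst
    rb converts M1 into more rb and into E (the autocatalytic core that
    produces the leak advantage of M1); an uncatalyzed branch converts S
    into the biomass precursor M2, which E turns into biomass at k=0.01.
    """
    reactions = (
        Reaction(FIG2_S, FIG2_M1, catalyst=FIG2_E, k=k_s_m1, r=r),
        Reaction(FIG2_M1, FIG2_RB, catalyst=FIG2_RB, k=k_m1),
        Reaction(FIG2_M1, FIG2_E, catalyst=FIG2_RB, k=k_m1),
        Reaction(FIG2_S, FIG2_M2, catalyst=None, k=k_s_m2, r=r),
        Reaction(FIG2_M2, None, catalyst=FIG2_E, k=0.01),
    )
    net = ReactionNetwork(
        n=5, n_enzyme=2, reactions=reactions,
        enzyme_indices=(FIG2_RB, FIG2_E), nutrient_indices=(FIG2_S,),
        growth_rule="designated_growth_reactions", names=_FIG2_NAMES)
    D = np.zeros(5)
    D[FIG2_S] = 1.0
    return CellSpecies(species_id=species_id, network=net, D=D, D_S=1.0,
                       adaptation_groups=((FIG2_M1,), (FIG2_M2,)))


# --- s1_minimal -----------------------------------------------------------
# SYNTHETIC RECONSTRUCTION of a coarse "minimal bioreaction" model of
# central carbon metabolism (glycolysis, pentose-phosphate shunt, overflow
# and amination branches, and an explicit adenylate cycle).  The original
# diagram this emulates was not available when the fixture was written, so
# the topology below is a from-scratch coarse-graining constrained to:
# unit rate constants; glucose and glutamine as the supplied nutrients;
# growth mu = x_Nucleotides * x_Alanine consuming both precursors; and
# CO2, NH4 and lactate as terminal (leak-neutral) end products.

_S1_NAMES = ("Glucose", "Glutamine", "G6P", "F6P", "T3P", "Pyruvate", "R5P",
             "E4P", "Glutamate", "AKG", "Nucleotides", "Alanine", "ATP",
             "ADP", "CO2", "NH4", "Lactate")
_S1 = {name: i for i, name in enumerate(_S1_NAMES)}


def _s1_minimal() -> CellSpecies:
    c = _S1
    reactions = (
        # glucose phosphorylation (ATP investment)
        Reaction(c["Glucose"], c["G6P"],
                 co_substrates=((c["ATP"], 1.0),), byproducts=((c["ADP"], 1.0),)),
        Reaction(c["G6P"], c["F6P"]),
        # upper glycolysis: second ATP investment, split into two trioses
        Reaction(c["F6P"], c["T3P"], product_coef=2.0,
                 co_substrates=((c["ATP"], 1.0),), byproducts=((c["ADP"], 1.0),)),
        # lower glycolysis lumped: 2 ATP regained per triose
        Reaction(c["T3P"], c["Pyruvate"],
                 co_substrates=((c["ADP"], 2.0),), byproducts=((c["ATP"], 2.0),)),
        # oxidative pentose-phosphate branch
        Reaction(c["G6P"], c["R5P"], byproducts=((c["CO2"], 1.0),)),
        # transketolase-like sugar shuffle (both directions as distinct
        # irreversible reactions)
        Reaction(c["F6P"], c["E4P"], co_substrates=((c["T3P"], 1.0),),
                 byproducts=((c["R5P"], 1.0),)),
        Reaction(c["E4P"], c["F6P"], co_substrates=((c["R5P"], 1.0),),
                 byproducts=((c["T3P"], 1.0),)),
        # overflow to lactate
        Reaction(c["Pyruvate"], c["Lactate"]),
        # glutaminase: amide nitrogen released as ammonium
        Reaction(c["Glutamine"], c["Glutamate"], byproducts=((c["NH4"], 1.0),)),
        # alanine transaminase
        Reaction(c["Pyruvate"], c["Alanine"],
                 co_substrates=((c["Glutamate"], 1.0),),
                 byproducts=((c["AKG"], 1.0),)),
        # nucleotide synthesis from ribose-5-P, glutamine nitrogen and ATP
        Reaction(c["R5P"], c["Nucleotides"],
                 co_substrates=((c["Glutamine"], 1.0), (c["ATP"], 1.0)),
                 byproducts=((c["Glutamate"], 1.0), (c["ADP"], 1.0))),
        # coarse oxidation of 2-oxoglutarate with ATP regeneration
        Reaction(c["AKG"], c["CO2"], co_substrates=((c["ADP"], 1.0),),
                 byproducts=((c["ATP"], 1.0),)),
        # de novo adenylate synthesis from the nucleotide pool
        Reaction(c["Nucleotides"], c["ADP"]),
        # biomass: mu = x_Nucleotides * x_Alanine
        Reaction(c["Nucleotides"], None, co_substrates=((c["Alanine"], 1.0),), k=1.0),
    )
    net = ReactionNetwork(
        n=len(_S1_NAMES), n_enzyme=0, reactions=reactions, enzyme_indices=(),
        nutrient_indices=(c["Glucose"], c["Glutamine"]),
        growth_rule="designated_growth_reactions", names=_S1_NAMES)
    D = np.zeros(net.n)
    D[c["Glucose"]] = D[c["Glutamine"]] = 1.0
    return CellSpecies(species_id="s1_minimal", network=net, D=D, D_S=1.0,
                       adaptation_groups=tuple((i,) for i in net.non_nutrient_metabolites))


def s1_clamped_environment() -> np.ndarray:
    """The S1 protocol's fixed environment: nutrients at 1.0, the rest 0."""
    x_env = np.zeros(len(_S1_NAMES))
    x_env[_S1["Glucose"]] = x_env[_S1["Glutamine"]] = 1.0
    return x_env


def fixture(name: str, r: float = 0.01) -> CellSpecies:
    """Return a built-in example species by name.

    ``fig2_leaker`` / ``fig2_consumer``: the five-chemical pair whose
    exchanged metabolite M1 supports leaker-consumer mutualism
    (rate constants k_S->M1 = 1 vs 0.4, the remaining constants 1 vs 2,
    biomass k = 0.01 for both).

    ``s2_reversible_leaker`` / ``s2_reversible_consumer``: the same
    networks with the S->M1 and S->M2 reactions made reversible with
    strength ``r`` (consumer k_S->M1 = 0.3).

    ``s1_minimal``: a synthetic reconstruction of a coarse
    central-carbon-metabolism model (see module source) whose growth rate
    is mu = x_Nucleotides * x_Alanine, with glucose and glutamine as the
    supplied nutrients.
    """
    if name == "fig2_leaker":
        return _leaker_consumer(1.0, 1.0, 1.0, 0.0, "fig2_leaker")
    if name == "fig2_consumer":
        return _leaker_consumer(0.4, 2.0, 2.0, 0.0, "fig2_consumer")
    if name == "s2_reversible_leaker":
        return _leaker_consumer(1.0, 1.0, 1.0, r, "s2_reversible_leaker")
    if name == "s2_reversible_consumer":
        return _leaker_consumer(0.3, 2.0, 2.0, r, "s2_reversible_consumer")
    if name == "s1_minimal":
        return _s1_minimal()
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def network_to_json(network: ReactionNetwork) -> str:
    """Serialize a network to the versioned JSON schema (see docs/schema)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "n": network.n,
        "n_enzyme": network.n_enzyme,
        "enzyme_indices": list(network.enzyme_indices),
        "nutrient_indices": list(network.nutrient_indices),
        "growth_rule": network.growth_rule,
        "names": list(network.names) if network.names else None,
        "reactions": [
            {
                "substrate": rx.substrate,
                "product": rx.product,
                "catalyst": rx.catalyst,
                "k": rx.k,
                "r": rx.r,
                "substrate_coef": rx.substrate_coef,
                "product_coef": rx.product_coef,
                "co_substrates": [list(t) for t in rx.co_substrates],
                "byproducts": [list(t) for t in rx.byproducts],
            }
            for rx in network.reactions
        ],
    }
    return json.dumps(doc, indent=1)


def network_from_json(text: str) -> ReactionNetwork:
    doc = json.loads(text)
    version = doc.get("schema_version", 0)
    if version > SCHEMA_VERSION:
        raise ValueError(f"unsupported network schema version {version}")
    reactions = tuple(
        Reaction(
            substrate=rx["substrate"], product=rx["product"],
            catalyst=rx["catalyst"], k=rx["k"], r=rx.get("r", 0.0),
            substrate_coef=rx.get("substrate_coef", 1.0),
            product_coef=rx.get("product_coef", 1.0),
            co_substrates=tuple((int(i), float(c)) for i, c in rx.get("co_substrates", [])),
            byproducts=tuple((int(i), float(c)) for i, c in rx.get("byproducts", [])),
        )
        for rx in doc["reactions"]
    )
    return ReactionNetwork(
        n=doc["n"], n_enzyme=doc["n_enzyme"], reactions=reactions,
        enzyme_indices=tuple(doc["enzyme_indices"]),
        nutrient_indices=tuple(doc.get("nutrient_indices", [0])),
        growth_rule=doc["growth_rule"],
        names=tuple(doc["names"]) if doc.get("names") else None)


def network_to_graphml(network: ReactionNetwork, path: str) -> None:
    """Export the conversion graph for visualization (write-only)."""
    import networkx as nx

    g = nx.MultiDiGraph()
    for i in range(network.n):
        role = ("enzyme" if i in network.enzyme_indices
                else "nutrient" if i in network.nutrient_indices else "metabolite")
        g.add_node(i, label=network.name_of(i), role=role)
    for rx in network.reactions:
        if rx.product is None:
            continue
        g.add_edge(rx.substrate, rx.product,
                   catalyst=-1 if rx.catalyst is None else rx.catalyst,
                   k=rx.k, r=rx.r)
    nx.write_graphml(g, path)
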