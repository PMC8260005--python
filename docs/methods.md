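# Methods

## Model

`crossfeed` simulates a well-mixed community of cell species, each
described by the concentrations `x_i` of `n` chemicals — one externally
supplied nutrient, `n_enzyme` non-diffusible enzymes, and diffusible
metabolites — coupled through a shared environment.

**Intracellular dynamics.** For species α,

    dx_i/dt = F_i(x) + D_i (x_env_i − x_i) − μ(x) x_i

`F` collects mass-action reaction rates: a catalyzed conversion
`i + k → j + k` proceeds at `k_rate · x_i · x_k`, an uncatalyzed one at
`k_rate · x_i`; a reversible reaction adds the reverse rate
`r · k_rate · x_j (· x_k)`.  The exchange flux is passive diffusion with
per-chemical coefficient `D_i` (units 1/time; interpretable as membrane
permeability or coarse-grained transporter abundance), positive into
the cell.  The dilution term `−μ x_i` models the growth of cell volume.

**Growth rules.** Two definitions of μ are supported.
`designated_growth_reactions`: μ is the summed rate of explicit biomass
reactions, which consume their substrates at that rate (the
five-chemical leaker/consumer example uses `M2 → biomass` catalyzed by
E with k = 0.01; the minimal bioreaction model uses
μ = x_Nucleotides · x_Alanine).  `enzyme_synthesis_total`: μ is the
summed net rate of all enzyme-producing reactions, with no separate
biomass drain.  Random networks default to the designated rule with a
single biomass reaction (a uniformly drawn non-nutrient metabolite
converted by a uniformly drawn enzyme, k = 1, drawn beyond the ρ·n
conversion reactions).  The reason is structural: leak advantage
requires tension between an autocatalytic enzyme module and a separate
growth drain.  When enzyme synthesis *is* growth, draining any
intermediate can only slow growth — in our ensembles, no random network
under the enzyme-total rule had a single leak-advantage chemical,
whereas under the designated rule roughly a third of viable n = 10
networks and four fifths of viable n = 20 networks have at least one,
increasing with n as expected for this model class.

**Environment.** Chemical i in the environment obeys

    dx_env_i/dt = Σ_α p_α D_i^(α) (x_i^(α) − x_env_i) / V_env − R_deg x_env_i

with a supply term `D_S_env (S_env − x_env_i)` added for the
nutrient(s).  `V_env` is the environment-to-total-cell-volume ratio
(1/V_env measures crowding and hence cell–cell coupling strength);
`R_deg` degrades or washes out environmental chemicals.

**Population dynamics.** Fractions follow the replicator equation
`dp_α/dt = (μ_α − μ̄) p_α` with `μ̄ = Σ p_α μ_α`, so the total is
conserved and coexistence forces equal growth rates.  Species with
`p < p_min = 2.5 × 10⁻⁴` are eliminated and the remainder renormalized.

**Leak advantage.** Chemical i is leak-advantage for a species if an
infinitesimal increase of `D_i` — with the environment a perfect sink
for i (clamped at 0) — raises the steady growth rate.  Detection uses a
finite difference at ε = 10⁻³ with acceptance tolerance 10⁻⁹ on μ;
the nutrient clamp level is the cell-free reservoir equilibrium
`D_S_env·S_env/(D_S_env+R_deg)` (or the species' own isolated
environment when it already leaks).  The growth-vs-leakiness scan uses
the same perfect-sink protocol by default, because that is the setting
in which the leak-advantage optimum is an interior maximum; against the
species' own dynamic environment the curve typically saturates instead
(leakage throttles itself through accumulation), and that variant
remains available via `clamp_env=False`.

## Numerics

Steady states are found by chunked stiff integration (LSODA, analytic
Jacobians assembled from the reaction tables, rtol 10⁻⁸ / atol 10⁻¹⁰)
from the standard initial condition (all intracellular concentrations
0.1 — enzymes must start positive to seed the autocatalytic core),
with a Newton polish (scipy `root`, hybr) attempted once the relative
residual falls below 10⁻³.  A polished point is accepted only if it is
nonnegative, has residual below 10⁻⁹, and is linearly stable (largest
Jacobian eigenvalue real part < 10⁻⁶; the community system keeps its
neutral replicator direction).  The steady-state criterion is
`max_i |ẋ_i| / max(x_i, 10⁻⁶) < 10⁻⁷` sustained across a 10-time-unit
window, plus `|ṗ| < 10⁻⁸` for communities.  Hitting the time cap
(default 10⁵, desk preset 10⁴) flags the result as non-converged and
attaches the time-averaged growth rate — never an exception.
Warm-started Newton solves make the finite-difference probes of the
adaptation loops cheap.  Concentrations are clamped at zero inside rate
evaluations, so small negative integrator excursions (within −10⁻⁹)
cannot feed back.

Community Newton polish solves for the concentrations plus the first
m − 1 fractions with equal-growth conditions replacing the replicator
equations, which pins survivor growth-rate spread to the 10⁻⁵ relative
tolerance or far better.

A quasi-steady-state mode (`CommunityConfig(mode="nested")`) relaxes
cells and environment at frozen fractions and applies the replicator
map between relaxations.  It is a cross-check, not the default: the
map can settle on a quasi-equilibrium near, but not identical to, the
fully coupled steady state (a few percent in μ for the two-species
example), which is the expected cost of the timescale-separation
approximation.

**Interaction classification.** A lone survivor is noncoexistence.
Otherwise the community growth μ* is compared with the best survivor's
isolated growth (alone, dynamic environment, in-community D values,
standard initial condition): above is mutualism, below parasitism,
within 10⁻³ relative borderline.  Two refinements cover states with no
steady state within the cap, which occur at excessive leakage: if no
survivor can persist alone either, the roster is a transient of a
collective collapse and the point is noncoexistence; if some survivor
is viable alone, the time-capped community is labelled from its
time-averaged growth — the finite-horizon reading under which an
over-leaky pair that persists while growth decays presents as
parasitic coexistence.  Strict mode (the default for user calls)
labels any non-converged input UNRESOLVED instead.

## Adaptation protocol

Invasion-time optimization maximizes the invader's steady growth
against the frozen pre-invasion environment with a derivative-free
coordinate hill climb over its grouped coefficients (start D = 0 plus
seeded random restarts in [0, D_max], initial step 1.0 halving to the
step floor, bounds [0, D_max = 10]).  Resident adaptation then runs
`n_rounds` events: every survivor simultaneously moves each free
coefficient group by η (in D-units, the natural scale of the trait)
along the sign of the finite-difference gradient of its own growth
against the same frozen environment snapshot, with per-species step
halving if the proposed step would lower its frozen growth — accepted
steps are monotone against their own snapshot by construction —
followed by a full community re-relaxation with pruning.  A fixed-size
signed step rather than a gradient-proportional one keeps adaptation
effective: frozen-environment growth gradients are of order 10⁻³, so a
gradient-proportional step at any reasonable η would never move the
coefficients on the scale where leakage decisions live.  Failed re-relaxations roll
the event back and halve η; three consecutive failures abort the phase.
Defaults: η = 0.1 (desk 0.5), ε = 10⁻³, n_rounds = 50 (desk 4).

The leakage *specificity* g groups the non-nutrient metabolites into g
equal contiguous blocks sharing one coefficient; g = 1 is a single
whole-membrane leakiness, the default is fully independent
coefficients.

## Ensembles and the synthetic-data generator

Random networks emulate unstructured catalytic repertoires: ρ·n
two-body conversions with substrates uniform over metabolites
(nutrient included), products uniform over non-nutrient chemicals, and
enzyme catalysts uniform; all rate constants 1; a chemical may
catalyze its own synthesis (a legal two-body form that the generator
does not exclude).  They do not emulate stoichiometric mass balance,
thermodynamic consistency, or modular pathway structure of real
metabolism — so passing ensemble tests shows the *mechanism* (leak
advantage → leaker-consumer mutualism → entangled exchange) operates
in generic dense networks, not that real metabolic networks have these
frequencies.  Species pools reject candidates whose isolated growth is
below μ_floor = 10⁻⁶ (rejection rates are logged) and resample the
whole pool from the next seed until the fastest isolated grower has at
least one leak-advantage chemical.

Headline study conditions (the `paper` preset): n = 20, ρ = 2,
n_enzyme = n/5, S_env = 0.03, V_env = 3, D_S_env = 20, D_S = 1,
R_deg = 5 × 10⁻⁵, pools of N = 50, 50 sweep replicates.  The `desk`
preset runs the same model at workstation scale — pools of N = 6,
10 replicates per condition, 4 adaptation rounds, time cap 10⁴ —
chosen so a full trend comparison completes on a single core in
minutes.  Ensemble means at this scale carry replicate noise of order
±0.3 species; trend tests compare condition means, not the paper-scale
frequency tables.

The minimal bioreaction fixture (`s1_minimal`) is a synthetic
reconstruction of a coarse central-carbon-metabolism model (glycolysis
with an explicit adenylate cycle, pentose-phosphate shuffle, overflow
and amination branches; unit rate constants; glucose and glutamine
supplied at external concentration 1.0 with D = 1;
μ = x_Nucleotides·x_Alanine).  Its isolated baseline growth computes to
μ = 0.0466 and its leak-advantage set is {Alanine}; its robust,
topology-level properties — terminal CO2/NH4/lactate are exactly
leak-neutral, nutrients are never leak-advantage candidates, a leak
advantage exists — are what the tests assert.

## Known limitations and open behavior

At workstation pool sizes (N ≲ 16) the fixed-random-permeability
control assembles *more* coexisting species on average than the
adaptive protocol, inverting the direction expected at full scale:
indiscriminate fixed leakage creates niches from the first invasion,
whereas the adaptive exchange web builds up only over many invasions
and small-pool adaptive winners are nearly unbeatable optimized
residents.  The gap narrows as the pool grows (mean roster 2.4 vs 1.7
at N = 6, 1.75 vs 1.5 at N = 16) but does not cross within desk-scale
budgets.  The trend test asserts the full-scale direction and is
expected to fail at this scale — a deliberate red marker of the
limitation, not a defect to be patched around.  The other ensemble
directions (more chemicals → more coexistence; larger environment →
less) hold at desk scale.

- No demographic stochasticity, spatial structure, or explicit cell
  numbers; fractions only.
- Reversibility is supported only for plain one-substrate/one-product
  reactions (sufficient for the reversible leaker/consumer variant).
- The collapse-vs-parasitism boundary at excessive leakage is resolved
  by the time cap: points near it can change label with the cap, which
  is inherent to classifying states that have no steady state.
- Desk-scale ensemble comparisons are directional checks with small-
  sample noise, not estimates of the full-scale coexistence
  frequencies.
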