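# Methods

## Model and assumptions

`examo` treats metabolism as a constraint-based model: feasible states are
flux vectors **v** with **S v** = 0 (steady state) and **lb** ≤ **v** ≤
**ub** (directionality and capacity). Three modeling assumptions run through
the whole pipeline:

1. *Unknown environment.* No uptake rates are imposed; every exchange
   reaction is opened to ±M. The expression data alone must select which
   boundary fluxes are used.
2. *Expression as a ternary signal.* Only the extreme tails of the
   expression distribution are trusted as evidence ("high" / "low"); the
   middle of the distribution is uninformative, and absolute expression
   magnitudes are never used quantitatively.
3. *Growth.* The biomass reaction is forced to carry flux (≥ ε) in the
   agreement MILP and in the flux-state MILP; context models are therefore
   always growth-capable.

## Pipeline stages and their numerical choices

### Exchange opening and dead-end trimming (`preprocess`)

An exchange reaction is one with a single metabolite in its stoichiometry.
Opening sets its bounds to [−M, +M], M = 1000 by default — the conventional
"effectively unbounded" magnitude, which also keeps every big-M
linearization in the MILPs finite and tight (the indicator constraints use
the model's own bounds as big-M).

Dead ends are found by flux variability analysis: two LPs per reaction,
with no growth constraint. A reaction is blocked when its FVA range lies
within (−tol, +tol), tol = 1e−9 (the LP noise floor). Because removing a
reaction can newly block others, FVA-trimming iterates to a fixed point;
the result is flux-consistent, which trimming a second time verifies
(idempotence is a test invariant). Metabolites left without reactions are
dropped.

### Discretization and reaction calls (`expression`)

Genes are ranked per condition; the top ⌈hi·G⌉ get +1 and the bottom
⌈lo·G⌉ get −1 (defaults hi = lo = 0.15). Ties at a percentile boundary are
broken by gene id so calls are reproducible; if all values are equal there
is no ranking and every call is 0 (with a warning). The 15% default tails
correspond to cutoffs about one standard deviation from the mean of a
log-normal expression distribution (a property test checks this on large
simulated samples).

Reaction calls evaluate the GPR tree with AND ↦ min and OR ↦ max over the
order −1 < 0 < +1, unmeasured genes counting 0. On flat rules this
reproduces the four classification rules for complexes and isoenzymes
exactly; on nested rules it is the unique monotone extension (raising a
gene call can never lower a reaction call — also a property test).
Reactions without gene association are never classified.

### Agreement-score MILP (`imat`)

Variables: fluxes v, binaries y⁺/y⁻ per rH reaction and y per rL reaction.
y⁺ = 1 forces v ≥ ε via v + (lb − ε)y⁺ ≥ lb; y⁻ = 1 forces v ≤ −ε
symmetrically; y = 1 pins an rL flux to exactly zero via
lb(1−y) ≤ v ≤ ub(1−y). y⁺ + y⁻ ≤ 1 is imposed explicitly (for ε > 0 both
cannot hold anyway). ε = 1.0 throughout; "non-zero biomass" is quantified
as v_biomass ≥ biomass_min with biomass_min = ε by default, keeping a
single flux scale. The MILP is solved by HiGHS with a required relative
gap of 0 — scores are proven optima, and a test re-derives the score from
the fluxes alone, ignoring the solver's binaries.

### Alternative-optima exploration (`alt_optima`)

Each reaction is modulated in turn: off (v = 0), forward (v ≥ ε), and
reverse (v ≤ −ε, reversible reactions only); each modulated MILP is solved
to proven optimality and retained iff its score equals the baseline
optimum. Infeasible or suboptimal modulations are recorded as failures,
never fatal. Activity is counted at |v| > 1e−6 (above LP noise, far below
ε). HFR = active in all retained solutions, ZFR = active in none;
intermediate frequencies are reported in the frequency table.

The modulation scheme samples a *subset* of the optimal solution space, so
its HFR can only be a superset, and its ZFR a subset, of the sets defined
over all optima. The fixtures module provides the exhaustive ground truth
on small networks (below), and the test suite asserts exactly these
containments on 50 seeded random networks; on the toy network heuristic
and exhaustive sets coincide.

The number of *distinct flux vectors* among retained solutions
(componentwise dedup at 1e−6) is reported for summaries but is not a
stable quantity: the optimal set is a polytope, and which vertex each
modulated solve returns is solver-dependent. The stable count is the
number of optimal activity patterns, which the exhaustive oracle computes.

### Context-model construction (`context`)

ZFR are deleted first; if that blocks any HFR the conflict set is reported
as an error (nothing guarantees it cannot happen). Greedy pruning then
visits non-core reactions in seeded random order, tentatively removing each
and restoring it if any core reaction's FVA range collapses; sweeps repeat
until a full sweep removes nothing. The fixed point is locally minimal —
removing any single remaining non-core reaction blocks some core reaction —
which the suite verifies exhaustively on fixtures ≤ 20 reactions. A batch
tradeoff with a "moderate-probability" reaction tier is deliberately not
used: with only two tiers (core and other) single-reaction greedy removal
expresses the constraint exactly and yields a testable minimality property.
The pruning order is the only stochastic element; default seed 0, and
genome-scale use should compare ≥ 3 seeds.

### Flux states and essentiality (`flux_states`)

Total flux Σ(v⁺+v⁻) is minimized with v = v⁺ − v⁻, v⁻ ≡ 0 for irreversible
reactions. Each forced reversible reaction has a binary y: y = 1 gives
v⁺ ∈ [ε, ub], v⁻ = 0; y = 0 gives v⁻ ∈ [ε, −lb], v⁺ = 0 — so exactly one
direction is active. For non-forced reactions simultaneous v⁺, v⁻ > 0 is
already excluded at optimality (it would inflate the objective); this is
asserted, not constrained. When the forced joint activation is infeasible,
reactions are re-activated one at a time to name the first conflict.
Reported flux tables suppress entries below 1e−10.

Essentiality uses two-valued GPR logic: the deleted gene is false, all
others true; reactions whose rule evaluates false get bounds [0, 0]; a gene
is essential when the FBA biomass optimum falls below growth_tol = 1e−6.
With open exchanges, growth is either zero or bound-limited, so any
positive optimum means viable — the threshold only guards against LP
noise. Sensitivity and PPV are computed after removing an optional excluded
set from both predicted and observed genes (the pattern needed when a
deletion library constructed in one condition cannot probe genes already
essential there). A "highly expressed genes" baseline needs no extra
machinery: pass the top-fraction gene set as the prediction.

## Oracles and the synthetic generator (`fixtures`)

Two exhaustive oracles make the MILP stack testable end to end:

- **Route enumeration**: all support-minimal signed supports admitting a
  steady-state flux with every member at |v| ≥ δ (δ = 1e−2) and biomass
  active, via a support-indicator MILP with no-good cuts, visiting minimal
  supports in nondecreasing cardinality. Every returned route is verified
  feasible, and minimality means removing any one member is infeasible.
- **Decision-pattern enumeration**: every combination of rH activations
  (forward/reverse/skip) and rL inactivations (off/skip) is checked by one
  LP; the maximal feasible decision count is the brute-force agreement
  score, the feasible maximal patterns are the optimal activity patterns,
  and per-reaction LP sweeps over those patterns give the exhaustive
  HFR/ZFR. This path shares no code with the production MILP.

Both oracles refuse models above 20 reactions (they are exponential).

The ten-reaction toy network is gated by its four printed counts — 8
routes, 2 without the two-carbon uptake, agreement score 4, 3 optimal
patterns — all recomputed by the oracles in the acceptance tests. "Flux
distribution" is operationalized as a support-minimal biomass-producing
route: raw flux vectors form a continuum, and only route-level counting
makes the printed integers well-defined.

The synthetic generator plants a linear pathway (uptake → k conversions →
biomass drain) and hangs decoy branches off chain metabolites, each ending
in its own exchange so the generated model has no dead ends (trimming is a
no-op, tested). Planted genes are called +1; a sampled fraction (default
0.6) of decoy genes are called −1; each non-zero call flips with the noise
rate. Defaults: 30 reactions, chain length 6, 20% reversible decoys.
Because the planted pathway is the unique path to biomass, forcing any of
it off is always suboptimal, while every decoy has a retained optimum in
which it is off — so at zero noise HFR equals the planted set exactly, and
the context model contains the planted core. This makes recovery at zero
noise a *structural* guarantee, and recovery under call noise nearly so:
what passing these tests shows is that the implementation realizes the
method's semantics, not that the method would recover pathway structure in
real data, where cores are not unique paths, GPRs are deeper, and
expression noise is not independent per gene.

## Known limitations

- Genome-scale runs (~2m MILPs of ~m binaries) take hours on one CPU; the
  exploration is embarrassingly parallel across modulations but the
  implementation here runs them serially.
- The modulation heuristic's HFR/ZFR are only bracketed by, not equal to,
  the all-optima sets in general; the gap is quantified on small instances
  only.
- SBML import is not implemented; the reaction-list CSV dialect is the
  interchange format.
- Flux-consistency checks use plain per-reaction FVA rather than
  accelerated consistency algorithms; this is deliberate (correctness and
  simplicity at desk scale).
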