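# examo

**Environment-specific metabolic models from gene expression alone.**

`examo` infers the metabolic state of cells growing in *uncharacterized*
environments — industrial fermentation broths, host tissues, rich media of
unknown effective composition — where the nutrient uptakes that normally
constrain a genome-scale metabolic model are unknown. Instead of nutrient
data it uses a single transcriptome per condition: gene expression is
discretized, mapped onto reactions through Boolean gene–protein–reaction
(GPR) rules, and integrated with the stoichiometric model by exploring the
*alternative optima* of an expression–flux agreement problem.

It is aimed at systems-biology practitioners working with constraint-based
models (the COBRA ecosystem) who want condition-specific reaction activity
calls, reduced context models, flux-state predictions and
condition-specific essential genes without specifying a medium.

## The method

Given a stoichiometric matrix **S** (n metabolites × m reactions), flux
bounds **lb** ≤ **v** ≤ **ub**, and reaction sets rH (highly expressed) and
rL (lowly expressed) derived from one expression value per gene:

1. **Preprocessing.** All exchange reactions are opened to ±M (default
   M = 1000), modeling complete ignorance of nutrient availability; dead-end
   reactions (FVA range {0}) are removed iteratively until the model is
   flux-consistent.
2. **Expression calls.** The top and bottom 15% of genes by expression are
   called +1 / −1 (on a log-normal expression distribution these cutoffs sit
   about one standard deviation from the mean). Reaction calls follow by
   three-valued GPR evaluation (AND = min, OR = max over −1 < 0 < +1): a
   complex is low if any subunit is low and high only if all are; isoenzymes
   are high if any isoform is high and low only if all are.
3. **Agreement maximization (iMAT).** A MILP finds a steady-state flux
   distribution maximizing the *agreement score*

   max Σ<sub>i∈rH</sub> (y⁺ᵢ + y⁻ᵢ) + Σ<sub>i∈rL</sub> yᵢ
   s.t. **S v** = 0, **lb** ≤ **v** ≤ **ub**,
   y⁺ᵢ = 1 ⇒ vᵢ ≥ ε, y⁻ᵢ = 1 ⇒ vᵢ ≤ −ε (i ∈ rH),
   yᵢ = 1 ⇒ vᵢ = 0 (i ∈ rL), v<sub>biomass</sub> ≥ ε,

   with ε = 1.0 and all binaries in {0,1}.
4. **Alternative-optima exploration.** The optimum is massively degenerate.
   Every reaction is forced, in turn, to be inactive, to carry forward flux
   ≥ ε, and (if reversible) reverse flux ≤ −ε; each modulated MILP is
   re-solved and solutions attaining the global optimum are retained.
   Reactions active in *all* retained optima form the high-frequency set
   (HFR, predicted active); reactions active in *none* form the
   zero-frequency set (ZFR, predicted inactive).
5. **Context model.** ZFR are deleted, then non-HFR reactions are greedily
   pruned (seeded random order, repeated sweeps to a fixed point) under the
   constraint that every HFR reaction can still carry flux.
6. **Flux states and essentiality.** The metabolic state is predicted by
   minimizing total flux Σ(v⁺+v⁻) with every HFR and the biomass reaction
   forced to |v| ≥ ε (binary direction selectors for reversible HFR);
   condition-specific essential genes are predicted by FBA single-gene
   deletions on the context model and scored by sensitivity tp/(tp+fn) and
   positive predictive value tp/(tp+fp).

All LPs/MILPs are solved with SciPy's HiGHS interfaces at zero relative
optimality gap.

## Worked example

The package ships a ten-reaction toy network in which a five-carbon biomass
precursor (E5) is synthesized from a two-carbon (A2) and/or a three-carbon
(B3) substrate; five reactions carry expression calls, with r3 an OR of two
lowly expressed isoenzyme genes and r7 an AND complex with one lowly
expressed subunit.

```sh
examo fixtures toy --out toy.csv --calls toy_calls.tsv
examo trim    --model toy.csv     --out trimmed.csv
examo calls   --model trimmed.csv --calls toy_calls.tsv --out rcalls.tsv
examo explore --model trimmed.csv --calls rcalls.tsv    --out freq.tsv
examo build   --model trimmed.csv --freq freq.tsv       --out context.csv
examo minflux --model context.csv --hfr freq.tsv        --out state.tsv
```

prints

```
trimmed 10 -> 10 reactions (0 removed)
|rH| = 3, |rL| = 2
score 4; 19 retained solutions; |HFR| = 2, |ZFR| = 0
context model: 5 of 10 reactions
total flux 5
```

Reading the numbers: three reactions are called highly expressed
({r2, r5, r6}) and two lowly expressed ({r3, r7}); the best achievable
agreement is 4 of 5 — every two-carbon unit is made by r3 or r7, so
activating the condensation r5 forces one "low" reaction to carry flux.
Across the alternative optima only the 3C uptake r2 and the biomass drain
r6 are active in every solution (HFR); no reaction is inactive in all of
them (ZFR = ∅). The context model keeps a five-reaction subnetwork in which
both HFR carry flux, and the minimum-total-flux state routes one unit of
each substrate through the direct condensation r9 (total flux 5).

The same stages are available as library functions
(`examo.solve_imat`, `examo.explore_optima`, `examo.build_context_model`,
`examo.minimize_total_flux`, ...), and `examo run --config run.cfg` chains
them and writes a run manifest.

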