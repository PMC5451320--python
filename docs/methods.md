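# Methods

## Scope and model class

`wcsim` integrates a composition of pathway submodels over a shared pool of
integer molecule counts. Supported formalisms: exact stochastic simulation
(SSA), deterministic mass-action ODEs, flux balance analysis (FBA), and
Boolean regulatory rules. The model class is deliberately narrow:
irreversible mass-action reactions with integer stoichiometry, well-mixed
compartments, no events, no algebraic constraints, no spatial or
particle-based state. Reversible reactions are split into forward/backward
halves at load time. State is molecule counts, never concentrations;
compartment volumes are carried for completeness but no engine currently
converts through them.

## Conventions

**Stochastic propensity.** `a = c·∏ᵢ C(nᵢ, sᵢ)` — the rate constant times
the number of distinct reactant combinations. Constants taken from the
permutation convention (falling-factorial factors `nᵢ!/(nᵢ−sᵢ)!`) must be
multiplied by `∏ᵢ sᵢ!` before use. A reactant-free reaction has propensity
`c`; disabled reactions and insufficient copy numbers give zero.

**Deterministic rates.** The ODE engine uses the count-based law
`c·∏ᵢ nᵢ^{sᵢ}` (molecules/s), so an SSA and an ODE encoding of the same
reaction agree in the large-count limit with no unit conversion. This is
also why the `volume` argument of `net_rates` is inert.

**FBA units.** Fluxes are molecules/second, matching the pool. A standard
FBC model in mmol·gDW⁻¹·h⁻¹ must be rescaled by
(cell dry mass × N_A / 3600) before use.

## Per-step semantics

All submodels integrate from the same immutable snapshot; requests are
arbitrated and committed together. Specific choices where the design was
genuinely open:

- **Arbitration policy.** "Accept or reject" is realized as *partial*
  acceptance: per deficient species, consumers are scaled proportionally
  with largest-remainder apportionment (exact integer arithmetic, ties
  broken by ascending submodel id). Production is never scaled and counts
  toward availability. Rationale: preserves every submodel's intent
  fractionally instead of starving whichever is unlucky in ordering; the
  deterministic tie-break keeps runs reproducible.
- **Redo before scale.** Scaling distorts kinetics, so a scaled step above
  `dt_min` is *redone* from the same snapshot at Δt/2 (fresh random
  substream indexed by the retry count, so the redo is an independent
  draw). Scaling is committed only at the Δt floor or when the retry
  budget (default 5) is exhausted, with a warning either way — the
  simulation never aborts mid-run.
- **Step growth.** After K = 3 consecutive scale-free commits, Δt doubles,
  capped at `dt_max`. Defaults: `dt_init = dt_max = 1 s`,
  `dt_min = 0.125 s`.
- **Boolean effects are one step delayed.** Rules are evaluated
  synchronously against the step's input snapshot and their effects
  (parameter values, reaction enablement — never species counts) apply
  from the next snapshot. This keeps request arbitration the sole writer
  of the pool and makes rule order provably irrelevant. Two true rules
  assigning different values to one target are a hard error.
- **ODE/FBA integerization.** Continuous per-step deltas are rounded to
  the nearest integer with a persistent per-species residual carry, so
  over any k steps the committed total differs from the continuous total
  by < 1 molecule per species. Deterministic rounding was chosen over
  stochastic rounding for reproducibility; the carry makes it unbiased
  over time. When non-negativity clips a delta, the clipped mass is
  dropped and the residual re-capped into (−1, 1) rather than owed
  indefinitely.
- **Sequential reference mode.** `simulate(..., mode="sequential")`
  integrates submodels one after another within a step, each seeing the
  previous one's output. It exists for comparison only: it demonstrates
  the within-step ordering artifact the snapshot scheme removes, and the
  two modes converge as Δt → 0.

## Numerical choices

- **SSA**: direct method (exponential waiting time from total propensity,
  cumulative-sum reaction choice). Events straddling the step end are
  discarded, so each request is attributable to `[t, t+Δt)`. No
  tau-leaping or next-reaction optimizations.
- **ODE**: classical RK4 with `max(1, ⌈Δt/h_max⌉)` equal substeps,
  `h_max = Δt/10` by default. Fixed substeps (not an embedded adaptive
  pair) because the controller already adapts Δt and determinism matters
  more than per-step efficiency here. Negative transients inside the
  integrator are clamped to zero in rate evaluation.
- **FBA**: `scipy.optimize.linprog` (HiGHS). Infeasible/unbounded programs
  degrade to a zero request with a diagnostic flag — the biological
  reading is a cell with halted metabolism. Degenerate optima are
  expected; only the objective value is unique and only it is asserted in
  tests. Availability enters both as per-reaction bound tightening
  (`ub ← min(ub, n_s/(Δt·|a|))`) and as aggregate per-species inequality
  rows, so an FBA request alone can never overdraw a pool.
- **Randomness**: `numpy` PCG64 generators seeded by
  `SeedSequence((seed, crc32(submodel id), step, retry))`. Streams are a
  pure function of those keys, so submodel invocation order is
  unobservable and redone steps draw fresh randomness.

## File formats

Submodels are standalone SBML Level 3 Version 1 documents restricted to a
documented subset: compartments, species with integer `initialAmount`
(`hasOnlySubstanceUnits` semantics), irreversible mass-action kinetic laws
(one rate parameter times reactant species; reversible laws must be
`kf·∏−kr·∏` and are split), and the FBC idiom (bound parameters, an active
maximization objective, `boundaryCondition` marking pool-coupled species)
for FBA submodels. Events, rules, constraints, initial assignments,
function definitions, and non-mass-action kinetics are rejected with the
offending element named — never silently dropped. Numeric attributes
round-trip exactly for values representable at 15 significant digits (the
SBML writer's precision); package-generated models snap constants there.

Composition uses an explicit JSON/YAML manifest (submodel files, formalism
tags, total local→global species maps, global initial counts, parameters,
Boolean rules) instead of the SBML hierarchical-composition package: the
manifest is dependency-light, keeps each submodel file valid standalone
SBML, and makes the shared-species identity map explicit rather than
inferred from names. Manifest initial counts override per-file values; a
species whose local values disagree *must* be set in the manifest.
Formalism tags live in the manifest (duplicated as a model annotation on
write) because core SBML has no formalism attribute.

Trajectories persist to CSV (`time` + one column per global species) or
HDF5 (`/times`, `/counts`, `/species_ids`, `/diagnostics`), with lossless
integer counts.

## What the generators emulate — and what they do not

`make_transcription_submodel` builds the lumped encoding of transcription:
one reaction per RNA species (polymerase + NTP composition → polymerase +
RNA) instead of per-base elongation, and no explicit DNA–protein binding.
`make_minimal_cell_model` is a three-compartment cell with one submodel
per formalism; its constants are arbitrary, chosen so a 10 s demo stays in
the hundreds-of-molecules regime (uptake 21/s, biomass 5/s, 4/s per NTP,
~0.5 transcription initiations/s per RNA, k_deg = 0.05 s⁻¹ gated by a
total-RNA < 5 rule). `make_random_hybrid_model` fuzzes the controller with
random SSA/ODE compositions sharing at least one species.

None of these reproduce real organism biology: no genome-scale inventory,
no growth-dependent parameters, no cell division, no realistic kinetic
constants. Passing tests demonstrate the *integration machinery* — pool
safety, conservation, convergence, reproducibility — not biological
accuracy of any particular cell model.

Test problem sizes (10⁴-step conservation runs, 200-replicate convergence
studies, 100-seed fuzzing, 24 stationary-mean windows) were chosen so the
statistical assertions are well-powered while the whole suite runs in well
under a minute of CPU per module.

## Known limitations

- Boolean rules cannot write species counts (by design) and cannot express
  rate *expressions*, only set parameter values.
- FBA submodels ignore kinetic constants entirely; coupling is purely
  through bounds and boundary pools.
- The ODE engine is explicit; stiff submodels will force tiny `h_max`.
- Residual carries are per-submodel and not persisted to trajectory files;
  a restarted run is reproducible only from t = 0.
- No parallel execution: submodels are invoked sequentially (isolation
  makes this semantically invisible, but not faster).
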