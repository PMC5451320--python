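# wcsim

A multi-algorithm whole-cell simulator. Whole-cell models compose many
pathway-level submodels written in *different* mathematical formalisms —
stochastic simulation (Gillespie/SSA), deterministic ODEs, flux balance
analysis (FBA), and Boolean regulatory rules — all exchanging material
through one global pool of integer molecule counts. `wcsim` provides the
integration machinery that makes such a composition well-defined, plus SBML
subset I/O, a composition-manifest format, example model generators, and a
CLI. It is aimed at systems-biology modelers who need to couple
heterogeneous submodels without writing ad hoc glue code.

## The integration scheme

At every time step of length Δt:

1. **Snapshot.** The controller takes an immutable snapshot
   `(t, counts, parameters)` of the global state.
2. **Integrate.** Every submodel is advanced over `[t, t+Δt)` from that
   *same* snapshot (the "arrow of time": no submodel ever observes another's
   uncommitted output). Each engine produces a **change request** — proposed
   integer species deltas:
   - **SSA**: exact direct-method simulation with propensity
     `a = c·∏ᵢ C(nᵢ, sᵢ)` (combinatorial mass action);
   - **ODE**: fixed-substep RK4 on count-based mass-action rates
     `c·∏ᵢ nᵢ^{sᵢ}`, integerized with a per-species residual carry;
   - **FBA**: a per-step LP — maximize the objective subject to steady
     state for internal metabolites and availability-tightened exchange
     bounds (consumption of species *s* cannot exceed `n_s/Δt`) — with
     optimal boundary fluxes × Δt converted to integer deltas;
   - **Boolean rules** are evaluated on the snapshot and switch parameters
     or reaction enablement for the *next* step.
3. **Arbitrate.** Production is always accepted. Where total requested
   consumption `C_s` of a species exceeds availability `A_s` (pool +
   production), consumers are scaled to `⌊rᵢ·A_s/C_s⌋` with leftover units
   assigned by largest fractional remainder (ties by submodel id). The
   committed pool is never negative.
4. **Adapt.** A step that needed scaling is redone from the same snapshot
   at Δt/2 (down to `dt_min`, where it commits with a warning); after K
   consecutive clean steps Δt doubles back up to `dt_max`.

Every stochastic submodel draws from its own counter-based random stream
keyed by `(seed, submodel, step, retry)`, so results are independent of
submodel invocation order and bit-reproducible from `(model, config)`.

## Worked example

```python
from wcsim import fixtures, simulate, SimulationConfig

model, manifest = fixtures.make_minimal_cell_model()
traj = simulate(model, SimulationConfig(t_max=10.0, seed=4))
print(traj.to_frame().iloc[[0, -1]].to_string(index=False))
```

```
 time  ATP_c  BIOMASS_c  CTP_c  GTP_c  P_c  RNAP_c  RNA_1_c  RNA_2_c  T_m  UTP_c   X_e
  0.0    500          0    500    500    0      10        0        0    1    500 10000
 10.0    521         50    524    524    0      10        3        5    1    521  9790
```

The minimal cell has three compartments (extracellular, membrane, cytosol)
and four submodels, one per formalism. Over ten seconds the FBA submodel
takes up 21 nutrient molecules per second (hence `X_e` drops by 210),
converts them into 5 biomass/s (`BIOMASS_c` reaches 50) and 4 of each
NTP/s; stochastic transcription consumes NTPs to make the two RNA species
(~0.5 initiations/s each), so the NTP pools rise slightly more slowly than
synthesis alone would predict; the Boolean rule keeps first-order RNA
degradation switched off until total RNA reaches 5 copies.

The same model is available from the shell:

```bash
wcsim make-example minimal-cell --out demo/
wcsim validate demo/manifest.yaml
wcsim simulate demo/manifest.yaml --t-max 10 --seed 4 --out traj.csv
```

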