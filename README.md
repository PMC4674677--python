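# dcdc — distributed cell division counting

Microbial growth rates are easy to measure when cells can be watched or
death is rare — and nearly impossible in places like the mammalian gut,
where growth, death, and washout are convolved. Distributed cell division
counting (DCDC) resolves this with a synthetic mark-and-recapture: cells
are induced to assemble a single, inert, bright fluorescent particle; the
inducer is removed, and at each division the particle segregates to exactly
one daughter. The fraction of bright ('on') cells therefore halves each
generation, so for an on-fraction *f*

```
log2 f(t) = log2 f(0) − t / τ_ON
```

and an ordinary least-squares fit of log2 *f* against time yields the
population doubling time τ_ON — even when the population is only
observable through sampled snapshots (flow cytometry of faecal samples).

This package implements the computational side of that method for
scientists studying bacterial population dynamics:

- **`dcdc.error_model`** — deterministic ODEs for particle/cell dynamics
  (`dp/dt = K_split·p + K_fp·(n−p) − p/τ_p`,
  `dn/dt = μ_B·p + μ_D·(n−p)`), with the counter's steady-state on/off
  floor (≈ the per-generation false-production rate K*_fp), its dynamic
  range `log2(f₀/L)` in generations, the transient of growth-rate
  disparities between bright and dark cells, and the decomposition of the
  error budget into splitting, degradation, and false production.
- **`dcdc.division_simulator`** — a stochastic, generation-synchronous
  branching simulator of segregating particles, plus a turbidostat
  simulator with feedback dilution.
- **`dcdc.cytometry`** — synthetic two-population log-normal fluorescence
  mixtures, threshold classification, ROC curves and AUC, and Wilson
  intervals for on-fractions.
- **`dcdc.growth_inference`** — every estimator: τ_ON from on-fraction
  decay, the α correction (α + 1/τ_ON = 1/τ_OD), the turbidostat optical
  density calibration chain (% transmittance → raw OD → origin-forced
  quadratic calibration → log-linear fit → τ_OD), in-vivo red/green fits
  pooled across mice, and gut transit time from the GFP⁺ faecal pulse.
- **`dcdc.gut_dynamics`** — seven ODE cases for gut colonization (no
  feedback, nutrient limitation, interspecies interactions, adaptation,
  physiological removal, immune response, bacteriophage), with closed
  forms where they exist, fixed-point/bifurcation analysis, and regime
  classification.
- **`dcdc.synthetic_data`** — generators that emulate the experiments end
  to end (gavage/faecal sampling, turbidostat photodiode traces, fixture
  suite), so every estimator can be validated against known ground truth.
- **`dcdc.io` / `dcdc.cli`** — CSV/JSON/YAML schemas with row-level
  validation and a `dcdc` command-line tool.

## Worked example

Simulate a counting experiment with a realistic error floor and recover
the growth rate:

```python
from dcdc.division_simulator import SimulationParams, simulate_generations, sample_cells
from dcdc.growth_inference import OnFractionSeries, fit_on_fraction_decay

params = SimulationParams(
    doubling_time=0.55,        # 33 min, fast growth in rich medium
    initial_on=70_000, initial_off=30_000,   # 70% induced at t = 0
    p_false_per_gen=1e-3,      # spontaneous particle production
    seed=0,
)
series = simulate_generations(params, n_generations=6)
ons = [sample_cells(int(o), int(n), 100_000, seed=i)[0]
       for i, (o, n) in enumerate(zip(series.n_on, series.n_total))]
fit = fit_on_fraction_decay(
    OnFractionSeries(time_h=series.time_h, n_on=ons, n_total=[100_000] * 7),
    exclude_lag=0, floor=None,
)
print(f"doubling time: {fit.doubling_time * 60:.1f} min "
      f"(R² = {fit.r_squared:.4f})")
```

This prints

```
doubling time: 33.5 min (R² = 0.9999)
```

The estimate is ~1.5% above the true 33 min: spontaneous false production
adds bright cells and slightly flattens the decay, a bias the error model
predicts and bounds. The same model shows the counter's dynamic range is
`log2(0.7 / 10⁻³) ≈ 9.5` generations at this floor, and that a doubling
time range of 0.5–5 h corresponds to a `2¹⁰/2¹ = 512`-fold difference in
population size per slowest generation:

```python
from dcdc.growth_inference import fold_spread_per_slowest_generation
fold_spread_per_slowest_generation(0.5, 5.0)   # 512.0
```

## Command line

```sh
dcdc make-fixtures --out fixtures/ --seed 7
dcdc fit-growth --in fixtures/on_fraction_tau1h.csv --exclude-lag 0 --floor -1 --out fit.json
dcdc gut-model --case adaptation --params fixtures/gut_model_spec.json --duration 168 --out traj.csv
dcdc roc --bright on.csv --dark off.csv --out roc.csv --summary roc.json
```

Every run writes a sidecar `*.config.json` with the resolved
configuration, seed, and package version.

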