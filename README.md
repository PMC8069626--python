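# relmech — mechanism-decomposed drug-release modelling

`relmech` models the cumulative release of a drug from a polymer film as the
weighted sum of three physical mechanisms and fits that decomposition to
measured release profiles:

- **initial burst** of surface-associated drug, first-order in time:
  `F1(t) = 1 − exp(−k_b t)`;
- **matrix diffusion** through a plane sheet of thickness `h`, the exact
  Fourier-series solution of Fick's second law:
  `F2(t) = 1 − (8/π²) Σ_{n≥0} exp(−(2n+1)² π² D_e t / h²)/(2n+1)²`;
- **osmotic pumping** across the film, zero-order in time:
  `F3(t) = k_os · t`, with `k_os = γ·Δπ` linking the slope to the osmotic
  pressure gradient `Δπ` through a device constant `γ`.

The composite model is `M_t/M_∞ = μ₁F1 + μ₂F2 + μ₃F3` with mechanism weights
`μᵢ ≥ 0, Σμᵢ = 1`. Fitting such a model answers the formulation question
*"how much of the release is burst, how much diffusion, how much osmosis?"*
for each film composition and hydrodynamic condition.

The constrained least-squares fit is performed by an **SQP (sequential
quadratic programming) optimizer implemented in this package**: an active-set
QP subproblem solver, damped-BFGS Hessian updates, an ℓ1 exact-penalty line
search, and KKT-residual convergence, with the simplex constraint on the
weights handled exactly. A deterministic multistart over the weight simplex
and log-spaced kinetic constants makes the fit reproducible run to run.

The package also ships the supporting membrane physics (Poiseuille pressure
drop, hydraulic permeability, solute reflection coefficient, free-volume
coefficient), empirical correlations that link the fitted kinetic constants
to drug load and medium flow rate, a synthetic-data generator with five
built-in study conditions, CSV/JSON I/O, and a CLI.

## Worked example

Simulate one noisy release experiment for the mid-load film and fit the
decomposition back (this is `examples/simulate_and_fit.py`):

```python
from relmech import GeneratorConfig, fit_release, generate_profile

profile, truth = generate_profile(GeneratorConfig(label="PU-20%DE-Q7.5", seed=3))
result = fit_release(profile)
print(result.contributions, result.rmse, result.r_squared)
```

Output of the full example script:

```
condition: PU-20%DE-Q7.5  (101 points, noise sd 0.01)
                     truth      fitted
burst %               31.3        30.8
diffusion %           55.9       53.68
osmosis %             12.8       15.52
k_b (1/h)              2.5       1.947
D_e (m^2/h)       1.62e-08   1.788e-08
k_os (1/h)        0.009999    0.009854

RMSE = 0.0103, R^2 = 0.9964, delta_pi = 0.00887 atm
```

On a noiseless profile the same fit recovers all six parameters to better
than 0.1% for every built-in condition (see `tests/test_acceptance.py`).
The kinetic rate `k_b` is the hardest parameter under noise: its burst
transient (half-life ≈ 17 min here) is barely resolved by hourly sampling —
see `docs/methods.md` for the identifiability analysis.

Other examples in `examples/`:

- `mechanism_decomposition.py` — per-mechanism contributions over time for
  all built-in conditions;
- `predict_unseen_condition.py` — correlate the fitted constants with drug
  load (`ln k = a + b/C`) and predict a 15%-load profile;
- `membrane_physics.py` — hydraulics behind the osmotic term;
- `sqp_demo.py` — the SQP optimizer on constrained Rosenbrock, with the merit
  trace.

## Command-line interface

```sh
relmech conditions                       # list built-in study conditions
relmech simulate --condition PU-20%DE-Q7.5 --noise-sd 0.01 --seed 1 -o run.csv
relmech fit run.csv --label PU-20%DE-Q7.5 --concentration 20 --flow 7.5 -o fit.json
relmech predict --constants-from reports/ --concentration 15 --flow 7.5 -o pred.csv
relmech physics sigma --phi 0.5          # reflection coefficient
relmech physics lp --pore-radius 1e-6 --pore-density 1e6 \
    --thickness 1e-3 --viscosity 8.9e-4  # hydraulic permeability
```

Profile CSVs have a `time_h,fraction_released` header (or `time_h,mass_mg`
plus `--m-inf`). `fit` writes a JSON report with the parameters, mechanism
percentages, fit quality and provenance (settings digest, seed, software
version); `predict` consumes a directory of such reports. Exit codes: 0
success, 1 invalid input, 2 fit did not converge (report still written).

## Reproduction

Run the test suite (unit, property-based and acceptance tests; the noisy-fit
acceptance test takes a few minutes):

```sh
python -m pytest -q tests/
```

Recompute the headline numbers from scratch (noiseless refits of three study
conditions plus a 20-replicate noisy study):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which reports, for example, the refitted burst share of the mid-load film
(`t3` ≈ 31.3%), its osmotic gradient (`t7` ≈ 0.009 atm), the diffusional
share of the low-load film (`t5` ≈ 65.7%), the osmotic share of the
high-load film (`t4` ≈ 14.7%), and the median R² (`t8`) and RMSE (`t9`) over
20 noisy replicates at noise sd 0.02. All randomness derives from `--seed`.

## Layout

```
src/relmech/        library (mechanisms, membrane, sqp, fitting,
                    correlations, synthetic, io, cli)
tests/              pytest suite
examples/           narrative example scripts
scripts/acceptance.py  end-to-end recomputation of the headline numbers
docs/methods.md     methods note: model, numerics, limitations
```
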