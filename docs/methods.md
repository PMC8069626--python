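# Methods

## Model

Cumulative fractional release from a drug-loaded polymer film is modelled as
a convex combination of three mechanisms:

```
M_t/M_∞ = μ1·F1(t) + μ2·F2(t) + μ3·F3(t),   μi ≥ 0,  μ1+μ2+μ3 = 1
```

- **Burst** `F1(t) = 1 − exp(−k_b t)`: first-order depletion of a
  surface-associated drug pool with rate `k_b` (1/h).
- **Matrix diffusion** `F2(t) = 1 − (8/π²) Σ_{n≥0} exp(−(2n+1)²π²D_e t/h²)/(2n+1)²`:
  the exact series solution of Fick's second law for a plane sheet of
  thickness `h` with constant effective diffusivity `D_e` (m²/h), uniform
  initial loading and perfect-sink boundaries. The sum runs over odd modes
  only; this normalization gives `F2(0) = 0` and `F2(∞) = 1` exactly
  (`Σ 1/(2n+1)² = π²/8`). The early-time square-root law
  `F2 ≈ 4·√(D_e t/(π h²))` is provided as a cross-check; it tracks the series
  to within 1% while `F2 < 0.4` and a warning is emitted if it is evaluated
  beyond `F2 ≈ 0.6`.
- **Osmotic pumping** `F3(t) = k_os·t`: zero-order release driven by an
  osmotic pressure gradient `Δπ` (atm) across the film. The slope factors as
  `k_os = γ·Δπ`, where `γ = A·h·K′·S/M_∞` collects device geometry
  (`GeometryConstants`); when geometry is not supplied, the default
  `γ = 1.111 h⁻¹·atm⁻¹` is used so that `Δπ = 0.009 atm` corresponds to
  `k_os = 0.01 1/h`.

Assumptions: the three mechanisms act independently and additively; film
thickness, diffusivity and the osmotic gradient are constant over the
experiment; the osmotic term is not truncated at exhaustion, so the composite
model can exceed 1 at late times (fitting accepts observed fractions up to
1.2 as a scale-error guard, and a `clamp` option caps forward simulations at
1 for display).

## Membrane physics

The osmotic mechanism presumes the osmotic gradient dominates the hydrostatic
back-pressure generated by the release flux. For a membrane idealized as `n`
parallel cylindrical pores of radius `a` over thickness `δ` in a fluid of
viscosity `η`:

- Poiseuille pressure drop `ΔP = 8ηδ·Jv/(nπa⁴)` at volumetric flux `Jv`;
- hydraulic permeability `Lp = nπa⁴/(8ηδ)` (so `Jv = Lp·ΔP` identically);
- solute reflection coefficient `σ = (1 − (1−∅)²)²` for solute/pore radius
  ratio `∅ ∈ [0, 1]` (σ(0)=0, σ(1)=1, monotone);
- free-volume coefficient `f_g = B·Δα·A/2.303` for the temperature dependence
  of diffusivity in the polymer;
- `osmosis_dominance_check` compares `Δπ` (converted at 101325 Pa/atm)
  against `ΔP` with a default dominance factor of 10.

## Parameters and built-in conditions

Five named study conditions (polyurethane films loaded with diclofenac,
varied in drug load C at fixed flow, and in eluent flow rate Q at fixed
load) are built in:

| label | C (%) | Q (mL/s) | μ_burst | μ_diff | μ_osm | k_b (1/h) | D_e (m²/h) | Δπ (atm) |
|---|---|---|---|---|---|---|---|---|
| PU-10%DE-Q7.5 | 10 | 7.5 | 0.232 | 0.657 | 0.111 | 1.5 | 1.10e-8 | 0.005 |
| PU-20%DE-Q7.5 | 20 | 7.5 | 0.313 | 0.559 | 0.128 | 2.5 | 1.62e-8 | 0.009 |
| PU-30%DE-Q7.5 | 30 | 7.5 | 0.360 | 0.493 | 0.147 | 3.4 | 1.96e-8 | 0.014 |
| PU-20%DE-Q0   | 20 | 0   | 0.290 | 0.620 | 0.090 | 1.7 | 8.70e-9 | 0.007 |
| PU-20%DE-Q23.5| 20 | 23.5| 0.319 | 0.535 | 0.146 | 3.9 | 2.77e-8 | 0.012 |

Film thickness defaults to `h = 0.002 m`; `k_os = γ·Δπ` with the default γ.

## Fitting

`fit_release` minimizes the sum of squared residuals over
`x = (μ1, μ2, μ3, k_b, D_e, k_os)` subject to `Σμ = 1` (explicit equality
constraint), `μi ∈ [0, 1]`, and wide positivity bounds on the kinetic
constants (`k_b ∈ [1e-3, 100]`, `D_e ∈ [1e-12, 1e-5]`, `k_os ∈ [0, 1]`).
Internally `k_b` and `D_e` are parameterized as log10 values because `D_e`
spans seven decades of the search box. The SSE gradient is analytic (chain
rule through the series and the log parameterization); this, rather than
finite differences, is what makes noiseless refits exact far beyond the
0.1% tolerance the acceptance test asserts.

The optimizer is started from a deterministic multistart: the resolution-2
simplex lattice of weight vectors (6 points) plus the centroid, each paired
with 2 log-spaced interior values of each kinetic constant (14 starts
total). The best converged start by objective wins; the full start table is
recorded in the result for audit.

## SQP optimizer

`solve_sqp` is a dense sequential-quadratic-programming implementation:

- QP subproblems with the current BFGS Hessian, linearized constraints and
  bounds folded into inequalities, solved by a primal active-set method over
  dense KKT systems;
- Powell-damped BFGS updates (damping threshold 0.2) keep the Hessian
  approximation positive definite;
- globalization by an ℓ1 exact-penalty merit function with Armijo
  backtracking (c₁ = 1e-4, halving steps), penalty kept a margin above the
  largest multiplier;
- convergence declared on the max-norm KKT residual (stationarity, primal and
  dual feasibility, complementarity) below `tol` (default 1e-4; the fit uses
  1e-9);
- gradients by forward finite differences unless analytic callbacks are
  supplied.

The test suite checks the solver against closed-form KKT solutions and, on a
six-problem constrained suite, against an independent reference optimizer
(scipy's trust-constr at tight tolerances, polished by SLSQP) to 1e-6.

## Synthetic data generator

`generate_profile` evaluates the forward model for a built-in condition (or
explicit parameters) on a uniform grid — default 0–100 h, 101 points — and
adds i.i.d. Gaussian noise (default sd 0.01 on the fraction scale, seeded via
`numpy.random.default_rng`); negative noisy values are clipped to 0 by
default. The defaults represent the study design: hourly sampling over ~4
days at roughly 1% measurement error. The generator returns the ground-truth
parameter record alongside the profile so recovery can be scored.

## Identifiability of the burst rate

At the built-in conditions the burst half-life is `ln 2/k_b ≈ 12–28 min`,
while the default grid samples hourly: the burst transient is essentially
complete within the first one or two samples. The Cramér–Rao bound computed
at the high-load condition (`tests/test_fitting.py::TestIdentifiability`)
makes this quantitative: at noise sd 0.01 on the hourly grid, the relative
standard error of any unbiased estimator of `k_b` exceeds 10% (it is ≈ 28%),
so no fitting method can recover the burst rate to 10% from such data. On a
0.25 h grid the bound drops below 10% for both `k_b` and `D_e`, and the
noisy-recovery property test (median relative error ≤ 10% over replicates)
is run at that sampling rate. The weights, `D_e` at moderate precision, and
`k_os` remain well identified on the hourly grid, as the noisy acceptance
test (median RMSE ≤ 0.03, median R² ≥ 0.97 at noise sd 0.02) shows.

## Correlations

Fitted constants are correlated with the varied factors by ordinary least
squares on two scales: `ln k = a + b·(1/C)` against drug load and
`k = a + b·Q` against flow rate (zero-intercept variants optional).
Predictions at unseen factor values transform back to the natural scale;
values far outside the training range raise a warning. Mechanism weights at
an unseen condition are interpolated linearly in the varied factor and
renormalized to the simplex; the assembled parameter set is simulated
forward to a full profile. With two training points the correlations pass
through their knots exactly (reproduction tested to 1e-9 relative).

## Limitations

- The mechanisms are assumed additive and non-interacting; no mechanism
  couples to drug depletion, so the composite curve is unbounded in time and
  late-time data beyond exhaustion should not be fitted.
- The plane-sheet solution assumes constant `D_e`, uniform loading and
  perfect sink; swelling, erosion, or concentration-dependent diffusivity are
  out of scope.
- `γ` converts osmotic slope to pressure gradient only as accurately as the
  device geometry it summarizes; reported `Δπ` inherits any error in `γ`.
- The correlations are empirical two-to-three-point regressions intended for
  interpolation between studied conditions, not extrapolation.
- The burst rate is weakly identified at hourly sampling (see above); design
  sampling intervals against the expected burst half-life.
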