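# Methods

## Model structure

The forward model is a daily-timestep carbon box model of the DALEC
family. State: foliage `Cf`, fine roots `Cr`, wood `Cw` (branches, stems,
coarse roots), litter `Clit`, soil organic matter `Csom`, all in g C m⁻²;
deciduous runs add a labile store `Clab` that funds leaf flushing. Each
pool obeys the explicit Euler update `C(t+1) = C(t) + I(t) − k·C(t)`.
Fluxes route as in the classic DALEC topology: foliage and fine-root
turnover feed litter; wood turnover feeds SOM; litter is partly
mineralized to CO₂ (`k_lit_min`) and partly humified to SOM
(`k_lit_dec`); SOM is mineralized at `k_som`. Dead-pool rates are
multiplied by a temperature scalar `f_Ta = exp(θ·Ta)` and a soil-moisture
scalar `f_Sw = (Sw/Sc)^b` clipped to [0, 1]. The moisture scalar's
power-law form is this package's design choice: it is the simplest
monotone function that is 1 at saturation, 0 in completely dry soil, and
has a retrievable shape parameter.

GPP uses the aggregated canopy model (ACM): a canopy-conductance term
from the diurnal temperature range and hydraulics, a quadratic for
internal CO₂, an LAI-saturation factor, and an astronomical day-length
factor from latitude and day of year. The ten empirical coefficients ship
as an overridable default set (`ACMCoefficients`); the published
calibration constants are used verbatim, with the foliar-nitrogen
multiplier exposed as the site parameter `canopy_eff`. GPP is zero
whenever LAI or PAR is zero and is monotone in both.

Effective daily removal fractions are capped at 1 per pool, so pools can
never be driven negative; the cap rescales competing fluxes
proportionally, which preserves exact mass balance. Every daily step
satisfies `Δ(ΣC) = GPP − Ra − Rh` to floating-point precision (~1e-16
relative; the test suite enforces 1e-9).

Deciduous phenology is a pair of step rules: from `day_leafout` the
labile pool releases into foliage at rate `k_lab`; in the 30 days ending
at `day_leaffall` canopy growth stops and foliage transfers linearly to
litter, completing exactly at `day_leaffall`, so leaf area is exactly
zero from leaf-fall to leaf-out. Off-season photosynthate allocated to
foliage is redirected to the labile store.

## Parameters, units, defaults

| name | meaning | unit | default | prior |
|---|---|---|---|---|
| f_a | GPP fraction respired autotrophically | – | 0.45 | 0.2–0.8 |
| f_f, f_r | NPP fractions to foliage / fine roots | – | 0.25, 0.25 | 0.05–0.5 |
| k_f, k_r | foliage / fine-root turnover | d⁻¹ | 1/2.5 yr, 1/2 yr | (10 yr)⁻¹–(0.5 yr)⁻¹ |
| k_w | wood turnover | d⁻¹ | 1/50 yr | (1000 yr)⁻¹–(10 yr)⁻¹ |
| k_lit_min, k_lit_dec | litter mineralization / humification | d⁻¹ | 2e-3 | 1e-4–1e-2 |
| k_som | SOM mineralization | d⁻¹ | 5e-5 | (1000 yr)⁻¹–(10 yr)⁻¹ |
| θ | temperature sensitivity (Q10 = e^{10θ}) | °C⁻¹ | 0.0693 | 0.02–0.08 |
| sw_exp | moisture-scalar exponent | – | 1.0 | 0.1–3 (held fixed) |
| canopy_eff | ACM canopy efficiency (foliar-N proxy) | – | 3.5 | 1–8 (held fixed) |
| lcma | leaf C mass per area | g C m⁻² | 60 | fixed |

The default retrieved set is exactly the ten process parameters
`f_a, f_f, f_r, k_f, k_r, k_w, k_lit_min, k_lit_dec, k_som, θ` (plus
`clab0` for deciduous sites). LCMA is measured in the field and treated
as a constant; holding the photosynthesis-side constants (`canopy_eff`,
ACM coefficients) and the moisture-scalar shape fixed concentrates the
retrieval on allocation and turnover, which the stock streams actually
constrain. Priors are independent uniforms on the bounds above, chosen
from commonly reported tissue longevities and allocation ranges for
temperate/subtropical forests.

## Likelihood, constraints, sampler

The likelihood is the product over streams of independent Gaussians with
one standard deviation `σ_j` per stream. When a stream does not carry its
own σ, defaults are used: 10% of the stream mean for tissue biomass, 20%
for LAI and annual litterfall, 15% for SOC, and 0.5 g C m⁻² d⁻¹ for
daily NEE.

Ecological and dynamic constraints (EDCs) are named, individually
toggleable hard-rejection rules: `f_f + f_r ≤ 0.9`; leaves and fine roots
turn over faster than wood; litter processes faster than SOM;
`0.2 ≤ f_a ≤ 0.8`; and, on the simulated trajectory, no pool below
1e-3 g C m⁻² or above 10× its initial stock.

The sampler is Metropolis simulated annealing: a geometric cooling phase
from `t0 = 100` to 1 over the first half of `n_iter` (acceptance
probability `min(1, exp(Δlog L / T))`), doubling as burn-in, followed by
a sampling phase at T = 1 whose states are retained (thinning 1). The
proposal is an adaptive-Metropolis step in [0,1]-normalized parameter
space, reflected at the bounds: a global factor, tuned during cooling
toward 25–40% acceptance and frozen afterwards, times the Cholesky factor
of the running chain covariance (scaled 2.38/√k). The covariance keeps
adapting with diminishing influence through the sampling phase, which is
the standard ergodic form of adaptive Metropolis; plain per-coordinate
widths mixed too slowly in this correlated 10-dimensional posterior and
produced badly underdispersed credible intervals. Sampler calibration is
verified two ways: a Kolmogorov–Smirnov test against the closed-form
posterior on a 1-D conjugate Gaussian toy, and agreement of the sampled
marginal standard deviations with a Laplace (inverse-Hessian)
approximation at the MAP on the synthetic benchmark.

Non-steady state is taken seriously: initial `Cf, Cr, Cw, Csom` are fixed
at the earliest observed stocks, the initial litter stock comes from the
site configuration (a litter-layer survey value), and only the deciduous
`Clab(0)` is retrieved. There is no spin-up anywhere.

## Turnover times and products

Turnover times are "stock over outgoing flux" with multi-year means over
whole calendar years: `τ_veg = C_live/(litterfall + Ra)` (litterfall here
is the turnover leaving *all* live pools), `τ_soil = C_dead/Rh`,
`τ_eco = (C_live + C_dead)/(Ra + Rh)`. Daily mean fluxes are annualized
with 365.25 d yr⁻¹, and the equilibrium cross-check uses the same
convention, so the two agree to ~1e-12 at a fixed point. Note that
`τ_eco` is *not* bracketed by `τ_veg` and `τ_soil`: litterfall is an
internal transfer at ecosystem scale and drops out of the ecosystem
denominator, so `τ_eco` routinely exceeds both.

Annual products are calendar-year sums of daily fluxes and means of daily
stocks; `NEP = GPP − Ra − Rh` equals the year's total pool change
identically, because both derive from the same conservative update.
Across-site summaries report unweighted means (total stock in kg C m⁻²,
soil share of total in %); per-site `total_c` is `biomass + SOC`, with
the litter pool excluded from "SOC" (the measured quantity maps to the
SOM pool alone).

Fit statistics are squared Pearson correlation (R²), RMSE, bias and the
Taylor components (sd ratio, correlation, centered RMSD). Sensitivity
analysis perturbs each parameter ±10% one at a time (clipping at the
prior bounds, recorded) and reports `VR` (% change of annual-mean NEE,
GPP, Ra, Reco and mean total stock) and `β = VR/ΔP%`.

## Synthetic data

The generator emulates a humid subtropical monsoon site: sinusoidal
annual cycles in temperature (16 ± 9 °C), PAR (2.5–9 MJ m⁻² d⁻¹),
relative humidity and soil moisture, with seeded Gaussian day-to-day
noise and exponential wet-day precipitation peaking in summer.
Observations follow the monitoring-network cadence — tissue biomass and
SOC in years 0, 5, 10; annual litterfall; quarterly LAI (mid-quarter
dates); daily NEE — with Gaussian noise at the default σ per stream and
negative draws of non-negative quantities truncated at zero (flagged).
True parameters are uniform draws from the priors, resampled until the
parameter-level EDCs pass. The default site is evergreen (the deciduous
preset exists but phenology makes the recovery benchmark harder to
interpret); initial stocks are mature-forest magnitudes (Cw 9000,
Csom 8500, Cf 250, Cr 420, Clit 350 g C m⁻²).

What the generator does *not* emulate: autocorrelated weather and
climate trends, observation biases and non-Gaussian errors, missing-data
patterns (a missingness option exists for gap-filling tests), species
composition, disturbance. Passing the recovery benchmark therefore shows
the estimator is correct and well-calibrated under its own assumptions,
not that real-site retrievals reach the same accuracy.

## Numerical choices

- Dates ISO-8601; 1-based day of year; daily explicit Euler, no sub-daily
  integration. Trajectories are bit-reproducible for identical inputs.
- The simulation kernel is JIT-compiled with numba (pure-Python fallback
  when unavailable); an 11-year forward run costs ~0.4 ms, which keeps a
  50 000-iteration retrieval near 20 s on one core.
- CSV round trips are lossless: `%.17g` on write, `round_trip` float
  parsing on read.
- 3-σ outlier screening uses the full-series mean/sd once (no
  re-estimation); zero sd flags nothing. Gap filling interpolates runs of
  1–2 missing days linearly and regresses longer (or boundary) runs on a
  neighbour series, requiring ≥ 10 co-observed days.
- Equilibrium tests run at latitude 0 (constant day length) so constant
  drivers give a true fixed point.
- Problem sizes in the shipped checks: 3–5-year driver sets for
  unit-level oracles, a 240-year constant-driver run for the fixed point,
  and the 10-seed × 50 000-iteration benchmark for recovery; these sizes
  give stable statistics while keeping the full suite fast.

## Known limitations

- **Fine-root allocation is weakly identified.** With fine-root stocks
  observed three times in 11 years at 10% noise, the inflow `f_r·NPP` and
  outflow `k_r·Cr` form a ridge; the posterior constrains their ratio
  much better than either factor. When the true `f_r` is small
  (~0.05–0.1), a 20%-relative-error recovery of `f_r` is beyond the
  information content of the data (posterior sd ≈ 0.03), whatever the
  sampler does. `f_a` and `f_f` recover to a few percent on the same
  data.
- **Fixed noisy initial states bias the fit.** Fixing initial pools at
  observed (noisy) stocks — the price of avoiding spin-up — injects model
  error: the pseudo-true parameters shift by roughly one posterior
  standard deviation on sensitive parameters, so 90% credible intervals
  cover the generator's truth at somewhat less than nominal rate.
- Single homogeneous soil pool; no DOC export, disturbance, nitrogen
  cycle or demography. Southern-hemisphere phenology is not handled.
- EDCs enter as hard rejections; a penalty formulation may behave
  differently near constraint boundaries.
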