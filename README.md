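# dalecmdf — non-steady-state carbon model–data fusion for forests

`dalecmdf` estimates how forest ecosystems allocate, store and turn over
carbon by fusing a daily carbon box model (DALEC) with the kind of
long-term, irregularly sampled observations that ecosystem monitoring
networks actually produce: tissue biomass from ~5-yearly inventories,
annual litterfall, at-least-quarterly leaf area index (LAI), 5-yearly
layered soil organic carbon (SOC), and optionally daily eddy-covariance
NEE. It is written for ecosystem modellers and carbon-cycle researchers
who need site-level allocation coefficients, turnover times and
time-continuous C sequestration products (NEP, NPP, stocks) without
assuming the ecosystem is in steady state.

## The model and the retrieval

DALEC tracks five pools (foliage `Cf`, fine roots `Cr`, wood `Cw`, litter
`Clit`, soil organic matter `Csom`; plus a labile pool `Clab` for
deciduous canopies), each updated daily by

    C_i(t+1) = C_i(t) + I_i(t) − k_i C_i(t),    C_i(0) = C_i0

GPP comes from the Aggregated Canopy Model (ACM) driven by LAI
(`= Cf/LCMA`), light, temperature and CO₂; a fraction `f_a` of GPP is
respired (Ra), and NPP is split between foliage (`f_f`), fine roots
(`f_r`) and wood (the remainder). Litter and soil decomposition rates are
scaled by `exp(θ·Ta)` and a soil-moisture factor `(Sw/Sc)^b`.

Parameters **P** are retrieved by maximising/sampling the Gaussian
likelihood over all observation streams *j*,

    log L(P) = Σ_j Σ_i [ −½ln(2π) − ln σ_j − (x_ji − μ_ji(P))² / 2σ_j² ]

with a Metropolis simulated-annealing chain (geometric cooling T₀ → 1,
then posterior sampling at T = 1) under ecological and dynamic
constraints (EDCs). Crucially, initial pools are fixed from the earliest
stock observations — no spin-up, no steady-state assumption — so the
retrieval is valid for aggrading forests in dynamic disequilibrium.

Products derived from the optimised forward run include disequilibrium
turnover times (stock over outgoing flux, multi-year means):

    τ_veg = C_live / (litterfall + Ra)
    τ_soil = C_dead / Rh
    τ_eco = (C_live + C_dead) / (Ra + Rh)

annual GPP/Ra/Rh/NPP/NEP tables, Taylor-diagram fit statistics, and a
±10% one-at-a-time parameter sensitivity index β.

## Worked example

Forward-run five years of generated seasonal drivers with the default
evergreen parameterisation and summarise the products:

```python
from dalecmdf import (ParameterVector, gen_met_drivers, run_forward,
                      compute_annual_products, compute_turnover_times)
from dalecmdf.synthetic_data import DEFAULT_INIT

drivers = gen_met_drivers(5, seed=0)
traj = run_forward(drivers, ParameterVector(), DEFAULT_INIT)
print(compute_annual_products(traj)[["year", "gpp", "npp", "nep"]].round(1))
print(compute_turnover_times(traj))
```

prints (g C m⁻² yr⁻¹; stocks g C m⁻²; τ in years):

```
 year    gpp    ra    rh   npp   nep  biomass_c    soc
 2005 1361.5 612.7 646.4 748.8 102.4     9788.6 8572.5
 2006 1362.9 613.3 542.7 749.6 206.9    10026.5 8589.3
 2007 1370.6 616.8 538.9 753.8 214.9    10249.3 8577.0
 2008 1384.3 622.9 556.2 761.4 205.2    10461.5 8573.4
 2009 1372.2 617.5 549.0 754.7 205.7    10659.3 8574.3

tau_veg = 8.89 yr   tau_soil = 15.36 yr   tau_eco = 16.00 yr
```

The site fixes ~1370 g C m⁻² yr⁻¹ by photosynthesis, respires about 45%
autotrophically, and sequesters ~200 g C m⁻² yr⁻¹ (a net sink), with
vegetation carbon residing ~9 years and dead organic carbon ~15 years.

A full assimilation on a synthetic site with known truth:

```python
from dalecmdf import make_case, assimilate_site, MDFConfig

case = make_case(seed=1)                   # 11 years, network cadence
res = assimilate_site(case.drivers, case.streams, case.site,
                      MDFConfig(n_iter=50_000, seed=7))
print(res.map_params.f_a, case.truth.f_a)  # retrieved vs true
print(res.credible_interval(0.90))
```

The same workflow is scriptable from the shell:

```
dalecmdf synth --seed 1 --out case/
dalecmdf qc --drivers case/drivers.csv --observations case/observations.csv --out qc.json
dalecmdf simulate --drivers case/drivers.csv --params case/truth_params.json \
    --init '{"cf":250,"cr":420,"cw":9000,"clit":350,"csom":8500}' --out traj.csv
```

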