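# popimpact

Bayesian multi-stage assessment of energy-development impacts on wildlife
populations, built around the monitoring designs used for greater
sage-grouse near geothermal developments: repeated counts at fixed breeding
sites (leks), individual telemetry encounter histories, nest/clutch/brood
records, predator point-count surveys, and raster/vector landscape layers.

The package answers three questions in sequence:

1. **Did population patterns change, and over what footprint?**
   A before-after control-impact (BACI) state-space model of lek counts
   partitions log abundance into a latent walk and observation error,

   ```
   log y[l,j]   ~ Normal(log N[l,j], σ²_obs)
   log N[l,j+1] = log N[l,j] + r[l,j]
   r[l,j]       ~ Normal(α_l + β_tp + η_j, σ²_r)
   ```

   with a constant effect `β_tp` for each period-treatment cell.  Candidate
   impact zones (2, 5, 10, 15, 20, 30 km from infrastructure) are compared
   by PSIS-LOO; evidence is summarised on the λ = e^r scale through the
   BACI ratio `R = (λ_i,b/λ_c,b) / (λ_i,a/λ_c,a)` with weak / moderate /
   substantial grades at 0.85 / 0.90 / 0.95 posterior mass above 1, plus
   CI-contribution and CI-divergence contrasts.  A parallel Bernoulli GLM
   tests changes in lek *absence* rates over the final two years of each
   period.

2. **Which demographic processes drive the change?**
   Two-stage shared-frailty survival models: a control likelihood
   `UH = exp(Σ β_c X_c + ψ_a + Z_k + Γ_i + Λ_j)` fitted at undeveloped
   sites runs concurrently with an impact likelihood
   `UH_G = exp(LUH_P + Σ δ_g X_g + Ω_i)`, where the predicted log unit
   hazard `LUH_P` is rebuilt from the control parameters at every MCMC
   iteration, so confounder uncertainty propagates into the development
   effects δ (distance to infrastructure, terrain impedance, predator
   density).  The same pattern on the logit scale covers renest propensity,
   hatchability and chick survival; clutch size is a Poisson log-link fit;
   unobserved stages come from informative priors.  Development covariates
   carry Bayesian-Lasso or indicator-selection priors (prior inclusion
   0.75, strong heredity for interactions) summarised as Bayes factors.

3. **Where would development hurt most?**
   Vital rates compose into fecundity
   `g = np1·c1·ns1·h·cs·js + (1−ns1)·np2·c2·ns2·h·cs·js` and an
   age-structured projection `NT[j+1] = Σ NT·g/2 + Σ NT·jan`, giving the
   finite rate of change λ_P = NT[j+1]/NT[j].  The before-minus-after
   Δλ_P surface, weighted by an abundance index and summed in 2/5/10-km
   buffers, ranks candidate development sites.

All posterior sampling runs through a common adaptive-Metropolis engine
with split-R-hat/ESS diagnostics and PSIS-LOO via ArviZ.  A synthetic-data
module generates every input with known ground truth, so the whole
pipeline is testable end to end without any data download.

## Worked example

```python
import numpy as np
from popimpact import growth, mcmc
from popimpact.synthetic import SimConfig, simulate_lek_counts

cfg = SimConfig(seed=3, n_leks=200, true_beta_tp=(0, 0, 0, -0.2))
counts = simulate_lek_counts(cfg)                    # 200 leks x 14 years
(zone,) = growth.assign_zones(counts, [10.0])
draws = growth.fit_ssm(counts, zone, iters=8000, burn_in=4000, seed=1)
stats = growth.baci_ratio(growth.derive_lambda(draws))
print(f"R_BACI median {np.median(stats.r_baci):.3f}  "
      f"mass>1 {stats.mass_above_1:.3f}  evidence: {stats.evidence}")
```

prints

```
R_BACI median 1.182  mass>1 1.000  evidence: substantial
```

— the simulated after-impact decline of −0.2 on the log scale corresponds
to a BACI ratio of e^0.2 ≈ 1.22; the posterior median lands nearby and
essentially all posterior mass sits above 1, so the impact is graded
"substantial".  The same objects feed `mcmc.psis_loo` for zone comparison
and the absence, demography and ranking stages (see `popimpact run --help`
for the pipeline CLI: `simulate`, `fit-growth`, `fit-absence`,
`fit-demography`, `tis`, `rdi`, `rank-sites`, `run`).

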