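# Methods

This note documents the statistical models, their priors and numerical
implementation, the synthetic study system the test suites run against,
and the design choices made where more than one reasonable option existed.

## 1. BACI growth-rate model (`popimpact.growth`)

**Model.** Annual maximum counts per population node (lek) follow a
Gaussian state-space model on the log scale: observed log counts are the
latent log abundance plus observation noise `σ_obs`; the latent state
advances by an intrinsic growth rate `r`, itself Normal with mean
`α_l + β_tp + η_j` and interannual spread `σ_r`.  `β_tp` is a constant
effect for each of the four period-treatment cells (before/after ×
control/impact); `α_l` (lek) and `η_j` (year) are zero-centred varying
effects with estimated standard deviations.  The transition into year
`j+1` inherits that year's period label.  The impact-zone boundary is
closed on the impact side (`distance ≤ threshold` ⇒ impact).

**Inference.** Conditional on the cell effects, year effects and the four
variance parameters, the latent log abundance and the lek offset `α_l` are
jointly Gaussian, so they are marginalised *exactly* by a per-lek Kalman
filter over the augmented state (log N, α).  MCMC therefore runs over
roughly twenty hyper- and cell-parameters rather than thousands of
latents.  The initial state uses the stated vague prior
Normal(log of first observed count, sd 10); standard deviations get
half-Normal(0, 2) priors (sampled on the log scale with the Jacobian);
cell effects get Normal(0, 10²).  The pointwise log likelihood recorded
for PSIS-LOO is the one-step-ahead prediction-density factorisation of the
marginal likelihood (each observation's contribution given its lek's
past), which sums exactly to the total.

**Identifiability and λ.** The likelihood identifies `β` cells only up to
common shifts traded against the period means of `η` (and group means of
`α`); the hierarchical priors pin those directions softly.  Reported cell
growth rates therefore use the *cell mean growth*:
`λ_cell = exp(β_cell + mean of η over the period + group mean of the
filtered posterior-mean lek offsets)`.  The BACI ratio is algebraically
invariant to these shifts, so evidence grades do not depend on the
convention.  On noise-free constant-count data the cell mean growth
concentrates at zero as it must, while `β` alone would not.

**Zero counts.** Zero counts are treated as missing observations and
positive counts enter on the plain log scale.  The alternative
log(count + 1) transform (available via `zero_counts="log1p"`) keeps zeros
in the likelihood but compresses the log scale at small abundance: in
recovery experiments with a declining impact group its estimated declines
were systematically attenuated (credible intervals sitting wholly above
the generating value), whereas the plain-log form is unbiased.  Excluding
zero counts from log-scale trend models is also the common field practice.
The state-space model still *predicts* low abundance at those lek-years;
only the likelihood contribution of the zero itself is dropped.  Absence
analysis (below) uses the zeros directly.

**Evidence.** One-sided posterior mass of the BACI ratio above 1.0 is
graded weak / moderate / substantial at 0.85 / 0.90 / 0.95 (highest grade
whose threshold is met).  For a one-sided exceedance statement the
highest-density and tail-mass formulations coincide in the relevant
regime, so the simpler tail mass is computed.  CI-contribution
`|λ_i,a − λ_i,b| − |λ_c,a − λ_c,b|` and CI-divergence
`|λ_i,a − λ_c,a| − |λ_i,b − λ_c,b|` are evaluated per draw.

## 2. Absence-rate model (`popimpact.absence`)

Counts are subset to the final two years of each period; a node is absent
within a period iff both retained years have a zero count (any second-year
activity confirms presence).  Absence is modelled with a cell-means
Bayesian logistic regression, Normal(0, 1.5²) priors on the four logit
intercepts, and the same BACI ratio machinery applied to the absence
probability A.  Because a *rise* in absence after impact pushes the ratio
to the opposite side of 1 from a *fall* in growth, both one-sided masses
are reported and the evidence grade should be read against the direction
of interest.  Cells with all-identical outcomes are fitted under the prior
and flagged.

## 3. Two-stage demographic models (`popimpact.demography`)

**Survival.** Piecewise-constant-hazard likelihood at discrete intervals:
an interval survived contributes `exp(−UH)`, a death contributes
`1 − exp(−UH)`, censored tails contribute survival terms only (censoring
treated as non-informative).  This event likelihood makes the cumulative
hazard and survival identities (`CH = Σ UH`, `S = e^−CH`) exact
consequences.  The control stage estimates confounder coefficients, age
offsets (adult as reference class), per-interval baseline log hazards, and
zero-centred site and year effects with estimated sds.  The impact stage
rebuilds the predicted log unit hazard at impact sites from the
concurrently sampled control parameters and locally measured covariates —
*excluding* the control-site effect, whose mean is zero — then adds the
development coefficients `δ` and per-site constants `Ω`.  Year effects are
matched by calendar year (a flag zeroes them instead).  Both likelihoods
live in one posterior, so the spread of `δ` reflects the full confounder
uncertainty; freezing the control block at posterior medians (provided for
comparison) measurably narrows `δ` exactly when impact-site confounders
are collinear with the development covariates — the regime the two-stage
design exists to handle.

Priors: confounders and baselines Normal(0, 10²) ("non-informative");
varying-effect sds half-Normal(0, 2); impact-site constants
Normal(0, 2.5²); development coefficients Normal(0, 10²) without
selection, or the selection priors of §4.

**Binary vital rates.** Renest propensity (Bernoulli), hatchability
(Binomial, trials = clutch) and chick survival to 50 days (Binomial,
trials = eggs hatched) use the same two-stage construction on the logit
scale: the control-stage intercept+confounder prediction `P`, evaluated at
impact-site covariates per draw, plus `Σ δ X_g + Ω`.

**Clutch size.** Single Poisson log-link likelihood,
`log N_cs = ψ_age + T_attempt` with the first attempt as reference for
`T` (one redundancy removed; the paper's formulation indexes both
freely).  No control stage: clutch size is assumed unaffected by
development, so no confounder adjustment is needed.

**Nest survival.** Daily intervals with a constant daily baseline, a
nest-attempt effect, optional covariates, and a hen-level Normal frailty
shared across a hen's nests.  The frailty is integrated out by 15-node
Gauss-Hermite quadrature rather than sampled, keeping the chain dimension
fixed; the per-hen likelihood is the quadrature average of the product of
her nests' daily-hazard terms.

**Unobserved stages.** First-nest propensity and juvenile survival are
drawn from user-specified informative priors (Beta for probabilities;
point mass and uniform also supported), with draw counts matched to the
fitted posteriors so the stages compose per draw in the matrix model.

## 4. Selection priors (`popimpact.selection`)

Development coefficients can carry either of two selection priors, used as
alternatives per model run (indicator selection is the default mode;
the Lasso serves as a sensitivity analysis):

* **Indicator selection** — each coefficient is multiplied by a Bernoulli
  indicator with prior inclusion 0.75.  Interactions obey strong heredity:
  conditional inclusion 0.75 when all parents are in, exactly 0 otherwise,
  so the joint prior puts zero mass on an orphaned interaction.  In the
  sampler, indicators flip through Metropolis moves restricted to
  heredity-valid states (a parent cannot switch off while a child is in;
  a child cannot switch on without all parents), which keeps the move set
  symmetric and the chain reversible.  Coefficients under selection use a
  Normal(0, 1) slab appropriate for standardised covariates — a diffuse
  slab would make the indicator flips mix poorly.
* **Bayesian Lasso** — a shared Laplace(0, τ) prior with τ ~ Uniform(0, 10);
  τ is marginalised on a 64-point log grid inside the prior density, which
  is equivalent to sampling it up to quadrature error.

Evidence per term is the Bayes factor from posterior vs prior inclusion
odds, graded on the conventional 1 / 3 / 20 / 150 boundaries; saturated
indicators are reported as odds bounds at half a Monte-Carlo draw from the
boundary and flagged.  Spatial extents (30, 75, 167.9, 439.5, 1451.7 m
radii as applicable) and distance-effect forms (plant vs footprint,
Euclidean vs exponential decay) are reduced covariate-by-covariate by
single-covariate PSIS-LOO before the full model is assembled.

## 5. Matrix model (`popimpact.matrix`)

Fecundity composes first- and second-attempt nesting outcomes; the annual
projection sums recruits (`Σ NT g / 2`, the divisor assuming an equal sex
ratio at hatch) and survivors.  Recruits enter the yearling class and
surviving yearlings graduate to adults (the printed recursion tracks only
totals; a flag reproduces that literal total-only form, which has the same
age-summed trajectory).  λ_P is the ratio of successive age-summed totals;
it is undefined (error) at zero total abundance, scale-invariant, and in a
one-age model with constant rates equals `g/2 + jan` exactly.  The impact
contrast Δλ_P is before-minus-after per draw, positive when development
reduces growth.

## 6. Spatial tools (`popimpact.spatial`, `popimpact.raster`)

Rasters are regular 30-m grids in planar metre coordinates, row-major from
the north-west origin with cell-centre semantics; GeoTIFF I/O goes through
`tifffile` with the geotransform in a JSON ImageDescription tag, and point
sets serialise as GeoJSON.

* **Topographic impedance (TIS).**  For every start cell, the supercover
  line of cells to the source (every cell the segment touches, traced by
  an Amanatides-Woo grid walk with corner handling) is extracted; a
  baseline elevation is interpolated at constant slope between the start
  and source cell elevations; the cell's TIS is the maximum
  (baseline − elevation) along the line.  The literal below-line
  convention is the default — terrain dipping under the sightline scores
  high; a `sign="above_line"` flag flips to occlusion by high terrain,
  since both readings of the construction are defensible.  Nodata along a
  line propagates to its start cell with a count warning.  The
  implementation is verified against dense sub-cell sampling of the same
  segments within a per-line interpolation tolerance.
* **Distances** to nearest infrastructure (shapely geometries; polygon and
  line *edges*), Euclidean or `exp(−d/scale)` decay.
* **Neighbourhood percent cover**: mean over cells whose centres fall
  within the radius.
* **Candidate clustering**: single-linkage components at a 4-km threshold;
  merged clusters carry summed numeric attributes at their centroid.
* **Site ranking**: per site and buffer (2/5/10 km), the sum of the
  aligned (Δλ_P × abundance-index) product over in-buffer cells, ranked
  descending.

## 7. Distance sampling (`popimpact.ravens`)

Half-normal detection with covariates on the log scale parameter; five
distance bins with cut-points 225/450/675/900/1125 m and truncation at
1.125 km.  For a bird uniform on the disc the joint bin-and-detect
probability has the closed form
`ψ_b = (2σ²/w²)(e^{−a²/2σ²} − e^{−b²/2σ²})`, implemented in an `expm1`
form stable for σ ≫ w and verified against quadrature to 1e−8.  The scale
is estimated by maximising the multinomial likelihood of bin membership
conditional on per-survey totals (a full abundance-mixture model is not
needed for a density index); site/year group effects are added only for
groups with at least 60 detections, smaller groups sharing the baseline.
Density per survey is the Horvitz-Thompson form `n / (p̂ π w²)` with
`p̂ = Σ ψ_b`, and each nest's raven density index (RDI) is the mean of
in-radius (3.5 km), year-matched survey densities — a pooled-count mode is
available since averaging vs pooling is a free choice; nests with no
eligible survey are flagged missing.

## 8. Posterior computation (`popimpact.mcmc`)

The sampler is adaptive random-walk Metropolis run as independent chains
advanced in lock-step (vectorised likelihood evaluations).  During burn-in
the step size follows a Robbins-Monro recursion toward 0.25 acceptance and
the proposal covariance is re-estimated every few hundred iterations from
the pooled recent history; both are frozen at the end of burn-in so
retained draws come from a fixed kernel.  Retained draws are exactly
`chains × (iters − burn_in) / thin`; the conventional full-scale schedule
(3 × 50,000, burn-in 40,000, thin 10 → 3000 draws) is the default, and the
recovery suites run a reduced desk-scale schedule (3 × 8,000 for the
count models, 3 × 6,000 for the survival models, no thinning) chosen so
the full acceptance suite completes in minutes on one core while split
R-hat stays near 1.  Convergence is flagged (never silently passed) at
split R-hat > 1.1 via ArviZ, which also provides ESS and PSIS-LOO
(`elpd`, `looic = −2·elpd`, pointwise terms and Pareto-k diagnostics).
Model comparison returns the lowest-LOOIC candidate with ties broken
toward the smallest impact-zone threshold.  The growth-model likelihood
kernel is JIT-compiled with numba.

## 9. Synthetic study system (`popimpact.synthetic`)

The generator mirrors the target monitoring design with every parameter
explicit and seeded (independent substreams per output):

* **Lek counts** — 103 leks by default, 7 before + 7 after years,
  distances uniform on [0, 60] km, generative impact footprint 10 km,
  initial counts around 25 males (log-normal, sd 0.5), observation sd 0.2,
  growth sd 0.1, lek and year effect sds 0.05, counts rounded with zeros
  allowed so the absence pipeline is exercised.
* **Encounter histories** — 400 birds (≈ a quarter at two development
  sites, mirroring the real design's proportion), 12 monthly intervals,
  baseline hazard 0.04/month (≈ 0.62 annual survival, typical of
  grouse-sized birds), confounder effects (0.5, −0.5), development effect
  −0.6 on an exponential-decay exposure covariate, site/year effect sds
  0.2/0.15, 2% per-interval random right-censoring; every bird ends dead
  or censored.
* **Reproduction** — 300 hens; daily nest hazard 0.02 over 38 days; renest
  propensity logit −0.4 after a failed first attempt; clutch means 8.0 /
  6.5 (attempt 1 / 2) with a small adult effect; hatchability 0.9; chick
  survival 0.35.
* **Landscape** — 1000 × 1000 cells at 30 m (30 × 30 km) so the 4-km
  clustering and 2/5/10-km buffers operate at their real scales; DEM =
  plane + Gaussian bumps; abundance index a smoothed field squashed to
  [0, 1]; 25 clustered candidate points with MWh attributes.
* **Predator surveys** — 500 points, true density 2 birds/km², half-normal
  σ = 400 m, binned at the five stated cut-points.

What the synthetic system deliberately omits: spatial correlation between
leks, imperfect/variable detection in counts (observation error is
homoscedastic), seasonal hazard shape (baseline flat by default),
covariate measurement error, and any attempt to mimic real Great Basin
topography or abundance surfaces.  Passing recovery tests therefore
demonstrates the estimators are correct *under the stated design*, not
that real monitoring data meet those assumptions.

## 10. Numerical notes and limitations

* Event probabilities use `−expm1(−UH)`; logit likelihoods clip the linear
  predictor at ±500; the Kalman filter runs in double precision with a
  vague (variance 100) initial state.
* The degenerate all-censored likelihood reduces to a product of survival
  terms; a dataset with no events at all is flagged as hazard-unidentified.
* Ties in LOOIC comparisons resolve to the smallest distance threshold so
  the reported footprint is conservative.
* The pipeline's ranking stage builds its Δλ_P surface from posterior
  medians (median vital rates, median hazard shift applied through an
  exponential-decay exposure within 10 km of each clustered candidate);
  a fully propagated per-draw surface would scale linearly in draws and is
  straightforward but unnecessary for a ranking demonstration.
* Random-walk Metropolis limits practical dimension: site/year/hen varying
  effects are kept few (or integrated out — Kalman for lek latents,
  quadrature for hen frailties).  Models with hundreds of free varying
  effects would need a gradient-based backend behind the same `ModelSpec`
  contract.
* Recovery and calibration suites are Monte-Carlo experiments with fixed
  seeds and pre-registered replicate counts; their pass thresholds
  (e.g. ≥ 18/20 coverage) sit at the design's nominal operating point,
  not with wide safety margins.
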