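# Methods

This note documents the models, the numerical choices and the synthetic
study conditions implemented in `fluxlue`, and what the passing tests do
and do not establish about real flux data.

## 1. From daily records to the unit of analysis

The unit of analysis is a growing-season, 15-day composite of light use
efficiency with window-averaged predictors.

**Photon flux.** Daily PPFD (mol m⁻² d⁻¹) is a fixed fraction of daily
mean shortwave radiation: 2.04 µmol photons per joule, times 86 400 s.

**Cloudiness and diffuse light.** The cloudiness index is CI = 1 − S_t/S_o
(surface over top-of-atmosphere shortwave); days with S_o ≤ 0 are flagged
undefined and excluded from CI-dependent terms. Diffuse transmittance
follows the one-parameter Bristow form

    T_d = T_T · (1 − exp(0.6·(1 − B/T_T)/(B − 0.4))),   0.4 < B ≤ 1,

which forces T_d = 0 at T_T = B (clear sky) and T_d → T_T as T_T → 0. B is
estimated by bounded 1-D least squares (tolerance 1e-8) on the sites that
report diffuse radiation, and the fitted relation gap-fills the rest.
Records with observed diffuse flux are never overwritten.

**fAPAR.** Sparse observations are cleaned (values of exactly 1 dropped
as saturated; points further than 3×IQR from the site median dropped as
outliers) and interpolated to daily values with a cubic smoothing spline
whose penalty is chosen by generalized cross-validation. A site with
fewer than four surviving observations is excluded and reported in the
audit. Daily values are clipped to (0, 1].

**Site-day filters.** A day is dropped when (in this precedence order,
each drop counted once) the gap-filled fraction is ≥ 0.5 (strict "less
than half" reading — exactly half is dropped), GPP is negative, absorbed
light PPFD×fAPAR is below 0.1 mol m⁻² d⁻¹ (the "near-zero absorbed
light" cut is not quantified anywhere authoritative, so the threshold is
configuration-exposed; 0.1 removes ratio blow-ups without touching
growing-season data), or the daily apparent LUE exceeds 0.12 mol C mol⁻¹
photons. The LUE cap is applied to site-days, not windows; a window mean
can in principle not exceed the cap if every contributing day passed.

**Growing season.** Per site-year, daily GPP is scaled so its 0.05
quantile maps to 0 and its 0.95 quantile to 1 (quantiles by linear
interpolation of order statistics); days strictly above 0.2 on that scale
are retained. Site-years with fewer than 30 valid days, or a degenerate
quantile range, are excluded. Quantiles are computed on quality-filtered
days (the alternative — all days — is a one-line change).

**Compositing.** Within a site, consecutive runs of retained calendar
days are cut into non-overlapping 15-day blocks starting at each run's
first day; trailing stubs shorter than 15 days are discarded, so the
window count equals Σ floor(run/15). Per window, LUE = Σ(GPP/12.011) /
(ΣPPFD × mean fAPAR) — the 12.011 g mol⁻¹ molar mass of carbon is forced
by the mol-per-mol units of LUE. Window CI is the energy-consistent
ratio of sums 1 − ΣS_t/ΣS_o (a mean-of-daily-ratios variant is a config
switch); all other predictors are plain window means, and the window year
is the calendar year of its first day.

## 2. The gamma mixed model

LUE is strictly positive and right-skewed, so the response is modelled as
gamma with log link; the shape ν is estimated by maximum likelihood
jointly with everything else. Random intercepts for site and for year
nested in site are Gaussian on the log scale.

**Fitting.** The marginal likelihood integrates the random effects out by
a Laplace approximation. At each evaluation of the variance/shape
parameters (optimized on log scales by L-BFGS-B, tolerance ~1e-11), the
fixed effects and random-effect modes are profiled by an exact Newton
solver on the joint penalized log-likelihood; the per-site block
structure of the random-effects Hessian reduces each Newton step to one
p×p solve plus small per-site solves, so a fit on 3 000 windows takes
well under a second. Starting values are the gamma GLM with zero variance
components, making fits deterministic. ML (never REML) likelihoods are
reported so AIC/BIC comparisons across fixed-effect designs are valid.
Against an independent 15-node adaptive Gauss–Hermite quadrature oracle
the Laplace log-likelihood agrees to ~3e-4 on a 3-site instance.

Fixed-effect standard errors are the square roots of the β-block of the
inverse joint penalized Hessian (the conditional covariance, as mixed-
model software conventionally reports). A variance component estimated
below 1e-6 is reported as a boundary zero with a flag.

**Degrees of freedom.** df = fixed coefficients + variance components +
gamma shape. Software bookkeeping of the dispersion parameter differs
between packages; rankings are unaffected because the constant cancels
within a ladder.

**Design choices.**
- The quadratic temperature term uses raw centered temperature, not an
  orthogonal polynomial basis: the column span (hence fit, likelihood and
  AIC) is identical, and the vertex formula T_opt = center − β₁/(2β₂)
  is then direct. Orthogonal polynomials would change the printed
  coefficients but nothing the package reports except their labels.
- The cloudiness term enters as log CI (consistent with the other
  concave, positive-domain predictors); a linear-CI term is available as
  `ci_linear` for sensitivity work, as are interaction terms CI:fAPAR and
  T_d:fAPAR and an optional PPFD term.
- The selection ladder (M01–M08) runs backward from a maximal design
  (adding CO₂, elevation and the CI:fAPAR interaction) to a
  no-transformations linear design, all sharing the year-in-site random
  structure, on a common row set; the AIC minimizer is flagged.

**Variance partition.** Fractions are computed on the link scale:
(σ²_site, σ²_year, σ²_res)/total, where σ²_res is the variance of working
residuals (y − μ)/μ with μ including the random effects. They sum to one
by construction. The response-scale alternative would differ by a
delta-method factor that cancels in the ratios to first order.

**Response curves.** Conditional curves evaluate the fixed term along an
observed-range grid with every other numeric predictor at its median.
Partial residuals add the working residual to the focal term's
contribution (on top of the all-median baseline) and are shown on the
response scale. The pointwise band uses the delta method with the
diagonal of the coefficient covariance — conservative, since it ignores
negative covariance between the intercept and slopes.

**Cross-validation.** Leave-one-site-out folds fit a fixed-effects-only
gamma GLM (a mixed model cannot predict a site it has never seen) and
predict the held-out site; pooled R² is the squared Pearson correlation
of observed against predicted over all held-out rows (an SSE-based R² is
the documented alternative). The companion in-sample metric is the R² of
the full model's fixed term.

## 3. The optimality simulator

The P-model predicts χ = ci/ca from temperature, VPD, CO₂ and pressure by
balancing carboxylation against transpiration costs, and LUE as
φ0(T) · β_sm(θ) · m · √(1 − (c*/m)^{2/3}). Constants follow the published
"FULL" calibration of the rpmodel setup (β = 146, c* = 0.41,
kphio = 0.087182 with the quadratic temperature dependence of the
intrinsic quantum yield, soil-moisture stress a = 0, b = 0.733 below
θ* = 0.6; Bernacchi-type Arrhenius kinetics for Γ* and the Michaelis
constants); all are configuration-exposed because the package treats the
simulator as a fixed comparator, not a tuning target. The water-viscosity
ratio η* uses the Vogel–Fulcher–Tammann correlation in ratio form
(η*(25 °C) = 1 exactly; <1% deviation from the full Huber formulation
over 0–40 °C). Elevation maps to pressure by the standard barometric
formula. The simulator has no diffuse-radiation pathway, so its
cloudiness response is flat by construction — which is exactly what the
statistical refit to simulator output recovers (max/min of the fitted CI
curve < 1.05), together with the simulator's own temperature optimum
(grid argmax vs refitted parabola vertex agree to well under 2 °C).

## 4. Third-party model benchmarking

A model supplying daily GPP and LAI (or fAPAR) on the forcing's site-days
is pushed through the identical machinery: fAPAR from Beer–Lambert
(k = 0.5), the forcing's retained growing-season days and window grid
reused verbatim, LUE computed with the forcing's PAR as the common
denominator (so every model is judged on the same absorbed-light basis),
and the common mixed design refitted per model. Per-model failures are
isolated and reported, never silently dropped. Nash–Sutcliffe efficiency
is computed on window-level GPP by default (LUE is a switch). Because the
log link turns response scaling into an intercept shift, a model that is
a constant multiple of the truth reproduces the response *shapes*
exactly — the comparison machinery deliberately separates functional
response from flux bias.

## 5. The synthetic study conditions

Defaults are one draw of the study conditions, not dials: 50 sites ×
5 years, latitudes 28–55° N; top-of-atmosphere radiation from solar
geometry (solar constant 1361 W m⁻²); cloudiness an AR(1) with
persistence 0.7 clipped to [0.02, 0.95] (persistence gives realistic
weather runs while avoiding degenerate logs at CI = 0 or 1); temperature
a latitude-dependent seasonal sinusoid with AR(1) anomalies; log VPD
linear in temperature (slope 0.045 K⁻¹) plus its own AR(1) anomalies, so
VPD and temperature correlate but retain independent variation; soil
moisture a 2-parameter bucket (150 mm capacity, Bernoulli–exponential
rain, temperature-scaled draw-down) — a deliberately stylized stand-in
for a full water-balance simulation; a logistic green-up/senescence
canopy observed every 4 days with 5% lognormal noise, occasional
saturated (=1) and outlier values; diffuse radiation present at half the
sites. True daily LUE follows the mixed-model mean structure with
α = −2.1, β_T = 0.07, β_T² = −0.0035 (optimum 25 °C), β_logVPD = −0.25,
β_logSm = 0.10, β_logCI = 0.15, site SD 0.20 and year SD 0.12 on the log
scale, and GPP adds multiplicative gamma noise of shape 25 (CV 20%, the
order of daily flux-partitioning uncertainty). Half-hourly structure is
not simulated: the analysis consumes daily values. A single seed drives
one named stream per site, so subsets regenerate identically.

**Two generation routes.** `generate_site_network` emits daily records
and is the integration-test route: with noise disabled, the LUE identity
closes through the full pipeline to 1e-10. `sample_composites` draws
15-day composites directly from the mean structure and is the
calibration route for estimator-recovery studies, where the fitted model
must *be* the data-generating process. The distinction matters because
compositing real (or realistic daily) data introduces small Jensen-type
aggregation biases — the window mean of log VPD is not the log of the
window-mean VPD — which at these settings displace the log-CI
coefficient by roughly 15% of its value, several standard errors at
n = 3 000 windows. That is a property of the compositing convention
(shared with any analysis of window-averaged predictors), not of the
estimator, and is why recovery-calibration tests run at the window
level while the daily route is held to closure, sign and
temperature-optimum (±1.5 °C) checks.

**What passing tests do not show.** The generator has no spatial
correlation between sites, no disturbance or land-cover change, no
C₄ vegetation, no instrument drift, and residuals independent across
days (real GPP residuals are autocorrelated within the growing season;
the effective sample size of real composites is therefore smaller than
the nominal count). Results on real FLUXNET-style archives inherit none
of the generator's guarantees.

## 6. Numerical conventions and degenerate inputs

- FLUXNET missing sentinel −9999 maps to NaN on read and back on write.
- Quantiles: linear interpolation of order statistics throughout.
- Constant GPP series (q05 = q95) exclude the site-year; all-constant
  observed vectors make Nash–Sutcliffe undefined and raise.
- Bristow fits hitting the (0.4, 1] search boundary are flagged.
- Gamma fits with non-positive responses raise; rows with non-positive
  values under a log transform are dropped and counted in the audit.
- Every pipeline artifact carries a hash of the scientific configuration
  (paths excluded), so changing any threshold changes the hash.

## 7. Problem sizes

The shipped studies use 50 sites × 60 windows for recovery/calibration
(100 replicates) and selection (50 replicates), a 25-site × 4-year
network for the end-to-end reproduction script, and 3-site instances for
quadrature-oracle comparisons — sizes at which the Monte-Carlo bands in
the tests are tight while a full run of the suite stays in the minutes
range on one CPU.
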