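# fluxlue

Environmental controls on the light use efficiency (LUE) of terrestrial
gross primary production (GPP), as a tested, reusable analysis pipeline.

## The problem

GPP at an eddy-covariance site is, to first order, proportional to the
light the canopy absorbs:

    GPP = PPFD × fAPAR × LUE

Dividing absorbed light out of GPP isolates LUE — the residual efficiency
with which absorbed photons are converted to fixed carbon — and makes the
*secondary* environmental controls of photosynthesis visible: daytime air
temperature, vapor pressure deficit (VPD), soil moisture, and the diffuse
fraction of sunlight (proxied by a cloudiness index CI = 1 − S_t/S_o).
`fluxlue` derives growing-season, 15-day composite LUE values from daily
flux-tower-style records and models them with a gamma generalized linear
mixed model (log link),

    log LUE_ijk = α + β₁·T + β₂·T² + β₃·log VPD + β₄·log Sm + β₅·log CI
                  + a_k + a_j|k + ε_ijk

for window *i* of year *j* at site *k*, with Gaussian random intercepts
for site (a_k) and year-within-site (a_j|k). The fitted response curves
can then be compared, like for like, against mechanistic models: a
built-in optimality-based LUE simulator (P-model), or any third-party
model that supplies GPP and LAI series (fAPAR ≈ 1 − e^(−k·LAI)), with
agreement on raw fluxes summarized by Nash–Sutcliffe efficiency.

The package is aimed at biogeoscientists who want to benchmark the
*functional responses* of terrestrial biosphere models — the shape, the
strength and the sign of each environmental dependence — rather than
goodness-of-fit alone.

Because the real inputs (FLUXNET2015, MODIS fAPAR, site-model archives)
cannot ship with code, a first-class synthetic-data module generates
multi-site daily networks with the same statistical structure — seasonal
radiation and temperature, VPD correlated with temperature, bucket soil
moisture, sparse noisy fAPAR, Bristow diffuse radiation, and LUE drawn
from a known mixed model — so every stage is testable against ground
truth.

## What is inside

| module | role |
| --- | --- |
| `fluxlue.synthdata` | seeded synthetic site networks with truth sidecar; top-of-atmosphere radiation from solar geometry |
| `fluxlue.preprocess` | photon-flux conversion (2.04 µmol J⁻¹), cloudiness index, Bristow diffuse transmittance (fit + gap-fill), fAPAR outlier filter + smoothing spline, site-day quality filters, quantile growing-season mask, 15-day compositing |
| `fluxlue.glmm` | gamma mixed models via Laplace approximation, backward selection ladder, variance partition, conditional response curves with partial residuals, temperature optimum, leave-one-site-out CV |
| `fluxlue.pmodel` | optimality-based LUE simulator (optimal χ, temperature-dependent quantum yield, soil-moisture stress) and stylized one-driver experiments |
| `fluxlue.compare` | common-design refits of third-party GPP+LAI output, Beer–Lambert fAPAR, Nash–Sutcliffe efficiency |
| `fluxlue.io` / `fluxlue.cli` | FLUXNET-style CSV dialects, run configuration, provenance, `fluxlue` subcommand CLI |

## Worked example

```python
import fluxlue as fl
from fluxlue import glmm

cfg = fl.SyntheticConfig(n_sites=12, years_per_site=3, seed=42)
daily, truth = fl.generate_site_network(cfg)
composites, audit = fl.prepare_composites(daily)
print(f"{len(daily)} site-days -> {len(composites)} growing-season windows")
print(f"refit Bristow B = {audit['bristow']['B']:.3f}")

fit = glmm.fit_design(composites, glmm.ModelDesign(label="M06"))
for name, b, se in zip(fit.colnames, fit.beta, fit.beta_se):
    print(f"  {name:12s} {b: .4f} +/- {se:.4f}")
topt, _ = glmm.temperature_optimum(fit)
print(f"temperature optimum: {topt:.1f} C")
```

prints

```
13140 site-days -> 379 growing-season windows
refit Bristow B = 0.889
  (Intercept)  -1.5584 +/- 0.1717
  temp_c        0.0583 +/- 0.0015
  temp_c2      -0.0033 +/- 0.0002
  log_vpd      -0.3071 +/- 0.0253
  log_soil_m    0.1119 +/- 0.0345
  log_ci        0.1755 +/- 0.0173
temperature optimum: 26.0 C
```

The preprocessing recovers the diffuse-transmittance shape parameter the
generator used (B = 0.889); the fitted coefficients carry the generating
signs — LUE falls with VPD (β₃ < 0), rises with soil moisture and
cloudiness (β₄, β₅ > 0) — and the vertex of the temperature parabola sits
within a degree of the generator's 25 °C optimum at this sample size.

The same analysis from a shell:

```sh
fluxlue simulate --out daily.csv --sites 12 --years 3 --seed 42
fluxlue preprocess daily.csv --out composites.csv
fluxlue select composites.csv --out selection.csv
fluxlue run-all --out-dir run1 --seed 42     # whole pipeline in one go
```

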