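"""Synthetic multi-site daily flux archives with known ground truth.

Emulates the statistical structure of a daily eddy-covariance network
(FLUXNET-style variables) so that every downstream stage — compositing,
filtering, mixed-model fitting — can be exercised against a known
data-generating process:

* top-of-atmosphere radiation from solar geometry, surface shortwave via a
  bounded autoregressive cloudiness series;
* seasonal air temperature with persistent (AR(1)) anomalies, vapor pressure
  deficit log-linear in temperature with its own persistent anomalies;
* a two-parameter bucket soil-moisture store (stochastic rain events minus
  temperature-scaled evaporative draw-down);
* a seasonal logistic canopy green-up/senescence observed sparsely and
  noisily (the remote-sensing fAPAR analogue), with occasional outliers and
  saturated (=1) values;
* diffuse photon flux from the Bristow transmittance relation, present only
  at a subset of "instrumented" sites;
* true daily light use efficiency from a log-linear model in temperature
  (quadratic), log VPD, log soil moisture and log cloudiness index, with
  Gaussian site and year-within-site random intercepts, and GPP assembled
  from the LUE identity with multiplicative gamma noise.

All randomness derives from a single seed; each site consumes its own named
child stream, so regenerating a subset of sites reproduces them exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "TrueCoefficients",
    "potential_radiation",
    "generate_site_network",
    "sample_composites",
]

SOLAR_CONSTANT = 1361.0  # W m-2
C_MOLAR_MASS = 12.011  # g mol-1
SW_TO_PPFD = 2.04  # µmol photons per J of shortwave energy


@dataclass(frozen=True)
class TrueCoefficients:
    """Fixed-effect truth for the log-LUE mean structure.

    log LUE = alpha + b_temp*(T - temp_center) + b_temp2*(T - temp_center)^2
              + b_logvpd*log VPD + b_logsm*log Sm + b_logci*log CI
    """

    alpha: float = -2.10
    b_temp: float = 0.07
    b_temp2: float = -0.0035
    b_logvpd: float = -0.25
    b_logsm: float = 0.10
    b_logci: float = 0.15
    temp_center: float = 15.0

    @property
    def temperature_optimum(self) -> float:
        """Vertex of the temperature parabola in °C (requires b_temp2 < 0)."""
        return self.temp_center - self.b_temp / (2.0 * self.b_temp2)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.b_temp, self.b_temp2,
             self.b_logvpd, self.b_logsm, self.b_logci]
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic network draw."""

    n_sites: int = 50
    years_per_site: int = 5
    latitude_range: tuple[float, float] = (28.0, 55.0)
    true_coefficients: TrueCoefficients = field(default_factory=TrueCoefficients)
    sd_site: float = 0.20      # SD of site intercepts, log scale
    sd_year: float = 0.12      # SD of year-within-site intercepts, log scale
    gamma_shape: float = 25.0  # shape of multiplicative GPP noise (inf = none)
    bristow_B: float = 0.889
    gap_rate: float = 0.10
    fapar_obs_interval_days: int = 4
    fapar_noise_sd: float = 0.05      # lognormal sigma of fAPAR observation noise
    fapar_outlier_prob: float = 0.015
    fapar_unity_prob: float = 0.01
    diffuse_site_fraction: float = 0.5  # share of sites with a diffuse sensor
    ci_ar_rho: float = 0.7
    ci_bounds: tuple[float, float] = (0.02, 0.95)
    start_year: int = 2001
    seed: int = 20220101

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.years_per_site < 1:
            raise ValueError("years_per_site must be >= 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.sd_site < 0 or self.sd_year < 0:
            raise ValueError("random-intercept SDs must be >= 0")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must be in [0, 1)")
        lo, hi = self.ci_bounds
        if not 0 < lo < hi < 1:
            raise ValueError("ci_bounds must satisfy 0 < lo < hi < 1")

    def noise_free(self) -> "SyntheticConfig":
        """A copy with observation noise switched off (closure testing)."""
        return replace(
            self,
            gamma_shape=math.inf,
            fapar_noise_sd=0.0,
            fapar_outlier_prob=0.0,
            fapar_unity_prob=0.0,
            fapar_obs_interval_days=1,
            gap_rate=0.0,
        )


def potential_radiation(latitude: float, day_of_year) -> np.ndarray | float:
    """Daily-mean top-of-atmosphere shortwave irradiance (W m⁻²).

    Standard solar geometry: solar constant 1361 W m⁻², sinusoidal
    declination, inverse-square Sun–Earth distance correction and the
    sunset-hour-angle integral of cos(zenith) over the day. Returns zero
    during polar night.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    doy = np.asarray(day_of_year, dtype=float)
    if np.any(doy < 1) or np.any(doy > 366):
        raise ValueError("day_of_year outside [1, 366]")
    phi = math.radians(latitude)
    gamma = 2.0 * math.pi * doy / 365.0
    dr = 1.0 + 0.033 * np.cos(gamma)
    decl = 0.409 * np.sin(gamma - 1.39)
    cos_ws = np.clip(-math.tan(phi) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)  # ws = 0 → polar night, ws = pi → polar day
    daily = (SOLAR_CONSTANT * dr / math.pi) * (
        ws * math.sin(phi) * np.sin(decl)
        + math.cos(phi) * np.cos(decl) * np.sin(ws)
    )
    out = np.maximum(daily, 0.0)
    return float(out) if out.ndim == 0 else out


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series with innovation SD `sd`."""
    x = np.empty(n)
    stat_sd = sd / math.sqrt(max(1.0 - rho * rho, 1e-12))
    x[0] = rng.normal(0.0, stat_sd)
    eps = rng.normal(0.0, sd, size=n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x


def _diffuse_transmittance(t_t: np.ndarray, B: float) -> np.ndarray:
    # Bristow relation; duplicated here in minimal form so the generator does
    # not depend on the preprocessing module.
    return t_t * (1.0 - np.exp(0.6 * (1.0 - B / t_t) / (B - 0.4)))


def _gamma_multiplier(rng: np.random.Generator, shape: float, n: int) -> np.ndarray:
    if math.isinf(shape):
        return np.ones(n)
    return rng.gamma(shape, 1.0 / shape, size=n)


def generate_site_network(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one network; returns (daily records, ground-truth sidecar).

    Identical config (including seed) yields identical tables. The daily
    table uses internal column names; :func:`fluxlue.io.write_daily_table`
    maps them to the FLUXNET-style CSV dialect.
    """
    root = np.random.SeedSequence(config.seed)
    site_streams = root.spawn(config.n_sites + 1)
    master = np.random.default_rng(site_streams[0])
    tc = config.true_coefficients

    latitudes = master.uniform(*config.latitude_range, size=config.n_sites)
    elevations = master.uniform(50.0, 1500.0, size=config.n_sites)
    mu_ci = master.uniform(0.25, 0.45, size=config.n_sites)
    site_intercepts = master.normal(0.0, config.sd_site, size=config.n_sites)
    has_diffuse = (
        np.arange(config.n_sites) < config.diffuse_site_fraction * config.n_sites
    )

    daily_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    for k in range(config.n_sites):
        rng = np.random.default_rng(site_streams[k + 1])
        site_id = f"SYN-{k + 1:03d}"
        lat = latitudes[k]
        dates = pd.date_range(
            start=f"{config.start_year}-01-01",
            end=f"{config.start_year + config.years_per_site - 1}-12-31",
            freq="D",
        )
        n = len(dates)
        doy = dates.dayofyear.to_numpy().astype(float)
        years = dates.year.to_numpy()

        year_levels = np.arange(config.start_year, config.start_year + config.years_per_site)
        year_int = rng.normal(0.0, config.sd_year, size=config.years_per_site)
        year_intercept = year_int[np.searchsorted(year_levels, years)]

        # --- radiation & cloudiness -------------------------------------
        sw_pot = potential_radiation(lat, doy)
        ci = mu_ci[k] + _ar1(rng, n, config.ci_ar_rho, 0.08)
        ci = np.clip(ci, *config.ci_bounds)
        sw_in = (1.0 - ci) * sw_pot

        # --- temperature & humidity -------------------------------------
        t_mean = 24.0 - 0.40 * lat
        t_amp = 8.0 + 0.15 * lat
        ta = (
            t_mean
            + t_amp * np.cos(2.0 * math.pi * (doy - 200.0) / 365.25)
            + _ar1(rng, n, 0.8, 0.8)
        )
        log_vpd = 5.6 + 0.045 * ta + _ar1(rng, n, 0.8, 0.12)
        vpd = np.exp(log_vpd)

        # --- bucket soil moisture ---------------------------------------
        whc = 150.0  # mm
        rain = rng.binomial(1, 0.3, size=n) * rng.exponential(6.0, size=n)
        soil = np.empty(n)
        s = 0.7
        for t in range(n):
            pet = 0.5 + 0.08 * max(ta[t], 0.0)
            s = s + (rain[t] - pet * s) / whc
            s = min(max(s, 0.02), 1.0)
            soil[t] = s

        # --- canopy greenness --------------------------------------------
        season_start = 80.0 + 1.2 * (lat - 28.0)
        season_end = 330.0 - 1.0 * (lat - 28.0)
        base, fmax = 0.12, 0.75
        grow = 1.0 / (1.0 + np.exp(-(doy - season_start) / 10.0))
        sene = 1.0 / (1.0 + np.exp((doy - season_end) / 15.0))
        fapar_true = base + (fmax - base) * grow * sene

        fapar_obs = np.full(n, np.nan)
        obs_idx = np.arange(0, n, config.fapar_obs_interval_days)
        obs = fapar_true[obs_idx]
        if config.fapar_noise_sd > 0:
            obs = obs * rng.lognormal(0.0, config.fapar_noise_sd, size=obs.size)
        if config.fapar_outlier_prob > 0:
            mask = rng.random(obs.size) < config.fapar_outlier_prob
            obs = np.where(mask, np.minimum(obs * 1.9, 0.999), obs)
        if config.fapar_unity_prob > 0:
            mask = rng.random(obs.size) < config.fapar_unity_prob
            obs = np.where(mask, 1.0, obs)
        fapar_obs[obs_idx] = np.clip(obs, 1e-4, 1.0)

        # --- diffuse radiation (Bristow) ----------------------------------
        with np.errstate(divide="ignore", invalid="ignore"):
            t_t = np.where(sw_pot > 0, sw_in / np.maximum(sw_pot, 1e-12), np.nan)
            t_d = np.where(
                np.isfinite(t_t) & (t_t > 0),
                _diffuse_transmittance(np.maximum(t_t, 1e-9), config.bristow_B),
                0.0,
            )
        sw_dif = t_d * sw_pot
        ppfd_dif = sw_dif * SW_TO_PPFD  # µmol m-2 s-1 (daily mean)
        if not has_diffuse[k]:
            ppfd_dif = np.full(n, np.nan)

        # --- LUE truth and GPP -------------------------------------------
        tcen = ta - tc.temp_center
        log_lue = (
            tc.alpha
            + tc.b_temp * tcen
            + tc.b_temp2 * tcen**2
            + tc.b_logvpd * np.log(vpd)
            + tc.b_logsm * np.log(soil)
            + tc.b_logci * np.log(ci)
            + site_intercepts[k]
            + year_intercept
        )
        lue_true = np.exp(log_lue)
        ppfd_mol = sw_in * SW_TO_PPFD * 1e-6 * 86400.0  # mol m-2 d-1
        noise = _gamma_multiplier(rng, config.gamma_shape, n)
        gpp = lue_true * fapar_true * ppfd_mol * noise * C_MOLAR_MASS

        if config.gap_rate > 0:
            b = 2.0 * (1.0 - config.gap_rate) / config.gap_rate
            gapfill = rng.beta(2.0, b, size=n)
        else:
            gapfill = np.zeros(n)

        co2 = (
            400.0
            + 2.0 * (years - config.start_year)
            + rng.normal(0.0, 2.0, size=n)
        )

        daily_frames.append(
            pd.DataFrame(
                {
                    "site_id": site_id,
                    "date": dates,
                    "gpp": gpp,
                    "sw_in": sw_in,
                    "sw_in_pot": sw_pot,
                    "ppfd_dif": ppfd_dif,
                    "ta_day": ta,
                    "vpd_day": vpd,
                    "co2": co2,
                    "soil_m": soil,
                    "fapar_obs": fapar_obs,
                    "gapfill_frac": gapfill,
                    "elv": elevations[k],
                }
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "site_id": site_id,
                    "date": dates,
                    "lue_true": lue_true,
                    "fapar_true": fapar_true,
                    "site_intercept": site_intercepts[k],
                    "year_intercept": year_intercept,
                    "in_growing_season": (doy > season_start) & (doy < season_end),
                }
            )
        )

    daily = pd.concat(daily_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return daily, truth


def sample_composites(config: SyntheticConfig, windows_per_site: int = 60) -> pd.DataFrame:
    """Draw 15-day composites directly from the mixed-model truth.

    Samples window-level predictors with realistic marginal ranges and
    correlation (VPD log-linear in temperature), applies the exact log-LUE
    mean structure plus site / year-within-site intercepts, and multiplies
    by gamma noise of shape ``config.gamma_shape``. This is the canonical
    calibration input for estimator-recovery studies: the fitted model is
    exactly the data-generating process, so coverage of reported standard
    errors can be judged without compositing artefacts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    tc = config.true_coefficients
    n_years = config.years_per_site
    rows = []
    for k in range(config.n_sites):
        u = rng.normal(0.0, config.sd_site)
        v = rng.normal(0.0, config.sd_year, size=n_years)
        m = windows_per_site
        year_ix = rng.integers(0, n_years, size=m)
        temp = rng.uniform(2.0, 30.0, size=m)
        vpd = np.exp(5.6 + 0.045 * temp + rng.normal(0.0, 0.25, size=m))
        soil = rng.uniform(0.15, 1.0, size=m)
        ci = rng.uniform(*config.ci_bounds, size=m)
        tcen = temp - tc.temp_center
        eta = (
            tc.alpha
            + tc.b_temp * tcen
            + tc.b_temp2 * tcen**2
            + tc.b_logvpd * np.log(vpd)
            + tc.b_logsm * np.log(soil)
            + tc.b_logci * np.log(ci)
            + u
            + v[year_ix]
        )
        lue = np.exp(eta) * _gamma_multiplier(rng, config.gamma_shape, m)
        rows.append(
            pd.DataFrame(
                {
                    "site_id": f"SYN-{k + 1:03d}",
                    "year": config.start_year + year_ix,
                    "window_index": np.arange(m),
                    "lue": lue,
                    "temp": temp,
                    "vpd": vpd,
                    "soil_m": soil,
                    "ci": ci,
                    "td": (1.0 - ci)
                    * (1.0 - np.exp(0.6 * (1.0 - config.bristow_B / (1.0 - ci))
                                    / (config.bristow_B - 0.4))),
                    "fapar": rng.uniform(0.3, 0.8, size=m),
                    "ppfd": rng.uniform(15.0, 45.0, size=m),
                    "co2": 400.0 + rng.normal(0.0, 4.0, size=m),
                    "elv": rng.uniform(50.0, 1500.0),
                    "n_days": 15,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
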