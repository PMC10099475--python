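"""Optimality-based light use efficiency (P-model), the mechanistic comparator.

The P-model predicts the ratio of leaf-internal to ambient CO₂ partial
pressure, χ, by balancing the unit costs of transpiration and
carboxylation:

    ξ  = sqrt(β (K + Γ*) / (1.6 η*)),
    χ  = Γ*/ca + (1 − Γ*/ca) · ξ / (ξ + √D),

with D the vapor pressure deficit (Pa), K the effective Michaelis–Menten
coefficient of Rubisco, Γ* the photorespiratory compensation point and η*
the viscosity of water relative to 25 °C. The CO₂ limitation factor of
light-limited assimilation, m = (ci − Γ*)/(ci + 2Γ*), together with a
Jmax-limitation factor and a temperature-dependent intrinsic quantum
yield φ0(T) and an empirical soil-moisture stress β_sm, gives

    LUE = φ0(T) · β_sm · m · sqrt(1 − (c*/m)^(2/3)),   m > c*, else 0.

Deterministic; one site-day (or one composite window) in, one LUE out.
Kinetic constants follow the published "FULL" calibration of the rpmodel
setup; all are configuration-exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PModelParams",
    "photosynthesis_kinetics",
    "atmospheric_pressure",
    "optimal_chi",
    "lue",
    "stylized_experiment",
]

R_GAS = 8.3145  # J mol-1 K-1
T25 = 298.15    # K
P0 = 101325.0   # Pa


@dataclass(frozen=True)
class PModelParams:
    """Constants of the LUE formulation (published "FULL" calibration)."""

    beta_cost: float = 146.0        # unit cost ratio b/a
    c_star: float = 0.41            # Jmax limitation constant
    kphio: float = 0.087182         # calibrated quantum-yield scalar
    phi0_coeffs: tuple[float, float, float] = (0.352, 0.022, -3.4e-4)
    soilm_theta_star: float = 0.6   # no stress above this soil-moisture fraction
    soilm_a: float = 0.0            # stress-magnitude intercept
    soilm_b: float = 0.733          # stress-magnitude slope on mean alpha
    gammastar25: float = 4.332      # Pa, at standard pressure
    dha_gammastar: float = 37830.0  # J mol-1
    kc25: float = 39.97             # Pa
    dha_kc: float = 79430.0
    ko25: float = 27480.0           # Pa
    dha_ko: float = 36380.0
    o2_fraction: float = 0.209476


def atmospheric_pressure(elevation: float) -> float:
    """Barometric pressure (Pa) at elevation (m), standard atmosphere."""
    return P0 * (1.0 - 0.0065 * elevation / 288.15) ** 5.2553


def _arrhenius(dha: float, tk) -> np.ndarray:
    return np.exp(dha * (tk - T25) / (T25 * R_GAS * tk))


def _viscosity_water(tc) -> np.ndarray:
    # Vogel correlation for liquid water, mPa s; used only as a ratio
    tk = np.asarray(tc, dtype=float) + 273.15
    return np.exp(-3.7188 + 578.919 / (tk - 137.546))


def photosynthesis_kinetics(temp, elevation: float = 0.0, params: PModelParams | None = None):
    """(Γ*, K, η*) at the given temperature (°C) and elevation (m).

    Γ* and the Rubisco Michaelis–Menten coefficients scale from their
    25 °C references by Arrhenius functions; Γ* additionally scales with
    pressure. η* is the water-viscosity ratio relative to 25 °C.
    """
    p = params or PModelParams()
    t = np.asarray(temp, dtype=float)
    if np.any(t < -25) or np.any(t > 60):
        raise ValueError("temperature outside [-25, 60] °C")
    pr = atmospheric_pressure(elevation)
    tk = t + 273.15
    gammastar = p.gammastar25 * (pr / P0) * _arrhenius(p.dha_gammastar, tk)
    kc = p.kc25 * _arrhenius(p.dha_kc, tk)
    ko = p.ko25 * _arrhenius(p.dha_ko, tk)
    po2 = p.o2_fraction * pr
    k = kc * (1.0 + po2 / ko)
    eta_star = _viscosity_water(t) / _viscosity_water(25.0)
    if np.ndim(temp) == 0:
        return float(gammastar), float(k), float(eta_star)
    return gammastar, k, eta_star


def optimal_chi(temp, vpd, co2, elevation: float = 0.0,
                params: PModelParams | None = None):
    """Optimal χ = ci/ca and the CO₂ limitation factor m.

    ``vpd`` in Pa, ``co2`` in µmol mol⁻¹. The D → 0 limit gives χ → 1.
    """
    p = params or PModelParams()
    gammastar, k, eta_star = photosynthesis_kinetics(temp, elevation, p)
    pr = atmospheric_pressure(elevation)
    ca = np.asarray(co2, dtype=float) * 1e-6 * pr
    d = np.maximum(np.asarray(vpd, dtype=float), 0.0)
    xi = np.sqrt(p.beta_cost * (k + gammastar) / (1.6 * eta_star))
    g = gammastar / ca
    chi = g + (1.0 - g) * xi / (xi + np.sqrt(d))
    ci = chi * ca
    mj = np.where(ci > gammastar, (ci - gammastar) / (ci + 2.0 * gammastar), 0.0)
    if np.ndim(chi) == 0:
        return float(chi), float(mj)
    return chi, mj


def _phi0(temp, params: PModelParams) -> np.ndarray:
    c0, c1, c2 = params.phi0_coeffs
    t = np.asarray(temp, dtype=float)
    return params.kphio * np.maximum(c0 + c1 * t + c2 * t * t, 0.0)


def _soilm_stress(soil_m, mean_alpha: float, params: PModelParams) -> np.ndarray:
    """Empirical quadratic soil-moisture stress, 1 above θ*, ≤1 below."""
    theta = np.asarray(soil_m, dtype=float)
    beta0 = params.soilm_a + params.soilm_b * mean_alpha
    q = (beta0 - 1.0) / params.soilm_theta_star**2
    stress = 1.0 + q * (theta - params.soilm_theta_star) ** 2
    return np.clip(np.where(theta >= params.soilm_theta_star, 1.0, stress), 0.0, 1.0)


def lue(temp, vpd, co2=400.0, soil_m=1.0, elevation: float = 0.0,
        mean_alpha: float = 1.0, params: PModelParams | None = None):
    """P-model light use efficiency (mol C mol⁻¹ photons)."""
    p = params or PModelParams()
    _, mj = optimal_chi(temp, vpd, co2, elevation, p)
    mj = np.asarray(mj, dtype=float)
    with np.errstate(invalid="ignore"):
        jlim = np.where(
            mj > p.c_star,
            np.sqrt(np.maximum(1.0 - (p.c_star / np.maximum(mj, 1e-12)) ** (2.0 / 3.0), 0.0)),
            0.0,
        )
    out = _phi0(temp, p) * _soilm_stress(soil_m, mean_alpha, p) * mj * jlim
    return float(out) if out.ndim == 0 else out


def stylized_experiment(
    composites: pd.DataFrame,
    variable: str,
    n_grid: int = 100,
    params: PModelParams | None = None,
) -> pd.DataFrame:
    """One-driver-at-a-time P-model response over the observed range.

    All other drivers are held at their medians in the composite table.
    Output matches the tidy response-curve format of the statistical model
    so the two can be overlaid. The cloudiness index has no pathway into
    the model, so its curve is flat by construction.
    """
    drivers = {"temp": "temp", "vpd": "vpd", "soil_m": "soil_m",
               "co2": "co2", "ci": "ci"}
    if variable not in drivers:
        raise ValueError(f"unknown driver {variable!r}")
    med = {c: float(composites[c].median())
           for c in ("temp", "vpd", "soil_m", "co2") if c in composites}
    med.setdefault("co2", 400.0)
    x = composites[variable].to_numpy()
    grid = np.linspace(np.nanmin(x), np.nanmax(x), n_grid)
    vals = []
    for g in grid:
        v = dict(med)
        if variable in v:
            v[variable] = g
        vals.append(lue(v["temp"], v["vpd"], v["co2"], v["soil_m"], params=params))
    return pd.DataFrame({"variable": variable, "x": grid, "mu": vals})


def simulate_lue(composites: pd.DataFrame, params: PModelParams | None = None) -> np.ndarray:
    """P-model LUE evaluated row-wise on a composite table."""
    return lue(
        composites["temp"].to_numpy(),
        composites["vpd"].to_numpy(),
        composites["co2"].to_numpy() if "co2" in composites else 400.0,
        composites["soil_m"].to_numpy(),
        params=params,
    )
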