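"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: daily
radiation by brute-force integration of the solar zenith angle, and the
mixed-model marginal likelihood by per-group adaptive Gauss–Hermite
quadrature of the gamma likelihood against the Gaussian random-intercept
density.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, roots_hermite

SOLAR_CONSTANT = 1361.0


def daily_radiation_by_integration(latitude: float, day_of_year: int,
                                   minutes: int = 1) -> float:
    """Daily-mean TOA irradiance by direct integration of cos(zenith).

    Uses the same declination / distance conventions as the closed form but
    integrates cos(zenith) over the day at `minutes` resolution instead of
    using the sunset-hour-angle integral.
    """
    phi = math.radians(latitude)
    gamma = 2.0 * math.pi * day_of_year / 365.0
    dr = 1.0 + 0.033 * math.cos(gamma)
    decl = 0.409 * math.sin(gamma - 1.39)
    t = np.arange(0, 24 * 60, minutes) / 60.0  # hours
    hour_angle = math.pi * (t - 12.0) / 12.0
    cosz = (math.sin(phi) * math.sin(decl)
            + math.cos(phi) * math.cos(decl) * np.cos(hour_angle))
    return float(SOLAR_CONSTANT * dr * np.mean(np.maximum(cosz, 0.0)))


def gamma_loglik(y: np.ndarray, eta: np.ndarray, nu: float) -> float:
    return float(np.sum(
        nu * (math.log(nu) + np.log(y) - eta - y * np.exp(-eta))
        - np.log(y) - gammaln(nu)
    ))


def agq_marginal_loglik(
    y: np.ndarray,
    eta_fixed: np.ndarray,
    groups: np.ndarray,
    nu: float,
    sigma2: float,
    n_nodes: int = 15,
) -> float:
    """Marginal log-likelihood with one Gaussian intercept per group.

    For each group the 1-D integral over the intercept is evaluated by
    adaptive Gauss–Hermite quadrature: nodes are centered at the
    conditional mode and scaled by the curvature there.
    """
    z_nodes, w_nodes = roots_hermite(n_nodes)
    total = 0.0
    for g in np.unique(groups):
        sel = groups == g
        yg, eg = y[sel], eta_fixed[sel]

        def neg_joint(b: float) -> float:
            return -(gamma_loglik(yg, eg + b, nu) - b * b / (2.0 * sigma2))

        res = minimize_scalar(neg_joint, bounds=(-5.0, 5.0), method="bounded",
                              options={"xatol": 1e-12})
        b_hat = float(res.x)
        curv = nu * float(np.sum(yg * np.exp(-(eg + b_hat)))) + 1.0 / sigma2
        sd = 1.0 / math.sqrt(curv)
        shifted = b_hat + math.sqrt(2.0) * sd * z_nodes
        log_f = np.array([
            gamma_loglik(yg, eg + b, nu) - b * b / (2.0 * sigma2)
            for b in shifted
        ])
        log_integrand = log_f + z_nodes**2
        m = log_integrand.max()
        integral = math.sqrt(2.0) * sd * float(
            np.sum(w_nodes * np.exp(log_integrand - m))
        )
        total += m + math.log(integral) - 0.5 * math.log(2.0 * math.pi * sigma2)
    return total
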