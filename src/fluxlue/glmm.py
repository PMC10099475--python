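"""Gamma mixed models of light use efficiency.

LUE for window *i* of year *j* at site *k* is modelled as gamma-distributed
with log link,

    log E[LUE_ijk] = alpha + f(predictors_ijk) + a_k + a_j|k,

with independent Gaussian random intercepts for site (a_k) and year within
site (a_j|k). Fitting maximizes the marginal likelihood with the random
effects integrated out by a Laplace approximation; the fixed effects are
profiled at the joint conditional mode (the standard Laplace / nAGQ=1
scheme for generalized mixed models). ML (not REML) likelihoods are
reported throughout so AIC/BIC comparisons across fixed-effect designs are
meaningful.

The module also provides the backward model-selection ladder, variance
apportionment between site / year / residual components, conditional
response curves with partial residuals, the notional temperature optimum
implied by the quadratic temperature term, leave-one-site-out
cross-validation with a fixed-effects-only gamma GLM, and prediction with
or without the estimated random intercepts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, polygamma
import statsmodels.api as sm

__all__ = [
    "ModelDesign",
    "GlmmFit",
    "ResponseCurve",
    "build_design",
    "fit_gamma_glmm",
    "fit_design",
    "default_ladder",
    "selection_ladder",
    "variance_partition",
    "conditional_response",
    "temperature_optimum",
    "loo_site_cv",
    "predict_lue",
]

# term name -> (source columns, builder). Builders receive the composites
# frame and the centering dict and return (column names, column arrays).
_TERMS = {
    "temp_poly2", "temp_linear", "log_vpd", "vpd_linear", "log_soil_m",
    "soil_m_linear", "log_ci", "ci_linear", "elevation", "co2",
    "ci_x_fapar", "td_x_fapar", "ppfd",
}

# composite columns each term needs, and whether positivity is required
_TERM_VARS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "temp_poly2": (("temp",), ()),
    "temp_linear": (("temp",), ()),
    "log_vpd": (("vpd",), ("vpd",)),
    "vpd_linear": (("vpd",), ()),
    "log_soil_m": (("soil_m",), ("soil_m",)),
    "soil_m_linear": (("soil_m",), ()),
    "log_ci": (("ci",), ("ci",)),
    "ci_linear": (("ci",), ()),
    "elevation": (("elv",), ()),
    "co2": (("co2",), ()),
    "ci_x_fapar": (("ci", "fapar"), ()),
    "td_x_fapar": (("td", "fapar"), ()),
    "ppfd": (("ppfd",), ()),
}


@dataclass(frozen=True)
class ModelDesign:
    """Declarative fixed + random structure for one candidate model."""

    fixed_terms: tuple[str, ...] = ("temp_poly2", "log_vpd", "log_soil_m", "log_ci")
    random_terms: str = "year_in_site"  # year_in_site | site_only | year_only | none
    label: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.fixed_terms) - _TERMS
        if unknown:
            raise ValueError(f"unknown fixed terms: {sorted(unknown)}")
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise ValueError("fixed terms must be unique")
        if self.random_terms not in {"year_in_site", "site_only", "year_only", "none"}:
            raise ValueError(f"unknown random structure {self.random_terms!r}")

    def required_columns(self) -> set[str]:
        cols: set[str] = set()
        for t in self.fixed_terms:
            cols.update(_TERM_VARS[t][0])
        return cols

    def positive_columns(self) -> set[str]:
        cols: set[str] = set()
        for t in self.fixed_terms:
            cols.update(_TERM_VARS[t][1])
        return cols


def build_design(
    composites: pd.DataFrame,
    design: ModelDesign,
    centers: dict[str, float] | None = None,
) -> dict:
    """Assemble response vector, fixed-effect matrix and grouping factors.

    The quadratic temperature term uses raw centered temperature (the
    centering constant is stored so the parabola vertex maps directly back
    to °C). Logs are natural. Rows with missing values, a non-positive
    response, or non-positive values under a log transform are dropped and
    counted in the returned audit.
    """
    if composites.empty:
        raise ValueError("no composites supplied")
    needed = sorted(design.required_columns() | {"lue", "site_id", "year"})
    df = composites[needed].copy()
    n0 = len(df)
    df = df.dropna()
    n_na = n0 - len(df)
    ok = df["lue"] > 0
    for col in design.positive_columns():
        ok &= df[col] > 0
    n_nonpos = int((~ok).sum())
    df = df[ok]
    if df.empty:
        raise ValueError("no usable rows after dropping invalid values")

    if centers is None:
        centers = {}
        if "temp_poly2" in design.fixed_terms or "temp_linear" in design.fixed_terms:
            centers["temp"] = float(df["temp"].mean())

    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["(Intercept)"]
    for t in design.fixed_terms:
        if t == "temp_poly2":
            tc = df["temp"].to_numpy() - centers["temp"]
            cols += [tc, tc**2]
            names += ["temp_c", "temp_c2"]
        elif t == "temp_linear":
            tc = df["temp"].to_numpy() - centers["temp"]
            cols.append(tc)
            names.append("temp_c")
        elif t == "log_vpd":
            cols.append(np.log(df["vpd"].to_numpy()))
            names.append("log_vpd")
        elif t == "vpd_linear":
            cols.append(df["vpd"].to_numpy())
            names.append("vpd")
        elif t == "log_soil_m":
            cols.append(np.log(df["soil_m"].to_numpy()))
            names.append("log_soil_m")
        elif t == "soil_m_linear":
            cols.append(df["soil_m"].to_numpy())
            names.append("soil_m")
        elif t == "log_ci":
            cols.append(np.log(df["ci"].to_numpy()))
            names.append("log_ci")
        elif t == "ci_linear":
            cols.append(df["ci"].to_numpy())
            names.append("ci")
        elif t == "elevation":
            cols.append(df["elv"].to_numpy())
            names.append("elv")
        elif t == "co2":
            cols.append(df["co2"].to_numpy())
            names.append("co2")
        elif t == "ci_x_fapar":
            cols.append(df["ci"].to_numpy() * df["fapar"].to_numpy())
            names.append("ci:fapar")
        elif t == "td_x_fapar":
            cols.append(df["td"].to_numpy() * df["fapar"].to_numpy())
            names.append("td:fapar")
        elif t == "ppfd":
            cols.append(df["ppfd"].to_numpy())
            names.append("ppfd")

    X = np.column_stack(cols)
    y = df["lue"].to_numpy()
    site = df["site_id"].astype(str).to_numpy()
    siteyear = np.char.add(np.char.add(site, ":"), df["year"].astype(str).to_numpy())
    yearonly = df["year"].astype(str).to_numpy()
    return {
        "y": y,
        "X": X,
        "colnames": names,
        "site": site,
        "siteyear": siteyear,
        "year": yearonly,
        "centers": centers,
        "frame": df,
        "audit": {"dropped_na": n_na, "dropped_nonpositive": n_nonpos},
    }


@dataclass
class GlmmFit:
    """One fitted gamma mixed model."""

    design: ModelDesign
    beta: np.ndarray
    beta_se: np.ndarray
    colnames: list[str]
    sigma2_site: float
    sigma2_year: float
    shape: float
    loglik: float
    aic: float
    bic: float
    df: int
    n_obs: int
    blups: dict[str, dict[str, float]]
    centers: dict[str, float]
    medians: dict[str, float]
    converged: bool
    boundary: bool = False
    mu: np.ndarray | None = None       # fitted means incl. random effects
    eta_fixed: np.ndarray | None = None
    frame: pd.DataFrame | None = None

    def summary_dict(self) -> dict:
        return {
            "label": self.design.label or "+".join(self.design.fixed_terms),
            "fixed_terms": list(self.design.fixed_terms),
            "random_terms": self.design.random_terms,
            "coefficients": dict(zip(self.colnames, self.beta.tolist())),
            "std_errors": dict(zip(self.colnames, self.beta_se.tolist())),
            "sigma2_site": self.sigma2_site,
            "sigma2_year": self.sigma2_year,
            "shape": self.shape,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "df": self.df,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "boundary": self.boundary,
            "centers": self.centers,
        }


@dataclass
class ResponseCurve:
    """Conditional response of LUE to one predictor."""

    variable: str
    grid: np.ndarray
    mu: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    partial_x: np.ndarray
    partial_y: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variable": self.variable, "x": self.grid, "mu": self.mu,
             "lo": self.lo, "hi": self.hi}
        )


def _gamma_loglik(y: np.ndarray, eta: np.ndarray, nu: float) -> float:
    # Gamma(shape nu, mean mu=e^eta): nu*log(nu y / mu) - nu y/mu - log y - lgamma(nu)
    log_y = np.log(y)
    return float(
        np.sum(nu * (math.log(nu) + log_y - eta - y * np.exp(-eta))
               - log_y - gammaln(nu))
    )


class _Blocks:
    """Per-site random-effect layout for the nested (or single) structure."""

    def __init__(self, site: np.ndarray, siteyear: np.ndarray | None, structure: str):
        self.structure = structure
        if structure == "year_in_site":
            outer = site
        elif structure == "site_only":
            outer, siteyear = site, None
        elif structure == "year_only":
            outer, siteyear = siteyear, None  # caller passes year labels as `site`
        else:
            raise ValueError(structure)
        self.outer_levels, outer_codes = np.unique(outer, return_inverse=True)
        self.rows = [np.where(outer_codes == g)[0] for g in range(len(self.outer_levels))]
        self.inner_levels: list[np.ndarray] = []
        self.Z: list[np.ndarray] = []
        self.has_inner = siteyear is not None
        for rows in self.rows:
            if self.has_inner:
                lev, codes = np.unique(siteyear[rows], return_inverse=True)
                Zk = np.zeros((rows.size, 1 + lev.size))
                Zk[:, 0] = 1.0
                Zk[np.arange(rows.size), 1 + codes] = 1.0
            else:
                lev = np.empty(0, dtype=object)
                Zk = np.ones((rows.size, 1))
            self.inner_levels.append(lev)
            self.Z.append(Zk)
        self.q = sum(Z.shape[1] for Z in self.Z)

    def prior_precision(self, sigma2_site: float, sigma2_year: float) -> list[np.ndarray]:
        out = []
        for lev in self.inner_levels:
            d = np.full(1 + len(lev) if self.has_inner else 1, 0.0)
            d[0] = 1.0 / sigma2_site
            if self.has_inner:
                d[1:] = 1.0 / sigma2_year
            out.append(d)
        return out

    def prior_logdet(self, sigma2_site: float, sigma2_year: float) -> float:
        tot = 0.0
        for lev in self.inner_levels:
            tot += math.log(2 * math.pi * sigma2_site)
            if self.has_inner:
                tot += len(lev) * math.log(2 * math.pi * sigma2_year)
        return tot


def _inner_mode(
    y, X, blocks: _Blocks, nu, prec: list[np.ndarray],
    beta0: np.ndarray, b0: list[np.ndarray],
    max_iter: int = 100, tol: float = 1e-10,
):
    """Joint Newton maximization of the penalized log-likelihood over (β, b).

    Exploits the block-diagonal Hessian over the random effects: a Schur
    complement reduces each Newton step to one p×p solve plus small
    per-site solves. Step-halving guards convergence.
    """
    p = X.shape[1]
    beta = beta0.copy()
    b = [bk.copy() for bk in b0]

    def eta_of(beta, b):
        eta = X @ beta
        for rows, Zk, bk in zip(blocks.rows, blocks.Z, b):
            eta[rows] += Zk @ bk
        return eta

    def penalized(beta, b, eta):
        pen = sum(0.5 * float(dk @ (bk * bk)) for dk, bk in zip(prec, b))
        norm = 0.5 * sum(
            float(np.sum(np.log(2 * math.pi / dk))) for dk in prec
        )
        return _gamma_loglik(y, eta, nu) - pen - norm

    eta = eta_of(beta, b)
    f = penalized(beta, b, eta)
    for _ in range(max_iter):
        mu = np.exp(eta)
        r = nu * (y / mu - 1.0)          # d loglik / d eta
        w = nu * y / mu                  # -d2 loglik / d eta2 (observed, > 0)
        Xw = X * w[:, None]
        H_bb_inv_parts = []
        S = X.T @ Xw                      # p x p, to be reduced
        g_beta = X.T @ r
        rhs_red = g_beta.copy()
        for rows, Zk, bk, dk in zip(blocks.rows, blocks.Z, b, prec):
            wk = w[rows]
            rk = r[rows]
            A = Zk.T @ (Zk * wk[:, None])
            A[np.diag_indices_from(A)] += dk
            C = X[rows].T @ (Zk * wk[:, None])   # p x qk
            gb = Zk.T @ rk - dk * bk
            Ainv = np.linalg.inv(A)
            H_bb_inv_parts.append((Ainv, gb, C))
            S -= C @ Ainv @ C.T
            rhs_red -= C @ (Ainv @ gb)
        try:
            d_beta = np.linalg.solve(S, rhs_red)
        except np.linalg.LinAlgError:
            d_beta = np.linalg.lstsq(S, rhs_red, rcond=None)[0]
        d_b = [Ainv @ (gb - C.T @ d_beta) for Ainv, gb, C in H_bb_inv_parts]

        step = 1.0
        improved = False
        for _ in range(30):
            beta_new = beta + step * d_beta
            b_new = [bk + step * dbk for bk, dbk in zip(b, d_b)]
            eta_new = eta_of(beta_new, b_new)
            f_new = penalized(beta_new, b_new, eta_new)
            if np.isfinite(f_new) and f_new >= f - 1e-13:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        delta = max(np.max(np.abs(step * d_beta)),
                    max((np.max(np.abs(step * dbk)) if dbk.size else 0.0) for dbk in d_b))
        beta, b, eta, f_prev, f = beta_new, b_new, eta_new, f, f_new
        if delta < 1e-9 or abs(f - f_prev) < tol:
            break
    return beta, b, eta, f


def _laplace_loglik(y, X, blocks, nu, sigma2_site, sigma2_year, beta, b):
    """Laplace marginal log-likelihood at the conditional mode (β, b)."""
    prec = blocks.prior_precision(sigma2_site, sigma2_year)
    eta = X @ beta
    for rows, Zk, bk in zip(blocks.rows, blocks.Z, b):
        eta[rows] += Zk @ bk
    mu = np.exp(eta)
    w = nu * y / mu
    f = _gamma_loglik(y, eta, nu)
    f -= sum(0.5 * float(dk @ (bk * bk)) for dk, bk in zip(prec, b))
    f -= 0.5 * sum(float(np.sum(np.log(2 * math.pi / dk))) for dk in prec)
    logdet = 0.0
    for rows, Zk, dk in zip(blocks.rows, blocks.Z, prec):
        A = Zk.T @ (Zk * w[rows][:, None])
        A[np.diag_indices_from(A)] += dk
        sign, ld = np.linalg.slogdet(A)
        logdet += ld
    q = blocks.q
    return f + 0.5 * q * math.log(2 * math.pi) - 0.5 * logdet


def _glm_start(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Gamma GLM (log link) fixed-effect start and shape MLE."""
    glm = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = glm.fit()
    beta = np.asarray(res.params)
    mu = np.exp(X @ beta)
    nu = _gamma_shape_mle(y, mu)
    return beta, nu


def _gamma_shape_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile MLE of the gamma shape given fitted means."""
    n = y.size
    c = float(np.mean(np.log(y) - np.log(mu) - y / mu)) + 1.0
    # solve log(nu) - digamma(nu) = -c  via Newton on log-nu
    nu = max(1.0 / max(-2.0 * c, 1e-8), 1e-3)
    for _ in range(100):
        g = math.log(nu) - float(polygamma(0, nu)) + c
        dg = 1.0 / nu - float(polygamma(1, nu))
        step = -g / dg
        nu_new = nu + step
        if nu_new <= 0:
            nu_new = nu / 2.0
        if abs(nu_new - nu) < 1e-12 * max(1.0, nu):
            nu = nu_new
            break
        nu = nu_new
    return float(min(max(nu, 1e-3), 1e9))


_SIGMA_FLOOR = 1e-8   # variance below this is reported as a boundary zero


def fit_gamma_glmm(
    y: np.ndarray,
    X: np.ndarray,
    site: np.ndarray,
    siteyear: np.ndarray | None,
    design: ModelDesign,
    colnames: list[str] | None = None,
    centers: dict[str, float] | None = None,
    medians: dict[str, float] | None = None,
    frame: pd.DataFrame | None = None,
) -> GlmmFit:
    """Maximum-likelihood fit of the gamma mixed model.

    Outer optimization runs over (log shape, log SDs of the random
    intercepts) with the fixed effects and random-effect modes profiled by
    an exact Newton solver at each evaluation; the marginal likelihood is
    the Laplace approximation. Starting values come from the gamma GLM
    with zero variance components, so the fit is deterministic.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma response must be strictly positive")
    n, p = X.shape
    colnames = colnames or [f"b{j}" for j in range(p)]

    beta_glm, nu_glm = _glm_start(y, X)

    if design.random_terms == "none":
        return _fit_fixed_only(y, X, design, colnames, centers, medians, frame,
                               beta_glm, nu_glm)

    if design.random_terms == "year_in_site":
        blocks = _Blocks(site, siteyear, "year_in_site")
        n_vc = 2
    elif design.random_terms == "site_only":
        blocks = _Blocks(site, None, "site_only")
        n_vc = 1
    else:  # year_only: group by calendar year
        blocks = _Blocks(siteyear if siteyear is not None else site, None, "site_only")
        n_vc = 1
    if len(blocks.outer_levels) < 2:
        raise ValueError("random-intercept fit needs at least 2 groups")

    state = {
        "beta": beta_glm.copy(),
        "b": [np.zeros(Z.shape[1]) for Z in blocks.Z],
    }

    def unpack(phi):
        nu = math.exp(phi[0])
        s2_site = math.exp(2.0 * phi[1])
        s2_year = math.exp(2.0 * phi[2]) if n_vc == 2 else 0.0
        return nu, s2_site, s2_year

    def neg_marginal(phi):
        nu, s2_site, s2_year = unpack(phi)
        prec = blocks.prior_precision(s2_site, max(s2_year, _SIGMA_FLOOR))
        beta, b, eta, f = _inner_mode(
            y, X, blocks, nu, prec, state["beta"], state["b"]
        )
        state["beta"], state["b"] = beta, b
        ll = _laplace_loglik(y, X, blocks, nu, s2_site,
                             max(s2_year, _SIGMA_FLOOR), beta, b)
        return -ll

    x0 = [math.log(nu_glm), math.log(0.3)]
    bounds = [(-3.0, 16.0), (-7.0, 3.0)]
    if n_vc == 2:
        x0.append(math.log(0.2))
        bounds.append((-7.0, 3.0))
    res = minimize(
        neg_marginal, np.array(x0), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-8},
    )
    converged = bool(res.success)
    nu, s2_site, s2_year = unpack(res.x)
    prec = blocks.prior_precision(s2_site, max(s2_year, _SIGMA_FLOOR))
    beta, b, eta, _ = _inner_mode(y, X, blocks, nu, prec, state["beta"], state["b"])
    loglik = _laplace_loglik(y, X, blocks, nu, s2_site,
                             max(s2_year, _SIGMA_FLOOR), beta, b)

    # conditional covariance of beta from the joint penalized Hessian
    mu = np.exp(eta)
    w = nu * y / mu
    S = X.T @ (X * w[:, None])
    for rows, Zk, dk in zip(blocks.rows, blocks.Z, prec):
        wk = w[rows]
        A = Zk.T @ (Zk * wk[:, None])
        A[np.diag_indices_from(A)] += dk
        C = X[rows].T @ (Zk * wk[:, None])
        S -= C @ np.linalg.inv(A) @ C.T
    cov_beta = np.linalg.inv(S)
    beta_se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))

    boundary = False
    if s2_site < 100 * _SIGMA_FLOOR:
        s2_site, boundary = 0.0, True
    if n_vc == 2 and s2_year < 100 * _SIGMA_FLOOR:
        s2_year, boundary = 0.0, True

    blups: dict[str, dict[str, float]] = {"site": {}, "site_year": {}}
    for lev, bk, inner in zip(blocks.outer_levels, b, blocks.inner_levels):
        blups["site"][str(lev)] = float(bk[0])
        for ylev, val in zip(inner, bk[1:]):
            blups["site_year"][str(ylev)] = float(val)

    df = p + n_vc + 1
    aic = -2.0 * loglik + 2.0 * df
    bic = -2.0 * loglik + df * math.log(n)
    return GlmmFit(
        design=design, beta=beta, beta_se=beta_se, colnames=list(colnames),
        sigma2_site=float(s2_site),
        sigma2_year=float(s2_year) if n_vc == 2 else 0.0,
        shape=float(nu), loglik=float(loglik), aic=float(aic), bic=float(bic),
        df=df, n_obs=n, blups=blups, centers=centers or {},
        medians=medians or {}, converged=converged, boundary=boundary,
        mu=mu, eta_fixed=X @ beta, frame=frame,
    )


def _fit_fixed_only(y, X, design, colnames, centers, medians, frame,
                    beta_glm, nu_glm) -> GlmmFit:
    n, p = X.shape
    eta = X @ beta_glm
    mu = np.exp(eta)
    loglik = _gamma_loglik(y, eta, nu_glm)
    w = nu_glm * y / mu
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    df = p + 1
    return GlmmFit(
        design=design, beta=beta_glm, beta_se=np.sqrt(np.diag(cov)),
        colnames=list(colnames or [f"b{j}" for j in range(p)]),
        sigma2_site=0.0, sigma2_year=0.0, shape=float(nu_glm),
        loglik=float(loglik), aic=float(-2 * loglik + 2 * df),
        bic=float(-2 * loglik + df * math.log(n)), df=df, n_obs=n,
        blups={"site": {}, "site_year": {}}, centers=centers or {},
        medians=medians or {}, converged=True, mu=mu, eta_fixed=eta,
        frame=frame,
    )


def fit_design(composites: pd.DataFrame, design: ModelDesign) -> GlmmFit:
    """Convenience wrapper: build the design matrix and fit."""
    d = build_design(composites, design)
    medians = {c: float(d["frame"][c].median())
               for c in design.required_columns()}
    grouping = d["siteyear"] if design.random_terms == "year_in_site" else (
        d["year"] if design.random_terms == "year_only" else None
    )
    site = d["year"] if design.random_terms == "year_only" else d["site"]
    return fit_gamma_glmm(
        d["y"], d["X"], site, grouping, design,
        colnames=d["colnames"], centers=d["centers"], medians=medians,
        frame=d["frame"],
    )


def default_ladder() -> list[ModelDesign]:
    """The backward selection ladder, from most to least complex."""
    return [
        ModelDesign(("temp_poly2", "log_vpd", "log_soil_m", "elevation", "co2",
                     "ci_x_fapar"), "year_in_site", "M01"),
        ModelDesign(("temp_poly2", "log_vpd", "log_soil_m", "elevation",
                     "ci_x_fapar"), "year_in_site", "M02"),
        ModelDesign(("temp_poly2", "log_vpd", "log_soil_m", "ci_x_fapar"),
                    "year_in_site", "M03"),
        ModelDesign(("temp_poly2", "log_vpd", "log_soil_m"), "year_in_site", "M04"),
        ModelDesign(("temp_poly2", "log_vpd", "log_soil_m", "td_x_fapar"),
                    "year_in_site", "M05"),
        ModelDesign(("temp_poly2", "log_vpd", "log_soil_m", "log_ci"),
                    "year_in_site", "M06"),
        ModelDesign(("temp_poly2", "log_vpd", "log_ci"), "year_in_site", "M07"),
        ModelDesign(("temp_linear", "vpd_linear", "soil_m_linear", "ci_linear"),
                    "year_in_site", "M08"),
    ]


def selection_ladder(
    composites: pd.DataFrame, ladder: list[ModelDesign] | None = None
) -> tuple[pd.DataFrame, dict[str, GlmmFit]]:
    """Fit every design on a common observation set; rank by AIC.

    Rows missing (or invalid under) any ladder variable are dropped before
    any fit so the information criteria are comparable.
    """
    ladder = ladder or default_ladder()
    needed: set[str] = set()
    positive: set[str] = {"lue"}
    for d in ladder:
        needed |= d.required_columns()
        positive |= d.positive_columns()
    df = composites.dropna(subset=sorted(needed & set(composites.columns)))
    for col in positive & set(df.columns):
        df = df[df[col] > 0]

    rows = []
    fits: dict[str, GlmmFit] = {}
    for d in ladder:
        label = d.label or "+".join(d.fixed_terms)
        try:
            fit = fit_design(df, d)
            fits[label] = fit
            rows.append({
                "model": label,
                "fixed_term": " + ".join(d.fixed_terms),
                "df": fit.df, "aic": fit.aic, "bic": fit.bic,
                "loglik": fit.loglik, "converged": fit.converged,
            })
        except Exception as exc:  # keep the ladder alive per spec
            rows.append({
                "model": label, "fixed_term": " + ".join(d.fixed_terms),
                "df": np.nan, "aic": np.nan, "bic": np.nan,
                "loglik": np.nan, "converged": False, "error": str(exc),
            })
    table = pd.DataFrame(rows)
    ok = table["aic"].notna()
    table["preferred"] = False
    if ok.any():
        table.loc[table.loc[ok, "aic"].idxmin(), "preferred"] = True
    return table, fits


def variance_partition(fit: GlmmFit) -> dict[str, float]:
    """Fractions of link-scale variance: site, year-in-site, residual.

    The residual component is the variance of working residuals
    (y − μ)/μ on the log-link scale, with μ including the random effects.
    Fractions sum to one.
    """
    if fit.mu is None:
        raise ValueError("fit carries no fitted values")
    if fit.design.random_terms != "year_in_site":
        raise ValueError("variance partition requires the nested random design")
    # working residuals on the link scale: d eta/d mu = 1/mu
    r = (fit.frame["lue"].to_numpy() - fit.mu) / fit.mu
    s2_res = float(np.var(r))
    total = fit.sigma2_site + fit.sigma2_year + s2_res
    if total <= 0:
        raise ValueError("zero total variance")
    return {
        "site": fit.sigma2_site / total,
        "year_in_site": fit.sigma2_year / total,
        "residual": s2_res / total,
    }


# mapping from response-curve variable to design terms and columns
_VAR_TERMS = {
    "temp": {"temp_poly2", "temp_linear"},
    "vpd": {"log_vpd", "vpd_linear"},
    "soil_m": {"log_soil_m", "soil_m_linear"},
    "ci": {"log_ci", "ci_linear"},
    "ppfd": {"ppfd"},
}
_TERM_COLS = {
    "temp_poly2": ["temp_c", "temp_c2"], "temp_linear": ["temp_c"],
    "log_vpd": ["log_vpd"], "vpd_linear": ["vpd"],
    "log_soil_m": ["log_soil_m"], "soil_m_linear": ["soil_m"],
    "log_ci": ["log_ci"], "ci_linear": ["ci"], "elevation": ["elv"],
    "co2": ["co2"], "ci_x_fapar": ["ci:fapar"], "td_x_fapar": ["td:fapar"],
    "ppfd": ["ppfd"],
}


def _design_row(fit: GlmmFit, values: dict[str, float]) -> np.ndarray:
    """One fixed-effect design row from raw predictor values."""
    row = {}
    for t in fit.design.fixed_terms:
        if t in ("temp_poly2", "temp_linear"):
            tc = values["temp"] - fit.centers["temp"]
            row["temp_c"] = tc
            if t == "temp_poly2":
                row["temp_c2"] = tc * tc
        elif t == "log_vpd":
            row["log_vpd"] = math.log(values["vpd"])
        elif t == "vpd_linear":
            row["vpd"] = values["vpd"]
        elif t == "log_soil_m":
            row["log_soil_m"] = math.log(values["soil_m"])
        elif t == "soil_m_linear":
            row["soil_m"] = values["soil_m"]
        elif t == "log_ci":
            row["log_ci"] = math.log(values["ci"])
        elif t == "ci_linear":
            row["ci"] = values["ci"]
        elif t == "elevation":
            row["elv"] = values["elv"]
        elif t == "co2":
            row["co2"] = values["co2"]
        elif t == "ci_x_fapar":
            row["ci:fapar"] = values["ci"] * values["fapar"]
        elif t == "td_x_fapar":
            row["td:fapar"] = values["td"] * values["fapar"]
        elif t == "ppfd":
            row["ppfd"] = values["ppfd"]
    return np.array([1.0] + [row[c] for c in fit.colnames[1:]])


def conditional_response(
    fit: GlmmFit, variable: str, n_grid: int = 100
) -> ResponseCurve:
    """Fixed-effect response of LUE to one predictor, others at medians.

    Partial residual for observation *i* is the linear-predictor
    contribution of the focal variable at x_i plus the working residual,
    shown on the response scale against x_i.
    """
    terms = _VAR_TERMS.get(variable, set()) & set(fit.design.fixed_terms)
    if not terms:
        raise ValueError(f"{variable!r} is not in the fitted design")
    if fit.frame is None:
        raise ValueError("fit carries no model frame")
    x_obs = fit.frame[variable].to_numpy()
    grid = np.linspace(x_obs.min(), x_obs.max(), n_grid)

    base_vals = dict(fit.medians)
    eta_grid = np.array([
        _design_row(fit, {**base_vals, variable: g}) @ fit.beta for g in grid
    ])
    mu = np.exp(eta_grid)

    # pointwise band via the delta method on the link scale
    rows = np.stack([_design_row(fit, {**base_vals, variable: g}) for g in grid])
    cov = np.diag(fit.beta_se**2)  # conservative: ignores coefficient covariance
    se = np.sqrt(np.sum((rows @ cov) * rows, axis=1))
    lo, hi = np.exp(eta_grid - 1.96 * se), np.exp(eta_grid + 1.96 * se)

    # partial residuals: focal contribution at x_i on top of the all-median
    # baseline, plus the working residual
    eta_focal_obs = np.array([
        _design_row(fit, {**base_vals, variable: xv}) @ fit.beta for xv in x_obs
    ])
    wres = (fit.frame["lue"].to_numpy() - fit.mu) / fit.mu
    partial_y = np.exp(eta_focal_obs + wres)
    return ResponseCurve(
        variable=variable, grid=grid, mu=mu, lo=lo, hi=hi,
        partial_x=x_obs, partial_y=partial_y,
    )


def temperature_optimum(fit: GlmmFit) -> tuple[float, bool]:
    """Vertex of the fitted temperature parabola, mapped back to °C.

    Returns ``(optimum, ok)``; when the quadratic coefficient is not
    negative there is no interior optimum and ``(inf, False)`` is returned.
    """
    if "temp_c2" not in fit.colnames:
        raise ValueError("fit has no quadratic temperature term")
    b1 = fit.beta[fit.colnames.index("temp_c")]
    b2 = fit.beta[fit.colnames.index("temp_c2")]
    if b2 >= 0:
        return math.inf, False
    return fit.centers["temp"] + (-b1 / (2.0 * b2)), True


def predict_lue(
    fit: GlmmFit, newdata: pd.DataFrame, include_random: bool = False
) -> np.ndarray:
    """Response-scale LUE predictions for new composite rows.

    With ``include_random``, known site and site-year intercepts are added
    on the link scale; unknown groups silently fall back to fixed-only.
    """
    eta = np.empty(len(newdata))
    for i, (_, row) in enumerate(newdata.iterrows()):
        vals = {c: row[c] for c in row.index if isinstance(row[c], (int, float, np.floating))}
        eta[i] = _design_row(fit, vals) @ fit.beta
    if include_random:
        site_b = fit.blups.get("site", {})
        sy_b = fit.blups.get("site_year", {})
        for i, (_, row) in enumerate(newdata.iterrows()):
            s = str(row.get("site_id", ""))
            eta[i] += site_b.get(s, 0.0)
            eta[i] += sy_b.get(f"{s}:{row.get('year', '')}", 0.0)
    return np.exp(eta)


def loo_site_cv(
    composites: pd.DataFrame,
    design: ModelDesign,
    full_fit: GlmmFit | None = None,
) -> dict:
    """Leave-one-site-out cross-validation with a fixed-effects gamma GLM.

    Each fold drops one site, fits the design with no random term on the
    rest, and predicts the held-out site. The pooled R² is the squared
    Pearson correlation between observed and predicted LUE across all
    held-out rows. The in-sample fixed-only R² of the full model (mixed if
    supplied, plain GLM otherwise) is reported as the companion metric.
    """
    sites = composites["site_id"].unique()
    if len(sites) < 3:
        raise ValueError("leave-one-site-out CV needs at least 3 sites")
    d_all = build_design(composites, design)
    frame = d_all["frame"]
    centers = d_all["centers"]
    obs_all, pred_all = [], []
    skipped: list[str] = []
    fixed_design = ModelDesign(design.fixed_terms, "none", design.label + "-glm")
    for s in sites:
        train = frame[frame["site_id"] != s]
        test = frame[frame["site_id"] == s]
        if test.empty or len(train) < len(fixed_design.fixed_terms) + 2:
            skipped.append(str(s))
            continue
        try:
            d_tr = build_design(train, fixed_design, centers=centers)
            fit = fit_gamma_glmm(
                d_tr["y"], d_tr["X"], d_tr["site"], None, fixed_design,
                colnames=d_tr["colnames"], centers=centers,
            )
            pred = predict_lue(fit, test, include_random=False)
        except Exception:
            skipped.append(str(s))
            continue
        obs_all.append(test["lue"].to_numpy())
        pred_all.append(pred)
    obs = np.concatenate(obs_all)
    pred = np.concatenate(pred_all)
    r = np.corrcoef(obs, pred)[0, 1]
    cv_r2 = float(r * r)

    if full_fit is not None and full_fit.eta_fixed is not None:
        mu_fixed = np.exp(full_fit.eta_fixed)
        y_full = full_fit.frame["lue"].to_numpy()
    else:
        fit_full = fit_design(composites, fixed_design)
        mu_fixed = fit_full.mu
        y_full = fit_full.frame["lue"].to_numpy()
    r_in = np.corrcoef(y_full, mu_fixed)[0, 1]
    return {
        "cv_r2": cv_r2,
        "fixed_r2": float(r_in * r_in),
        "n_heldout": int(obs.size),
        "skipped_sites": skipped,
        "observed": obs,
        "predicted": pred,
    }
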