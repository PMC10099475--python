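"""From daily site records to growing-season 15-day LUE composites.

The unit of analysis downstream is a 15-day non-overlapping window of
growing-season days. This module implements the full path from raw daily
records to those composites:

1. photon-flux conversion of shortwave radiation (2.04 µmol J⁻¹);
2. the cloudiness index CI = 1 − S_t/S_o and the Bristow mapping from total
   to diffuse atmospheric transmittance (one shape parameter B), including
   its least-squares fit and gap-filling of missing diffuse records;
3. remote-sensing style fAPAR cleaning (drop saturated values and >3×IQR
   outliers) and daily interpolation with a cubic smoothing spline;
4. site-day quality filters (gap-filled fraction, negative GPP, near-zero
   absorbed light, infeasible apparent LUE);
5. a quantile-threshold growing-season mask per site-year;
6. compositing of consecutive retained days into 15-day windows carrying
   LUE = ΣGPP / (ΣPPFD × mean fAPAR) and window-mean predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import minimize_scalar

from .synthdata import C_MOLAR_MASS, SW_TO_PPFD

__all__ = [
    "FilterThresholds",
    "ppfd_from_shortwave",
    "cloudiness_index",
    "diffuse_transmittance",
    "fit_bristow",
    "gapfill_diffuse",
    "interpolate_fapar",
    "filter_site_days",
    "growing_season_mask",
    "compose_windows",
    "prepare_composites",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Quality and growing-season thresholds applied to site-days."""

    max_gapfill_frac: float = 0.5
    max_lue: float = 0.12              # mol C mol-1 photons, daily apparent LUE
    min_absorbed_ppfd: float = 0.1     # mol m-2 d-1, fAPAR x PPFD
    growing_season_quantiles: tuple[float, float] = (0.05, 0.95)
    growing_season_keep: float = 0.2
    window_days: int = 15
    min_days_per_site_year: int = 30
    ci_ratio_of_sums: bool = True      # window CI as 1 - ΣSt/ΣSo vs mean of daily CI

    def __post_init__(self) -> None:
        if self.max_lue <= 0:
            raise ValueError("max_lue must be positive")
        q1, q2 = self.growing_season_quantiles
        if not 0 <= q1 < q2 <= 1:
            raise ValueError("growing_season_quantiles must be ordered in [0, 1]")
        if not 0 < self.growing_season_keep < 1:
            raise ValueError("growing_season_keep must lie in (0, 1)")


def ppfd_from_shortwave(sw_in):
    """Daily photon flux (mol m⁻² d⁻¹) from daily-mean shortwave (W m⁻²)."""
    sw = np.asarray(sw_in, dtype=float)
    if np.any(sw < 0):
        raise ValueError("shortwave radiation must be non-negative")
    out = sw * SW_TO_PPFD * 1e-6 * 86400.0
    return float(out) if out.ndim == 0 else out


def cloudiness_index(s_t, s_o):
    """CI = 1 − S_t/S_o; NaN where potential radiation is not positive."""
    s_t = np.asarray(s_t, dtype=float)
    s_o = np.asarray(s_o, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(s_o > 0, 1.0 - s_t / s_o, np.nan)
    out = np.clip(ci, 0.0, 1.0)
    out = np.where(np.isnan(ci), np.nan, out)
    return float(out) if out.ndim == 0 else out


def diffuse_transmittance(t_t, B: float):
    """Diffuse transmittance T_d from total transmittance T_T (Bristow).

    T_d = T_T · (1 − exp(0.6·(1 − B/T_T)/(B − 0.4))), valid for
    0 < T_T ≤ 1 and B in (0.4, 1]. T_d = 0 at T_T = B (clear bound) and
    T_d → T_T as T_T → 0 (fully diffuse sky).
    """
    if not 0.4 < B <= 1.0:
        raise ValueError("Bristow B must lie in (0.4, 1]")
    t = np.asarray(t_t, dtype=float)
    if np.any(t <= 0) or np.any(t > 1):
        raise ValueError("total transmittance must lie in (0, 1]")
    out = t * (1.0 - np.exp(0.6 * (1.0 - B / t) / (B - 0.4)))
    out = np.clip(out, 0.0, t)
    return float(out) if out.ndim == 0 else out


def fit_bristow(t_d_obs, t_t_obs) -> tuple[float, float, bool]:
    """Least-squares estimate of the Bristow shape parameter B.

    Returns ``(B_hat, se, boundary_flag)``; the standard error is the
    usual nonlinear-LS linearization, and the flag marks a solution on the
    search boundary B ∈ (0.4, 1].
    """
    td = np.asarray(t_d_obs, dtype=float)
    tt = np.asarray(t_t_obs, dtype=float)
    ok = np.isfinite(td) & np.isfinite(tt) & (tt > 0) & (tt <= 1)
    td, tt = td[ok], tt[ok]
    if td.size < 10:
        raise ValueError("need at least 10 paired transmittance observations")

    def sse(B: float) -> float:
        return float(np.sum((td - diffuse_transmittance(tt, B)) ** 2))

    res = minimize_scalar(sse, bounds=(0.4 + 1e-6, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    b_hat = float(res.x)
    boundary = b_hat < 0.401 or b_hat > 0.9999
    # linearized SE: sigma^2 / sum((dTd/dB)^2)
    h = 1e-6
    grad = (diffuse_transmittance(tt, b_hat + h) - diffuse_transmittance(tt, b_hat - h)) / (2 * h)
    dof = max(td.size - 1, 1)
    sigma2 = sse(b_hat) / dof
    denom = float(np.sum(grad**2))
    se = math.sqrt(sigma2 / denom) if denom > 0 else math.inf
    return b_hat, se, boundary


def gapfill_diffuse(daily: pd.DataFrame, B: float) -> pd.DataFrame:
    """Fill missing diffuse PPFD from the Bristow relation; keep observations.

    Adds/overwrites nothing except NaNs in ``ppfd_dif`` (µmol m⁻² s⁻¹,
    daily-mean), estimated as T_d(S_t/S_o, B) × S_o × 2.04.
    """
    out = daily.copy()
    miss = out["ppfd_dif"].isna() & (out["sw_in_pot"] > 0) & (out["sw_in"] > 0)
    t_t = np.clip(out.loc[miss, "sw_in"] / out.loc[miss, "sw_in_pot"], 1e-9, 1.0)
    t_d = diffuse_transmittance(t_t.to_numpy(), B)
    out.loc[miss, "ppfd_dif"] = t_d * out.loc[miss, "sw_in_pot"].to_numpy() * SW_TO_PPFD
    return out


def interpolate_fapar(
    dates: pd.Series | np.ndarray,
    values: pd.Series | np.ndarray,
    out_dates: pd.Series | np.ndarray,
    iqr_factor: float = 3.0,
) -> np.ndarray:
    """Clean sparse fAPAR observations and interpolate to daily values.

    Drops saturated (=1) values and points further than ``iqr_factor`` times
    the inter-quartile range from the median, then fits a cubic smoothing
    spline (penalty chosen by generalized cross-validation) through the
    survivors and evaluates it on ``out_dates``, clipped to (0, 1].

    Raises ``ValueError`` when fewer than four observations survive.
    """
    d = pd.to_datetime(pd.Series(np.asarray(dates)))
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(v) & (v < 1.0) & (v > 0.0)
    med = np.median(v[keep]) if keep.any() else np.nan
    if keep.any():
        q75, q25 = np.percentile(v[keep], [75, 25])
        iqr = q75 - q25
        if iqr > 0:
            keep &= np.abs(v - med) <= iqr_factor * iqr
    if keep.sum() < 4:
        raise ValueError("fewer than 4 usable fAPAR observations")
    x = d[keep].astype("int64").to_numpy() / 86_400e9  # days
    y = v[keep]
    # the GCV criterion needs strictly increasing x
    order = np.argsort(x)
    x, y = x[order], y[order]
    x, ix = np.unique(x, return_index=True)
    y = y[ix]
    if x.size < 4:
        raise ValueError("fewer than 4 usable fAPAR observations")
    spline = make_smoothing_spline(x, y)
    xo = pd.to_datetime(pd.Series(np.asarray(out_dates))).astype("int64").to_numpy() / 86_400e9
    return np.clip(spline(xo), 1e-6, 1.0)


def filter_site_days(
    daily: pd.DataFrame, thresholds: FilterThresholds
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply site-day quality filters; returns survivors and per-reason counts.

    Requires columns ``gpp``, ``gapfill_frac``, ``ppfd`` and ``fapar``
    (daily interpolated). A record violating several rules is counted once,
    under the first reason in the order: gap-filled fraction, negative GPP,
    near-zero absorbed light, infeasible LUE.
    """
    gap = daily["gapfill_frac"].to_numpy() >= thresholds.max_gapfill_frac
    neg = daily["gpp"].to_numpy() < 0
    absorbed = daily["ppfd"].to_numpy() * daily["fapar"].to_numpy()
    dark = absorbed < thresholds.min_absorbed_ppfd
    with np.errstate(divide="ignore", invalid="ignore"):
        lue_day = (daily["gpp"].to_numpy() / C_MOLAR_MASS) / absorbed
    infeasible = lue_day > thresholds.max_lue

    reasons = {
        "gapfill": gap,
        "negative_gpp": ~gap & neg,
        "low_absorbed_light": ~gap & ~neg & dark,
        "infeasible_lue": ~gap & ~neg & ~dark & infeasible,
    }
    audit = {name: int(mask.sum()) for name, mask in reasons.items()}
    drop = gap | neg | dark | infeasible
    audit["retained"] = int((~drop).sum())
    return daily.loc[~drop].copy(), audit


def growing_season_mask(gpp: np.ndarray, thresholds: FilterThresholds) -> np.ndarray:
    """Growing-season day mask for a single site-year's daily GPP.

    GPP is scaled so the lower quantile maps to 0 and the upper to 1
    (linear interpolation of order statistics); days with scaled GPP
    strictly above the keep threshold are retained. A site-year with fewer
    than ``min_days_per_site_year`` valid days, or a degenerate quantile
    range, is excluded entirely (all-False mask).
    """
    g = np.asarray(gpp, dtype=float)
    valid = np.isfinite(g)
    if valid.sum() < thresholds.min_days_per_site_year:
        return np.zeros(g.size, dtype=bool)
    q1, q2 = thresholds.growing_season_quantiles
    lo, hi = np.quantile(g[valid], [q1, q2])
    if hi <= lo:
        return np.zeros(g.size, dtype=bool)
    scaled = (g - lo) / (hi - lo)
    return valid & (scaled > thresholds.growing_season_keep)


def _runs(dates: np.ndarray) -> list[np.ndarray]:
    """Split a sorted date array into runs of consecutive calendar days."""
    if dates.size == 0:
        return []
    gaps = np.diff(dates).astype("timedelta64[D]").astype(int)
    breaks = np.where(gaps != 1)[0] + 1
    return np.split(np.arange(dates.size), breaks)


def compose_windows(daily: pd.DataFrame, thresholds: FilterThresholds) -> pd.DataFrame:
    """Cut retained days into non-overlapping 15-day windows per site.

    Consecutive runs of retained days restart the window grid; trailing
    stubs shorter than ``window_days`` are discarded. Per window:

    * LUE = Σ(GPP/12.011) / (ΣPPFD × mean fAPAR)  [mol C mol⁻¹ photons],
    * CI aggregated as 1 − ΣS_t/ΣS_o (energy-consistent) by default,
    * other predictors are plain window means,
    * the window year is the calendar year of its first day.
    """
    w = thresholds.window_days
    rows = []
    for site_id, grp in daily.sort_values(["site_id", "date"]).groupby("site_id", sort=False):
        dates = grp["date"].to_numpy().astype("datetime64[D]")
        for run in _runs(dates):
            n_windows = len(run) // w
            for i in range(n_windows):
                block = grp.iloc[run[i * w:(i + 1) * w]]
                ppfd_sum = block["ppfd"].sum()
                fapar_mean = block["fapar"].mean()
                lue = (block["gpp"].sum() / C_MOLAR_MASS) / (ppfd_sum * fapar_mean)
                if thresholds.ci_ratio_of_sums:
                    ci = 1.0 - block["sw_in"].sum() / block["sw_in_pot"].sum()
                    sd_sum = (block["ppfd_dif"] / SW_TO_PPFD).sum()
                    td = sd_sum / block["sw_in_pot"].sum()
                else:
                    ci = cloudiness_index(block["sw_in"], block["sw_in_pot"]).mean()
                    td = (block["ppfd_dif"] / SW_TO_PPFD / block["sw_in_pot"]).mean()
                first = block["date"].iloc[0]
                rows.append(
                    {
                        "site_id": site_id,
                        "year": first.year,
                        "window_index": i,
                        "start_date": first,
                        "lue": lue,
                        "temp": block["ta_day"].mean(),
                        "vpd": block["vpd_day"].mean(),
                        "soil_m": block["soil_m"].mean(),
                        "ci": ci,
                        "td": td,
                        "fapar": fapar_mean,
                        "ppfd": block["ppfd"].mean(),
                        "co2": block["co2"].mean(),
                        "elv": block["elv"].mean() if "elv" in block else np.nan,
                        "n_days": w,
                    }
                )
    composites = pd.DataFrame(rows)
    if not composites.empty:
        composites = composites.sort_values(
            ["site_id", "start_date"], ignore_index=True
        )
    return composites


def prepare_composites(
    daily: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    bristow_b: float | None = None,
    fapar_mode: str = "spline",
    return_retained: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Run the full daily → composite pipeline.

    Parameters
    ----------
    daily
        Daily records in internal column names (see `fluxlue.io`).
    thresholds
        Filter settings; defaults to :class:`FilterThresholds`.
    bristow_b
        Bristow shape parameter for diffuse gap-filling. When None it is
        fitted from the sites that report diffuse radiation, falling back
        to 0.889 if none do.
    fapar_mode
        "spline" (default) cleans and interpolates the sparse fAPAR
        observations; "observed" requires a complete daily ``fapar_obs``
        series and uses it verbatim (useful for closure checks).
    return_retained
        Also return the retained growing-season daily table (the forcing
        grid for third-party model comparisons) as a third element.

    Returns
    -------
    (composites, audit)
        The composite table and a dictionary of filter counts and fit
        metadata (fitted B, per-reason exclusions, excluded fAPAR sites).
    """
    thresholds = thresholds or FilterThresholds()
    audit: dict = {}

    df = daily.copy()
    df["ppfd"] = ppfd_from_shortwave(df["sw_in"].to_numpy())

    # Bristow fit from instrumented sites, then diffuse gap-filling
    if bristow_b is None:
        obs = df[df["ppfd_dif"].notna() & (df["sw_in_pot"] > 0) & (df["sw_in"] > 0)]
        if len(obs) >= 10:
            t_t = np.clip(obs["sw_in"] / obs["sw_in_pot"], 1e-9, 1.0)
            t_d = np.clip(obs["ppfd_dif"] / SW_TO_PPFD / obs["sw_in_pot"], 1e-9, 1.0)
            bristow_b, b_se, b_boundary = fit_bristow(t_d, t_t)
            audit["bristow"] = {"B": bristow_b, "se": b_se, "boundary": b_boundary}
        else:
            bristow_b = 0.889
            audit["bristow"] = {"B": bristow_b, "se": None, "boundary": False}
    else:
        audit["bristow"] = {"B": bristow_b, "se": None, "boundary": False}
    df = gapfill_diffuse(df, bristow_b)

    # daily fAPAR
    excluded_sites: list[str] = []
    if fapar_mode == "observed":
        if df["fapar_obs"].isna().any():
            raise ValueError("fapar_mode='observed' requires a complete daily series")
        df["fapar"] = df["fapar_obs"]
    elif fapar_mode == "spline":
        fapar = np.full(len(df), np.nan)
        for site_id, grp in df.groupby("site_id", sort=False):
            obs = grp[grp["fapar_obs"].notna()]
            try:
                fapar[grp.index.to_numpy()] = interpolate_fapar(
                    obs["date"], obs["fapar_obs"], grp["date"]
                )
            except ValueError:
                excluded_sites.append(site_id)
        df["fapar"] = fapar
        df = df[df["fapar"].notna()]
    else:
        raise ValueError(f"unknown fapar_mode {fapar_mode!r}")
    audit["fapar_excluded_sites"] = excluded_sites

    df, filter_audit = filter_site_days(df, thresholds)
    audit["site_day_filters"] = filter_audit

    # growing season per site-year
    keep = np.zeros(len(df), dtype=bool)
    df = df.reset_index(drop=True)
    year = df["date"].dt.year
    excluded_site_years = 0
    for _, grp in df.groupby(["site_id", year], sort=False):
        mask = growing_season_mask(grp["gpp"].to_numpy(), thresholds)
        if not mask.any():
            excluded_site_years += 1
        keep[grp.index.to_numpy()] = mask
    audit["growing_season"] = {
        "retained_days": int(keep.sum()),
        "excluded_site_years": excluded_site_years,
    }
    df = df.loc[keep]

    composites = compose_windows(df, thresholds)
    audit["n_windows"] = len(composites)
    if return_retained:
        return composites, audit, df
    return composites, audit
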