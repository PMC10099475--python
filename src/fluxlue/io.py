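"""CSV dialects, run configuration and the end-to-end pipeline driver.

The daily interchange format follows FLUXNET naming (GPP_NT_VUT_REF,
SW_IN_F, SW_IN_POT, PPFD_DIF, TA_F_DAY, VPD_F, CO2_F_MDS) extended with
SOIL_M, FAPAR_OBS, GAPFILL_FRAC, ELV, SITE_ID and ISO-8601 DATE. The
missing-value sentinel −9999 maps to NaN on read. All interchange is plain
CSV so runs are diff-able.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, glmm, pmodel
from .preprocess import FilterThresholds, prepare_composites
from .synthdata import SyntheticConfig, TrueCoefficients, generate_site_network

log = logging.getLogger("fluxlue")

MISSING = -9999.0

_FLUXNET_TO_INTERNAL = {
    "SITE_ID": "site_id",
    "DATE": "date",
    "GPP_NT_VUT_REF": "gpp",
    "SW_IN_F": "sw_in",
    "SW_IN_POT": "sw_in_pot",
    "PPFD_DIF": "ppfd_dif",
    "TA_F_DAY": "ta_day",
    "VPD_F": "vpd_day",
    "CO2_F_MDS": "co2",
    "SOIL_M": "soil_m",
    "FAPAR_OBS": "fapar_obs",
    "GAPFILL_FRAC": "gapfill_frac",
    "ELV": "elv",
}
_INTERNAL_TO_FLUXNET = {v: k for k, v in _FLUXNET_TO_INTERNAL.items()}
_REQUIRED = ["SITE_ID", "DATE", "GPP_NT_VUT_REF", "SW_IN_F", "SW_IN_POT",
             "TA_F_DAY", "VPD_F", "SOIL_M", "GAPFILL_FRAC"]


def read_daily_table(path) -> pd.DataFrame:
    """Read a FLUXNET-style daily CSV into internal column names."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"daily table is missing required column(s): {missing}")
    if df.empty:
        log.warning("daily table %s is empty", path)
    df = df.rename(columns=_FLUXNET_TO_INTERNAL)
    for col in df.columns:
        if col in ("site_id", "date"):
            continue
        df[col] = df[col].replace(MISSING, np.nan)
    df["date"] = pd.to_datetime(df["date"])
    for col in ("ppfd_dif", "co2", "fapar_obs", "elv"):
        if col not in df.columns:
            df[col] = np.nan
    return df


def write_daily_table(daily: pd.DataFrame, path) -> None:
    """Write internal daily records as a FLUXNET-style CSV (−9999 sentinel)."""
    out = daily.rename(columns=_INTERNAL_TO_FLUXNET).copy()
    out["DATE"] = pd.to_datetime(out["DATE"]).dt.strftime("%Y-%m-%d")
    num = out.columns.difference(["SITE_ID", "DATE"])
    out[num] = out[num].fillna(MISSING)
    out.to_csv(path, index=False)


def read_model_output(path) -> pd.DataFrame:
    """Read third-party model series (MODEL, SITE_ID, DATE, GPP[, LAI, FAPAR])."""
    df = pd.read_csv(path)
    for col in ("MODEL", "SITE_ID", "DATE", "GPP"):
        if col not in df.columns:
            raise ValueError(f"model-output table is missing column {col}")
    df = df.rename(columns={
        "MODEL": "model_name", "SITE_ID": "site_id", "DATE": "date",
        "GPP": "gpp_sim", "LAI": "lai_sim", "FAPAR": "fapar_sim",
    })
    df["date"] = pd.to_datetime(df["date"])
    for col in df.columns:
        if col not in ("model_name", "site_id", "date"):
            df[col] = df[col].replace(MISSING, np.nan)
    return df


@dataclasses.dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: str = "fluxlue_run"
    daily_csv: str | None = None        # None → simulate
    model_output_csv: str | None = None
    seed: int = 1
    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    thresholds: FilterThresholds = dataclasses.field(default_factory=FilterThresholds)
    fapar_mode: str = "spline"
    response_variables: tuple[str, ...] = ("temp", "vpd", "soil_m", "ci")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", {})
        coeffs = syn.pop("true_coefficients", {})
        thr = raw.pop("thresholds", {})
        cfg = cls(**raw)
        if syn or coeffs:
            cfg.synthetic = SyntheticConfig(
                **syn, true_coefficients=TrueCoefficients(**coeffs)
            )
        if thr:
            cfg.thresholds = FilterThresholds(**thr)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["response_variables"] = list(self.response_variables)
        return d

    def config_hash(self) -> str:
        # hash covers the scientific settings, not where results are written
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """simulate (optional) → preprocess → fit/select → responses → P-model → compare.

    Writes every table as CSV plus a provenance JSON (config hash, seed)
    into ``config.out_dir`` and returns the artifact bundle in memory.
    A failing stage raises with the stage name; audit counts accumulated so
    far are preserved in the bundle directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    bundle: dict = {}
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    _write_json(provenance, out / "provenance.json")

    stage = "simulate"
    try:
        if config.daily_csv is None:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            daily, truth = generate_site_network(syn)
            write_daily_table(daily, out / "daily.csv")
            truth.to_csv(out / "truth.csv", index=False)
            bundle["truth"] = truth
        else:
            daily = read_daily_table(config.daily_csv)
        bundle["daily"] = daily

        stage = "preprocess"
        composites, audit, retained_daily = prepare_composites(
            daily, config.thresholds, fapar_mode=config.fapar_mode,
            return_retained=True,
        )
        bundle["retained_daily"] = retained_daily
        audit["config_hash"] = provenance["config_hash"]
        composites.to_csv(out / "composites.csv", index=False)
        _write_json(audit, out / "filter_audit.json")
        bundle["composites"] = composites
        bundle["audit"] = audit

        stage = "select"
        table, fits = glmm.selection_ladder(composites)
        table.insert(0, "config_hash", provenance["config_hash"])
        table.to_csv(out / "selection.csv", index=False)
        bundle["selection"] = table
        preferred_label = table.loc[table["preferred"], "model"].iloc[0]
        fit = fits[preferred_label]
        _write_json(fit.summary_dict() | {"config_hash": provenance["config_hash"]},
                    out / "fit.json")
        bundle["fit"] = fit

        stage = "respond"
        curves = []
        for v in config.response_variables:
            try:
                rc = glmm.conditional_response(fit, v)
            except ValueError:
                continue
            curves.append(rc.to_frame())
        curve_table = pd.concat(curves, ignore_index=True)
        curve_table.insert(0, "config_hash", provenance["config_hash"])
        curve_table.to_csv(out / "response_curves.csv", index=False)
        bundle["curves"] = curve_table

        topt, ok = glmm.temperature_optimum(fit)
        vparts = glmm.variance_partition(fit)
        cv = glmm.loo_site_cv(composites, fit.design, full_fit=fit)
        summary = {
            "temperature_optimum_c": topt if ok else None,
            "variance_fractions": vparts,
            "cv_r2": cv["cv_r2"],
            "fixed_r2": cv["fixed_r2"],
            "config_hash": provenance["config_hash"],
        }

        stage = "pmodel"
        pcurves = [
            pmodel.stylized_experiment(composites, v)
            for v in ("temp", "vpd", "soil_m", "ci")
        ]
        ptable = pd.concat(pcurves, ignore_index=True)
        ptable.insert(0, "config_hash", provenance["config_hash"])
        ptable.to_csv(out / "pmodel_curves.csv", index=False)
        bundle["pmodel_curves"] = ptable
        plue = pmodel.simulate_lue(composites)
        summary["nse_pmodel_lue"] = compare.nash_sutcliffe(
            composites["lue"].to_numpy(), plue
        )

        stage = "compare"
        if config.model_output_csv is not None:
            series = read_model_output(config.model_output_csv)
            per_model = {}
            for name, grp in series.groupby("model_name"):
                per_model[name] = compare.model_lue_composites(
                    grp, retained_daily, config.thresholds
                )
            ens = compare.ensemble_fit(per_model)
            nse = compare.ensemble_nse(per_model, composites)
            _write_json({"nse": nse}, out / "ensemble_nse.json")
            bundle["ensemble"] = ens

        _write_json(summary, out / "summary.json")
        bundle["summary"] = summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle
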