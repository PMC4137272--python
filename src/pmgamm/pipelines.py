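"""End-to-end exposure-model pipelines: the direct PM2.5 / PM10 variants and
the historical ratio-based PM2.5 reconstruction, with native-scale
predictions and delta-method uncertainty.

A fitted model composes

* stage 1 (per region): site intercepts u_i, monthly regional intercepts
  a_tr, 1-D smooths of the time-varying covariates, and residual monthly (or
  seasonal) spatial surfaces;
* stage 2 (domain-wide): smooths of the time-invariant covariates and a
  spatial surface on the u_i.

A log-scale prediction sums the stage-2 prediction at the location, the
monthly intercept, the time-varying smooth terms, and the monthly/seasonal
surface; its variance adds the stage-2 posterior prediction variance, the
monthly-intercept variance and the surface prediction variance, treated as
independent across stages.  Observation-level variance optionally adds
sigma2_b + sigma2_e.  Native-scale means are exponentials; native SEs follow
the first-order delta method, SE = exp(mu) * sigma_log.

The ratio variant models ln(PM2.5 / predicted PM10) with seasonal surfaces
and a temporal smooth h(t); the predicted ratio is truncated at one before
multiplying by predicted PM10, and the coarse fraction is the difference of
the native-scale predictions, with variances combined under independence.
"""
from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import met as met_mod
from . import stage1 as s1
from . import stage2 as s2
from .covariates import CovariateTable
from .splines import InvalidArgument

logger = logging.getLogger(__name__)

Z195 = 1.959963984540054


@dataclass
class ModelSpec:
    """Configuration of one exposure-model variant."""

    variant: str = "pm_direct"          # pm_direct | pm10_direct | ratio
    x_terms: list = field(default_factory=lambda: [
        "elevation", "urban_1km", "log_pop_density"])
    z_terms: list = field(default_factory=lambda: [
        "temperature", "wind_speed"])
    stage1: s1.Stage1Config = field(default_factory=s1.Stage1Config)
    stage2: s2.Stage2Config = field(default_factory=s2.Stage2Config)
    predict_months: list | None = None  # ratio variant: historical window

    def __post_init__(self):
        if self.variant not in ("pm_direct", "pm10_direct", "ratio"):
            raise InvalidArgument(f"unknown variant {self.variant!r}")
        if self.variant == "ratio":
            # seasonal surfaces + temporal smooth + predicted-PM10 covariate
            self.stage1.seasonal = True
            self.stage1.h_term = True


@dataclass
class FittedExposureModel:
    """Stage-1 + stage-2 composition, sufficient for prediction with
    uncertainty."""

    spec: ModelSpec
    stage1_fits: dict                   # region -> Stage1Fit
    stage2_fit: "s2.Stage2Fit"
    covariates: CovariateTable          # with recorded training ranges
    sites: pd.DataFrame                 # training roster
    region_map: object
    months: np.ndarray
    outliers_removed: int = 0
    pm10_model: "FittedExposureModel | None" = None

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "FittedExposureModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def remove_ratio_outliers(pm25: pd.DataFrame, pm10_pred: pd.Series):
    """Delete records where observed PM2.5 exceeds 1.5 x predicted PM10.

    ``pm10_pred`` must be indexed like ``pm25`` rows.  The boundary case
    PM2.5 == 1.5 x predicted PM10 is kept (strict inequality).  Returns
    (filtered panel, removal count).
    """
    ratio = pm25["conc"].to_numpy(float) / np.asarray(pm10_pred, float)
    bad = ratio > 1.5
    return pm25[~bad].reset_index(drop=True), int(bad.sum())


def clamp_covariates(values: pd.DataFrame, ranges: dict,
                     regions=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clamp covariates to their training ranges.

    With ``regions`` None the ranges are global (time-invariant covariates,
    keys = column names); otherwise ranges are per region (keys =
    (column, region)) and ``regions`` gives each row's region.  Returns
    (clamped values, boolean flags).
    """
    out = values.copy()
    flags = pd.DataFrame(False, index=values.index, columns=values.columns)
    for c in values.columns:
        v = values[c].to_numpy(float)
        if regions is None:
            if c not in ranges:
                raise InvalidArgument(f"no recorded range for {c!r}")
            lo, hi = ranges[c]
            clamped = np.clip(v, lo, hi)
        else:
            clamped = v.copy()
            reg = np.asarray(regions)
            for r in pd.unique(reg):
                if (c, r) not in ranges:
                    raise InvalidArgument(f"no recorded range for {c!r} "
                                          f"in region {r!r}")
                lo, hi = ranges[(c, r)]
                m = reg == r
                clamped[m] = np.clip(v[m], lo, hi)
        flags[c] = clamped != v
        out[c] = clamped
    return out, flags


def fit_exposure_model(spec: ModelSpec, panel: pd.DataFrame,
                       sites: pd.DataFrame, cov: CovariateTable,
                       region_map, pm10_model: "FittedExposureModel" = None,
                       met_panel: pd.DataFrame | None = None
                       ) -> FittedExposureModel:
    """Fit one model variant end to end.

    ``panel``: site_id, month, conc (native).  For the ratio variant,
    ``pm10_model`` (a fitted pm10_direct model) is required: its predictions
    define the ratio response and serve as a time-varying covariate; records
    with PM2.5 > 1.5 x predicted PM10 are deleted first.

    If ``met_panel`` (station meteorology) is given, meteorology surfaces are
    fitted and evaluated at the sites to build the time-varying covariates;
    otherwise ``cov.Z`` is used as-is.
    """
    cov = cov.copy()
    if met_panel is not None:
        surfaces = met_mod.fit_met_surfaces(met_panel)
        months_all = np.sort(panel["month"].unique())
        zpred = met_mod.predict_met_panel(surfaces, sites, months_all)
        cov.Z = zpred.rename(columns={"stagnation": "log_stagnation"})
        cov.record_ranges(sites.set_index("site_id")["region"])
    z_terms = list(spec.z_terms)
    outliers = 0

    work_panel = panel
    if spec.variant == "ratio":
        if pm10_model is None:
            raise InvalidArgument("ratio variant requires a fitted PM10 model")
        pm10_hat = predict(pm10_model, sites, np.sort(panel["month"].unique()),
                           include_observation_var=False)
        key = pm10_hat.set_index(["site_id", "month"])["mean"]
        idx = pd.MultiIndex.from_frame(panel[["site_id", "month"]])
        hat = key.reindex(idx).to_numpy(float)
        ok = np.isfinite(hat)
        panel25, hat = panel[ok].reset_index(drop=True), hat[ok]
        work_panel, outliers = remove_ratio_outliers(panel25, hat)
        kept_hat = hat[panel25["conc"].to_numpy(float) / hat <= 1.5]
        # response: ratio of observed PM2.5 to predicted PM10
        work_panel = work_panel.assign(conc=work_panel["conc"].to_numpy()
                                       / kept_hat)
        # predicted PM10 (log scale) as an extra time-varying covariate
        zcol = "log_pm10_hat"
        extra = pd.DataFrame({
            "site_id": pm10_hat["site_id"], "month": pm10_hat["month"],
            zcol: np.log(pm10_hat["mean"].to_numpy(float))})
        cov.Z = cov.Z.merge(extra, on=["site_id", "month"], how="left")
        cov.record_ranges(sites.set_index("site_id")["region"])
        z_terms = z_terms + [zcol]

    fits = s1.fit_stage1(work_panel, sites, cov.Z, region_map,
                         spec.stage1, z_columns=z_terms)
    u = s1.combined_site_intercepts(fits)
    f2 = s2.fit_stage2(u, cov.X, sites[["site_id", "x", "y"]],
                       x_terms=spec.x_terms,
                       regions=sites.set_index("site_id")["region"],
                       config=spec.stage2)
    cov.record_ranges(sites.set_index("site_id")["region"])
    return FittedExposureModel(
        spec=spec, stage1_fits=fits, stage2_fit=f2, covariates=cov,
        sites=sites.copy(), region_map=region_map,
        months=np.sort(work_panel["month"].unique()),
        outliers_removed=outliers, pm10_model=pm10_model)


def predict_log(model: FittedExposureModel, locations: pd.DataFrame,
                months, X_new: pd.DataFrame | None = None,
                Z_new: pd.DataFrame | None = None,
                include_observation_var: bool = False) -> pd.DataFrame:
    """Log-scale predictions with variances at given sites and months.

    ``locations``: site_id, x, y, region.  ``X_new`` defaults to the model's
    covariate table (rows for the requested sites); ``Z_new`` likewise.
    Covariates are clamped to the training ranges (globally for X, within
    region for Z).  Months outside the training window raise an error.

    Returns columns site_id, month, log_mean, log_var, clamped (count of
    clamped covariates for the row).
    """
    months = np.atleast_1d(np.asarray(months, dtype=int))
    known = set(int(m) for m in model.months)
    bad = [m for m in months if int(m) not in known]
    if bad:
        raise InvalidArgument(f"months outside the training window: {bad}")
    if model.spec.predict_months is not None:
        allowed = set(int(m) for m in model.spec.predict_months)
        outside = [m for m in months if int(m) not in allowed]
        if outside:
            raise InvalidArgument(
                f"months outside the prediction window: {outside}")

    cov = model.covariates
    sids = locations["site_id"].to_numpy()
    regions = locations["region"].to_numpy()
    coords = locations[["x", "y"]].to_numpy(float)

    X_new = (cov.X.loc[sids] if X_new is None else X_new.loc[sids])
    x_cols = [c for c in model.spec.x_terms if c in X_new.columns]
    Xc, xflags = clamp_covariates(X_new[x_cols],
                                  {c: cov.x_ranges[c] for c in x_cols})

    u_pred, u_var = model.stage2_fit.predict(
        Xc, coords, regions=regions, with_var=True)

    if Z_new is None:
        Z_new = cov.Z
    Zi = Z_new.set_index(["site_id", "month"]).sort_index()

    out = []
    for m in months:
        mu = u_pred.copy()
        var = u_var.copy()
        nclamp = xflags.sum(axis=1).to_numpy(int).copy()
        zrows = Zi.reindex(list(zip(sids, [int(m)] * len(sids))))
        for region in pd.unique(regions):
            mask = regions == region
            f1 = model.stage1_fits[region]
            mu[mask] += float(f1.alpha_t.get(int(m), 0.0))
            var[mask] += float(f1.alpha_t_var.get(int(m), 0.0))
            # time-varying smooths at (clamped) covariate values
            for zname, sm in f1.f_smooths.items():
                zv = zrows[zname].to_numpy(float)[mask]
                lo, hi = cov.z_ranges.get((zname, region),
                                          (-np.inf, np.inf))
                zc = np.clip(zv, lo, hi)
                nclamp[mask] += (zc != zv).astype(int)
                mu[mask] += sm(zc)
            if f1.h_smooth is not None:
                mu[mask] += float(f1.h_smooth(np.array([float(m)]))[0])
            surf = f1.g_surfaces.get(f1.period_key(int(m)))
            if surf is not None:
                mu[mask] += surf(coords[mask])
                var[mask] += surf.predict_var(coords[mask])
            if include_observation_var:
                var[mask] += model.stage2_fit.sigma_b
                var[mask] += f1.sigma_e.get(int(m),
                                            float(np.mean(list(
                                                f1.sigma_e.values()))))
        out.append(pd.DataFrame({
            "site_id": sids, "month": int(m), "log_mean": mu,
            "log_var": var, "clamped": nclamp}))
    return pd.concat(out, ignore_index=True)


def predict_native(log_mean, log_se):
    """Native-scale mean and delta-method SE from log-scale mean and SE."""
    log_mean = np.asarray(log_mean, float)
    log_se = np.asarray(log_se, float)
    if np.any(log_se < 0):
        raise InvalidArgument("negative log-scale SE")
    mean = np.exp(log_mean)
    return mean, mean * log_se


def combine_ratio_pm10(ratio_mean, ratio_se, pm10_mean, pm10_se):
    """PM2.5 = (ratio truncated at 1) x PM10, with independent errors.

    Returns (mean, se, truncated flag).  var = r^2 var10 + pm10^2 var_r.
    """
    ratio_mean = np.asarray(ratio_mean, float)
    ratio_se = np.asarray(ratio_se, float)
    pm10_mean = np.asarray(pm10_mean, float)
    pm10_se = np.asarray(pm10_se, float)
    if np.any(ratio_mean < 0) or np.any(pm10_mean < 0):
        raise InvalidArgument("negative native-scale inputs")
    truncated = ratio_mean > 1.0
    r = np.minimum(ratio_mean, 1.0)
    mean = r * pm10_mean
    var = r ** 2 * pm10_se ** 2 + pm10_mean ** 2 * ratio_se ** 2
    return mean, np.sqrt(var), truncated


def coarse_fraction(pm10_mean, pm10_se, pm25_mean, pm25_se):
    """PM2.5-10 = PM10 - PM2.5 with independent errors.

    Negative means are retained but flagged (validation excludes them).
    Returns (mean, se, nonpositive flag).
    """
    pm10_mean = np.asarray(pm10_mean, float)
    pm25_mean = np.asarray(pm25_mean, float)
    mean = pm10_mean - pm25_mean
    se = np.hypot(np.asarray(pm10_se, float), np.asarray(pm25_se, float))
    return mean, se, mean <= 0


def predict(model: FittedExposureModel, locations: pd.DataFrame, months,
            include_observation_var: bool = True) -> pd.DataFrame:
    """Native-scale predictions with SEs and 95% intervals.

    Direct variants: mean = exp(log mean); the 95% interval is the
    exponentiated log-scale interval.  Ratio variant: the predicted ratio
    (truncated at 1) is multiplied by the PM10 model's prediction and errors
    are propagated on the native scale; intervals are native-scale normal
    with the lower bound floored at zero.
    """
    lg = predict_log(model, locations, months,
                     include_observation_var=include_observation_var)
    se_log = np.sqrt(lg["log_var"].to_numpy(float))
    mean, se = predict_native(lg["log_mean"].to_numpy(float), se_log)
    out = lg[["site_id", "month", "clamped"]].copy()

    if model.spec.variant != "ratio":
        out["mean"] = mean
        out["se"] = se
        out["lo95"] = np.exp(lg["log_mean"] - Z195 * se_log)
        out["hi95"] = np.exp(lg["log_mean"] + Z195 * se_log)
        return out

    pm10 = predict(model.pm10_model, locations, months,
                   include_observation_var=include_observation_var)
    key = pm10.set_index(["site_id", "month"])
    idx = pd.MultiIndex.from_frame(out[["site_id", "month"]])
    pm10_mean = key["mean"].reindex(idx).to_numpy(float)
    pm10_se = key["se"].reindex(idx).to_numpy(float)
    c_mean, c_se, trunc = combine_ratio_pm10(mean, se, pm10_mean, pm10_se)
    out["mean"] = c_mean
    out["se"] = c_se
    out["lo95"] = np.maximum(c_mean - Z195 * c_se, 0.0)
    out["hi95"] = c_mean + Z195 * c_se
    out["ratio_truncated"] = trunc
    return out


def write_predictions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
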