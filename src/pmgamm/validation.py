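"""Site-exclusive cross-validation and the bias/precision metric suite.

Sites (all their months) are assigned at random to one of 10 folds; fold 10
is reserved during covariate selection to detect selection-induced
over-fitting.  For sparse historical panels, a single well-observed
evaluation year drives CV instead: qualifying sites need enough monthly
values in that year and overall, and a random subset is withheld from
fitting so the evaluation year's network density matches the historical
years.

Metrics: CV R-squared (squared Pearson correlation of left-out observations
and predictions, native scale), its spatial version on per-site long-term
means, normalized mean bias and error factors (NMBF / NMEF), mean absolute
prediction error (CVMAE), major-axis regression of log observations on log
predictions, and 95% prediction-interval coverage.

NMBF / NMEF use the sign-symmetric factor definitions: with O observed and M
modelled, if mean(M) >= mean(O) then NMBF = sum(M)/sum(O) - 1 and
NMEF = sum|M - O| / sum(O); otherwise NMBF = 1 - sum(O)/sum(M) and
NMEF = sum|M - O| / sum(M); both reported in percent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .splines import InvalidArgument

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fold designs
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Site-level fold assignment; fold 10 is the reserved set."""

    folds: pd.Series               # site_id -> fold 1..n_folds
    seed: int
    design: str = "standard"       # standard | eval_year
    reserved_fold: int = 10
    withheld_sites: list = field(default_factory=list)  # eval-year design
    eval_months: list | None = None

    def sites_in(self, fold: int) -> list:
        return self.folds.index[self.folds == fold].tolist()


def assign_folds(site_ids, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Uniform random site-level partition into folds, deterministic in seed."""
    site_ids = list(site_ids)
    if len(site_ids) < n_folds:
        raise InvalidArgument("fewer sites than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(site_ids))
    fold = np.empty(len(site_ids), dtype=int)
    fold[order] = np.arange(len(site_ids)) % n_folds + 1
    return FoldAssignment(
        folds=pd.Series(fold, index=pd.Index(site_ids, name="site_id")),
        seed=seed, reserved_fold=n_folds)


def build_year2000_design(panel: pd.DataFrame, coords: pd.DataFrame,
                          eval_months, seed: int = 0,
                          min_eval_values: int = 10,
                          min_total_values: int = 70,
                          target_density: float | None = None,
                          n_folds: int = 10,
                          n_candidate_seeds: int = 25) -> FoldAssignment:
    """Evaluation-year CV design for sparse historical panels.

    Qualifying sites have >= ``min_eval_values`` monthly values within the
    evaluation year and >= ``min_total_values`` overall.  A random subset of
    qualifying sites is withheld from CV (its data stay in the fitting set)
    so that the evaluation year's fitting density is comparable to the
    historical years; the withheld set is chosen among ``n_candidate_seeds``
    draws as the one with the best spatial coverage (max-min nearest-
    neighbour distance).  The remaining qualifying sites are split into
    ``n_folds`` folds.
    """
    eval_months = sorted(int(m) for m in eval_months)
    in_eval = panel["month"].isin(eval_months)
    if not in_eval.any():
        raise InvalidArgument("panel does not span the evaluation year")
    n_eval = panel[in_eval].groupby("site_id").size()
    n_tot = panel.groupby("site_id").size()
    qual = n_eval[(n_eval >= min_eval_values)
                  & (n_tot.reindex(n_eval.index) >= min_total_values)].index
    if len(qual) == 0:
        raise InvalidArgument("no qualifying sites")
    if len(qual) < n_folds:
        raise InvalidArgument("fewer qualifying sites than folds")

    # fitting density in historical months vs the evaluation year
    hist = panel[~in_eval]
    hist_density = (hist.groupby("month")["site_id"].nunique().mean()
                    if len(hist) else 0.0)
    eval_density = panel[in_eval].groupby("month")["site_id"].nunique().mean()
    if target_density is None:
        target_density = hist_density
    n_withhold = int(max(min(len(qual) - n_folds,
                             round(eval_density - target_density)), 0))

    xy = coords.set_index("site_id").loc[qual, ["x", "y"]].to_numpy(float)
    best, best_score = [], -np.inf
    if n_withhold > 0:
        for trial in range(n_candidate_seeds):
            rng = np.random.default_rng(seed + 1000 + trial)
            pick = rng.choice(len(qual), size=n_withhold, replace=False)
            rest = np.setdiff1d(np.arange(len(qual)), pick)
            # spatial coverage of the *retained* CV sites
            pts = xy[rest]
            if len(pts) < 2:
                continue
            d = squareform(pdist(pts))
            np.fill_diagonal(d, np.inf)
            score = float(d.min(axis=1).min())
            if score > best_score:
                best_score = score
                best = [qual[i] for i in pick]
    cv_sites = [s for s in qual if s not in set(best)]
    fa = assign_folds(cv_sites, n_folds=n_folds, seed=seed)
    fa.design = "eval_year"
    fa.withheld_sites = list(best)
    fa.eval_months = eval_months
    return fa


def run_cv(fit_fn, predict_fn, panel: pd.DataFrame,
           assignment: FoldAssignment, folds=None) -> pd.DataFrame:
    """Site-exclusive cross-validation of a full pipeline.

    ``fit_fn(train_panel, train_sites) -> model`` and
    ``predict_fn(model, site_ids, months) -> DataFrame`` with site_id, month,
    mean (and optionally se / lo95 / hi95).  For each fold (default 1..9,
    the reserved fold excluded) the pipeline is refit without the fold's
    sites and predictions are pooled at the left-out site-months.  In the
    evaluation-year design only the evaluation months are scored.

    Returns the pooled table with observed values joined.
    """
    folds = list(folds) if folds is not None else [
        f for f in sorted(assignment.folds.unique())
        if f != assignment.reserved_fold]
    results = []
    for f in folds:
        held = set(assignment.sites_in(f))
        train_panel = panel[~panel["site_id"].isin(held)]
        try:
            model = fit_fn(train_panel, sorted(set(train_panel["site_id"])))
        except Exception as exc:   # noqa: BLE001 - fold id context matters
            raise RuntimeError(f"refit failed for fold {f}") from exc
        test = panel[panel["site_id"].isin(held)]
        if assignment.eval_months is not None:
            test = test[test["month"].isin(assignment.eval_months)]
        if test.empty:
            continue
        months = sorted(test["month"].unique())
        pred = predict_fn(model, sorted(held), months)
        merged = test.merge(pred, on=["site_id", "month"], how="inner")
        merged["fold"] = f
        results.append(merged)
    if not results:
        raise InvalidArgument("cross-validation produced no predictions")
    return pd.concat(results, ignore_index=True)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def cv_r2(observed, predicted) -> float:
    """Squared Pearson correlation of observations and predictions."""
    o = np.asarray(observed, float)
    m = np.asarray(predicted, float)
    if o.size < 3:
        raise InvalidArgument("need >= 3 pairs")
    if np.std(o) == 0 or np.std(m) == 0:
        return float("nan")
    return float(np.corrcoef(o, m)[0, 1] ** 2)


def spatial_cv_r2(observed, predicted, site_ids) -> float:
    """CV R-squared on per-site long-term means (one mean per site)."""
    df = pd.DataFrame({"o": np.asarray(observed, float),
                       "m": np.asarray(predicted, float),
                       "site_id": np.asarray(site_ids)})
    g = df.groupby("site_id").mean()
    if len(g) < 3:
        raise InvalidArgument("need >= 3 sites")
    return cv_r2(g["o"], g["m"])


def bias_error_metrics(observed, predicted) -> dict:
    """NMBF (%), NMEF (%), and CVMAE under the factor definitions above."""
    o = np.asarray(observed, float)
    m = np.asarray(predicted, float)
    so, sm = float(np.sum(o)), float(np.sum(m))
    if so <= 0 or sm <= 0:
        return {"nmbf_pct": float("nan"), "nmef_pct": float("nan"),
                "cvmae": float(np.mean(np.abs(m - o))) if o.size else
                float("nan")}
    sae = float(np.sum(np.abs(m - o)))
    if np.mean(m) >= np.mean(o):
        nmbf = sm / so - 1.0
        nmef = sae / so
    else:
        nmbf = 1.0 - so / sm
        nmef = sae / sm
    return {"nmbf_pct": 100.0 * nmbf, "nmef_pct": 100.0 * nmef,
            "cvmae": float(np.mean(np.abs(m - o)))}


def major_axis_fit(x, y) -> tuple[float, float]:
    """Major-axis (first principal axis) regression of y on x.

    Both variables are treated as error-prone; the slope is the direction of
    the leading eigenvector of the 2x2 covariance matrix, oriented to
    positive slope when the covariance is positive.  Returns
    (intercept, slope).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise InvalidArgument("need >= 3 pairs")
    C = np.cov(x, y)
    if np.allclose(C, 0):
        return float("nan"), float("nan")
    w, V = np.linalg.eigh(C)
    v = V[:, np.argmax(w)]
    if v[0] == 0:
        return float("nan"), float("inf")
    slope = v[1] / v[0]
    if C[0, 1] != 0 and np.sign(slope) != np.sign(C[0, 1]):
        slope = -slope
    intercept = float(np.mean(y) - slope * np.mean(x))
    return intercept, float(slope)


def pi_coverage(observed, lo, hi) -> float:
    """Fraction of observations inside their prediction interval."""
    o = np.asarray(observed, float)
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    if np.any(hi < lo):
        raise InvalidArgument("intervals not well ordered")
    return float(np.mean((o >= lo) & (o <= hi)))


def residual_acf(residuals: pd.DataFrame, max_lag: int = 15) -> pd.Series:
    """Within-site residual autocorrelation, averaged across sites per lag.

    ``residuals``: site_id, month, resid.  Sites need at least
    ``max_lag + 5`` observations to contribute.  A site with a constant
    series is skipped (undefined ACF).
    """
    acc = np.zeros(max_lag)
    cnt = np.zeros(max_lag)
    for _, grp in residuals.groupby("site_id"):
        g = grp.sort_values("month")
        r = g["resid"].to_numpy(float)
        if len(r) < max_lag + 5 or np.std(r) == 0:
            continue
        r = r - r.mean()
        denom = float(np.sum(r ** 2))
        for lag in range(1, max_lag + 1):
            acc[lag - 1] += float(np.sum(r[lag:] * r[:-lag])) / denom
            cnt[lag - 1] += 1
    out = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return pd.Series(out, index=pd.RangeIndex(1, max_lag + 1, name="lag"))


# ---------------------------------------------------------------------------
# stratified reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["stratum", "n", "n_excluded", "model_r2", "cv_r2",
                  "ma_intercept", "ma_slope", "nmbf_pct", "cvmae",
                  "nmef_pct", "spatial_cv_r2", "pi_coverage"]


@dataclass
class CVReport:
    """All validation metrics, overall and stratified."""

    table: pd.DataFrame

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _stratum_metrics(df: pd.DataFrame, name) -> dict:
    excl = df["excluded"].to_numpy(bool) if "excluded" in df else \
        np.zeros(len(df), dtype=bool)
    d = df[~excl]
    row = {"stratum": name, "n": int(len(d)), "n_excluded": int(excl.sum())}
    if len(d) < 3:
        for c in REPORT_COLUMNS[3:]:
            row[c] = float("nan")
        return row
    o = d["conc"].to_numpy(float)
    m = d["mean"].to_numpy(float)
    row["cv_r2"] = cv_r2(o, m)
    row["model_r2"] = cv_r2(o, d["fitted"]) if "fitted" in d else float("nan")
    pos = (o > 0) & (m > 0)
    if pos.sum() >= 3:
        itc, slp = major_axis_fit(np.log(m[pos]), np.log(o[pos]))
    else:
        itc, slp = float("nan"), float("nan")
    row["ma_intercept"], row["ma_slope"] = itc, slp
    row.update(bias_error_metrics(o, m))
    row["spatial_cv_r2"] = (spatial_cv_r2(o, m, d["site_id"])
                            if d["site_id"].nunique() >= 3 else float("nan"))
    row["pi_coverage"] = (pi_coverage(o, d["lo95"], d["hi95"])
                          if {"lo95", "hi95"} <= set(d.columns)
                          else float("nan"))
    return row


def stratified_report(predictions: pd.DataFrame,
                      strata: dict | None = None) -> CVReport:
    """Metrics overall and per stratum.

    ``predictions`` needs site_id, month, conc (observed), mean (predicted),
    optionally fitted / lo95 / hi95 / excluded.  ``strata`` maps a stratum
    family name to a label column in ``predictions`` (e.g. region, season,
    urban tertile); metrics are computed per label.  Rows flagged
    ``excluded`` (e.g. nonpositive coarse-fraction records) are counted but
    not scored.
    """
    rows = [_stratum_metrics(predictions, "overall")]
    for fam, col in (strata or {}).items():
        for label, grp in predictions.groupby(col):
            rows.append(_stratum_metrics(grp, f"{fam}={label}"))
    table = pd.DataFrame(rows)
    cols = [c for c in REPORT_COLUMNS if c in table.columns]
    return CVReport(table=table[cols])


# ---------------------------------------------------------------------------
# stage-2 selection harness
# ---------------------------------------------------------------------------

class Stage2CVHarness:
    """Cross-validation harness over the second-stage model only.

    Scores candidate time-invariant covariate sets by site-exclusive CV of
    the stage-2 fit on fixed site intercepts; used by the covariate-selection
    procedure (the full-pipeline monthly screen is a separate, heavier
    harness that callers can supply instead).
    """

    def __init__(self, u_hat: pd.DataFrame, X: pd.DataFrame,
                 coords: pd.DataFrame, n_folds: int = 5, seed: int = 0,
                 config=None):
        from . import stage2 as s2
        self._s2 = s2
        self.u_hat = u_hat.reset_index(drop=True)
        self.X = X
        self.coords = coords
        self.config = config or s2.Stage2Config()
        self.assignment = assign_folds(self.u_hat["site_id"],
                                       n_folds=n_folds, seed=seed)
        self.assignment.reserved_fold = -1   # score all folds
        self._cache: dict = {}

    def covariate_values(self, name: str) -> np.ndarray:
        return self.X.loc[self.u_hat["site_id"], name].to_numpy(float)

    def final_fit(self, x_terms, z_terms=()):
        return self._s2.fit_stage2(self.u_hat, self.X, self.coords,
                                   x_terms=list(x_terms), config=self.config)

    def spatial_cv_r2(self, x_terms, z_terms=()) -> float:
        key = tuple(sorted(x_terms))
        if key in self._cache:
            return self._cache[key]
        preds = np.full(len(self.u_hat), np.nan)
        xy = self.coords.set_index("site_id")
        for f in sorted(self.assignment.folds.unique()):
            held = set(self.assignment.sites_in(f))
            mask = self.u_hat["site_id"].isin(held).to_numpy()
            train = self.u_hat[~mask]
            fit = self._s2.fit_stage2(train, self.X, self.coords,
                                      x_terms=list(x_terms),
                                      config=self.config)
            sids = self.u_hat.loc[mask, "site_id"]
            preds[mask] = fit.predict(
                self.X.loc[sids], xy.loc[sids, ["x", "y"]].to_numpy(float))
        r2 = cv_r2(self.u_hat["u_hat"], preds)
        self._cache[key] = r2
        return r2
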