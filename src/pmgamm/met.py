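"""Spatial smoothing of station meteorology, one surface per
parameter/month/region.

Each monthly regional surface is a thin-plate penalized spline fit

    y_it = a_tr + g_tr(s_i) + e_it,   e_it ~ N(0, sigma2_tr)

with basis dimension k_tr = floor(I_tr * 0.9) (as large as the station count
allows) and GCV smoothing with a gamma multiplier of 1.4 to deter
over-fitting.  Air-stagnation fractions are natural-log transformed (after a
half-percentage-point shift to avoid log 0) before smoothing.

Fitting is month-by-month and region-by-region, so results are independent of
fitting order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import splines
from .splines import InvalidArgument

logger = logging.getLogger(__name__)

STAGNATION_SHIFT = 0.005   # half a percentage point, as a fraction
GAMMA_MET = 1.4


@dataclass
class MetSurface:
    """One fitted monthly regional surface for one meteorological parameter."""

    parameter: str
    month: int
    region: object
    n_stations: int
    k: int
    alpha: float                      # regional monthly mean (response scale)
    basis: "splines.BasisTPRS | None"
    fit: "splines.PenalizedFit | None"
    bbox: tuple                       # (xmin, xmax, ymin, ymax) of stations
    log_transformed: bool = False

    @property
    def scale(self) -> float:
        return self.fit.scale if self.fit is not None else float("nan")


def fit_met_surface(panel: pd.DataFrame, gamma: float = GAMMA_MET) -> MetSurface:
    """Fit the surface for one parameter/month/region slice of the panel.

    ``panel`` needs columns x, y, value plus constant parameter, month,
    region columns.  Stagnation values (parameter name containing
    'stagnation') are log transformed before fitting.  Fewer than 5 finite
    stations yields a constant-mean surface with a warning.
    """
    par = str(panel["parameter"].iloc[0])
    month = int(panel["month"].iloc[0])
    region = panel["region"].iloc[0]
    panel = panel.sort_values("station_id")   # order-independent fits
    ok = np.isfinite(panel["value"].to_numpy(float))
    panel = panel[ok]
    y = panel["value"].to_numpy(float)
    log_transformed = "stagnation" in par
    if log_transformed:
        y = np.log(y + STAGNATION_SHIFT)
    coords = panel[["x", "y"]].to_numpy(float)
    n = len(y)
    bbox = (float(coords[:, 0].min()), float(coords[:, 0].max()),
            float(coords[:, 1].min()),
            float(coords[:, 1].max())) if n else (0.0, 0.0, 0.0, 0.0)
    if n < 5:
        logger.warning("met surface %s m=%d r=%s: only %d stations; "
                       "constant-mean surface", par, month, region, n)
        alpha = float(np.mean(y)) if n else float("nan")
        return MetSurface(par, month, region, n, 0, alpha,
                          None, None, bbox, log_transformed)
    k = max(int(np.floor(n * 0.9)), 4)
    basis = splines.build_basis_tprs(coords, k=k)
    term = splines.TermSpec("g_tr", basis.design(coords), basis.penalty, 3)
    fit = splines.fit_penalized([term], y, gamma=gamma)
    return MetSurface(par, month, region, n, basis.k, float(np.mean(y)),
                      basis, fit, bbox, log_transformed)


def predict_met(surface: MetSurface, locations) -> np.ndarray:
    """Evaluate a fitted surface at arbitrary locations.

    Values are returned on the fitting scale (log scale for stagnation).
    Locations far outside the training bounding box (beyond 50% of its
    diagonal) are still predicted but logged as extrapolation.
    """
    locations = np.asarray(locations, dtype=float).reshape(-1, 2)
    x0, x1, y0, y1 = surface.bbox
    diag = float(np.hypot(x1 - x0, y1 - y0))
    if diag > 0:
        over = np.maximum.reduce([
            x0 - locations[:, 0], locations[:, 0] - x1,
            y0 - locations[:, 1], locations[:, 1] - y1,
            np.zeros(len(locations)),
        ])
        if np.any(over > 0.5 * diag):
            logger.warning("met prediction extrapolates >50%% of the "
                           "training bbox diagonal (%s m=%d r=%s)",
                           surface.parameter, surface.month, surface.region)
    if surface.fit is None:
        return np.full(len(locations), surface.alpha)
    return surface.basis.design(locations) @ surface.fit.beta


def fit_met_surfaces(panel: pd.DataFrame, gamma: float = GAMMA_MET) -> dict:
    """Fit every (parameter, month, region) surface in a long-format panel.

    Returns a dict keyed by (parameter, month, region).
    """
    if panel.empty:
        raise InvalidArgument("empty meteorology panel")
    out = {}
    for (par, month, region), grp in panel.groupby(
            ["parameter", "month", "region"], sort=True):
        out[(par, int(month), region)] = fit_met_surface(grp, gamma=gamma)
    return out


def predict_met_panel(surfaces: dict, locations: pd.DataFrame, months,
                      parameters=None) -> pd.DataFrame:
    """Predict every parameter at given sites for the requested months.

    ``locations`` is a DataFrame with site_id, x, y, region columns.  Returns
    a long table site_id, month, <one column per parameter>.
    """
    parameters = parameters or sorted({k[0] for k in surfaces})
    locations = locations.reset_index(drop=True)
    rows = []
    for m in months:
        block = {"site_id": locations["site_id"].to_numpy(), "month": int(m)}
        for par in parameters:
            vals = np.full(len(locations), np.nan)
            for r, grp in locations.groupby("region"):
                key = (par, int(m), r)
                if key in surfaces:
                    vals[grp.index.to_numpy()] = predict_met(
                        surfaces[key], grp[["x", "y"]].to_numpy())
            block[par] = vals
        rows.append(pd.DataFrame(block))
    return pd.concat(rows, ignore_index=True)
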