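"""Covariate engineering for exposure-surface models.

Builds the geographic predictors used by the exposure models from point and
grid inputs: skew-reducing transforms with recorded metadata (so the identical
mapping applies at prediction time), quadratic-kernel densities of road or
point-source weights, distance-to-road truncation, raster neighbourhood
averaging, and spatial smoothing of values observed at scattered points
(e.g. county-centroid population density).

Transforms always anchor on the *training* minimum: applying a recorded
transform to new data reuses the stored minimum and shift, never statistics of
the new data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import splines
from .splines import InvalidArgument

logger = logging.getLogger(__name__)

ROAD_DISTANCE_CAP_M = 500.0


@dataclass(frozen=True)
class TransformMeta:
    """Enough state to reproduce a training-time transform bit-for-bit."""

    kind: str          # 'log_shift' | 'sqrt_shift' | 'identity'
    shift: float
    train_min: float

    def apply(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.kind == "log_shift":
            arg = z - self.train_min + self.shift
            if np.any(arg <= 0):
                raise InvalidArgument("log-shift argument non-positive")
            return np.log(arg)
        if self.kind == "sqrt_shift":
            return np.sqrt(np.maximum(z - self.train_min + self.shift, 0.0))
        if self.kind == "identity":
            return z
        raise InvalidArgument(f"unknown transform {self.kind!r}")


def log_shift_transform(z, shift: float = 10.0, name: str = ""):
    """ln(z - min(z) + shift): skew-reducing log transform.

    The shift keeps the argument away from zero, reducing the leverage of
    values near the minimum.  Returns (transformed, meta).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise InvalidArgument(f"non-finite values in {name or 'covariate'}")
    if shift <= 0:
        raise InvalidArgument("shift must be positive")
    meta = TransformMeta("log_shift", shift, float(np.min(z)))
    return meta.apply(z), meta


def sqrt_shift_transform(elev, name: str = "elevation"):
    """sqrt(elev - min(elev) + 1): mild skew reduction for elevation.

    The constant guarantees a minimum transformed value of one.
    """
    elev = np.asarray(elev, dtype=float)
    if not np.all(np.isfinite(elev)):
        raise InvalidArgument(f"non-finite values in {name}")
    meta = TransformMeta("sqrt_shift", 1.0, float(np.min(elev)))
    return meta.apply(elev), meta


def quadratic_kernel_density(points, weights, bandwidth: float,
                             eval_locations) -> np.ndarray:
    """Quadratic (biweight) kernel density of weighted points.

    density(s) = sum_j w_j (3 / (pi h^2)) (1 - (d_j/h)^2)^2 for d_j < h.
    The kernel integrates to one, so integrating the density over the plane
    recovers the total weight.
    """
    if bandwidth <= 0:
        raise InvalidArgument("bandwidth must be positive")
    eval_locations = np.asarray(eval_locations, dtype=float).reshape(-1, 2)
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if points.shape[0] == 0:
        return np.zeros(eval_locations.shape[0])
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(w < 0):
        logger.warning("negative kernel weights supplied")
    d = cdist(eval_locations, points) / bandwidth
    kern = np.where(d < 1.0, (1.0 - d ** 2) ** 2, 0.0)
    return kern @ w * (3.0 / (np.pi * bandwidth ** 2))


def truncate_distance(d, cap: float = ROAD_DISTANCE_CAP_M) -> np.ndarray:
    """Cap distance-to-road at 500 m; beyond that the covariate carries no
    near-road information."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise InvalidArgument("negative distances")
    return np.minimum(d, cap)


def cardinal_cell_average(grid) -> np.ndarray:
    """Average each cell with its four cardinal neighbours.

    Edge cells average over the neighbours that exist.  Smooths the
    discontinuities of tract-level density rasters.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 2 or min(g.shape) < 3:
        raise InvalidArgument("grid must be 2-D and at least 3x3")
    total = g.copy()
    count = np.ones_like(g)
    for shift, axis in [(1, 0), (-1, 0), (1, 1), (-1, 1)]:
        rolled = np.roll(g, shift, axis=axis)
        mask = np.ones_like(g, dtype=bool)
        idx = 0 if shift == 1 else -1
        if axis == 0:
            mask[idx, :] = False
        else:
            mask[:, idx] = False
        total += np.where(mask, rolled, 0.0)
        count += mask
    return total / count


def circular_window_average(grid, cellsize: float, radius: float) -> np.ndarray:
    """Mean over a circular window (membership by cell-centre distance).

    Used for elevation rasters, mimicking a moving-window focal mean.
    """
    g = np.asarray(grid, dtype=float)
    r_cells = int(np.floor(radius / cellsize))
    offs = np.arange(-r_cells, r_cells + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    inside = (oy ** 2 + ox ** 2) * cellsize ** 2 <= radius ** 2
    total = np.zeros_like(g)
    count = np.zeros_like(g)
    nr, nc = g.shape
    for dy, dx in zip(oy[inside], ox[inside]):
        ys = slice(max(dy, 0), nr + min(dy, 0))
        yt = slice(max(-dy, 0), nr + min(-dy, 0))
        xs = slice(max(dx, 0), nc + min(dx, 0))
        xt = slice(max(-dx, 0), nc + min(-dx, 0))
        total[yt, xt] += g[ys, xs]
        count[yt, xt] += 1.0
    return total / count


@dataclass
class SmoothSurface:
    """A fitted thin-plate smooth of scattered point values."""

    basis: "splines.BasisTPRS | None"
    fit: "splines.PenalizedFit | None"
    planar_coef: np.ndarray | None = None   # fallback when geometry degenerate

    def predict(self, locations) -> np.ndarray:
        locations = np.asarray(locations, dtype=float).reshape(-1, 2)
        if self.planar_coef is not None:
            T = np.column_stack([np.ones(len(locations)), locations])
            return T @ self.planar_coef
        return self.basis.design(locations) @ self.fit.beta


def smooth_point_values(locations, values, k: int | None = None,
                        gamma: float = 1.0, lam: float | None = None) -> SmoothSurface:
    """Fit a thin-plate smooth surface to values at scattered points.

    Used e.g. to spread county-centroid population density to arbitrary
    locations.  Falls back to a planar least-squares fit when the geometry is
    degenerate (collinear points).
    """
    locations = np.asarray(locations, dtype=float).reshape(-1, 2)
    values = np.asarray(values, dtype=float).ravel()
    n = len(values)
    if n < 10:
        raise InvalidArgument("need at least 10 points to smooth")
    # collinearity check on the coordinates
    cen = locations - locations.mean(axis=0)
    sv = np.linalg.svd(cen, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        logger.warning("collinear point geometry; planar fallback")
        T = np.column_stack([np.ones(n), locations])
        coef, *_ = np.linalg.lstsq(T, values, rcond=None)
        return SmoothSurface(basis=None, fit=None, planar_coef=coef)
    if k is None:
        k = min(max(10, int(0.9 * n)), 150, n)
    basis = splines.build_basis_tprs(locations, k=k)
    term = splines.TermSpec("surface", basis.design(locations),
                            basis.penalty, 3, lam=lam)
    fit = splines.fit_penalized([term], values, gamma=gamma)
    return SmoothSurface(basis=basis, fit=fit)


# ---------------------------------------------------------------------------
# containers and text I/O
# ---------------------------------------------------------------------------

@dataclass
class CovariateTable:
    """Site-level time-invariant covariates X and site-month covariates Z.

    ``X`` is indexed by site id; ``Z`` is long format with ``site_id`` and
    ``month`` columns.  ``meta`` records the transform applied to each
    covariate; ``x_ranges`` / ``z_ranges`` hold the training min/max used for
    prediction-time clamping (global for X, per region for Z).
    """

    X: pd.DataFrame
    Z: pd.DataFrame
    meta: dict = field(default_factory=dict)
    x_ranges: dict = field(default_factory=dict)
    z_ranges: dict = field(default_factory=dict)

    def x_columns(self) -> list[str]:
        return list(self.X.columns)

    def z_columns(self) -> list[str]:
        return [c for c in self.Z.columns if c not in ("site_id", "month")]

    def record_ranges(self, site_regions: pd.Series) -> None:
        """Record training min/max: global for X, per region for Z."""
        for c in self.x_columns():
            v = self.X[c].to_numpy(float)
            self.x_ranges[c] = (float(np.nanmin(v)), float(np.nanmax(v)))
        reg = self.Z["site_id"].map(site_regions)
        for c in self.z_columns():
            for r, grp in self.Z.groupby(reg):
                v = grp[c].to_numpy(float)
                self.z_ranges[(c, r)] = (float(np.nanmin(v)), float(np.nanmax(v)))

    def copy(self) -> "CovariateTable":
        return CovariateTable(self.X.copy(), self.Z.copy(), dict(self.meta),
                              dict(self.x_ranges), dict(self.z_ranges))


def write_table(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_grid(path, grid, xll=0.0, yll=0.0, cellsize=1.0, nodata=-9999.0) -> None:
    """Write a raster in the 6-line-header ASCII-grid convention."""
    g = np.asarray(grid, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.shape[1]}\n")
        fh.write(f"nrows {g.shape[0]}\n")
        fh.write(f"xllcorner {xll}\n")
        fh.write(f"yllcorner {yll}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, g, fmt="%.10g")


def read_grid(path):
    """Read an ASCII-grid raster; returns (array, header dict)."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = grid.reshape(int(header["nrows"]), int(header["ncols"]))
    return grid, header
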