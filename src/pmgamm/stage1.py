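"""Stage 1: regional back-fitting of the monthly panel model

    y_it = u_i + a_tr + sum_p f_pr(Z_itp) [+ h(t)] + g_tr(s_i) + e_it

The site intercepts u_i, monthly regional intercepts a_tr and the 1-D smooths
of the time-varying covariates are estimated jointly; the residual spatial
surfaces g_tr are estimated separately per month (or per season for the ratio
variant), alternating until the fitted values stabilise.  The surfaces use
basis dimension floor(I_tr * 0.9) and a GCV gamma multiplier of 1.4 (1.8 for
a designated sparse region).  Out-of-region sites within a 400 km buffer of
the region are included in the fit to suppress boundary effects; their u_i
are discarded downstream.

Identifiability conventions: u_i carries the site-level mean (site indicators,
no centring); the monthly intercepts are constrained to mean zero across
months within the region; every 1-D smooth is column-centred over training
rows; every monthly surface is centred to mean zero over that month's sites.
This makes u_i the adjusted long-term mean at each location, which is exactly
what the second stage models.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import splines
from .splines import (
    CenteredSmooth1D,
    CenteredSurface,
    InvalidArgument,
    TermSpec,
)

logger = logging.getLogger(__name__)


@dataclass
class Stage1Config:
    # the over-fit multiplier applies to the residual spatial surfaces;
    # the joint step (intercepts + covariate smooths) uses gamma_joint
    gamma: float = 1.4
    gamma_joint: float = 1.0
    gamma_by_region: dict = field(default_factory=dict)   # sparse region: 1.8
    tol: float = 1e-4              # max |change in fitted| on the log scale
    max_iter: int = 20
    buffer_km: float = 400.0
    k_z: int = 10                  # basis dimension of 1-D smooths
    df_cap: float = 6.0            # max df per 1-D smooth
    freeze_lambda_after: int = 3   # GCV re-selection only in early sweeps
    seasonal: bool = False         # one surface per season instead of month
    h_term: bool = False           # temporal smooth of the month index
    min_sites_per_period: int = 5
    # fixed smoothing parameters (term name -> lambda, and one lambda for all
    # residual surfaces); None means GCV-selected
    fixed_lambdas: dict = field(default_factory=dict)
    fixed_surface_lambda: float | None = None
    # Anderson acceleration of the (linear, for frozen lambdas) sweep map;
    # plain alternation is recovered with accelerate=False
    accelerate: bool = True
    accel_depth: int = 5

    @classmethod
    def from_yaml(cls, path) -> "Stage1Config":
        """Load a config block (gamma, gamma_by_region, tol, max_iter,
        buffer_km, ...) from a YAML file; unknown keys are rejected."""
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise InvalidArgument(f"unknown config keys: {sorted(unknown)}")
        if "gamma_by_region" in raw:
            raw["gamma_by_region"] = dict(raw["gamma_by_region"])
        return cls(**raw)


def season_of(months) -> np.ndarray:
    """Map month index to season 0..3 (winter = Dec-Feb, then 3-month blocks).

    Month indices are calendar months counted from 1; index 12 is December.
    """
    m = ((np.asarray(months, dtype=int) - 1) % 12) + 1
    return ((m % 12) // 3).astype(int)


@dataclass
class Stage1Fit:
    """Back-fit result for one region."""

    region: object
    u: pd.Series                        # site intercepts (all fitted sites)
    alpha_t: pd.Series                  # monthly intercepts, mean zero
    f_smooths: dict                     # covariate name -> CenteredSmooth1D
    h_smooth: CenteredSmooth1D | None
    g_surfaces: dict                    # period key -> CenteredSurface | None
    sigma_e: dict                       # month -> residual variance
    in_region_sites: list
    buffer_sites: list
    convergence: list
    converged: bool
    joint_fit: "splines.PenalizedFit"
    seasonal: bool
    alpha_t_var: pd.Series | None = None

    def period_key(self, month: int):
        return int(season_of([month])[0]) if self.seasonal else int(month)


def attach_buffer(sites: pd.DataFrame, region_map, region,
                  buffer_km: float = 400.0) -> pd.DataFrame:
    """Regional fitting set: in-region sites plus sites within the buffer.

    Returns a copy of the matching site rows with an ``in_region`` flag.
    """
    in_region = sites["region"] == region
    if not in_region.any():
        raise InvalidArgument(f"region {region!r} has no sites")
    dist = region_map.distance_to(sites[["x", "y"]].to_numpy(), region)
    keep = in_region.to_numpy() | (dist <= buffer_km)
    out = sites.loc[keep].copy()
    out["in_region"] = in_region.to_numpy()[keep]
    return out


def backfit_region(panel: pd.DataFrame, region_sites: pd.DataFrame,
                   Z: pd.DataFrame, region, config: Stage1Config,
                   z_columns=None) -> Stage1Fit:
    """Back-fit the stage-1 model for one region.

    ``panel``: site_id, month, conc (native scale); only rows for sites in
    ``region_sites`` are used.  ``Z``: long site-month covariates.
    """
    cfg = config
    gamma = cfg.gamma_by_region.get(region, cfg.gamma)
    sites = region_sites.sort_values("site_id").reset_index(drop=True)
    site_ids = sites["site_id"].tolist()
    # canonical row order makes the fit independent of input ordering
    panel = panel[panel["site_id"].isin(site_ids)] \
        .sort_values(["site_id", "month"]).reset_index(drop=True)
    months = np.sort(panel["month"].unique())
    if len(months) < 2 or sites.shape[0] < 10:
        raise InvalidArgument("need >= 2 months and >= 10 sites")
    z_columns = list(z_columns) if z_columns is not None else [
        c for c in Z.columns if c not in ("site_id", "month")]

    y = np.log(panel["conc"].to_numpy(float))
    n = len(y)
    sid = panel["site_id"].to_numpy()
    mon = panel["month"].to_numpy(int)
    coords_by_site = sites.set_index("site_id")[["x", "y"]]
    xy = coords_by_site.loc[sid].to_numpy()

    # --- joint design: site indicators + month contrasts + covariate smooths
    site_index = {s: i for i, s in enumerate(site_ids)}
    I = len(site_ids)
    S_ind = np.zeros((n, I))
    S_ind[np.arange(n), [site_index[s] for s in sid]] = 1.0

    T = len(months)
    month_pos = {m: j for j, m in enumerate(months)}
    M_con = np.zeros((n, T - 1))
    for i, m in enumerate(mon):
        j = month_pos[m]
        if j < T - 1:
            M_con[i, j] = 1.0
        else:
            M_con[i, :] = -1.0          # sum-to-zero contrast

    Zi = Z.set_index(["site_id", "month"]).sort_index()
    zvals = {c: Zi[c].loc[list(zip(sid, mon))].to_numpy(float)
             for c in z_columns}
    terms = [TermSpec("sites", S_ind, None, 0),
             TermSpec("months", M_con, None, 0)]
    smooth_info = {}
    for c in z_columns:
        basis = splines.build_basis_1d(zvals[c], k=cfg.k_z, name=c)
        D = basis.design(zvals[c])
        mu = D.mean(axis=0)
        smooth_info[c] = (basis, mu)
        terms.append(TermSpec(f"f({c})", D - mu, basis.penalty, 1))
    if cfg.h_term:
        basis_h = splines.build_basis_1d(mon.astype(float), k=cfg.k_z,
                                         name="month_index")
        Dh = basis_h.design(mon.astype(float))
        mu_h = Dh.mean(axis=0)
        smooth_info["__h__"] = (basis_h, mu_h)
        terms.append(TermSpec("h(t)", Dh - mu_h, basis_h.penalty, 1))

    # --- period grouping for the residual spatial surfaces
    period = season_of(mon) if cfg.seasonal else mon
    period_keys = np.sort(np.unique(period))
    period_rows = {int(p): np.where(period == p)[0] for p in period_keys}
    surf_basis: dict = {}
    for p, rows in period_rows.items():
        pts = xy[rows]
        n_sites_p = len(np.unique(sid[rows]))
        if n_sites_p < cfg.min_sites_per_period:
            logger.warning("region %s period %s: %d sites; zero surface",
                           region, p, n_sites_p)
            surf_basis[p] = None
            continue
        k = max(int(np.floor(n_sites_p * 0.9)), 4)
        basis = splines.build_basis_tprs(pts, k=k)
        D = basis.design(pts)
        surf_basis[p] = (basis, D, D.mean(axis=0))

    # --- back-fitting loop
    state = {"joint": None, "g_state": {p: None for p in period_rows},
             "smooth_lams": dict(cfg.fixed_lambdas)}
    joint_work = splines._PLSWork(terms, y)

    def one_sweep(g_cur: np.ndarray, select: bool) -> np.ndarray:
        """One back-fitting sweep: joint step, then per-period surfaces."""
        sweep_terms = []
        for t in terms:
            if t.penalty is None:
                lam = None
            elif t.name in state["smooth_lams"] and (
                    t.name in cfg.fixed_lambdas or not select):
                lam = state["smooth_lams"][t.name]
            else:
                lam = None          # GCV-selected this sweep
            sweep_terms.append(TermSpec(t.name, t.design, t.penalty,
                                        t.null_dim, lam=lam))
        joint = splines.fit_penalized(
            sweep_terms, y - g_cur, gamma=cfg.gamma_joint,
            _work=joint_work.with_response(y - g_cur))
        if select:
            for tf in joint.terms:
                if (tf.lam is not None and tf.name not in cfg.fixed_lambdas
                        and tf.edf > cfg.df_cap + 0.05):
                    joint = splines.cap_edf(joint, tf.name, cfg.df_cap)
            for tf in joint.terms:
                if tf.lam is not None and tf.name not in cfg.fixed_lambdas:
                    state["smooth_lams"][tf.name] = tf.lam
        state["joint"] = joint

        g_new = np.zeros(n)
        resid = y - joint.fitted
        for p, rows in period_rows.items():
            if surf_basis[p] is None:
                continue
            basis, D, mu = surf_basis[p]
            if cfg.fixed_surface_lambda is not None:
                lam = cfg.fixed_surface_lambda
            elif select or state["g_state"][p] is None:
                lam = None
            else:
                lam = state["g_state"][p].lam
            fit_p = splines.fit_penalized(
                [TermSpec("g", D, basis.penalty, 3, lam=lam)],
                resid[rows], gamma=gamma)
            tf = fit_p.terms[0]
            state["g_state"][p] = CenteredSurface(
                basis=basis, col_means=mu, beta=fit_p.beta,
                lam=tf.lam, edf=tf.edf, cov=fit_p.cov)
            g_new[rows] = (D - mu) @ fit_p.beta
        return g_new

    # Back-fitting with optional Anderson acceleration of the sweep map
    # (the map is linear once the smoothing parameters are frozen, so the
    # extrapolated iterates converge to the same fixed point as plain
    # alternation, just much faster when blocks overlap strongly).
    g_fit = np.zeros(n)
    convergence: list = []
    converged = False
    hist_x: list = []
    hist_gx: list = []
    for sweep in range(cfg.max_iter):
        select = sweep < cfg.freeze_lambda_after
        g_new = one_sweep(g_fit, select)
        delta = float(np.max(np.abs(g_new - g_fit)))
        convergence.append(delta)
        if delta < cfg.tol:
            g_fit = g_new
            converged = True
            break
        if cfg.accelerate and not select:
            hist_x.append(g_fit.copy())
            hist_gx.append(g_new.copy())
            if len(hist_x) > cfg.accel_depth:
                hist_x.pop(0)
                hist_gx.pop(0)
            if len(hist_x) >= 2:
                F = np.column_stack([gx - x for x, gx
                                     in zip(hist_x, hist_gx)])
                dF = F[:, 1:] - F[:, :-1]
                coef, *_ = np.linalg.lstsq(dF, F[:, -1], rcond=None)
                G = np.column_stack(hist_gx)
                dG = G[:, 1:] - G[:, :-1]
                g_fit = hist_gx[-1] - dG @ coef
            else:
                g_fit = g_new
        else:
            g_fit = g_new
    if converged:
        # one synchronising sweep so surface/joint state matches g_fit
        g_fit = one_sweep(g_fit, select=False)
    joint = state["joint"]
    g_state = state["g_state"]
    if not converged:
        logger.warning("region %s back-fit did not converge in %d sweeps "
                       "(last delta %.3g)", region, cfg.max_iter,
                       convergence[-1] if convergence else float("nan"))

    # --- unpack results
    u = pd.Series(joint.coef_block("sites"), index=pd.Index(site_ids,
                  name="site_id"), name="u_hat")
    cm = joint.coef_block("months")
    alpha_vals = np.append(cm, -cm.sum())
    alpha_t = pd.Series(alpha_vals, index=pd.Index(months, name="month"),
                        name="alpha_t")
    # variance of each monthly intercept from the joint posterior
    Vm = joint.cov_block("months")
    var_last = float(np.ones(T - 1) @ Vm @ np.ones(T - 1))
    alpha_t_var = pd.Series(np.append(np.diag(Vm), var_last),
                            index=alpha_t.index)
    f_smooths = {}
    for c in z_columns:
        basis, mu = smooth_info[c]
        tf = joint.term(f"f({c})")
        f_smooths[c] = CenteredSmooth1D(basis, mu, joint.beta[tf.sl],
                                        tf.lam, tf.edf)
    h_smooth = None
    if cfg.h_term:
        basis, mu = smooth_info["__h__"]
        tf = joint.term("h(t)")
        h_smooth = CenteredSmooth1D(basis, mu, joint.beta[tf.sl],
                                    tf.lam, tf.edf)

    resid_final = y - (joint.fitted + g_fit)
    sigma_e = {}
    for m in months:
        rows = mon == m
        sigma_e[int(m)] = float(np.mean(resid_final[rows] ** 2))

    in_reg = sites.loc[sites.get("in_region", pd.Series(True, index=sites.index)),
                       "site_id"].tolist()
    buffer = [s for s in site_ids if s not in set(in_reg)]
    return Stage1Fit(
        region=region, u=u, alpha_t=alpha_t, f_smooths=f_smooths,
        h_smooth=h_smooth, g_surfaces=g_state, sigma_e=sigma_e,
        in_region_sites=in_reg, buffer_sites=buffer,
        convergence=convergence, converged=converged, joint_fit=joint,
        seasonal=cfg.seasonal, alpha_t_var=alpha_t_var)


def extract_site_intercepts(fit: Stage1Fit) -> pd.DataFrame:
    """Site intercepts for in-region sites only (buffer overlap removed)."""
    u = fit.u.loc[fit.in_region_sites]
    return u.reset_index().rename(columns={0: "u_hat"})


def fit_stage1(panel: pd.DataFrame, sites: pd.DataFrame, Z: pd.DataFrame,
               region_map, config: Stage1Config | None = None,
               z_columns=None) -> dict:
    """Back-fit every region (with its 400 km buffer); returns region -> fit."""
    config = config or Stage1Config()
    out = {}
    for region in sorted(sites["region"].unique()):
        rs = attach_buffer(sites, region_map, region, config.buffer_km)
        out[region] = backfit_region(panel, rs, Z, region, config,
                                     z_columns=z_columns)
    return out


def save_stage1_fit(fit: Stage1Fit, outdir) -> None:
    """Serialize a regional fit to a directory of delimited tables:
    site intercepts, monthly intercepts/variances, and the coefficient
    vector of each period's residual surface."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    u = fit.u.reset_index()
    u["in_region"] = u["site_id"].isin(set(fit.in_region_sites))
    u.to_csv(out / "site_intercepts.tsv", sep="\t", index=False)
    pd.DataFrame({
        "month": fit.alpha_t.index, "alpha_t": fit.alpha_t.to_numpy(),
        "var": fit.alpha_t_var.to_numpy(),
        "sigma2_e": [fit.sigma_e.get(int(m), np.nan)
                     for m in fit.alpha_t.index],
    }).to_csv(out / "monthly_intercepts.tsv", sep="\t", index=False)
    rows = []
    for p, surf in fit.g_surfaces.items():
        if surf is None:
            continue
        for j, b in enumerate(surf.beta):
            rows.append({"period": p, "coef_index": j, "beta": b,
                         "lam": surf.lam, "edf": surf.edf})
    pd.DataFrame(rows).to_csv(out / "surface_coefficients.tsv",
                              sep="\t", index=False)


def combined_site_intercepts(fits: dict) -> pd.DataFrame:
    """Stack in-region intercepts from all regional fits (buffers dropped)."""
    parts = [extract_site_intercepts(f) for f in fits.values()]
    return pd.concat(parts, ignore_index=True)
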