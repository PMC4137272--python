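"""Stage 2: the domain-wide spatial model on estimated site intercepts,

    u_i = a + sum_q d_q(X_iq) + g(s_i) + b_i,    b_i ~ N(0, sigma2_b),

with 1-D penalized smooths of the time-invariant geographic covariates
(basis dimension 10, at most 6 effective df each), a thin-plate spatial
surface with basis dimension floor((I - Q) * 0.9), optional regional
interactions of covariate effects, Wald tests on every smooth term, and the
covariate-selection procedure driven by site-exclusive cross-validation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import splines
from .splines import (
    CenteredSmooth1D,
    CenteredSurface,
    InvalidArgument,
    TermSpec,
)

logger = logging.getLogger(__name__)


@dataclass
class Stage2Config:
    k_x: int = 10                 # basis dimension of covariate smooths
    df_cap: float = 6.0           # max df per covariate smooth
    gamma: float = 1.0
    spatial_df_cap: float | None = None   # optional cap on the g(s) term
    k_spatial_max: int | None = None      # override of the spatial basis size
    min_region_sites: int = 15


@dataclass
class Stage2Fit:
    """Fitted second-stage spatial model."""

    alpha: float
    d_smooths: dict                     # name -> CenteredSmooth1D
    g_surface: CenteredSurface
    k_spatial_requested: int            # floor((I - Q) * 0.9)
    k_spatial: int                      # effective basis dimension used
    sigma_b: float
    wald_p: dict
    edf: dict
    fit: "splines.PenalizedFit"
    x_columns: list
    interactions: dict = field(default_factory=dict)
    # name -> {"group_map": region->group, "smooths": {group: smooth}}
    region_effects: dict = field(default_factory=dict)   # region -> alpha_r

    def predict(self, X_new: pd.DataFrame, coords, regions=None,
                with_var: bool = False):
        """Predicted adjusted long-term mean at new sites (log scale).

        ``X_new`` must carry the model's covariate columns; ``regions`` is
        required when the model has regional interaction terms.
        """
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        m = len(coords)
        pred = np.full(m, self.alpha)
        rows = np.zeros((m, len(self.fit.beta))) if with_var else None
        if with_var:
            rows[:, self.fit.term("intercept").sl] = 1.0
        for name, sm in self.d_smooths.items():
            x = X_new[name].to_numpy(float)
            pred += sm(x)
            if with_var:
                rows[:, self.fit.term(f"d({name})").sl] = sm.design_row(x)
        for name, info in self.interactions.items():
            if regions is None:
                raise InvalidArgument("regions required for interaction model")
            x = X_new[name].to_numpy(float)
            grp = np.asarray([info["group_map"][r] for r in regions])
            for g, sm in info["smooths"].items():
                mask = grp == g
                if mask.any():
                    pred[mask] += sm(x[mask])
                    if with_var:
                        sl = self.fit.term(f"d({name})|g{g}").sl
                        rows[np.ix_(np.where(mask)[0],
                                    np.arange(sl.start, sl.stop))] = \
                            sm.design_row(x[mask])
        if self.region_effects:
            if regions is None:
                raise InvalidArgument("regions required for interaction model")
            pred += np.array([self.region_effects.get(r, 0.0)
                              for r in regions])
        pred += self.g_surface(coords)
        if with_var:
            rows[:, self.fit.term("g(s)").sl] = \
                self.g_surface.design_row(coords)
            var = np.einsum("ij,jk,ik->i", rows, self.fit.cov, rows)
            return pred, var
        return pred


def _centered_smooth_term(name, values, k, mask=None, basis=None):
    if basis is None:
        basis = splines.build_basis_1d(values, k=k, name=name)
    D_all = basis.design(values)
    if mask is None:
        mu = D_all.mean(axis=0)
        D = D_all - mu
    else:
        mu = D_all[mask].mean(axis=0)
        D = np.where(mask[:, None], D_all - mu, 0.0)
    return basis, mu, D


def fit_stage2(u_hat: pd.DataFrame, X: pd.DataFrame, coords: pd.DataFrame,
               x_terms=None, interactions=None, regions=None,
               config: Stage2Config | None = None) -> Stage2Fit:
    """Fit the second-stage model to site intercepts.

    ``u_hat``: site_id, u_hat.  ``X``: indexed by site_id.  ``coords``:
    site_id, x, y.  ``x_terms`` selects covariate columns (default: all).
    ``interactions`` maps covariate name -> {region: group} to fit separate
    smooths per region group (with a categorical region main effect);
    ``regions`` (site_id -> region) is then required.

    The spatial basis dimension follows floor((I - Q) * 0.9) but is
    additionally capped so the total coefficient count stays below the
    number of sites.
    """
    cfg = config or Stage2Config()
    x_terms = list(x_terms) if x_terms is not None else list(X.columns)
    interactions = interactions or {}
    u = u_hat.set_index("site_id")["u_hat"]
    sids = u.index
    I = len(u)
    Q = len(x_terms)
    if I - Q < 10:
        raise InvalidArgument("too few sites for the requested model")
    Xm = X.loc[sids]
    xy = coords.set_index("site_id").loc[sids, ["x", "y"]].to_numpy(float)
    reg = None
    if regions is not None:
        reg = pd.Series(regions).loc[sids].to_numpy()
    elif interactions:
        raise InvalidArgument("interactions need a region assignment")

    terms = [TermSpec("intercept", np.ones((I, 1)), None, 0)]
    builders = {}
    shared = [q for q in x_terms if q not in interactions]
    for q in shared:
        basis, mu, D = _centered_smooth_term(q, Xm[q].to_numpy(float), cfg.k_x)
        terms.append(TermSpec(f"d({q})", D, basis.penalty, 1))
        builders[f"d({q})"] = (basis, mu)
    inter_info = {}
    if interactions:
        all_regions = np.sort(pd.unique(reg))
        R = len(all_regions)
        if R < 2:
            raise InvalidArgument("regional interactions need >= 2 regions")
        # sum-to-zero region main effect
        Mr = np.zeros((I, R - 1))
        rpos = {r: j for j, r in enumerate(all_regions)}
        for i, r in enumerate(reg):
            j = rpos[r]
            if j < R - 1:
                Mr[i, j] = 1.0
            else:
                Mr[i, :] = -1.0
        terms.append(TermSpec("region_main", Mr, None, 0))
        for q, group_map in interactions.items():
            grp = np.asarray([group_map[r] for r in reg])
            inter_info[q] = {"group_map": dict(group_map), "groups": {}}
            # one shared basis across groups, so the group coefficient
            # blocks are directly comparable
            basis_q = splines.build_basis_1d(Xm[q].to_numpy(float),
                                             k=cfg.k_x, name=q)
            for g in np.sort(pd.unique(grp)):
                mask = grp == g
                basis, mu, D = _centered_smooth_term(
                    f"{q}|g{g}", Xm[q].to_numpy(float), cfg.k_x, mask=mask,
                    basis=basis_q)
                terms.append(TermSpec(f"d({q})|g{g}", D, basis.penalty, 1))
                inter_info[q]["groups"][g] = (basis, mu)

    k_req = int(np.floor((I - Q) * 0.9))
    used_cols = sum(t.design.shape[1] for t in terms)
    k_eff = max(min(k_req, I - used_cols - 5), 10)
    if cfg.k_spatial_max is not None:
        k_eff = min(k_eff, cfg.k_spatial_max)
    g_basis = splines.build_basis_tprs(xy, k=k_eff)
    Dg = g_basis.design(xy)
    mu_g = Dg.mean(axis=0)
    terms.append(TermSpec("g(s)", Dg - mu_g, g_basis.penalty, 2))

    fit = splines.fit_penalized(terms, u.to_numpy(float), gamma=cfg.gamma)
    for tf in fit.terms:
        if tf.lam is None or tf.name == "g(s)":
            continue
        if tf.edf > cfg.df_cap + 0.05:
            fit = splines.cap_edf(fit, tf.name, cfg.df_cap)
    if cfg.spatial_df_cap is not None and \
            fit.term("g(s)").edf > cfg.spatial_df_cap + 0.05:
        fit = splines.cap_edf(fit, "g(s)", cfg.spatial_df_cap)

    d_smooths = {}
    for q in shared:
        basis, mu = builders[f"d({q})"]
        tf = fit.term(f"d({q})")
        d_smooths[q] = CenteredSmooth1D(basis, mu, fit.beta[tf.sl],
                                        tf.lam, tf.edf)
    inter_out = {}
    for q, info in inter_info.items():
        smooths = {}
        for g, (basis, mu) in info["groups"].items():
            tf = fit.term(f"d({q})|g{g}")
            smooths[g] = CenteredSmooth1D(basis, mu, fit.beta[tf.sl],
                                          tf.lam, tf.edf)
        inter_out[q] = {"group_map": info["group_map"], "smooths": smooths}
    region_effects = {}
    if interactions:
        cm = fit.coef_block("region_main")
        all_regions = np.sort(pd.unique(reg))
        vals = np.append(cm, -cm.sum())
        region_effects = dict(zip(all_regions, vals))

    tf_g = fit.term("g(s)")
    g_surface = CenteredSurface(g_basis, mu_g, fit.beta[tf_g.sl],
                                tf_g.lam, tf_g.edf,
                                cov=fit.cov[tf_g.sl, tf_g.sl])
    wald_p = {t.name: splines.wald_smooth_test(fit, t.name)
              for t in fit.terms if t.lam is not None}
    edf = {t.name: t.edf for t in fit.terms}
    return Stage2Fit(
        alpha=float(fit.coef_block("intercept")[0]),
        d_smooths=d_smooths, g_surface=g_surface,
        k_spatial_requested=k_req, k_spatial=g_basis.k,
        sigma_b=float(fit.scale), wald_p=wald_p, edf=edf, fit=fit,
        x_columns=x_terms, interactions=inter_out,
        region_effects=region_effects)


def pool_small_regions(regions: pd.Series, coords: pd.DataFrame,
                       min_sites: int = 15) -> dict:
    """Grouping where each region is its own group, except regions with
    fewer than ``min_sites`` sites, which join their nearest larger region."""
    counts = regions.value_counts()
    cents = {}
    xy = coords.set_index("site_id")
    for r in counts.index:
        sids = regions.index[regions == r]
        cents[r] = xy.loc[sids, ["x", "y"]].mean().to_numpy()
    group = {r: r for r in counts.index}
    big = [r for r in counts.index if counts[r] >= min_sites]
    for r in counts.index:
        if counts[r] < min_sites:
            if not big:
                raise InvalidArgument("no region has enough sites")
            nearest = min(big, key=lambda b: np.sum((cents[r] - cents[b]) ** 2))
            group[r] = nearest
            logger.warning("region %s has %d sites; pooled with %s",
                           r, counts[r], nearest)
    return group


def test_region_interaction(u_hat: pd.DataFrame, X: pd.DataFrame,
                            coords: pd.DataFrame, covariate: str,
                            regions: pd.Series, x_terms=None,
                            config: Stage2Config | None = None,
                            alpha: float = 0.05):
    """Test whether a covariate's effect differs by region.

    Fits the expanded model with a region main effect and region-group
    smooths of ``covariate`` (small regions pooled with their nearest
    neighbour), then Wald-tests the joint block of contrasts between each
    group's smooth coefficients and the reference group's.  Returns
    (p_value, refit) where ``refit`` is the expanded Stage2Fit when the
    interaction is retained (p <= alpha), else None.
    """
    cfg = config or Stage2Config()
    uniq = pd.unique(regions)
    if len(uniq) < 2:
        raise InvalidArgument("interaction test needs >= 2 regions")
    group_map = pool_small_regions(regions, coords, cfg.min_region_sites)
    if len(set(group_map.values())) < 2:
        raise InvalidArgument("pooling left a single region group")
    expanded = fit_stage2(u_hat, X, coords, x_terms=x_terms,
                          interactions={covariate: group_map},
                          regions=regions, config=cfg)
    groups = sorted(expanded.interactions[covariate]["smooths"])
    names = [f"d({covariate})|g{g}" for g in groups]
    fit = expanded.fit
    slices = [fit.term(nm).sl for nm in names]
    p_tot = len(fit.beta)
    k_blk = min(sl.stop - sl.start for sl in slices)
    rows = []
    for sl in slices[1:]:
        C = np.zeros((k_blk, p_tot))
        for j in range(k_blk):
            C[j, sl.start + j] = 1.0
            C[j, slices[0].start + j] = -1.0
        rows.append(C)
    C = np.vstack(rows)
    delta = C @ fit.beta
    V = C @ fit.cov @ C.T
    df = max(1, int(round(sum(fit.term(nm).edf for nm in names[1:]))))
    Vinv = splines.rank_truncated_inverse(V, df)
    stat = float(delta @ Vinv @ delta)
    p = float(chi2.sf(stat, df))
    return (p, expanded if p <= alpha else None)


# ---------------------------------------------------------------------------
# covariate selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionLedger:
    """Audit trail of the covariate-selection procedure."""

    records: list = field(default_factory=list)

    def log(self, step, term, metric, decision, reason) -> None:
        self.records.append({"step": step, "term": term, "metric": metric,
                             "decision": decision, "reason": reason})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def select_covariates(harness, base_x_terms, candidate_pool,
                      base_z_terms=None, expected_signs=None,
                      min_improve: float = 0.002, wald_alpha: float = 0.05):
    """Covariate selection driven by cross-validated predictive accuracy.

    ``harness`` must provide:
      - ``spatial_cv_r2(x_terms, z_terms)``: spatial CV R-squared of a model,
      - optionally ``monthly_cv_r2(x_terms, z_terms)`` (used to screen the
        time-varying terms; skipped when z terms are not supplied),
      - ``final_fit(x_terms, z_terms)``: a Stage2Fit on the full data,
      - ``covariate_values(name)``: the covariate vector (for the screens).

    Procedure: (1) score the base terms; (2) drop each time-varying term that
    does not improve monthly CV R-squared by ``min_improve``; (3) greedily add
    candidates that raise spatial CV R-squared (candidates collinear with an
    included term are refused at a rank screen); (4) drop Wald-insignificant
    smooths; (5) drop terms whose fitted trend over the central 80% of the
    covariate range contradicts the declared expected direction.  Returns
    (ledger, final Stage2Fit, x_terms, z_terms).
    """
    ledger = SelectionLedger()
    x_terms = list(base_x_terms)
    z_terms = list(base_z_terms) if base_z_terms else []
    expected_signs = expected_signs or {}

    base_spatial = harness.spatial_cv_r2(x_terms, z_terms)
    ledger.log("base", "+".join(x_terms), base_spatial, "start", "base model")

    if z_terms and hasattr(harness, "monthly_cv_r2"):
        full_m = harness.monthly_cv_r2(x_terms, z_terms)
        for zt in list(z_terms):
            reduced = [z for z in z_terms if z != zt]
            m = harness.monthly_cv_r2(x_terms, reduced)
            if full_m - m > min_improve:
                ledger.log("drop_z", zt, full_m - m, "kept", "improves CV")
            else:
                z_terms.remove(zt)
                full_m = m
                ledger.log("drop_z", zt, full_m - m, "dropped",
                           "no CV improvement")

    best = harness.spatial_cv_r2(x_terms, z_terms)
    pool = list(candidate_pool)
    improved = True
    while improved and pool:
        improved = False
        scores = {}
        restart = False
        for cand in list(pool):
            # rank screen: refuse candidates collinear with included terms
            v = harness.covariate_values(cand)
            collinear = np.std(v) == 0
            for q in x_terms:
                u = harness.covariate_values(q)
                if collinear or abs(np.corrcoef(u, v)[0, 1]) > 0.999:
                    collinear = True
                    break
            if collinear:
                ledger.log("add_x", cand, np.nan, "dropped", "collinear")
                pool.remove(cand)
                restart = True
                break
            scores[cand] = harness.spatial_cv_r2(x_terms + [cand], z_terms)
        if restart:
            improved = True
            continue
        if scores:
            cand = max(scores, key=scores.get)
            if scores[cand] - best > min_improve:
                x_terms.append(cand)
                pool.remove(cand)
                best = scores[cand]
                improved = True
                ledger.log("add_x", cand, best, "added", "raises CV")
            else:
                for c, s in scores.items():
                    ledger.log("add_x", c, s, "not added",
                               "no CV improvement")

    # Wald screen on the full-data fit
    fit = harness.final_fit(x_terms, z_terms)
    while x_terms:
        insig = {q: fit.wald_p.get(f"d({q})", 0.0) for q in x_terms
                 if fit.wald_p.get(f"d({q})", 0.0) > wald_alpha}
        if not insig:
            break
        worst = max(insig, key=insig.get)
        x_terms.remove(worst)
        ledger.log("wald", worst, insig[worst], "dropped", "p > 0.05")
        fit = harness.final_fit(x_terms, z_terms)

    # a-priori sign screen over the central 80% of the covariate range
    for q in list(x_terms):
        want = expected_signs.get(q)
        if want is None:
            continue
        sm = fit.d_smooths.get(q)
        if sm is None:
            continue
        v = harness.covariate_values(q)
        lo, hi = np.quantile(v, [0.1, 0.9])
        inner = v[(v >= lo) & (v <= hi)]
        qlo, qhi = np.quantile(inner, [0.2, 0.8])
        trend = float(np.mean(sm(inner[inner >= qhi]))
                      - np.mean(sm(inner[inner <= qlo])))
        if np.sign(trend) != 0 and np.sign(trend) != np.sign(want):
            x_terms.remove(q)
            ledger.log("sign", q, trend, "dropped", "sign")
            fit = harness.final_fit(x_terms, z_terms)
    if not x_terms:
        logger.warning("selection emptied the model; intercept + spatial only")
        ledger.log("final", "(none)", np.nan, "fallback",
                   "intercept + spatial")
    final_spatial = harness.spatial_cv_r2(x_terms, z_terms)
    ledger.log("final", "+".join(x_terms) or "(none)", final_spatial,
               "final", "selected model")
    return ledger, fit, x_terms, z_terms
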