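"""Synthetic monitoring networks, covariates, meteorology and PM panels.

The generators emulate the statistical structure the exposure models assume:
log-normal monthly concentrations driven by smooth covariate effects, a
domain-wide spatial field plus regional monthly spatial fields, site random
effects, and region-month heteroscedastic noise,

    log y_it = a + a_tr + sum_q d_q(X_iq) + sum_p f_pr(Z_itp)
               + g(s_i) + g_tr(s_i) + b_i + e_it,

together with a coupled PM2.5:PM10 ratio process (logistic-squashed so the
true ratio lies in (0, 1)) with a slow temporal trend and seasonal regional
spatial fields.  Every generator is a pure function of (config, seed), and the
returned truth object makes all components evaluable anywhere, so estimation
error can be separated exactly from irreducible noise.

Spatial fields are sums of Gaussian bumps with random centres and scales:
cheap, smooth, and evaluable at arbitrary coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import (
    CovariateTable,
    log_shift_transform,
    sqrt_shift_transform,
    truncate_distance,
)

DOMAIN_KM = (1500.0, 1000.0)


# ---------------------------------------------------------------------------
# region geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMap:
    """Rectangular regions tiling a planar domain (coordinates in km)."""

    rects: dict  # region id -> (x0, x1, y0, y1)

    @property
    def regions(self) -> list:
        return list(self.rects)

    @classmethod
    def tile(cls, n_regions: int, domain=DOMAIN_KM) -> "RegionMap":
        W, H = domain
        nrows = 1 if n_regions <= 4 else 2
        per_row = [n_regions] if nrows == 1 else [
            (n_regions + 1) // 2, n_regions // 2]
        rects, rid = {}, 0
        for i, ncol in enumerate(per_row):
            y0, y1 = H * i / nrows, H * (i + 1) / nrows
            for j in range(ncol):
                rects[rid] = (W * j / ncol, W * (j + 1) / ncol, y0, y1)
                rid += 1
        return cls(rects=rects)

    def assign(self, coords) -> np.ndarray:
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        out = np.empty(len(coords), dtype=int)
        for i, (x, y) in enumerate(coords):
            d = {r: self._rect_dist(x, y, rect) for r, rect in self.rects.items()}
            out[i] = min(d, key=d.get)
        return out

    def distance_to(self, coords, region) -> np.ndarray:
        """Euclidean distance from each point to a region's rectangle (km)."""
        rect = self.rects[region]
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        return np.array([self._rect_dist(x, y, rect) for x, y in coords])

    @staticmethod
    def _rect_dist(x, y, rect) -> float:
        x0, x1, y0, y1 = rect
        dx = max(x0 - x, 0.0, x - x1)
        dy = max(y0 - y, 0.0, y - y1)
        return float(np.hypot(dx, dy))


# ---------------------------------------------------------------------------
# smooth random fields
# ---------------------------------------------------------------------------

class BumpField:
    """Sum of Gaussian bumps; a cheap stand-in for a smooth GP draw."""

    def __init__(self, rng: np.random.Generator, domain=DOMAIN_KM,
                 n_bumps=(5, 20), amplitude=1.0, length=(120.0, 400.0)):
        W, H = domain
        n = int(rng.integers(n_bumps[0], n_bumps[1] + 1))
        self.centers = np.column_stack([
            rng.uniform(-0.1 * W, 1.1 * W, n), rng.uniform(-0.1 * H, 1.1 * H, n)
        ])
        self.scales = rng.uniform(length[0], length[1], n)
        self.heights = rng.normal(0.0, 1.0, n)
        # normalise so the field SD over the domain is ~amplitude
        probe = np.column_stack([
            rng.uniform(0, W, 400), rng.uniform(0, H, 400)])
        v = self._raw(probe)
        sd = np.std(v)
        self.gain = amplitude / sd if sd > 0 else 0.0

    def _raw(self, coords):
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        out = np.zeros(len(coords))
        for c, s, h in zip(self.centers, self.scales, self.heights):
            d2 = np.sum((coords - c) ** 2, axis=1)
            out += h * np.exp(-0.5 * d2 / s ** 2)
        return out

    def __call__(self, coords):
        return self.gain * self._raw(coords)


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Closed-form components of the generating process.

    ``d_funcs`` / ``f_funcs`` map covariate names to callables on the
    covariate scale the model sees; spatial fields are callables on
    coordinates.  ``r2_star`` is the realized explainable-variance fraction
    of the panel on the native (exponentiated) scale -- the scale on which
    the validation metrics are computed.
    """

    alpha: float
    d_funcs: dict
    f_funcs: dict
    g_field: object                       # callable(coords)
    gt_fields: dict                       # (region, month) -> callable(coords)
    alpha_t: dict                         # (region, month) -> float
    sigma_b: float
    sigma_e: dict                         # (region, month) -> float
    r2_star: float
    region_map: RegionMap
    h_func: object = None                 # ratio-variant temporal trend
    gseas_fields: dict = field(default_factory=dict)

    def signal_table(self) -> pd.DataFrame:
        """True fixed-effect log-mean per site-month (no b_i, no e_it),
        as generated (wide: sites x months)."""
        return self._signal


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_network(n_sites: int, n_regions: int, seed: int,
                     domain=DOMAIN_KM):
    """Monitor network: clustered urban sites plus rural background.

    Returns (site table, RegionMap).  The site table has columns site_id, x,
    y, region, urban (cluster-proximity score in [0, 1]) and urban_tertile.
    """
    if n_sites < 10 * n_regions:
        raise ValueError("need at least 10 sites per region")
    rng = np.random.default_rng(seed)
    W, H = domain
    rmap = RegionMap.tile(n_regions, domain)
    n_clusters = max(3, n_sites // 40)
    centers = np.column_stack([
        rng.uniform(0.05 * W, 0.95 * W, n_clusters),
        rng.uniform(0.05 * H, 0.95 * H, n_clusters),
    ])
    n_urban = int(0.6 * n_sites)
    which = rng.integers(0, n_clusters, n_urban)
    urban_pts = centers[which] + rng.normal(0, 30.0, (n_urban, 2))
    rural_pts = np.column_stack([
        rng.uniform(0, W, n_sites - n_urban),
        rng.uniform(0, H, n_sites - n_urban)])
    pts = np.vstack([urban_pts, rural_pts])
    pts[:, 0] = np.clip(pts[:, 0], 0, W)
    pts[:, 1] = np.clip(pts[:, 1], 0, H)
    # proximity to nearest cluster centre -> urbanness score
    d = np.min(np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2),
               axis=1)
    urban = 1.0 / (1.0 + (d / 40.0) ** 2)
    region = rmap.assign(pts)
    sites = pd.DataFrame({
        "site_id": [f"S{i:04d}" for i in range(n_sites)],
        "x": pts[:, 0], "y": pts[:, 1], "region": region, "urban": urban,
    })
    # guarantee enough sites per region: relocate from the fullest region
    counts = sites["region"].value_counts()
    for r in rmap.regions:
        deficit = 10 - int(counts.get(r, 0))
        if deficit > 0:
            donor = counts.idxmax()
            take = sites.index[sites["region"] == donor][:deficit]
            x0, x1, y0, y1 = rmap.rects[r]
            sites.loc[take, "x"] = rng.uniform(x0, x1, len(take))
            sites.loc[take, "y"] = rng.uniform(y0, y1, len(take))
            sites.loc[take, "region"] = r
            counts = sites["region"].value_counts()
    tert = pd.qcut(sites["urban"].rank(method="first"), 3, labels=[0, 1, 2])
    sites["urban_tertile"] = tert.astype(int)
    return sites, rmap


def generate_covariates(sites: pd.DataFrame, n_months: int, seed: int,
                        domain=DOMAIN_KM) -> CovariateTable:
    """Geographic and meteorological covariates at the sites.

    Time-invariant: elevation (sqrt-transformed), urban fraction within 1 km,
    population density, distance to road (right-skewed, truncated at 500 m),
    point-source emissions density (sparse, skewed) -- the skewed ones
    log-shift transformed.  Time-varying: monthly wind speed, temperature,
    precipitation, and log air-stagnation fraction with seasonal cycles and
    spatial correlation.
    """
    rng = np.random.default_rng(seed)
    n = len(sites)
    coords = sites[["x", "y"]].to_numpy()
    urban = sites["urban"].to_numpy()

    # regional relief plus realistic site-scale relief: a monitoring site on
    # a hillside differs from its neighbours by O(100 m)
    elev_field = BumpField(rng, domain, amplitude=400.0, length=(200.0, 500.0))
    elev_raw = elev_field(coords) + rng.normal(0, 150.0, n)
    elev_raw -= elev_raw.min()          # sea level at the lowest site
    elev, elev_meta = sqrt_shift_transform(elev_raw)

    # population density spans orders of magnitude at any given urbanness;
    # moderate correlation with urban land use (~0.45) keeps the two
    # covariates' effects separately identifiable
    pop_raw = np.exp(3.0 + 1.5 * urban + rng.normal(0, 1.0, n))
    log_pop, pop_meta = log_shift_transform(pop_raw, name="pop_density")

    # distance to road in metres: short in urban cores, long in the rural
    # background; heavy right tail before the 500 m truncation
    droad_raw = rng.exponential(250.0 + 2000.0 * (1.0 - urban))
    droad = truncate_distance(droad_raw)
    log_droad, droad_meta = log_shift_transform(droad, name="dist_road")

    # sparse point sources: most sites see ~zero density
    psrc_raw = np.where(rng.uniform(size=n) < 0.3,
                        np.exp(rng.normal(1.0, 1.0, n)) * (0.3 + urban), 0.0)
    log_psrc, psrc_meta = log_shift_transform(psrc_raw, name="point_source")

    X = pd.DataFrame({
        "elevation": elev,
        "urban_1km": urban,
        "log_pop_density": log_pop,
        "log_dist_road": log_droad,
        "log_point_source": log_psrc,
    }, index=pd.Index(sites["site_id"], name="site_id"))

    # time-varying meteorology: seasonal cycle + spatial field + noise
    months = np.arange(1, n_months + 1)
    temp_field = BumpField(rng, domain, amplitude=2.0)
    wind_field = BumpField(rng, domain, amplitude=0.6)
    prec_field = BumpField(rng, domain, amplitude=0.4)
    stag_field = BumpField(rng, domain, amplitude=0.15)
    lat = coords[:, 1] / domain[1]          # pseudo-latitude in [0, 1]
    rows = []
    for m in months:
        phase = 2.0 * np.pi * (m % 12) / 12.0
        temp = (12.0 - 8.0 * lat + 11.0 * np.cos(phase - np.pi)
                + temp_field(coords) + rng.normal(0, 1.2, n))
        wind = np.maximum(
            3.5 + 0.8 * np.cos(phase) + wind_field(coords)
            + rng.normal(0, 0.5, n), 0.2)
        precip = np.maximum(
            6.0 + 3.0 * np.sin(phase) + 4.0 * prec_field(coords)
            + rng.normal(0, 2.0, n), 0.0)
        stag_frac = np.clip(
            0.15 + 0.10 * np.cos(phase - np.pi) + stag_field(coords)
            + rng.normal(0, 0.04, n), 0.0, 0.9)
        # avoid log 0 by adding half a percentage point
        log_stag = np.log(stag_frac + 0.005)
        rows.append(pd.DataFrame({
            "site_id": sites["site_id"].to_numpy(), "month": m,
            "temperature": temp, "wind_speed": wind,
            "precipitation": precip, "log_stagnation": log_stag,
        }))
    Z = pd.concat(rows, ignore_index=True)
    meta = {
        "elevation": elev_meta, "log_pop_density": pop_meta,
        "log_dist_road": droad_meta, "log_point_source": psrc_meta,
    }
    tab = CovariateTable(X=X, Z=Z, meta=meta)
    tab.record_ranges(sites.set_index("site_id")["region"])
    return tab


def generate_met_stations(region_map: RegionMap, n_stations: int,
                          n_months: int, seed: int, domain=DOMAIN_KM):
    """Station meteorology panel in long format (one row per
    station/month/parameter) plus the true spatial fields for comparison."""
    rng = np.random.default_rng(seed)
    W, H = domain
    pts = np.column_stack([rng.uniform(0, W, n_stations),
                           rng.uniform(0, H, n_stations)])
    region = region_map.assign(pts)
    fields = {p: BumpField(rng, domain, amplitude=a)
              for p, a in [("temperature", 3.0), ("wind_speed", 0.8),
                           ("precipitation", 2.0), ("stagnation", 0.1)]}
    noise_sd = {"temperature": 0.8, "wind_speed": 0.4,
                "precipitation": 1.0, "stagnation": 0.03}
    rows = []
    for m in range(1, n_months + 1):
        phase = 2.0 * np.pi * (m % 12) / 12.0
        base = {
            "temperature": 12.0 + 11.0 * np.cos(phase - np.pi),
            "wind_speed": 3.5 + 0.8 * np.cos(phase),
            "precipitation": 6.0 + 3.0 * np.sin(phase),
            "stagnation": 0.15 + 0.1 * np.cos(phase - np.pi),
        }
        for p, f in fields.items():
            val = base[p] + f(pts) + rng.normal(0, noise_sd[p], n_stations)
            if p in ("wind_speed", "precipitation"):
                val = np.maximum(val, 0.0)
            if p == "stagnation":
                val = np.clip(val, 0.0, 0.9)
            rows.append(pd.DataFrame({
                "station_id": [f"M{i:04d}" for i in range(n_stations)],
                "x": pts[:, 0], "y": pts[:, 1], "region": region,
                "month": m, "parameter": p, "value": val,
            }))
    return pd.concat(rows, ignore_index=True), fields


@dataclass
class PanelConfig:
    """Scale of the generated PM panel and its variance budget."""

    r2_star: float = 0.8
    missing_rate: float = 0.10
    sigma_b_share: float = 0.3        # share of noise variance in b_i
    alpha: float = np.log(10.0)       # grand log-mean, ~10 ug/m3
    d_amplitude: float = 0.35
    f_amplitude: float = 0.25
    g_amplitude: float = 0.30
    gt_amplitude: float = 0.10
    season_amplitude: float = 0.20


def _smooth_effect(rng, values, amplitude):
    """Random smooth centred effect of one covariate: scaled tanh ramp."""
    lo, hi = np.quantile(values, [0.05, 0.95])
    centre = rng.uniform(lo, hi)
    width = max((hi - lo) * rng.uniform(0.4, 0.9), 1e-6)
    sign = rng.choice([-1.0, 1.0])
    mean_ref = np.mean(np.tanh((values - centre) / width))

    def fn(v, centre=centre, width=width, sign=sign, amp=amplitude,
           mean_ref=mean_ref):
        return sign * amp * (np.tanh((np.asarray(v, float) - centre) / width)
                             - mean_ref)
    return fn


def generate_pm_panel(sites: pd.DataFrame, cov: CovariateTable,
                      config: PanelConfig, seed: int, n_months: int = 24,
                      domain=DOMAIN_KM):
    """Monthly PM panel with the additive log-scale structure above.

    The noise variances are calibrated so the realized explainable fraction of
    log-scale variance matches ``config.r2_star``.  Returns (panel, truth);
    the panel has columns site_id, month, conc (native scale, ug/m3).
    """
    rng = np.random.default_rng(seed)
    site_ids = sites["site_id"].to_numpy()
    coords = sites[["x", "y"]].to_numpy()
    regions = sites["region"].to_numpy()
    region_ids = sorted(set(regions))
    n = len(sites)
    months = np.arange(1, n_months + 1)

    d_funcs = {name: _smooth_effect(rng, cov.X[name].to_numpy(),
                                    config.d_amplitude)
               for name in ("elevation", "urban_1km", "log_pop_density")}
    f_funcs = {name: _smooth_effect(rng, cov.Z[name].to_numpy(),
                                    config.f_amplitude)
               for name in ("temperature", "wind_speed")}
    g_field = BumpField(rng, domain, amplitude=config.g_amplitude)
    gt_fields, alpha_t = {}, {}
    for r in region_ids:
        r_phase = rng.uniform(0, 2 * np.pi)
        for m in months:
            gt_fields[(r, m)] = BumpField(
                rng, domain, amplitude=config.gt_amplitude,
                n_bumps=(3, 8), length=(150.0, 400.0))
            alpha_t[(r, m)] = (config.season_amplitude
                               * np.cos(2 * np.pi * (m % 12) / 12.0 - r_phase)
                               + rng.normal(0, 0.05))
    for r in region_ids:
        mean_r = np.mean([alpha_t[(r, m)] for m in months])
        for m in months:
            alpha_t[(r, m)] -= mean_r

    # assemble fixed signal per site-month
    Z = cov.Z.set_index(["site_id", "month"]).sort_index()
    d_part = np.zeros(n)
    for name, fn in d_funcs.items():
        d_part += fn(cov.X.loc[site_ids, name].to_numpy())
    g_part = g_field(coords)
    sig = np.empty((n, n_months))
    for j, m in enumerate(months):
        zblock = Z.xs(m, level="month").loc[site_ids]
        f_part = np.zeros(n)
        for name, fn in f_funcs.items():
            f_part += fn(zblock[name].to_numpy())
        col = config.alpha + d_part + g_part + f_part
        for r in region_ids:
            mask = regions == r
            col[mask] += alpha_t[(r, m)] + gt_fields[(r, m)](coords[mask])
        sig[:, j] = col

    # calibrate the noise budget so the *native-scale* explainable fraction
    # (the scale every validation metric uses) equals r2_star: with
    # S = exp(signal) and independent log-normal noise of log-variance v,
    # R2_native = Var(S) / (E[S^2] e^v - E[S]^2), solved for v
    S = np.exp(sig)
    m1, m2 = float(S.mean()), float((S ** 2).mean())
    var_S = m2 - m1 ** 2
    var_noise = float(np.log((var_S / config.r2_star + m1 ** 2) / m2))
    sigma_b = np.sqrt(config.sigma_b_share * var_noise)
    sigma_e_mean2 = (1.0 - config.sigma_b_share) * var_noise
    # heteroscedastic region-month factors with unit mean square
    factors = {(r, m): rng.uniform(0.8, 1.2)
               for r in region_ids for m in months}
    msq = np.mean([f ** 2 for f in factors.values()])
    sigma_e = {k: np.sqrt(sigma_e_mean2) * f / np.sqrt(msq)
               for k, f in factors.items()}

    b = rng.normal(0, sigma_b, n)
    rows = []
    for j, m in enumerate(months):
        e_sd = np.array([sigma_e[(r, m)] for r in regions])
        logy = sig[:, j] + b + rng.normal(0, 1.0, n) * e_sd
        rows.append(pd.DataFrame({
            "site_id": site_ids, "month": m, "conc": np.exp(logy)}))
    panel = pd.concat(rows, ignore_index=True)
    if config.missing_rate > 0:
        keep = rng.uniform(size=len(panel)) >= config.missing_rate
        panel = panel[keep].reset_index(drop=True)

    v_real = sigma_b ** 2 + sigma_e_mean2
    r2_real = var_S / (m2 * np.exp(v_real) - m1 ** 2)
    truth = SyntheticTruth(
        alpha=config.alpha, d_funcs=d_funcs, f_funcs=f_funcs,
        g_field=g_field, gt_fields=gt_fields, alpha_t=alpha_t,
        sigma_b=sigma_b, sigma_e=sigma_e, r2_star=r2_real,
        region_map=RegionMap.tile(len(region_ids), domain))
    truth._signal = pd.DataFrame(
        sig, index=pd.Index(site_ids, name="site_id"), columns=months)
    return panel, truth


def generate_ratio_panel(sites: pd.DataFrame, cov: CovariateTable,
                         pm10_panel: pd.DataFrame, seed: int,
                         contamination: float = 0.003, domain=DOMAIN_KM):
    """Coupled PM2.5 panel from a PM10 panel via a latent ratio process.

    The log-odds of the true ratio follow an additive process with a slow
    temporal trend h(t), seasonal regional spatial fields, an elevation
    effect and site/observation noise; the logistic squashing keeps the true
    ratio in (0, 1).  A small fraction of records is contaminated so that
    PM2.5 > 1.5 x PM10, exercising the outlier-deletion rule.

    Returns (pm25 panel, truth dict).
    """
    rng = np.random.default_rng(seed)
    regions = sites.set_index("site_id")["region"]
    coords_by_site = sites.set_index("site_id")[["x", "y"]]
    months = np.sort(pm10_panel["month"].unique())
    t_scale = max(months.max(), 1)

    def h_func(t):
        t = np.asarray(t, float)
        return (-0.15 * (t / t_scale - 0.5)
                + 0.05 * np.sin(2 * np.pi * t / t_scale))

    elev_fn = _smooth_effect(rng, cov.X["elevation"].to_numpy(), 0.25)
    gseas = {}
    for r in sorted(regions.unique()):
        for s in range(4):
            gseas[(r, s)] = BumpField(rng, domain, amplitude=0.15,
                                      n_bumps=(3, 8))
    b_site = pd.Series(rng.normal(0, 0.15, len(sites)),
                       index=sites["site_id"])

    season = ((pm10_panel["month"].to_numpy() % 12) // 3).astype(int)
    sid = pm10_panel["site_id"].to_numpy()
    xy = coords_by_site.loc[sid].to_numpy()
    reg = regions.loc[sid].to_numpy()
    eta = (0.4 + h_func(pm10_panel["month"].to_numpy())
           + elev_fn(cov.X.loc[sid, "elevation"].to_numpy())
           + b_site.loc[sid].to_numpy()
           + rng.normal(0, 0.2, len(pm10_panel)))
    for (r, s), fld in gseas.items():
        mask = (reg == r) & (season == s)
        if mask.any():
            eta[mask] += fld(xy[mask])
    ratio_true = 1.0 / (1.0 + np.exp(-eta))
    pm25 = ratio_true * pm10_panel["conc"].to_numpy() * np.exp(
        rng.normal(0, 0.05, len(pm10_panel)))
    contam = rng.uniform(size=len(pm25)) < contamination
    pm25[contam] = pm10_panel["conc"].to_numpy()[contam] * rng.uniform(
        1.6, 2.5, int(contam.sum()))
    panel = pd.DataFrame({
        "site_id": sid, "month": pm10_panel["month"].to_numpy(),
        "conc": pm25})
    truth = {"ratio_true": ratio_true, "contaminated": contam,
             "h_func": h_func, "gseas_fields": gseas, "elev_fn": elev_fn}
    return panel, truth


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    sites: pd.DataFrame
    region_map: RegionMap
    covariates: CovariateTable
    panel: pd.DataFrame
    truth: SyntheticTruth
    n_months: int


def scenario_default(seed: int, n_sites: int = 150, n_regions: int = 3,
                     n_months: int = 24,
                     config: PanelConfig | None = None) -> SyntheticDataset:
    """Desk-scale scenario: 150 sites, 3 regions, 24 months, R2* = 0.8."""
    config = config or PanelConfig()
    sites, rmap = generate_network(n_sites, n_regions, seed)
    cov = generate_covariates(sites, n_months, seed + 1)
    panel, truth = generate_pm_panel(sites, cov, config, seed + 2,
                                     n_months=n_months)
    truth.region_map = rmap
    return SyntheticDataset(sites, rmap, cov, panel, truth, n_months)


def scenario_large(seed: int) -> SyntheticDataset:
    """Larger scenario: 600 sites, 7 regions, 60 months."""
    return scenario_default(seed, n_sites=600, n_regions=7, n_months=60)


def scenario_historical(seed: int, n_sites: int = 100, n_months: int = 60,
                        eval_year_months=range(37, 49)) -> SyntheticDataset:
    """Historical-sparsity scenario: few sites report in early months.

    Site-months before the evaluation year are thinned so early network
    density is low -- the pattern the year-2000-style cross-validation
    design is built for.
    """
    ds = scenario_default(seed, n_sites=n_sites, n_regions=3,
                          n_months=n_months,
                          config=PanelConfig(missing_rate=0.0))
    rng = np.random.default_rng(seed + 9)
    early_sites = set(ds.sites["site_id"].sample(
        frac=0.3, random_state=seed % (2 ** 31)))
    m = ds.panel["month"].to_numpy()
    sid = ds.panel["site_id"].to_numpy()
    first_eval = min(eval_year_months)
    early = m < first_eval
    keep = ~early | np.isin(sid, list(early_sites))
    keep &= rng.uniform(size=len(ds.panel)) >= 0.05
    ds.panel = ds.panel[keep].reset_index(drop=True)
    return ds
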