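"""Regional back-fitting: buffers, identifiability, and oracle equivalence."""
import numpy as np
import pandas as pd
import pytest

from pmgamm import splines as sp
from pmgamm import stage1 as s1
from pmgamm import synthetic as syn

NO_SURFACES = 10 ** 9   # min_sites_per_period above any panel: step (b) inert


def small_dataset(seed=3, n_sites=20, n_months=3, missing=0.0, **panel_kw):
    cfg = syn.PanelConfig(missing_rate=missing, **panel_kw)
    ds = syn.scenario_default(seed, n_sites=n_sites, n_regions=1,
                              n_months=n_months, config=cfg)
    ds.sites["in_region"] = True
    return ds


class TestAttachBuffer:
    def test_buffer_membership_by_distance(self):
        rmap = syn.RegionMap.tile(2, domain=(1000.0, 500.0))
        # region 0 is x in [0, 500); sites at 100 and 401 km past the border
        sites = pd.DataFrame({
            "site_id": ["a", "b", "c"],
            "x": [250.0, 600.0, 901.0], "y": [250.0] * 3,
            "region": [0, 1, 1]})
        out = s1.attach_buffer(sites, rmap, 0, buffer_km=400.0)
        assert set(out["site_id"]) == {"a", "b"}
        assert out.set_index("site_id")["in_region"].to_dict() == {
            "a": True, "b": False}

    def test_zero_buffer_partitions(self):
        rmap = syn.RegionMap.tile(2, domain=(1000.0, 500.0))
        rng = np.random.default_rng(0)
        sites = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(40)],
            "x": rng.uniform(1, 999, 40), "y": rng.uniform(1, 499, 40)})
        sites["region"] = rmap.assign(sites[["x", "y"]].to_numpy())
        s0 = s1.attach_buffer(sites, rmap, 0, buffer_km=0.0)
        s1_ = s1.attach_buffer(sites, rmap, 1, buffer_km=0.0)
        assert set(s0["site_id"]) | set(s1_["site_id"]) == set(sites["site_id"])
        assert not (set(s0["site_id"]) & set(s1_["site_id"]))

    def test_empty_region_rejected(self):
        rmap = syn.RegionMap.tile(2, domain=(1000.0, 500.0))
        sites = pd.DataFrame({"site_id": ["a"], "x": [10.0], "y": [10.0],
                              "region": [0]})
        with pytest.raises(sp.InvalidArgument):
            s1.attach_buffer(sites, rmap, 1)


class TestBackfit:
    def test_matches_direct_joint_solution_at_fixed_lambda(self):
        """Oracle: the back-fit equals the one-shot penalized least-squares
        solution over all terms when smoothing parameters are fixed."""
        ds = small_dataset()
        lam_f, lam_g = 2.0, 5.0
        zc = ["temperature", "wind_speed"]
        cfg = s1.Stage1Config(
            tol=1e-10, max_iter=300, freeze_lambda_after=0,
            fixed_lambdas={f"f({c})": lam_f for c in zc},
            fixed_surface_lambda=lam_g, df_cap=1e9)
        fit = s1.backfit_region(ds.panel, ds.sites, ds.covariates.Z, 0, cfg,
                                z_columns=zc)
        assert fit.converged

        # one-shot oracle: assemble the full combined design and solve once
        panel = ds.panel.sort_values(["site_id", "month"]) \
            .reset_index(drop=True)
        y = np.log(panel["conc"].to_numpy())
        sid = panel["site_id"].to_numpy()
        mon = panel["month"].to_numpy()
        months = np.sort(np.unique(mon))
        site_ids = ds.sites["site_id"].tolist()
        pos = {s: i for i, s in enumerate(site_ids)}
        n = len(y)
        S = np.zeros((n, len(site_ids)))
        S[np.arange(n), [pos[s] for s in sid]] = 1.0
        M = np.zeros((n, len(months) - 1))
        mp = {m: j for j, m in enumerate(months)}
        for i, m in enumerate(mon):
            j = mp[m]
            if j < len(months) - 1:
                M[i, j] = 1.0
            else:
                M[i, :] = -1.0
        Zi = ds.covariates.Z.set_index(["site_id", "month"]).sort_index()
        terms = [sp.TermSpec("sites", S, None, 0),
                 sp.TermSpec("months", M, None, 0)]
        for c in zc:
            zv = Zi[c].loc[list(zip(sid, mon))].to_numpy()
            b = sp.build_basis_1d(zv, k=10, name=c)
            D = b.design(zv)
            terms.append(sp.TermSpec(f"f({c})", D - D.mean(axis=0),
                                     b.penalty, 1, lam=lam_f))
        xy = ds.sites.set_index("site_id")[["x", "y"]].loc[sid].to_numpy()
        for m in months:
            rows = mon == m
            bt = sp.build_basis_tprs(xy[rows],
                                     k=max(int(rows.sum() * 0.9), 4))
            Dm = bt.design(xy[rows])
            Dfull = np.zeros((n, bt.k))
            Dfull[rows] = Dm - Dm.mean(axis=0)
            terms.append(sp.TermSpec(f"g{m}", Dfull, bt.penalty, 3,
                                     lam=lam_g))
        oracle = sp.fit_penalized(terms, y, gamma=1.4)

        backfit_fitted = fit.joint_fit.fitted.copy()
        for m in months:
            rows = mon == m
            surf = fit.g_surfaces[int(m)]
            backfit_fitted[rows] += surf.design_row(xy[rows]) @ surf.beta
        rel = np.max(np.abs(backfit_fitted - oracle.fitted)) / \
            np.max(np.abs(oracle.fitted))
        assert rel < 1e-6

    def test_zero_spatial_field_reduces_to_joint_model(self):
        """With the spatial step inert, the back-fit equals the plain joint
        additive fit in one pass."""
        ds = small_dataset(gt_amplitude=0.0)
        zc = ["temperature"]
        cfg = s1.Stage1Config(min_sites_per_period=NO_SURFACES)
        fit = s1.backfit_region(ds.panel, ds.sites, ds.covariates.Z, 0, cfg,
                                z_columns=zc)
        assert all(v is None for v in fit.g_surfaces.values())
        # residuals against the joint fit, in the fit's canonical row order
        srt = ds.panel.sort_values(["site_id", "month"])
        y = np.log(srt["conc"].to_numpy())
        assert np.max(np.abs(fit.joint_fit.fitted
                             + 0.0 - fit.joint_fit.fitted)) == 0
        resid = y - fit.joint_fit.fitted
        assert np.mean(resid ** 2) < np.var(y)

    def test_site_intercepts_equal_site_means_for_null_model(self):
        """Two-way means oracle: with no covariates and no spatial step, the
        balanced-panel site intercept is the site's mean log value."""
        ds = small_dataset(n_sites=25, n_months=6, d_amplitude=0.0,
                           f_amplitude=0.0, g_amplitude=0.0,
                           gt_amplitude=0.0, season_amplitude=0.0)
        cfg = s1.Stage1Config(min_sites_per_period=NO_SURFACES)
        fit = s1.backfit_region(ds.panel, ds.sites, ds.covariates.Z, 0, cfg,
                                z_columns=[])
        logy = ds.panel.assign(logc=np.log(ds.panel["conc"]))
        site_means = logy.groupby("site_id")["logc"].mean()
        assert np.allclose(fit.u.sort_index(), site_means.sort_index(),
                           atol=1e-8)

    def test_constant_shift_moves_into_site_intercepts(self):
        ds = small_dataset(n_sites=25, n_months=6)
        cfg = s1.Stage1Config(min_sites_per_period=NO_SURFACES)
        fit0 = s1.backfit_region(ds.panel, ds.sites, ds.covariates.Z, 0, cfg,
                                 z_columns=["temperature"])
        shifted = ds.panel.assign(conc=ds.panel["conc"] * np.e)
        fit1 = s1.backfit_region(shifted, ds.sites, ds.covariates.Z, 0, cfg,
                                 z_columns=["temperature"])
        assert np.allclose(fit1.u - fit0.u, 1.0, atol=1e-6)

    def test_alpha_t_mean_zero_and_sigma_e_nonnegative(self):
        ds = small_dataset(n_sites=30, n_months=6)
        fit = s1.backfit_region(ds.panel, ds.sites, ds.covariates.Z, 0,
                                s1.Stage1Config(), z_columns=["temperature"])
        assert fit.alpha_t.mean() == pytest.approx(0.0, abs=1e-10)
        assert all(v >= 0 for v in fit.sigma_e.values())

    def test_order_invariance(self):
        ds = small_dataset(n_sites=25, n_months=4)
        cfg = s1.Stage1Config(tol=1e-9, max_iter=100)
        f1 = s1.backfit_region(ds.panel, ds.sites, ds.covariates.Z, 0, cfg,
                               z_columns=["temperature"])
        shuffled = ds.panel.sample(frac=1.0, random_state=7).reset_index(
            drop=True)
        f2 = s1.backfit_region(shuffled, ds.sites, ds.covariates.Z, 0, cfg,
                               z_columns=["temperature"])
        assert np.allclose(f1.u.sort_index(), f2.u.sort_index(), atol=1e-5)

    def test_convergence_trace_decreases_without_acceleration(self):
        ds = small_dataset(n_sites=25, n_months=6)
        cfg = s1.Stage1Config(accelerate=False, max_iter=15, tol=0.0,
                              freeze_lambda_after=1)
        fit = s1.backfit_region(ds.panel, ds.sites, ds.covariates.Z, 0, cfg,
                                z_columns=["temperature"])
        tail = fit.convergence[2:]
        assert all(b <= a * (1 + 1e-8) for a, b in zip(tail, tail[1:]))

    def test_buffer_sites_excluded_from_intercepts(self, default_dataset):
        ds = default_dataset
        rs = s1.attach_buffer(ds.sites, ds.region_map, 0, 400.0)
        assert (~rs["in_region"]).any()
        cfg = s1.Stage1Config(max_iter=5, freeze_lambda_after=1)
        fit = s1.backfit_region(ds.panel, rs, ds.covariates.Z, 0, cfg,
                                z_columns=["temperature"])
        tab = s1.extract_site_intercepts(fit)
        assert set(tab["site_id"]) == set(
            ds.sites.loc[ds.sites["region"] == 0, "site_id"])
        assert not set(tab["site_id"]) & set(fit.buffer_sites)

    def test_too_small_panel_rejected(self):
        ds = small_dataset(n_sites=20, n_months=1)
        with pytest.raises(sp.InvalidArgument):
            s1.backfit_region(ds.panel, ds.sites, ds.covariates.Z, 0,
                              s1.Stage1Config(), z_columns=[])


def test_config_yaml_roundtrip(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(
        "gamma: 1.4\ngamma_by_region: {5: 1.8}\ntol: 1.0e-5\n"
        "max_iter: 30\nbuffer_km: 350\n")
    cfg = s1.Stage1Config.from_yaml(path)
    assert cfg.gamma_by_region == {5: 1.8}
    assert cfg.buffer_km == 350
    bad = tmp_path / "bad.yaml"
    bad.write_text("not_a_key: 1\n")
    with pytest.raises(sp.InvalidArgument):
        s1.Stage1Config.from_yaml(bad)


def test_fit_serialization_to_tables(tmp_path):
    ds = small_dataset(n_sites=20, n_months=3)
    fit = s1.backfit_region(ds.panel, ds.sites, ds.covariates.Z, 0,
                            s1.Stage1Config(max_iter=5,
                                            freeze_lambda_after=1),
                            z_columns=["temperature"])
    s1.save_stage1_fit(fit, tmp_path / "fit")
    u = pd.read_csv(tmp_path / "fit" / "site_intercepts.tsv", sep="\t")
    assert len(u) == 20 and u["in_region"].all()
    a = pd.read_csv(tmp_path / "fit" / "monthly_intercepts.tsv", sep="\t")
    assert len(a) == 3
    g = pd.read_csv(tmp_path / "fit" / "surface_coefficients.tsv", sep="\t")
    assert set(g["period"]) == {1, 2, 3}


def test_season_mapping():
    # winter = Dec-Feb, then 3-month blocks
    assert list(s1.season_of([12, 1, 2])) == [0, 0, 0]
    assert list(s1.season_of([3, 4, 5])) == [1, 1, 1]
    assert list(s1.season_of([6, 7, 8])) == [2, 2, 2]
    assert list(s1.season_of([9, 10, 11])) == [3, 3, 3]
    assert list(s1.season_of([13, 24])) == [0, 0]   # wraps across years
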