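"""Fold designs and bias/precision metrics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmgamm import splines as sp
from pmgamm import synthetic as syn
from pmgamm import validation as val


class TestFolds:
    def test_uniform_partition(self):
        sites = [f"s{i}" for i in range(100)]
        fa = val.assign_folds(sites, 10, seed=4)
        counts = fa.folds.value_counts()
        assert (counts == 10).all()
        assert set(fa.folds.index) == set(sites)

    def test_deterministic_and_exclusive(self):
        sites = [f"s{i}" for i in range(57)]
        f1 = val.assign_folds(sites, 10, seed=9)
        f2 = val.assign_folds(sites, 10, seed=9)
        pd.testing.assert_series_equal(f1.folds, f2.folds)
        assert f1.folds.index.is_unique

    def test_too_few_sites_rejected(self):
        with pytest.raises(sp.InvalidArgument):
            val.assign_folds(["a", "b"], 10)


class TestYear2000Design:
    @pytest.fixture(scope="class")
    def historical(self):
        ds = syn.scenario_historical(4)
        return ds

    def test_qualifying_thresholds(self, historical):
        ds = historical
        eval_months = range(37, 49)
        fa = val.build_year2000_design(ds.panel, ds.sites, eval_months,
                                       seed=3, min_total_values=40)
        n_eval = ds.panel[ds.panel["month"].isin(eval_months)] \
            .groupby("site_id").size()
        n_tot = ds.panel.groupby("site_id").size()
        for s in fa.folds.index:
            assert n_eval.get(s, 0) >= 10
            assert n_tot.get(s, 0) >= 40
        for s in fa.withheld_sites:
            assert s not in fa.folds.index

    def test_deterministic(self, historical):
        ds = historical
        f1 = val.build_year2000_design(ds.panel, ds.sites, range(37, 49),
                                       seed=3, min_total_values=40)
        f2 = val.build_year2000_design(ds.panel, ds.sites, range(37, 49),
                                       seed=3, min_total_values=40)
        pd.testing.assert_series_equal(f1.folds, f2.folds)
        assert f1.withheld_sites == f2.withheld_sites

    def test_no_qualifiers_rejected(self, historical):
        ds = historical
        with pytest.raises(sp.InvalidArgument):
            val.build_year2000_design(ds.panel, ds.sites, range(37, 49),
                                      min_total_values=10 ** 6)


class TestRunCV:
    def test_left_out_sites_never_fit_their_own_fold(self):
        rng = np.random.default_rng(5)
        sites = [f"s{i}" for i in range(30)]
        panel = pd.DataFrame({
            "site_id": np.repeat(sites, 4),
            "month": np.tile([1, 2, 3, 4], 30),
            "conc": rng.lognormal(2, 0.3, 120)})
        fa = val.assign_folds(sites, 10, seed=0)
        rosters = {}

        def fit_fn(train_panel, train_sites):
            return {"sites": set(train_sites),
                    "mean": train_panel["conc"].mean()}

        def predict_fn(model, site_ids, months):
            rows = [(s, m, model["mean"]) for s in site_ids for m in months]
            rosters[frozenset(site_ids)] = model["sites"]
            return pd.DataFrame(rows, columns=["site_id", "month", "mean"])

        out = val.run_cv(fit_fn, predict_fn, panel, fa)
        for held, fitted in rosters.items():
            assert not (held & fitted)
        # a prediction exists for every left-out site-month in folds 1..9
        held_sites = set().union(*[fa.sites_in(f) for f in range(1, 10)])
        expect = panel[panel["site_id"].isin(held_sites)]
        assert len(out) == len(expect)

    def test_eval_year_design_scores_only_eval_months(self):
        rng = np.random.default_rng(8)
        sites = [f"s{i}" for i in range(25)]
        panel = pd.DataFrame({
            "site_id": np.repeat(sites, 24),
            "month": np.tile(np.arange(1, 25), 25),
            "conc": rng.lognormal(2, 0.3, 600)})
        fa = val.build_year2000_design(panel, pd.DataFrame({
            "site_id": sites, "x": rng.uniform(0, 100, 25),
            "y": rng.uniform(0, 100, 25)}), range(13, 25), seed=1,
            min_total_values=20)

        def fit_fn(train_panel, train_sites):
            return train_panel["conc"].mean()

        def predict_fn(model, site_ids, months):
            rows = [(s, m, model) for s in site_ids for m in months]
            return pd.DataFrame(rows, columns=["site_id", "month", "mean"])

        out = val.run_cv(fit_fn, predict_fn, panel, fa)
        assert out["month"].min() >= 13

    def test_fold_failure_reports_fold_id(self):
        sites = [f"s{i}" for i in range(20)]
        panel = pd.DataFrame({"site_id": sites, "month": 1,
                              "conc": np.ones(20)})
        fa = val.assign_folds(sites, 10, seed=0)

        def bad_fit(train_panel, train_sites):
            raise ValueError("boom")

        with pytest.raises(RuntimeError, match="fold 1"):
            val.run_cv(bad_fit, None, panel, fa)


class TestMetrics:
    def test_cv_r2_identity_and_affine(self):
        o = np.array([1.0, 2.0, 3.0, 4.0])
        assert val.cv_r2(o, o) == pytest.approx(1.0)
        assert val.cv_r2(o, 2 * o + 5) == pytest.approx(1.0)

    def test_cv_r2_brute_force_four_points(self):
        o = np.array([1.0, 3.0, 2.0, 5.0])
        m = np.array([2.0, 2.5, 2.2, 4.0])
        # direct correlation formula
        num = np.sum((o - o.mean()) * (m - m.mean()))
        den = np.sqrt(np.sum((o - o.mean()) ** 2) * np.sum((m - m.mean()) ** 2))
        assert val.cv_r2(o, m) == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_spatial_r2_uses_site_means(self):
        o = np.array([1.0, 3.0, 4.0, 6.0, 2.0, 2.0])
        m = np.array([2.0, 2.0, 5.0, 5.0, 2.0, 2.0])
        sites = ["a", "a", "b", "b", "c", "c"]
        want = val.cv_r2([2.0, 5.0, 2.0], [2.0, 5.0, 2.0])
        assert val.spatial_cv_r2(o, m, sites) == pytest.approx(want)

    def test_bias_factors_closed_forms(self):
        o = np.array([1.0, 2.0, 3.0])
        eq = val.bias_error_metrics(o, o)
        assert eq["nmbf_pct"] == pytest.approx(0.0)
        assert eq["nmef_pct"] == pytest.approx(0.0)
        assert eq["cvmae"] == pytest.approx(0.0)
        double = val.bias_error_metrics(o, 2 * o)
        assert double["nmbf_pct"] == pytest.approx(100.0)
        assert double["nmef_pct"] == pytest.approx(100.0)
        half = val.bias_error_metrics(o, o / 2)
        assert half["nmbf_pct"] == pytest.approx(-100.0)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=200)
    def test_nmef_dominates_nmbf(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        o = rng.lognormal(1, 0.8, n)
        m = rng.lognormal(1, 0.8, n)
        res = val.bias_error_metrics(o, m)
        assert res["nmef_pct"] >= abs(res["nmbf_pct"]) - 1e-9

    def test_major_axis_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        itc, slp = val.major_axis_fit(x, x)
        assert slp == pytest.approx(1.0)
        assert itc == pytest.approx(0.0, abs=1e-12)

    def test_major_axis_swap_gives_reciprocal(self, rng):
        x = rng.normal(0, 1, 50)
        y = 0.5 * x + rng.normal(0, 0.2, 50)
        _, s_xy = val.major_axis_fit(x, y)
        _, s_yx = val.major_axis_fit(y, x)
        assert s_xy == pytest.approx(1.0 / s_yx)

    def test_major_axis_eigenvector_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.5])
        y = np.array([0.2, 0.9, 2.3, 2.8, 4.9])
        itc, slp = val.major_axis_fit(x, y)
        C = np.cov(x, y)
        w, V = np.linalg.eigh(C)
        v = V[:, np.argmax(w)]
        want = v[1] / v[0]
        assert slp == pytest.approx(want, abs=1e-10)

    def test_pi_coverage_trivial_cases(self, rng):
        o = rng.normal(0, 1, 100)
        assert val.pi_coverage(o, o - 1, o + 1) == 1.0
        assert val.pi_coverage(o, o * 0, o * 0) == 0.0


class TestResidualACF:
    def test_white_noise_within_band(self):
        rng = np.random.default_rng(3)
        n_months = 60
        frames = []
        for i in range(30):
            frames.append(pd.DataFrame({
                "site_id": f"s{i}", "month": np.arange(n_months),
                "resid": rng.normal(0, 1, n_months)}))
        acf = val.residual_acf(pd.concat(frames), max_lag=15)
        band = 2 / np.sqrt(30 * n_months)
        assert np.mean(np.abs(acf) < 2 * band) >= 0.9

    def test_ar1_lag_one_recovered(self):
        rng = np.random.default_rng(4)
        rho = 0.5
        frames = []
        for i in range(40):
            e = rng.normal(0, 1, 80)
            r = np.zeros(80)
            for t in range(1, 80):
                r[t] = rho * r[t - 1] + e[t]
            frames.append(pd.DataFrame({
                "site_id": f"s{i}", "month": np.arange(80), "resid": r}))
        acf = val.residual_acf(pd.concat(frames), max_lag=5)
        assert acf.loc[1] == pytest.approx(rho, abs=0.1)

    def test_constant_series_skipped(self):
        df = pd.DataFrame({"site_id": "a", "month": np.arange(30),
                           "resid": np.ones(30)})
        acf = val.residual_acf(df, max_lag=5)
        assert acf.isna().all()


class TestStratifiedReport:
    def _preds(self, rng, n=200):
        obs = rng.lognormal(2, 0.4, n)
        return pd.DataFrame({
            "site_id": np.repeat([f"s{i}" for i in range(20)], n // 20),
            "month": np.tile(np.arange(n // 20), 20),
            "conc": obs, "mean": obs * rng.lognormal(0, 0.1, n),
            "lo95": obs * 0.5, "hi95": obs * 2.0,
            "label": np.repeat(["A", "B"], n // 2)})

    def test_identical_strata_identical_rows(self, rng):
        df = self._preds(rng)
        half = df[df["label"] == "A"].copy()
        other = half.copy()
        other["label"] = "B"
        rep = val.stratified_report(pd.concat([half, other]),
                                    {"lab": "label"})
        t = rep.table.set_index("stratum")
        a = t.loc["lab=A"].drop("n_excluded")
        b = t.loc["lab=B"].drop("n_excluded")
        pd.testing.assert_series_equal(a, b, check_names=False)

    def test_union_of_strata_equals_overall_n(self, rng):
        df = self._preds(rng)
        rep = val.stratified_report(df, {"lab": "label"})
        t = rep.table.set_index("stratum")
        assert t.loc["overall", "n"] == \
            t.loc["lab=A", "n"] + t.loc["lab=B", "n"]

    def test_exclusion_bookkeeping(self, rng):
        df = self._preds(rng)
        df["excluded"] = False
        df.loc[df.index[:17], "excluded"] = True
        rep = val.stratified_report(df)
        row = rep.table.set_index("stratum").loc["overall"]
        assert row["n_excluded"] == 17
        assert row["n"] == len(df) - 17

    def test_tiny_stratum_reports_missing_metrics(self, rng):
        df = self._preds(rng).iloc[:2]
        rep = val.stratified_report(df)
        row = rep.table.set_index("stratum").loc["overall"]
        assert row["n"] == 2 and np.isnan(row["cv_r2"])
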