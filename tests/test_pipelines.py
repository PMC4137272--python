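"""Model-variant pipelines: prediction rules, error propagation, round trips."""
import numpy as np
import pandas as pd
import pytest

from pmgamm import pipelines as pl
from pmgamm import splines as sp
from pmgamm import synthetic as syn


class TestRules:
    def test_ratio_outlier_removal_counts(self):
        panel = pd.DataFrame({
            "site_id": list("abcdef"), "month": [1] * 6,
            "conc": [10.0, 12.0, 16.0, 8.0, 32.0, 9.0]})
        pm10_hat = pd.Series([20.0, 20.0, 10.0, 20.0, 20.0, 20.0])
        kept, n = pl.remove_ratio_outliers(panel, pm10_hat)
        assert n == 2 and len(kept) == 4
        assert set(kept["site_id"]) == {"a", "b", "d", "f"}

    def test_ratio_outlier_boundary_kept(self):
        panel = pd.DataFrame({"site_id": ["a"], "month": [1],
                              "conc": [30.0]})
        kept, n = pl.remove_ratio_outliers(panel, pd.Series([20.0]))
        assert n == 0 and len(kept) == 1     # 30 == 1.5 * 20, strict rule

    def test_ratio_outlier_identity_when_clean(self):
        panel = pd.DataFrame({"site_id": ["a", "b"], "month": [1, 2],
                              "conc": [5.0, 6.0]})
        kept, n = pl.remove_ratio_outliers(panel, pd.Series([20.0, 20.0]))
        assert n == 0
        pd.testing.assert_frame_equal(kept, panel)

    def test_clamp_global_and_regional(self):
        vals = pd.DataFrame({"z": [1.0, 5.0, 9.0]})
        clamped, flags = pl.clamp_covariates(vals, {"z": (2.0, 8.0)})
        assert list(clamped["z"]) == [2.0, 5.0, 8.0]
        assert list(flags["z"]) == [True, False, True]
        regional, flags2 = pl.clamp_covariates(
            vals, {("z", "A"): (0.0, 4.0), ("z", "B"): (6.0, 10.0)},
            regions=["A", "A", "B"])
        assert list(regional["z"]) == [1.0, 4.0, 9.0]
        assert list(flags2["z"]) == [False, True, False]

    def test_clamp_unknown_covariate_rejected(self):
        with pytest.raises(sp.InvalidArgument):
            pl.clamp_covariates(pd.DataFrame({"q": [1.0]}), {})

    def test_predict_native_closed_form(self):
        mean, se = pl.predict_native(np.log(10.0), 0.05)
        assert mean == pytest.approx(10.0)
        assert se == pytest.approx(0.5)
        _, se0 = pl.predict_native(1.0, 0.0)
        assert se0 == 0.0
        with pytest.raises(sp.InvalidArgument):
            pl.predict_native(1.0, -0.1)

    def test_delta_se_against_monte_carlo(self, rng):
        """First-order delta SE within 10% of the Monte-Carlo SD of a
        log-normal for sigma_log <= 0.3."""
        for sigma in (0.05, 0.15, 0.3):
            mu = np.log(12.0)
            draws = np.exp(rng.normal(mu, sigma, 100_000))
            _, se = pl.predict_native(mu, sigma)
            assert se == pytest.approx(draws.std(), rel=0.10)

    def test_combine_ratio_closed_form(self):
        mean, se, trunc = pl.combine_ratio_pm10(0.6, 0.06, 20.0, 2.0)
        assert mean == pytest.approx(12.0)
        assert se == pytest.approx(np.sqrt(0.6 ** 2 * 4 + 400 * 0.0036))
        assert se == pytest.approx(1.697, abs=1e-3)
        assert not trunc

    def test_ratio_truncated_at_one(self):
        mean, se, trunc = pl.combine_ratio_pm10(1.3, 0.1, 20.0, 2.0)
        assert trunc
        assert mean == pytest.approx(20.0)

    def test_combine_zero_se(self):
        _, se, _ = pl.combine_ratio_pm10(0.5, 0.0, 10.0, 0.0)
        assert se == 0.0
        with pytest.raises(sp.InvalidArgument):
            pl.combine_ratio_pm10(-0.1, 0.1, 10.0, 1.0)

    def test_coarse_fraction_three_four_five(self):
        mean, se, flag = pl.coarse_fraction(25.0, 3.0, 15.0, 4.0)
        assert mean == pytest.approx(10.0)
        assert se == pytest.approx(5.0)
        assert not flag

    def test_coarse_negative_flagged(self):
        mean, _, flag = pl.coarse_fraction(10.0, 1.0, 15.0, 1.0)
        assert mean == -5.0 and flag

    def test_coarse_equal_ses(self):
        _, se, _ = pl.coarse_fraction(20.0, 2.0, 10.0, 2.0)
        assert se == pytest.approx(2.0 * np.sqrt(2))


class TestModelSpec:
    def test_ratio_variant_forces_seasonal_and_temporal_terms(self):
        spec = pl.ModelSpec(variant="ratio")
        assert spec.stage1.seasonal and spec.stage1.h_term

    def test_unknown_variant_rejected(self):
        with pytest.raises(sp.InvalidArgument):
            pl.ModelSpec(variant="nope")


@pytest.fixture(scope="module")
def fitted_model():
    ds = syn.scenario_default(11, n_sites=60, n_regions=2, n_months=12)
    spec = pl.ModelSpec(x_terms=["elevation", "urban_1km"],
                        z_terms=["temperature"])
    model = pl.fit_exposure_model(spec, ds.panel, ds.sites, ds.covariates,
                                  ds.region_map)
    return ds, model


class TestFittedPipeline:
    def test_ratio_requires_pm10_model(self, fitted_model):
        ds, _ = fitted_model
        with pytest.raises(sp.InvalidArgument):
            pl.fit_exposure_model(pl.ModelSpec(variant="ratio"), ds.panel,
                                  ds.sites, ds.covariates, ds.region_map)

    def test_month_outside_window_rejected(self, fitted_model):
        ds, model = fitted_model
        with pytest.raises(sp.InvalidArgument):
            pl.predict_log(model, ds.sites, [99])

    def test_observation_variance_increases_width(self, fitted_model):
        ds, model = fitted_model
        months = [1, 6]
        without = pl.predict_log(model, ds.sites, months,
                                 include_observation_var=False)
        with_ = pl.predict_log(model, ds.sites, months,
                               include_observation_var=True)
        assert np.all(with_["log_var"].to_numpy()
                      >= without["log_var"].to_numpy())
        assert np.allclose(with_["log_mean"], without["log_mean"])

    def test_roundtrip_serialization_bitwise(self, fitted_model, tmp_path):
        ds, model = fitted_model
        path = tmp_path / "model.pkl"
        model.save(path)
        back = pl.FittedExposureModel.load(path)
        p1 = pl.predict(model, ds.sites, [1, 6, 12])
        p2 = pl.predict(back, ds.sites, [1, 6, 12])
        pd.testing.assert_frame_equal(p1, p2)

    def test_interval_ordering_and_nonnegative_se(self, fitted_model):
        ds, model = fitted_model
        pred = pl.predict(model, ds.sites, [3])
        assert np.all(pred["se"] >= 0)
        assert np.all(pred["lo95"] <= pred["mean"])
        assert np.all(pred["mean"] <= pred["hi95"])


class TestRatioVariant:
    @pytest.fixture(scope="class")
    def ratio_setup(self):
        ds = syn.scenario_default(12, n_sites=60, n_regions=2, n_months=12)
        pm25, rtruth = syn.generate_ratio_panel(
            ds.sites, ds.covariates, ds.panel, 7, contamination=0.01)
        m10 = pl.fit_exposure_model(
            pl.ModelSpec(variant="pm10_direct",
                         x_terms=["elevation", "urban_1km"],
                         z_terms=["temperature"]),
            ds.panel, ds.sites, ds.covariates, ds.region_map)
        mr = pl.fit_exposure_model(
            pl.ModelSpec(variant="ratio", x_terms=["elevation"],
                         z_terms=["temperature"]),
            pm25, ds.sites, ds.covariates, ds.region_map, pm10_model=m10)
        return ds, pm25, rtruth, m10, mr

    def test_outlier_removal_matches_contamination(self, ratio_setup):
        ds, pm25, rtruth, m10, mr = ratio_setup
        # the 1.5x rule should catch roughly the contaminated records
        assert mr.outliers_removed >= 0.5 * rtruth["contaminated"].sum()

    def test_seasonal_cadence_four_surfaces(self, ratio_setup):
        _, _, _, _, mr = ratio_setup
        for r, f1 in mr.stage1_fits.items():
            assert f1.seasonal
            assert len(f1.g_surfaces) <= 4

    def test_predicted_pm10_is_a_covariate(self, ratio_setup):
        _, _, _, _, mr = ratio_setup
        for f1 in mr.stage1_fits.values():
            assert "log_pm10_hat" in f1.f_smooths

    def test_ratio_predictions_reasonable(self, ratio_setup):
        ds, pm25, _, _, mr = ratio_setup
        pred = pl.predict(mr, ds.sites, list(range(1, 13)))
        merged = pm25.merge(pred, on=["site_id", "month"])
        r = np.corrcoef(merged["conc"], merged["mean"])[0, 1]
        assert r ** 2 > 0.3
        assert np.all(pred["lo95"] >= 0)


def test_noiseless_native_recovery():
    """With zero noise and no monthly spatial fields, native predictions
    match truth within 1%."""
    cfg = syn.PanelConfig(missing_rate=0.0, gt_amplitude=0.0,
                          season_amplitude=0.15)
    ds = syn.scenario_default(13, n_sites=130, n_regions=1, n_months=12,
                              config=cfg)
    # rebuild the panel without noise: log y = signal exactly
    sig = ds.truth.signal_table()
    rows = []
    for m in sig.columns:
        rows.append(pd.DataFrame({"site_id": sig.index, "month": int(m),
                                  "conc": np.exp(sig[m].to_numpy())}))
    panel = pd.concat(rows, ignore_index=True)
    model = pl.fit_exposure_model(
        pl.ModelSpec(x_terms=["elevation", "urban_1km", "log_pop_density"],
                     z_terms=["temperature", "wind_speed"]),
        panel, ds.sites, ds.covariates, ds.region_map)
    pred = pl.predict(model, ds.sites, list(sig.columns),
                      include_observation_var=False)
    merged = panel.merge(pred, on=["site_id", "month"])
    rel = np.abs(merged["mean"] - merged["conc"]) / merged["conc"]
    assert rel.max() < 0.01
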