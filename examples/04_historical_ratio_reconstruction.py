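"""Reconstruct PM2.5 from a PM10 model via the PM2.5:PM10 ratio, and form
the coarse fraction PM2.5-10.

For periods with sparse PM2.5 monitoring, PM2.5 is predicted as
(predicted ratio, truncated at 1) x (predicted PM10).  The ratio model fits
ln(PM2.5 / predicted PM10) with seasonal regional surfaces, a slow temporal
smooth h(t), and predicted PM10 itself as a covariate; records with
observed PM2.5 > 1.5 x predicted PM10 are deleted as outliers first.
Errors propagate on the native scale assuming independence.
"""
import numpy as np

from pmgamm import pipelines as pl
from pmgamm import synthetic as syn
from pmgamm import validation as val

ds = syn.scenario_default(seed=2, n_sites=100, n_months=24)
pm10_panel = ds.panel
pm25_panel, truth = syn.generate_ratio_panel(ds.sites, ds.covariates,
                                             pm10_panel, seed=7)

pm10_model = pl.fit_exposure_model(
    pl.ModelSpec(variant="pm10_direct"), pm10_panel, ds.sites,
    ds.covariates, ds.region_map)
ratio_model = pl.fit_exposure_model(
    pl.ModelSpec(variant="ratio", x_terms=["elevation"]),
    pm25_panel, ds.sites, ds.covariates, ds.region_map,
    pm10_model=pm10_model)

print(f"outliers removed by the 1.5x rule: {ratio_model.outliers_removed} "
      f"of {len(pm25_panel)} records "
      f"(generator contaminated {truth['contaminated'].sum()})")

months = np.arange(1, 25)
pm25_pred = pl.predict(ratio_model, ds.sites, months)
pm10_pred = pl.predict(pm10_model, ds.sites, months)

merged = pm25_panel.merge(pm25_pred, on=["site_id", "month"])
print(f"reconstructed PM2.5 vs observed: R2 = "
      f"{val.cv_r2(merged['conc'], merged['mean']):.3f}, "
      f"PI coverage = {val.pi_coverage(merged['conc'], merged['lo95'], merged['hi95']):.3f}")
print(f"predicted ratios truncated at 1: "
      f"{pm25_pred['ratio_truncated'].mean():.1%} of predictions")

k10 = pm10_pred.set_index(["site_id", "month"])
k25 = pm25_pred.set_index(["site_id", "month"])
coarse_mean, coarse_se, neg = pl.coarse_fraction(
    k10["mean"].to_numpy(), k10["se"].to_numpy(),
    k25.loc[k10.index, "mean"].to_numpy(),
    k25.loc[k10.index, "se"].to_numpy())
print(f"coarse fraction PM2.5-10: mean {coarse_mean.mean():.2f} ug/m3, "
      f"{neg.mean():.1%} nonpositive (flagged, excluded from validation)")
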