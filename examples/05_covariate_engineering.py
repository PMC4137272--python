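"""Build geographic covariates from point and grid inputs.

Shows the skew-reducing transforms (with metadata that reproduces the same
mapping at prediction time), the quadratic-kernel density of point sources,
distance-to-road truncation at 500 m, cardinal-cell raster smoothing, and
thin-plate smoothing of county-centroid values to arbitrary locations.
"""
import numpy as np

from pmgamm import covariates as cov

rng = np.random.default_rng(0)

# skewed emissions density -> log-shift transform anchored at the minimum
emissions = rng.lognormal(1.0, 1.5, 8)
z, meta = cov.log_shift_transform(emissions, shift=10.0)
print("emissions:", np.round(emissions, 1))
print("ln(z - min + 10):", np.round(z, 3))
print(f"stored for prediction time: min = {meta.train_min:.2f}, "
      f"shift = {meta.shift}")

# distance to road, truncated at 500 m (no near-road signal beyond that)
d = rng.exponential(800.0, 6)
print("\ndistances (m):", np.round(d, 0))
print("truncated:    ", cov.truncate_distance(d))

# quadratic-kernel density of two point sources, 10 km bandwidth
sources = [[0.0, 0.0], [5.0, 0.0]]
weights = [2.0, 1.0]
at = [[0.0, 0.0], [2.5, 0.0], [20.0, 0.0]]
dens = cov.quadratic_kernel_density(sources, weights, 10.0, at)
print("\nkernel density at 0, 2.5 and 20 km:", np.round(dens, 5))
print("(zero beyond the 10 km neighbourhood; integrates to total weight 3)")

# tract-density raster smoothing: each cell averaged with its 4 neighbours
grid = np.zeros((5, 5))
grid[2, 2] = 5.0
print("\ncardinal-cell average of a unit spike (centre row):")
print(cov.cardinal_cell_average(grid)[2])

# county population density smoothed from centroids to any location
centroids = rng.uniform(0, 500, (60, 2))
density = 100 + 0.3 * centroids[:, 0] + rng.normal(0, 10, 60)
surface = cov.smooth_point_values(centroids, density)
print("\nsmoothed county density at (100, 250) and (400, 250):",
      np.round(surface.predict([[100, 250], [400, 250]]), 1))
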