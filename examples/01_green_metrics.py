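"""Green-space exposure and inequality for one synthetic city.

Builds a single city raster (clustered population, thresholded green cover),
then computes the per-cell green coverage rate within a 500 m walking buffer,
the population-weighted exposure, and the population-weighted Gini index.
"""

import greenmobility as gm

config = gm.SyntheticConfig(grid_shape=(32, 32), seed=7)
raster = gm.generate_city_raster(config, "demo_city", seed=7)

coverage = gm.green_coverage_rate(raster, buffer_radius_m=500.0)
metrics = gm.compute_metrics(raster, buffer_radius_m=500.0)

print(f"city green share (cells):      {raster.green_fraction.mean():.3f}")
print(f"coverage rate range:           {coverage.min():.3f} .. {coverage.max():.3f}")
print(f"population-weighted exposure:  {metrics.exposure:.3f}")
print(f"green-space Gini index:        {metrics.gini:.3f}")

# Exposure is the coverage rate the average resident experiences; it exceeds
# the raw green share when people cluster near green areas (and vice versa).
# Gini 0 would mean every resident sees identical coverage; values near 1
# mean green access is concentrated on a small share of the population.
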