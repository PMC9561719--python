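# firerange

Quantifying wildfire impact on a tracked wildlife population from satellite
active-fire detections, a population-density surface and GPS telemetry.

The package was built for spatial ecologists studying how mega-fire seasons
affect large carnivores — the motivating system is the jaguar population of
the Pantanal wetland — but every stage is generic: any species with a
density map and tracking data, any fire season, any region/protected-area
geometry.

## What it computes

Everything reduces to mass-normalised raster overlays on one shared grid:

- **Fire rasters.** Satellite thermal-anomaly detections (FIRMS-style CSV)
  are filtered at a brightness-temperature threshold (default
  T_b > 325 K, strict) and binned into annual occurrence (0/1 per cell) and
  intensity (Kelvin) rasters.
- **Burned fraction of a region.** A region mask w is rescaled so
  Σw = 1; then Σ(w·occurrence) is the burned fraction.
- **Density-weighted exposure.** A density surface D (individuals per cell,
  converted from individuals/100 km²) gives the affected-proxy count
  Σ(D·occurrence) — a stand-in for individuals displaced, injured or
  killed — with annual series, per-region shares and *factor effects*
  (a year's value over the median of a reference window).
- **Movement models.** Each cleaned GPS track is fitted with a 2-D
  Ornstein–Uhlenbeck (OU) process by restricted maximum likelihood under
  the exact transition
  `x(t+Δ) = μ + e^(−Δ/τ)(x(t) − μ) + ε, ε ~ N(0, σ²(1 − e^(−2Δ/τ)))`,
  giving the home-range centre μ, spatial variance σ² (km² per axis) and
  crossing timescale τ (days).  The effective sample size
  DOF_area = span/τ and the semi-variogram asymptote classify residency
  (resident iff DOF_area > 5 or the variogram levels off).
- **Home ranges.** Resident tracks get an autocorrelation-aware kernel
  utilization distribution: Gaussian kernels with the effective-sample-size
  reference bandwidth h² = σ̂²·DOF_area^(−1/2) (variance-corrected so the
  smoothed distribution keeps variance σ̂²), discretized to a per-cell
  probability mass function with Σpmf = 1, plus the 95% highest-density
  region and its area.
- **Home-range burn statistics.** Σ(pmf·occurrence) is the fraction of a
  home range burned; Σ(pmf·pa·occurrence) the burned fraction of its
  protected share; cohort summaries count affected ranges and median burn
  extents.
- **Synthetic scenarios.** A seeded generator produces all four inputs
  (clustered fire seasons straddling the 325 K threshold, a smooth density
  surface with known abundance, OU tracks with known σ²/τ, block protected
  areas) with ground truth, including placement-controlled scenarios where
  fires cover a known fraction of each home range's mass.

## Worked example

Generate a small synthetic scenario and run the full pipeline on it:

```python
from firerange import *
from firerange.synthetic import ScenarioConfig, make_scenario

cfg = ScenarioConfig(seed=7, lon_min=-57.0, lat_min=-18.0, lon_max=-55.5,
                     lat_max=-16.5, resolution=0.01, n_protected_areas=3,
                     pa_size_range=(0.1, 0.2), n_individuals=3,
                     sampling_span_days=120.0, sampling_interval_days=0.25,
                     n_ignitions=80, detections_per_cluster=30, years=(2020,))
make_scenario(cfg, "demo")
spec = cfg.grid()

dets = filter_by_threshold(read_detections("demo/fires_2020.csv"))  # T_b > 325 K
fy = build_fire_year(dets, spec, 2020)
region = rasterize_polygons(read_polygons_geojson("demo/region.geojson"), spec)
density = density_from_per100km2(read_raster("demo/density_per100km2.tif"))

affected, total = exposed_count(density, fy, region)
print(f"burned fraction of region: {exposed_fraction(region, fy):.3f}")
print(f"individuals affected: {affected:.0f} of {total:.0f} ({100*affected/total:.1f}%)")

for ident, raw in read_tracks("demo/tracks.csv").items():
    track = clean_track(raw, ident)
    fit = fit_ou(track)
    status = classify_residency(fit, empirical_variogram(track))
    hr = estimate_pmf(track, fit, spec, residency=status)
    rec = hr_burn(hr, fy)
    print(f"{ident}: sigma2={fit.sigma2:5.1f} km2  tau={fit.tau_days:4.1f} d  "
          f"DOF={fit.dof_area:5.1f}  {status.verdict}  HR95={hr.area_km2:6.1f} km2  "
          f"burn={rec.burn_fraction:.2f}")
```

Output:

```
burned fraction of region: 0.071
individuals affected: 124 of 1668 (7.5%)
ind000: sigma2=  7.2 km2  tau=11.4 d  DOF= 10.5  resident  HR95= 120.4 km2  burn=0.15
ind001: sigma2= 16.2 km2  tau= 7.6 d  DOF= 15.7  resident  HR95= 253.9 km2  burn=0.00
ind002: sigma2= 11.2 km2  tau= 5.2 d  DOF= 22.9  resident  HR95= 178.3 km2  burn=0.00
```

Reading: 7.1% of the region's cells burned that year, reaching cells that
hold an expected 124 of the 1668 simulated individuals (7.5% — higher than
the areal fraction because fires and animals both concentrate).  All three
tracked individuals are range-resident (DOF_area ≫ 5) with 95% home ranges
of 120–254 km²; fire overlapped 15% of the first animal's utilization
distribution and missed the other two.

The same steps are exposed as a CLI: `firerange simulate`,
`firerange exposure`, `firerange homerange`, `firerange hr-burn`
(see `firerange --help`).

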