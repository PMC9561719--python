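# Methods

## The overlay model

All impact statistics are expectations of indicator or density layers under
a probability mass on a shared regular lon/lat grid.  Write `occ_y` for the
year-y fire occurrence raster (0/1), `m` for a region mask, `D` for the
density surface (expected individuals per cell) and `p` for an individual's
utilization pmf (Σp = 1).  Then

- burned fraction of a region: `Σ(normalize(m)·occ_y)`,
- affected-proxy count: `Σ(D·m·occ_y)` out of `Σ(D·m)`,
- protected-area burn fraction: `Σ(pa·m·occ_y) / Σ(pa·m)`,
- home-range burn fraction: `Σ(p·occ_y)`,
- protected burn within a home range: `Σ(p·pa·occ_y)`.

Because every statistic is a plain cellwise product and sum, correctness is
checked against per-cell loop oracles, and additivity over any partition of
a region into sub-regions holds to floating tolerance.  Layers must share
one declared grid (origin, resolution, shape); nothing is reprojected
silently — resampling is an explicit operation with a declared method
(`nearest` for categorical layers, overlap-weighted mean for continuous
ones).

Cells carry a constant nominal area (default 1 km²) rather than a
latitude-dependent one, reproducing pixel-counting arithmetic on ~1-km
products; exact spherical per-cell areas are available
(`latitude_corrected_cell_areas`) where the approximation matters.  At the
study system's latitudes (~16–22°S) the constant-area error across the
region is below 3%.

## Fire ingest

Detections are FIRMS-style rows (lon, lat, date, brightness T_b in Kelvin).
A detection is a fire occurrence iff T_b is *strictly* above the threshold
(default 325 K); the tie rule is explicit and configurable.  Annual rasters
use calendar years; a cell's intensity aggregates its detections'
brightnesses with `max` by default (keeps the strongest thermal signal) or
`mean`.  Detections bin by cell-centre containment of their point
coordinate — the source product is already ~1-km gridded, so no footprint
spreading is applied.

## Movement model

Positions of a range-resident animal are modelled as a two-dimensional
isotropic Ornstein–Uhlenbeck process: attraction to a centre μ, stationary
variance σ² per axis (km²), autocorrelation timescale τ (days).  The exact
discrete transition handles irregular sampling with no interpolation:

    x(t+Δ) = μ + e^(−Δ/τ) (x(t) − μ) + ε,   ε ~ N(0, σ²(1 − e^(−2Δ/τ))).

Fitting profiles the likelihood over log τ with closed-form μ̂ and σ̂² at
each τ; the first fix enters with its stationary distribution.  The
default criterion is *restricted* likelihood (REML): plugging in μ̂ biases
σ̂² and τ̂ downward by roughly a factor (1 − O(τ/span)) on strongly
autocorrelated tracks, and integrating μ out removes that bias (verified
on simulations: ML means σ̂² ≈ 3.6, τ̂ ≈ 9.0 against truth 4 and 10 at
span = 30τ; REML ≈ 4.0 and 9.6–10.1).  Likelihood-ratio confidence
intervals come from scanning the profile until it drops χ²₁(0.95)/2.

At span 30τ the intrinsic sampling noise of τ̂ and σ̂² has a relative SD
near √(2/DOF) ≈ 26%, so median absolute relative errors over replicate
tracks concentrate around 10–15%; that is the efficiency limit of the
model, not an implementation defect.

Fits are flagged when τ̂ falls below half the shortest sampling interval
(white-noise limit: autocorrelation unresolvable) or reaches the upper
optimizer bound at 100× the span (drift/dispersal limit).

Coordinates are converted once per individual from lon/lat to a local
azimuthal-equidistant frame (km) centred on the track mean; the conversion
is explicit and invertible.

## Residency

An individual is classified resident iff either

1. DOF_area = span/τ̂ > 5 (at least five home-range crossings observed,
   and the fit is not flagged), or
2. its empirical semi-variogram has "obtained an asymptote".

The semi-variogram is γ(ℓ) = mean‖Δr‖²/(2·dims) over displacement pairs in
each time-lag bin; for a resident OU track γ(ℓ) = σ²(1 − e^(−ℓ/τ)) → σ².
The asymptote test fits that saturating form to the binned variogram
(pair-count weighted) and declares an asymptote when the fitted range t̂
is below max-lag/6, i.e. the curve is ≥95% saturated by half the maximum
lag.  A windowed-slope rule was evaluated first and discarded: over the
final third of lags the log-lag window spans only ~0.2 decades, so
per-decade slope estimates on true resident tracks are noise-dominated
(relative slopes of 0.2–2.6 observed on 40τ-span OU simulations); the
saturating-fit rule separates resident from near-Brownian tracks cleanly.
The expert judgement "inhabited the range during monitoring" cannot be
automated and is exposed as a manual override flag.

## Home-range estimation

The utilization distribution of a resident track is a Gaussian kernel
density on the analysis grid whose bandwidth uses the *effective* sample
size from the movement fit instead of the raw fix count — the defining
idea of autocorrelated kernel density estimation:

    h² = σ̂² · DOF_area^(−2/(d+2)),   d = 2.

Smoothing with h alone would estimate a distribution of variance σ̂² + h²
(a (1 + DOF^(−1/2)) inflation: +14% area at DOF 50), so relocations are
first shrunk about their mean by √(1 − h²/σ̂²) — the classical
variance-corrected KDE — keeping the estimate's variance at σ̂².  With the
correction, the 95% highest-density region of a long OU track converges on
the Gaussian closed form π·χ²₂(0.95)·σ² = 5.991π·σ² (≈3–5% at
DOF ≈ 1000 in the acceptance runs, dominated by σ̂² sampling noise).

Per-cell mass is exact (products of per-axis Gaussian CDF differences over
cell edges, averaged over relocations), truncated below 1e-12 per cell and
renormalized to exactly 1.  The highest-density region at level L is the
smallest cell set holding ≥ L of the mass (descending-mass order, ties
broken by stable row-major order); "home-range area" is the 95% HDR area
by default (the contour level is configurable).  Burned extent in km² is
burn fraction × HDR95 area; an alternative (burned HDR cells × cell area)
is easy to derive from the returned masks.  Mean fire intensity within a
home range is pmf-weighted over burned cells by default (unweighted
available).  The same home range is reused across all fire years,
mirroring the study design in which tracking (2005–2016) and fire seasons
(2005–2020) only partially overlap; restricting to the monitoring period
is a matter of passing only those fire years.

## Exposure summaries

The annual exposure table carries, per (year, region): affected proxy,
total proxy, percent affected, burned fraction and mean intensity.  Factor
effects divide a year's value by the reference-window median (midpoint
rule for even counts; window configurable, default the fifteen years
preceding the focal year).  Reporting conventions follow the field's
tables: proxy counts to the nearest individual, shares to the nearest
integer percent (rounded after summation), factor effects to one decimal;
full precision is kept internally.  Undefined quantities (no burned cells,
zero median, no protected cells) are NaN, never silently 0.

## Synthetic scenarios

The generator emulates the study system at its published scale: a
~200,000-cell grid at ~1-km resolution over a Pantanal-sized box, an
octagonal ecoregion, a Gaussian-smoothed log-positive density field scaled
to 1668 individuals, 48 resident individuals on a 6-hourly schedule with
σ² ∈ [3, 20] km² and τ ∈ [2, 10] d (95% ranges of roughly 55–375 km²),
non-overlapping rectangular protected areas, and fire seasons of clustered
detections whose dates concentrate on a mid-September dry-season peak and
whose brightness is 300 K + Gamma(2, θ) with θ solved so a configured
share (default 30%) falls below the 325 K threshold.  One global seed
expands into per-component sub-seeds via `SeedSequence` spawn keys, so
adding a component never reshuffles another; identical configs produce
byte-identical bundles (checksummed in a MANIFEST).  Bundles are written
in the same public formats the real pipeline reads (FIRMS-style CSV, TIFF
density with JSON sidecar, GeoJSON polygons, Movebank-style track CSV), so
the synthetic path exercises the production readers.

Placement-controlled scenarios visit each individual's true (stationary
Gaussian) pmf support in a seeded random order and accumulate cells until
a target mass q is reached: the achieved mass differs from q by at most
one cell's mass, and because selection is independent of cell mass the
*estimated* burn fraction is an unbiased probe of the whole
track→fit→pmf→overlay chain.

What the generator does not emulate: fire spread/contagion (detections are
i.i.d. around ignition points), cloud and smoke obscuration, detection
confidence structure, landscape covariates of density, habitat selection
within home ranges, and OU-velocity (OUF) autocorrelation.  Passing tests
therefore validate the estimation and overlay machinery under the stated
model, not the remote-sensing error budget of real fire products.

## Problem sizes and tolerances

Test and acceptance runs use deliberately modest problem sizes chosen to
leave estimator behaviour visible: 50 replicate tracks of n = 2001 fixes
(span 30τ) for parameter recovery; one n = 20001 track (DOF ≈ 1000) for
the Gaussian-limit check; a 500×500-cell grid with 20 separated home
ranges for the end-to-end scenario.  Floating tolerances: weight/pmf
normalization and overlay oracles at 1e-9 (compensated summation via
`math.fsum`); partition additivity at 1e-6; parameter recovery at the
15%-median level and the HDR limit at 10%, both reflecting intrinsic
sampling noise at the stated design.

## Known limitations

- The OU model has no velocity autocorrelation; for tracks sampled much
  faster than the velocity timescale, σ̂² remains consistent but DOF_area
  is optimistic.
- DOF_area = span/τ̂ is the simplest crossing-count estimator; reference
  implementations use a refined spectral version that differs by O(1)
  factors on short tracks.
- The density product is treated as exact; no uncertainty propagates from
  it into the affected-proxy counts.
- Equal cell areas are an approximation in geographic coordinates (see
  above); supply an equal-area grid or the per-cell correction when
  totals over large latitude spans matter.
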