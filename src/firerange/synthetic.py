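"""Seeded synthetic scenarios with known ground truth.

Generates the four inputs the pipeline consumes — clustered active-fire
detection tables, a smooth animal-density surface with a known total
abundance, OU tracks with known home-range parameters, and block-shaped
protected areas inside an ecoregion polygon — together with the quantities
a brute-force oracle can recompute from the generated layers (burned cells,
per-region burned fractions, per-individual OU parameters).

Defaults emulate the Pantanal study system: a ~160,000-cell 1-km-scale
grid, a jaguar-density surface integrating to 1668 individuals, 48 resident
individuals on a 6-hourly GPS schedule, and fire seasons concentrated in
the dry months with a brightness distribution straddling the 325 K
detection threshold.

One global seed expands into per-component sub-seeds through
``numpy.random.SeedSequence`` spawn keys, so adding a component never
reshuffles the draws of another.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import Polygon, box as shapely_box

from .exposure import DensitySurface
from .fires import DEFAULT_BRIGHTNESS_THRESHOLD_K
from .grid import (
    GridRaster,
    GridSpec,
    KM_PER_DEGREE,
    make_grid,
    rasterize_polygons,
    write_polygons_geojson,
    write_raster,
)
from .movement import Track, local_km_to_lonlat

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "simulate_landscape",
    "simulate_fire_season",
    "simulate_ou_tracks",
    "make_scenario",
    "stationary_pmf",
]

# spawn-key roots: one per generator component
_KEY_LANDSCAPE = 0
_KEY_FIRE = 1
_KEY_TRACKS = 2
_KEY_PLACEMENT = 3


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of a synthetic scenario; the defaults are the study system."""

    seed: int = 0
    # grid: ~1.1-km cells over a Pantanal-sized box -> 500 x 400 = 200k cells
    lon_min: float = -59.0
    lat_min: float = -21.0
    lon_max: float = -55.0
    lat_max: float = -16.0
    resolution: float = 0.01
    cell_area: float | None = None  # None: spherical cell area at mid-latitude
    # landscape
    region_corner_cut: float = 0.3  # degrees chamfered off the box corners
    n_protected_areas: int = 8
    pa_size_range: tuple[float, float] = (0.15, 0.45)  # degrees
    total_abundance: float = 1668.0
    density_correlation_km: float = 30.0
    # movement
    n_individuals: int = 48
    centre_min_separation_km: float = 0.0  # >0 keeps home ranges disjoint
    sigma2_range_km2: tuple[float, float] = (3.0, 20.0)
    tau_range_days: tuple[float, float] = (2.0, 10.0)
    sampling_interval_days: float = 0.25
    sampling_span_days: float = 365.0
    track_start: str = "2015-01-01T00:00:00"
    # fire season
    years: tuple[int, ...] = (2020,)
    n_ignitions: int = 150
    cluster_spread_km: float = 5.0
    detections_per_cluster: int = 40
    season_peak_doy: float = 255.0  # mid-September dry-season peak
    season_sd_days: float = 30.0
    brightness_shape: float = 2.0
    subthreshold_share: float = 0.3  # share of detections below 325 K
    # placement-controlled scenarios: fires cover exactly this pmf mass per HR
    target_burn_fraction: float | None = None

    def grid(self) -> GridSpec:
        cell_area = self.cell_area
        if cell_area is None:
            lat_mid = math.radians(0.5 * (self.lat_min + self.lat_max))
            cell_area = (KM_PER_DEGREE * self.resolution) ** 2 * math.cos(lat_mid)
        return make_grid(
            (self.lon_min, self.lat_min, self.lon_max, self.lat_max),
            self.resolution,
            cell_area,
        )

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=tuple(key)))


@dataclass
class GroundTruth:
    """Oracle values recomputable from the generated layers."""

    density_total: float = 0.0
    pa_extent_km2: float = 0.0
    region_cells: int = 0
    burned_cells: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    region_burned_fraction: dict[int, float] = field(default_factory=dict)
    abundance_burned_fraction: dict[int, float] = field(default_factory=dict)
    hr_centre_lonlat: dict[str, tuple[float, float]] = field(default_factory=dict)
    hr_sigma2_km2: dict[str, float] = field(default_factory=dict)
    hr_tau_days: dict[str, float] = field(default_factory=dict)
    hr_burn_mass: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        doc = asdict(self)
        doc["burned_cells"] = {str(y): cells for y, cells in self.burned_cells.items()}
        doc["region_burned_fraction"] = {str(y): v for y, v in self.region_burned_fraction.items()}
        doc["abundance_burned_fraction"] = {str(y): v for y, v in self.abundance_burned_fraction.items()}
        return json.dumps(doc, sort_keys=True)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _region_polygon(cfg: ScenarioConfig) -> Polygon:
    """Octagonal ecoregion: the bounding box with chamfered corners."""
    cut = cfg.region_corner_cut
    x0, y0, x1, y1 = cfg.lon_min, cfg.lat_min, cfg.lon_max, cfg.lat_max
    return Polygon(
        [
            (x0 + cut, y0), (x1 - cut, y0), (x1, y0 + cut), (x1, y1 - cut),
            (x1 - cut, y1), (x0 + cut, y1), (x0, y1 - cut), (x0, y0 + cut),
        ]
    )


def simulate_landscape(
    cfg: ScenarioConfig,
) -> tuple[GridRaster, Polygon, list[Polygon], DensitySurface, GroundTruth]:
    """Region mask, PA polygons, density surface and the partial ground truth.

    The density surface is a Gaussian-smoothed positive random field inside
    the region, rescaled so its cells sum exactly to the configured total
    abundance.  Protected areas are non-overlapping axis-aligned rectangles.
    """
    rng = cfg.rng(_KEY_LANDSCAPE)
    spec = cfg.grid()
    region = _region_polygon(cfg)
    mask = rasterize_polygons([region], spec)
    if not mask.values.any():
        raise ValueError("region polygon rasterized to an empty mask")

    # smoothed log-normal-ish field, strictly positive inside the region
    sigma_cells = cfg.density_correlation_km / (KM_PER_DEGREE * cfg.resolution)
    noise = rng.standard_normal(spec.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=max(sigma_cells, 1e-9), mode="reflect")
    fld = np.exp(smooth / max(smooth.std(), 1e-12)) * mask.values
    total = fld.sum()
    if total <= 0:
        raise ValueError("density field degenerated to zero")
    density_vals = fld * (cfg.total_abundance / total)
    density = DensitySurface(GridRaster(spec, density_vals, "density"))

    # non-overlapping rectangular protected areas inside the region
    pas: list[Polygon] = []
    attempts = 0
    while len(pas) < cfg.n_protected_areas and attempts < 200 * max(cfg.n_protected_areas, 1):
        attempts += 1
        w = rng.uniform(*cfg.pa_size_range)
        h = rng.uniform(*cfg.pa_size_range)
        x = rng.uniform(cfg.lon_min, cfg.lon_max - w)
        y = rng.uniform(cfg.lat_min, cfg.lat_max - h)
        cand = shapely_box(x, y, x + w, y + h)
        if not region.contains(cand):
            continue
        if any(cand.intersects(p) for p in pas):
            continue
        pas.append(cand)
    if len(pas) < cfg.n_protected_areas:
        raise ValueError("could not place the requested protected areas inside the region")

    pa_mask = rasterize_polygons(pas, spec)
    truth = GroundTruth(
        density_total=float(density_vals.sum()),
        pa_extent_km2=float(pa_mask.values.sum()) * spec.cell_area,
        region_cells=int(mask.values.sum()),
    )
    return mask, region, pas, density, truth


# ---------------------------------------------------------------------------
# fire seasons
# ---------------------------------------------------------------------------

def _brightness_scale(cfg: ScenarioConfig) -> float:
    """Gamma scale such that the configured share falls below the threshold."""
    margin = DEFAULT_BRIGHTNESS_THRESHOLD_K - 300.0
    if cfg.subthreshold_share <= 0:
        # push essentially all mass above the threshold
        return margin / stats.gamma.ppf(1e-9, cfg.brightness_shape)
    return margin / stats.gamma.ppf(cfg.subthreshold_share, cfg.brightness_shape)


def simulate_fire_season(
    cfg: ScenarioConfig,
    year: int,
    region: Polygon | None = None,
) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """One year of clustered detections and the oracle burned-cell list.

    Ignition centres fall uniformly in the region; detections scatter
    around them with a Gaussian spread, dates concentrate on the dry-season
    peak, and brightness is 300 K plus a Gamma draw whose scale puts the
    configured share below the 325 K threshold.  The burned-cell oracle is
    the set of grid cells holding at least one supra-threshold detection.
    """
    rng = cfg.rng(_KEY_FIRE, year)
    spec = cfg.grid()
    region = region if region is not None else _region_polygon(cfg)
    lon_min, lat_min, lon_max, lat_max = region.bounds
    lat_mid = 0.5 * (lat_min + lat_max)
    rows = []
    import shapely

    for _ in range(cfg.n_ignitions):
        while True:
            clon = rng.uniform(lon_min, lon_max)
            clat = rng.uniform(lat_min, lat_max)
            if shapely.contains_xy(region, clon, clat):
                break
        n_det = cfg.detections_per_cluster
        spread_lat = cfg.cluster_spread_km / KM_PER_DEGREE
        spread_lon = spread_lat / math.cos(math.radians(lat_mid))
        det_lon = clon + rng.normal(0.0, spread_lon, n_det)
        det_lat = clat + rng.normal(0.0, spread_lat, n_det)
        doy = np.clip(
            np.rint(rng.normal(cfg.season_peak_doy, cfg.season_sd_days, n_det)), 1, 365
        ).astype(int)
        brightness = 300.0 + rng.gamma(cfg.brightness_shape, _brightness_scale(cfg), n_det)
        for lo, la, d, b in zip(det_lon, det_lat, doy, brightness):
            ts = datetime(year, 1, 1) + timedelta(days=int(d) - 1)
            rows.append(
                {
                    "latitude": round(float(la), 6),
                    "longitude": round(float(lo), 6),
                    "acq_date": ts.strftime("%Y-%m-%d"),
                    "brightness": round(float(b), 2),
                    "confidence": int(rng.integers(30, 101)),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["latitude", "longitude", "acq_date", "brightness", "confidence"]
    )
    burned: set[tuple[int, int]] = set()
    if not frame.empty:
        hot = frame[frame.brightness > DEFAULT_BRIGHTNESS_THRESHOLD_K]
        r, c, inside = spec.cells_of(hot.longitude.to_numpy(), hot.latitude.to_numpy())
        burned = set(zip(r[inside].tolist(), c[inside].tolist()))
    return frame, sorted(burned)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def _simulate_ou_path(
    rng: np.random.Generator,
    n: int,
    dt: float,
    sigma2: float,
    tau: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact-discretization stationary OU sample path (2-D, centred on 0)."""
    rho = math.exp(-dt / tau)
    innov_sd = math.sqrt(sigma2 * (1.0 - rho * rho))
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = rng.normal(0.0, math.sqrt(sigma2), 2)
    ex = rng.normal(0.0, innov_sd, n - 1)
    ey = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + ex[i - 1]
        y[i] = rho * y[i - 1] + ey[i - 1]
    return x, y


def simulate_ou_tracks(
    cfg: ScenarioConfig,
    region: Polygon | None = None,
) -> tuple[list[Track], GroundTruth]:
    """Resident OU tracks with known parameters, centres inside the region.

    Each individual gets its own sub-seed, σ² and τ drawn from the
    configured ranges, and an exact-transition OU path on the regular
    sampling schedule; lon/lat are recovered through the inverse local
    projection so the tracks exercise the real readers downstream.
    """
    region = region if region is not None else _region_polygon(cfg)
    lon_min, lat_min, lon_max, lat_max = region.bounds
    import shapely

    truth = GroundTruth()
    tracks: list[Track] = []
    centres: list[tuple[float, float]] = []
    lat_mid = 0.5 * (lat_min + lat_max)
    min_sep_deg = cfg.centre_min_separation_km / KM_PER_DEGREE
    n_steps = int(round(cfg.sampling_span_days / cfg.sampling_interval_days)) + 1
    for k in range(cfg.n_individuals):
        rng = cfg.rng(_KEY_TRACKS, k)
        # keep centres away from the border so HRs stay inside the region
        for _ in range(10000):
            lon0 = rng.uniform(lon_min + 0.2, lon_max - 0.2)
            lat0 = rng.uniform(lat_min + 0.2, lat_max - 0.2)
            if not shapely.contains_xy(region, lon0, lat0):
                continue
            if min_sep_deg > 0 and any(
                math.hypot((lon0 - lo) * math.cos(math.radians(lat_mid)), lat0 - la)
                < min_sep_deg
                for lo, la in centres
            ):
                continue
            break
        else:
            raise ValueError("could not place home-range centres with the requested separation")
        centres.append((lon0, lat0))
        sigma2 = rng.uniform(*cfg.sigma2_range_km2)
        tau = rng.uniform(*cfg.tau_range_days)
        x, y = _simulate_ou_path(rng, n_steps, cfg.sampling_interval_days, sigma2, tau)
        times = np.arange(n_steps) * cfg.sampling_interval_days
        lons, lats = local_km_to_lonlat(x, y, lon0, lat0)
        ident = f"ind{k:03d}"
        tracks.append(
            Track(ident, times, x, y, lon0, lat0, lons=lons, lats=lats)
        )
        truth.hr_centre_lonlat[ident] = (lon0, lat0)
        truth.hr_sigma2_km2[ident] = sigma2
        truth.hr_tau_days[ident] = tau
    return tracks, truth


def tracks_to_frame(tracks: Sequence[Track], start: str) -> pd.DataFrame:
    """Movebank-style relocation table for a set of tracks."""
    t0 = pd.Timestamp(start)
    rows = []
    for tr in tracks:
        stamps = t0 + pd.to_timedelta(tr.times, unit="D")
        for ts, lo, la in zip(stamps, tr.lons, tr.lats):
            rows.append(
                {
                    "individual-local-identifier": tr.individual,
                    "timestamp": ts.strftime("%Y-%m-%d %H:%M:%S"),
                    "location-long": round(float(lo), 7),
                    "location-lat": round(float(la), 7),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# placement-controlled fires and ground-truth pmfs
# ---------------------------------------------------------------------------

def stationary_pmf(
    spec: GridSpec,
    lon0: float,
    lat0: float,
    sigma2: float,
) -> np.ndarray:
    """Discretized stationary OU (isotropic Gaussian) pmf on a grid.

    The oracle utilization distribution: per-cell mass from separable
    Gaussian CDF differences around (lon0, lat0) with SD √σ² km per axis,
    normalized over the grid.
    """
    from scipy.special import ndtr

    sd_lat = math.sqrt(sigma2) / KM_PER_DEGREE
    sd_lon = sd_lat / math.cos(math.radians(lat0))
    lat_e = spec.lat_edges()
    lon_e = spec.lon_edges()
    a = ndtr((lat_e[:-1] - lat0) / sd_lat) - ndtr((lat_e[1:] - lat0) / sd_lat)
    b = ndtr((lon_e[1:] - lon0) / sd_lon) - ndtr((lon_e[:-1] - lon0) / sd_lon)
    pmf = np.outer(a, b)
    total = pmf.sum()
    if total <= 0:
        raise ValueError("stationary pmf has no mass on the grid")
    return pmf / total


def placement_controlled_detections(
    cfg: ScenarioConfig,
    truth: GroundTruth,
    year: int,
) -> tuple[pd.DataFrame, list[tuple[int, int]], dict[str, float]]:
    """Fires covering cells that hold ≈ the target mass of each true HR.

    Support cells of each individual's oracle pmf are visited in a seeded
    random order and accumulated until the target mass is reached, so the
    achieved mass differs from the target by at most one cell's mass and the
    selection is unbiased with respect to cell mass.  One supra-threshold
    detection is emitted at each selected cell centre.
    """
    q = cfg.target_burn_fraction
    if q is None:
        raise ValueError("config has no target_burn_fraction")
    spec = cfg.grid()
    rng = cfg.rng(_KEY_PLACEMENT, year)
    lons_c, lats_c = spec.cell_centers()
    burned: set[tuple[int, int]] = set()
    achieved: dict[str, float] = {}
    for ident in sorted(truth.hr_sigma2_km2):
        lon0, lat0 = truth.hr_centre_lonlat[ident]
        pmf = stationary_pmf(spec, lon0, lat0, truth.hr_sigma2_km2[ident])
        rr, cc = np.nonzero(pmf > 1e-10)
        order = rng.permutation(len(rr))
        mass = 0.0
        for j in order:
            if mass >= q:
                break
            cell = (int(rr[j]), int(cc[j]))
            mass += float(pmf[cell])
            burned.add(cell)
        achieved[ident] = mass
    rows = []
    day = datetime(year, 9, 15)
    for r, c in sorted(burned):
        rows.append(
            {
                "latitude": round(float(lats_c[r]), 6),
                "longitude": round(float(lons_c[c]), 6),
                "acq_date": day.strftime("%Y-%m-%d"),
                "brightness": 352.3,
                "confidence": 90,
            }
        )
    return pd.DataFrame(rows), sorted(burned), achieved


# ---------------------------------------------------------------------------
# full bundles
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_scenario(cfg: ScenarioConfig, out_dir: str | Path, force: bool = False) -> GroundTruth:
    """Generate and persist a complete scenario bundle.

    Layout: ``region.geojson``, ``protected_areas.geojson``,
    ``density_per100km2.tif`` (+ ``.json`` sidecar, original per-100-km²
    units), ``fires_<year>.csv`` per year, ``tracks.csv``,
    ``ground_truth.json`` and a ``MANIFEST.json`` with the seed and SHA-256
    checksums of every file.  Refuses a non-empty directory unless forced.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    spec = cfg.grid()
    mask, region, pas, density, truth = simulate_landscape(cfg)
    tracks, track_truth = simulate_ou_tracks(cfg, region)
    truth.hr_centre_lonlat = track_truth.hr_centre_lonlat
    truth.hr_sigma2_km2 = track_truth.hr_sigma2_km2
    truth.hr_tau_days = track_truth.hr_tau_days

    write_polygons_geojson(out / "region.geojson", [region], [{"name": "ecoregion"}])
    write_polygons_geojson(
        out / "protected_areas.geojson", pas, [{"name": f"pa{i}"} for i in range(len(pas))]
    )
    # persist in the source product's original units (individuals / 100 km²)
    per100 = GridRaster(
        spec, density.raster.values * (100.0 / spec.cell_area), "generic"
    )
    write_raster(out / "density_per100km2.tif", per100)

    for year in cfg.years:
        if cfg.target_burn_fraction is not None:
            dets, burned, achieved = placement_controlled_detections(cfg, truth, year)
            truth.hr_burn_mass = achieved
        else:
            dets, burned = simulate_fire_season(cfg, year, region)
        dets.to_csv(out / f"fires_{year}.csv", index=False)
        truth.burned_cells[year] = [list(c) for c in burned]
        occ = np.zeros(spec.shape)
        for r, c in burned:
            occ[r, c] = 1.0
        in_region = mask.values > 0
        truth.region_burned_fraction[year] = float(
            occ[in_region].sum() / in_region.sum()
        )
        dens = density.raster.values
        truth.abundance_burned_fraction[year] = float(
            (dens * occ).sum() / dens.sum()
        )

    tracks_to_frame(tracks, cfg.track_start).to_csv(out / "tracks.csv", index=False)
    (out / "ground_truth.json").write_text(truth.to_json())

    files = sorted(p for p in out.iterdir() if p.name != "MANIFEST.json")
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "checksums": {p.name: _sha256(p) for p in files},
    }
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return truth
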