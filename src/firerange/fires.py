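"""Active-fire detection ingest and annual fire rasters.

Satellite thermal-anomaly products deliver point detections with a brightness
temperature in Kelvin.  Following the convention of the 1-km MODIS product,
a detection counts as a fire only when its brightness exceeds a threshold
(default 325 K, strict inequality); the surviving detections are binned into
annual occurrence (0/1 per cell) and intensity (Kelvin per burned cell)
rasters on the shared analysis grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import AlignmentError, GridRaster, GridSpec

__all__ = [
    "FireDetection",
    "FireYearRaster",
    "DEFAULT_BRIGHTNESS_THRESHOLD_K",
    "read_detections",
    "filter_by_threshold",
    "build_fire_year",
    "daily_profile",
    "intensity_stats",
]

logger = logging.getLogger(__name__)

DEFAULT_BRIGHTNESS_THRESHOLD_K = 325.0

#: FIRMS CSV dialect defaults; override via ``column_map`` in read_detections.
DEFAULT_COLUMNS = {
    "lon": "longitude",
    "lat": "latitude",
    "date": "acq_date",
    "brightness": "brightness",
    "confidence": "confidence",
}


@dataclass(frozen=True)
class FireDetection:
    """One satellite active-fire record."""

    lon: float
    lat: float
    timestamp: datetime
    brightness: float  # Kelvin
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.brightness > 0):
            raise ValueError("brightness must be positive Kelvin")
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(f"coordinates out of range: ({self.lon}, {self.lat})")


@dataclass
class FireYearRaster:
    """Occurrence and intensity of fire for one calendar year on one grid."""

    year: int
    occurrence: GridRaster
    intensity: GridRaster
    n_detections_used: int
    aggregation: Literal["max", "mean"] = "max"
    threshold_K: float = DEFAULT_BRIGHTNESS_THRESHOLD_K

    def __post_init__(self) -> None:
        if not self.occurrence.spec.compatible_with(self.intensity.spec):
            raise AlignmentError("occurrence and intensity must share one grid")


def read_detections(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[FireDetection]:
    """Parse a FIRMS-style CSV into detections.

    Rows with an unparseable coordinate, date or brightness are skipped and
    counted (logged at WARNING level); a missing mandatory column raises.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    frame = pd.read_csv(path)
    for key in ("lon", "lat", "date", "brightness"):
        if cols[key] not in frame.columns:
            raise ValueError(f"missing mandatory column {cols[key]!r} in {path}")
    lon = pd.to_numeric(frame[cols["lon"]], errors="coerce")
    lat = pd.to_numeric(frame[cols["lat"]], errors="coerce")
    bright = pd.to_numeric(frame[cols["brightness"]], errors="coerce")
    when = pd.to_datetime(frame[cols["date"]], errors="coerce", format="mixed")
    conf = None
    if cols.get("confidence") in frame.columns:
        conf = pd.to_numeric(frame[cols["confidence"]], errors="coerce")

    ok = (
        lon.notna() & lat.notna() & bright.notna() & when.notna()
        & (bright > 0) & lon.between(-180, 180) & lat.between(-90, 90)
    )
    n_skipped = int((~ok).sum())
    if n_skipped:
        for idx in frame.index[~ok]:
            logger.warning("skipping unparseable detection row %d in %s", idx, path)
    dets = [
        FireDetection(
            float(lon[i]), float(lat[i]), when[i].to_pydatetime(), float(bright[i]),
            None if conf is None or pd.isna(conf[i]) else float(conf[i]),
        )
        for i in frame.index[ok]
    ]
    return dets


def filter_by_threshold(
    detections: Iterable[FireDetection],
    threshold_K: float = DEFAULT_BRIGHTNESS_THRESHOLD_K,
) -> list[FireDetection]:
    """Keep detections whose brightness is strictly above the threshold."""
    if threshold_K <= 0:
        raise ValueError("threshold must be positive Kelvin")
    return [d for d in detections if d.brightness > threshold_K]


def build_fire_year(
    detections: Iterable[FireDetection],
    spec: GridSpec,
    year: int,
    aggregation: Literal["max", "mean"] = "max",
    threshold_K: float = DEFAULT_BRIGHTNESS_THRESHOLD_K,
) -> FireYearRaster:
    """Annual occurrence/intensity rasters from (pre-thresholded) detections.

    A cell is a fire occurrence when at least one detection dated inside the
    calendar year falls in it; the cell intensity aggregates that cell-year's
    brightnesses (``max`` keeps the strongest signal, ``mean`` averages).
    """
    if aggregation not in ("max", "mean"):
        raise ValueError("aggregation must be 'max' or 'mean'")
    occ = np.zeros(spec.shape)
    agg = np.zeros(spec.shape)
    count = np.zeros(spec.shape)
    n_used = 0
    for det in detections:
        if det.timestamp.year != year:
            continue
        cell = spec.cell_of(det.lon, det.lat)
        if cell is None:
            continue
        n_used += 1
        occ[cell] = 1.0
        if aggregation == "max":
            agg[cell] = max(agg[cell], det.brightness)
        else:
            agg[cell] += det.brightness
        count[cell] += 1
    if aggregation == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            agg = np.where(count > 0, agg / np.maximum(count, 1), 0.0)
    return FireYearRaster(
        year=year,
        occurrence=GridRaster(spec, occ, "occurrence"),
        intensity=GridRaster(spec, agg, "intensity"),
        n_detections_used=n_used,
        aggregation=aggregation,
        threshold_K=threshold_K,
    )


def daily_profile(
    detections: Iterable[FireDetection],
    spec: GridSpec,
    year: int,
    mask: GridRaster | None = None,
) -> pd.DataFrame:
    """Day-of-year series of burned-cell counts and mean cell intensity.

    Counts distinct cells with ≥1 detection that day (not detections);
    intensity is the mean over those cells of the per-cell max brightness.
    Restricted to ``mask`` cells when given.
    """
    if mask is not None and not mask.spec.compatible_with(spec):
        raise AlignmentError("mask grid does not match the analysis grid")
    n_days = 366 if date(year, 12, 31).timetuple().tm_yday == 366 else 365
    per_day: dict[int, dict[tuple[int, int], float]] = {}
    for det in detections:
        if det.timestamp.year != year:
            continue
        cell = spec.cell_of(det.lon, det.lat)
        if cell is None:
            continue
        if mask is not None and mask.values[cell] == 0:
            continue
        doy = det.timestamp.timetuple().tm_yday
        cells = per_day.setdefault(doy, {})
        cells[cell] = max(cells.get(cell, 0.0), det.brightness)
    rows = []
    for doy in range(1, n_days + 1):
        cells = per_day.get(doy, {})
        rows.append(
            {
                "day_of_year": doy,
                "n_cells_with_fire": len(cells),
                "mean_intensity_K": float(np.mean(list(cells.values()))) if cells else np.nan,
            }
        )
    return pd.DataFrame(rows)


def intensity_stats(fy: FireYearRaster, mask: GridRaster) -> dict[str, float]:
    """Mean/median brightness and burned-cell count inside a region mask.

    Statistics are over burned cells only; with no burned cell in the region
    the Kelvin statistics are NaN (explicitly undefined, not zero).
    """
    if not fy.occurrence.spec.compatible_with(mask.spec):
        raise AlignmentError("mask grid does not match the fire raster grid")
    burned = (fy.occurrence.values > 0) & (mask.values > 0)
    n = int(burned.sum())
    if n == 0:
        return {"mean_K": float("nan"), "median_K": float("nan"), "burned_cells": 0}
    vals = fy.intensity.values[burned]
    return {
        "mean_K": float(np.mean(vals)),
        "median_K": float(np.median(vals)),
        "burned_cells": n,
    }
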