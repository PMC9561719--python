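"""Region-level fire-impact statistics.

The exposure logic is mass-normalised overlay arithmetic.  A region mask is
rescaled so its cells sum to one; multiplying by the annual fire-occurrence
raster and summing gives the burned fraction of the region.  Replacing the
uniform weights with an animal-density surface (individuals per cell) turns
the same overlay into a proxy count of individuals whose cell burned — a
stand-in for the number displaced, injured or killed.  Annual series of
these quantities, per country and for the whole ecoregion, feed the
factor-effect summaries (a year's value over the median of a reference
window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fires import FireYearRaster
from .grid import (
    AlignmentError,
    EmptyRegionError,
    GridRaster,
    normalize_mask,
    overlay_product,
    raster_sum,
)

__all__ = [
    "DensitySurface",
    "density_from_per100km2",
    "exposed_fraction",
    "exposed_count",
    "pa_burn_fraction",
    "annual_series",
    "factor_effect",
    "median_midpoint",
    "share_by_region",
]


@dataclass
class DensitySurface:
    """Expected individuals per grid cell, converted from a per-100-km² map."""

    raster: GridRaster
    provenance: str = "individuals per 100 km², divided by 100 to per-1-km² cells"

    @property
    def total(self) -> float:
        return raster_sum(self.raster)


def density_from_per100km2(raw: GridRaster) -> DensitySurface:
    """Convert a density map in individuals/100 km² to individuals per cell.

    Dividing by 100 yields individuals per km²; multiplying by the grid's
    cell area (nominally 1 km²) yields expected individuals per cell, so the
    raster total is the estimated abundance of the mapped region.
    """
    if (raw.values < 0).any():
        raise ValueError("density input has negative cells")
    values = raw.values / 100.0 * raw.spec.cell_area
    return DensitySurface(GridRaster(raw.spec, values, "density"))


def _require_aligned(a: GridRaster, b: GridRaster) -> None:
    if not a.spec.compatible_with(b.spec):
        raise AlignmentError("layers are not on the same grid")


def exposed_fraction(region_mask: GridRaster, fy: FireYearRaster) -> float:
    """Fraction of a region's cells with fire occurrence (mass-normalised).

    Equals sum(normalize(mask) × occurrence), in [0, 1].
    """
    _require_aligned(region_mask, fy.occurrence)
    weights = normalize_mask(region_mask)  # raises EmptyRegionError on empty region
    return raster_sum(overlay_product(weights, fy.occurrence))


def exposed_count(
    density: DensitySurface,
    fy: FireYearRaster,
    region_mask: GridRaster,
) -> tuple[float, float]:
    """(affected, total) expected individuals in a region for one fire year.

    ``affected`` sums density over the region's burned cells; ``total`` sums
    density over the whole region.
    """
    _require_aligned(density.raster, fy.occurrence)
    _require_aligned(density.raster, region_mask)
    if not (region_mask.values > 0).any():
        raise EmptyRegionError("region mask has no cells")
    in_region = overlay_product(density.raster, region_mask)
    affected = raster_sum(overlay_product(in_region, fy.occurrence))
    total = raster_sum(in_region)
    return affected, total


def pa_burn_fraction(
    pa_mask: GridRaster,
    fy: FireYearRaster,
    region_mask: GridRaster,
) -> tuple[float, float]:
    """(burned fraction of PA extent, burned km²) within a region.

    Protected-area cells are intersected with the region mask; the fraction
    is burned PA extent over total PA extent there, NaN when the region holds
    no protected cells.
    """
    _require_aligned(pa_mask, region_mask)
    _require_aligned(pa_mask, fy.occurrence)
    pa_in_region = overlay_product(pa_mask, region_mask)
    total_cells = raster_sum(pa_in_region)
    if total_cells == 0:
        return float("nan"), 0.0
    burned_cells = raster_sum(overlay_product(pa_in_region, fy.occurrence))
    cell_area = pa_mask.spec.cell_area
    return burned_cells / total_cells, burned_cells * cell_area


def annual_series(
    density: DensitySurface,
    fire_years: Sequence[FireYearRaster],
    region_masks: Mapping[str, GridRaster],
    ecoregion: str | None = None,
    reference_years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Exposure table: one row per (year, region).

    Columns: proxy_affected, proxy_total, pct_affected, burned_fraction,
    mean_intensity_K and (for the ``ecoregion`` region when named) the
    factor effect of each year against the median of ``reference_years``.
    """
    from .fires import intensity_stats

    if not fire_years:
        raise ValueError("need at least one fire year")
    rows = []
    for fy in fire_years:
        for region, mask in region_masks.items():
            affected, total = exposed_count(density, fy, mask)
            stats = intensity_stats(fy, mask)
            rows.append(
                {
                    "year": fy.year,
                    "region": region,
                    "proxy_affected": affected,
                    "proxy_total": total,
                    "pct_affected": 100.0 * affected / total if total > 0 else float("nan"),
                    "burned_fraction": exposed_fraction(mask, fy),
                    "mean_intensity_K": stats["mean_K"],
                }
            )
    table = pd.DataFrame(rows).sort_values(["year", "region"]).reset_index(drop=True)
    if ecoregion is not None:
        eco = table[table.region == ecoregion].set_index("year")["proxy_affected"]
        ref_years = list(reference_years) if reference_years else [y for y in eco.index]
        table["factor_effect"] = [
            factor_effect(eco.to_dict(), int(row.year), ref_years)
            if row.region == ecoregion
            else float("nan")
            for row in table.itertuples()
        ]
    return table


def median_midpoint(values: Sequence[float]) -> float:
    """Sort-and-pick median, midpoint rule for even counts."""
    vals = sorted(values)
    n = len(vals)
    if n == 0:
        raise ValueError("median of empty sequence")
    mid = n // 2
    return vals[mid] if n % 2 else 0.5 * (vals[mid - 1] + vals[mid])


def factor_effect(
    series: Mapping[int, float],
    year: int,
    reference_years: Sequence[int],
) -> float:
    """A year's value divided by the median over a reference window.

    NaN when the reference median is zero (undefined rather than infinite).
    """
    if not reference_years:
        raise ValueError("reference window is empty")
    missing = [y for y in list(reference_years) + [year] if y not in series]
    if missing:
        raise KeyError(f"years missing from series: {missing}")
    ref = median_midpoint([series[y] for y in reference_years])
    if ref == 0:
        return float("nan")
    return series[year] / ref


def share_by_region(
    series: pd.DataFrame,
    year: int,
    regions: Sequence[str] | None = None,
    rounded: bool = True,
) -> dict[str, float]:
    """Percent of one year's affected total contributed by each region.

    With ``rounded`` (the reporting convention) shares are nearest-integer
    percentages and sum to 100 up to integer rounding.
    """
    rows = series[series.year == year]
    if rows.empty:
        raise KeyError(f"year {year} not in series")
    if regions is not None:
        rows = rows[rows.region.isin(regions)]
    total = rows.proxy_affected.sum()
    if total == 0:
        return {r: float("nan") for r in rows.region}
    shares = {
        str(row.region): 100.0 * row.proxy_affected / total for row in rows.itertuples()
    }
    if rounded:
        shares = {k: float(round(v)) for k, v in shares.items()}
    return shares
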