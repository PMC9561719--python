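"""Kernel home ranges, highest-density regions and burn overlays."""

import math

import numpy as np
import pytest

from firerange import (
    GridRaster,
    HomeRange,
    NonResidentError,
    ResidencyStatus,
    Track,
    classify_residency,
    cohort_summary,
    empirical_variogram,
    estimate_pmf,
    fit_ou,
    hdr_area,
    hr_burn,
    hr_pa_burn,
    make_grid,
    raster_sum,
)
from firerange.fires import FireYearRaster
from firerange.grid import KM_PER_DEGREE
from firerange.homerange import HRBurnRecord, hdr_area_from_pmf
from firerange.synthetic import ScenarioConfig, simulate_ou_tracks


def hr_grid(track, res=0.002, half_km=8.0):
    lat0 = track.lat0
    half_lat = half_km / KM_PER_DEGREE
    half_lon = half_lat / math.cos(math.radians(lat0))
    return make_grid(
        (track.lon0 - half_lon, lat0 - half_lat, track.lon0 + half_lon, lat0 + half_lat),
        res,
        cell_area=(KM_PER_DEGREE * res) ** 2 * math.cos(math.radians(lat0)),
    )


@pytest.fixture(scope="module")
def resident():
    cfg = ScenarioConfig(seed=21, n_individuals=1, sigma2_range_km2=(2.0, 2.0),
                         tau_range_days=(5.0, 5.0), sampling_interval_days=0.25,
                         sampling_span_days=200.0)
    (track,), _ = simulate_ou_tracks(cfg)
    fit = fit_ou(track)
    status = classify_residency(fit, empirical_variogram(track))
    assert status.resident
    return track, fit, status


def fire_year_from(spec, occ_values, year=2020, brightness=345.0):
    occ = GridRaster(spec, occ_values.astype(float), "occurrence")
    return FireYearRaster(year, occ, GridRaster(spec, occ.values * brightness, "intensity"), 0)


class TestEstimatePmf:
    def test_pmf_normalized(self, resident):
        track, fit, status = resident
        hr = estimate_pmf(track, fit, hr_grid(track), residency=status)
        assert abs(raster_sum(hr.pmf) - 1.0) <= 1e-9
        assert (hr.pmf.values >= 0).all()

    def test_duplicated_relocations_same_pmf(self, resident):
        track, fit, status = resident
        doubled = Track(
            track.individual,
            np.concatenate([track.times, track.times + track.times[-1] + 1.0]),
            np.concatenate([track.x, track.x]),
            np.concatenate([track.y, track.y]),
            track.lon0, track.lat0,
            lons=np.concatenate([track.lons, track.lons]),
            lats=np.concatenate([track.lats, track.lats]),
        )
        spec = hr_grid(track)
        a = estimate_pmf(track, fit, spec, residency=status)
        b = estimate_pmf(doubled, fit, spec, residency=status)
        assert np.allclose(a.pmf.values, b.pmf.values, atol=1e-12)

    def test_nonresident_refused(self, resident):
        track, fit, status = resident
        bad = ResidencyStatus("non-resident", False, False)
        with pytest.raises(NonResidentError):
            estimate_pmf(track, fit, hr_grid(track), residency=bad)

    def test_gaussian_limit_hdr95_area(self):
        # large effective sample size: hdr95 ≈ the Gaussian closed form
        # π·χ²₂(0.95)·σ² = 5.991·π·σ² ≈ 18.82 km² for σ² = 1
        cfg = ScenarioConfig(seed=31, n_individuals=1, sigma2_range_km2=(1.0, 1.0),
                             tau_range_days=(1.0, 1.0), sampling_interval_days=0.05,
                             sampling_span_days=250.0)  # n = 5001, DOF ≈ 250
        (track,), _ = simulate_ou_tracks(cfg)
        fit = fit_ou(track)
        hr = estimate_pmf(track, fit, hr_grid(track))
        assert hr.area_km2 == pytest.approx(5.991 * math.pi * 1.0, rel=0.10)


class TestHdrArea:
    def spec(self, n=10):
        return make_grid((0, 0, n, n), 1.0, cell_area=1.0)

    def test_uniform_pmf(self):
        spec = self.spec()
        pmf = GridRaster(spec, np.full(spec.shape, 0.01), "weight")
        area, mask = hdr_area_from_pmf(pmf, 0.95)
        assert area == 95.0
        assert mask.values.sum() == 95

    def test_single_cell_pmf(self):
        spec = self.spec(2)
        vals = np.zeros(spec.shape)
        vals[1, 1] = 1.0
        for level in (0.05, 0.5, 0.99):
            area, mask = hdr_area_from_pmf(GridRaster(spec, vals, "weight"), level)
            assert area == 1.0 and mask.values[1, 1] == 1

    def test_matches_bruteforce_accumulation_oracle(self, rng):
        spec = self.spec(6)
        vals = rng.random(spec.shape)
        vals /= vals.sum()
        pmf = GridRaster(spec, vals, "weight")
        area, mask = hdr_area_from_pmf(pmf, 0.8)
        # oracle: greedily take the largest cells until reaching the level
        flat = sorted(vals.ravel(), reverse=True)
        acc, k = 0.0, 0
        while acc < 0.8 - 1e-12:
            acc += flat[k]
            k += 1
        assert mask.values.sum() == k
        assert area == k * spec.cell_area
        assert (pmf.values * mask.values).sum() >= 0.8 - 1e-12

    def test_level_accessor_on_homerange(self, resident):
        track, fit, status = resident
        hr = estimate_pmf(track, fit, hr_grid(track), residency=status)
        a50, _ = hdr_area(hr, 0.50)
        a95, _ = hdr_area(hr, 0.95)
        assert 0 < a50 < a95 == hr.area_km2


class TestHrBurn:
    def test_fire_over_all_support(self, resident):
        track, fit, status = resident
        spec = hr_grid(track)
        hr = estimate_pmf(track, fit, spec, residency=status)
        rec = hr_burn(hr, fire_year_from(spec, np.ones(spec.shape)))
        assert rec.burn_fraction == pytest.approx(1.0, abs=1e-9)
        assert rec.burned_km2 == pytest.approx(hr.area_km2)
        assert rec.mean_intensity_K == pytest.approx(345.0)

    def test_fire_over_cells_holding_forty_percent(self, resident):
        track, fit, status = resident
        spec = hr_grid(track)
        hr = estimate_pmf(track, fit, spec, residency=status)
        # construction: pick cells in descending mass until exactly-known mass
        flat = hr.pmf.values.ravel()
        order = np.argsort(-flat)
        acc = np.cumsum(flat[order])
        k = int(np.searchsorted(acc, 0.40)) + 1
        occ = np.zeros(flat.shape)
        occ[order[:k]] = 1.0
        target = float(acc[k - 1])
        rec = hr_burn(hr, fire_year_from(spec, occ.reshape(spec.shape)))
        assert rec.burn_fraction == pytest.approx(target, abs=1e-12)
        # loop oracle
        oracle = math.fsum(
            hr.pmf.values[r, c] * occ.reshape(spec.shape)[r, c]
            for r in range(spec.n_rows) for c in range(spec.n_cols)
        )
        assert rec.burn_fraction == pytest.approx(oracle, abs=1e-12)

    def test_no_fire_zero_and_undefined_intensity(self, resident):
        track, fit, status = resident
        spec = hr_grid(track)
        hr = estimate_pmf(track, fit, spec, residency=status)
        rec = hr_burn(hr, fire_year_from(spec, np.zeros(spec.shape)))
        assert rec.burn_fraction == 0.0
        assert math.isnan(rec.mean_intensity_K)


class TestHrPaBurn:
    def test_pa_and_fire_cover_everything(self, resident):
        track, fit, status = resident
        spec = hr_grid(track)
        hr = estimate_pmf(track, fit, spec, residency=status)
        pa = GridRaster(spec, np.ones(spec.shape), "mask")
        rec = hr_pa_burn(hr, pa, fire_year_from(spec, np.ones(spec.shape)))
        assert rec.pa_burn_fraction == pytest.approx(1.0)
        assert rec.pa_km2 == pytest.approx(hr.area_km2)
        assert rec.pa_burned_km2 == pytest.approx(rec.pa_km2)

    def test_no_pa_overlap_undefined(self, resident):
        track, fit, status = resident
        spec = hr_grid(track)
        hr = estimate_pmf(track, fit, spec, residency=status)
        pa = GridRaster(spec, np.zeros(spec.shape), "mask")
        rec = hr_pa_burn(hr, pa, fire_year_from(spec, np.ones(spec.shape)))
        assert rec.pa_km2 == 0.0 and rec.pa_burned_km2 == 0.0
        assert math.isnan(rec.pa_burn_fraction)

    def test_triple_product_matches_loop_oracle_and_inequality(self, resident, rng):
        track, fit, status = resident
        spec = hr_grid(track)
        hr = estimate_pmf(track, fit, spec, residency=status)
        pa_vals = (rng.random(spec.shape) < 0.4).astype(float)
        occ_vals = (rng.random(spec.shape) < 0.3).astype(float)
        pa = GridRaster(spec, pa_vals, "mask")
        fy = fire_year_from(spec, occ_vals)
        rec = hr_pa_burn(hr, pa, fy)
        w = hr.pmf.values
        oracle = math.fsum(
            w[r, c] * pa_vals[r, c] * occ_vals[r, c]
            for r in range(spec.n_rows) for c in range(spec.n_cols)
        )
        assert rec.pa_burned_km2 / hr.area_km2 == pytest.approx(oracle, abs=1e-12)
        # Σ(pmf·pa·occ) ≤ min(Σ(pmf·pa), Σ(pmf·occ))
        assert oracle <= min((w * pa_vals).sum(), (w * occ_vals).sum()) + 1e-15
        assert 0.0 <= rec.pa_burned_km2 <= rec.pa_km2 <= hr.area_km2 + 1e-9

    def test_doubling_cell_area_scales_km2_not_fractions(self, resident):
        track, fit, status = resident
        spec1 = hr_grid(track)
        spec2 = make_grid(spec1.bounds, spec1.resolution, cell_area=2 * spec1.cell_area)
        occ = np.zeros(spec1.shape)
        occ[: spec1.n_rows // 2, :] = 1.0
        pa = np.ones(spec1.shape)
        r1 = hr_pa_burn(
            estimate_pmf(track, fit, spec1, residency=status),
            GridRaster(spec1, pa, "mask"),
            fire_year_from(spec1, occ),
        )
        r2 = hr_pa_burn(
            estimate_pmf(track, fit, spec2, residency=status),
            GridRaster(spec2, pa, "mask"),
            fire_year_from(spec2, occ),
        )
        assert r2.burn_fraction == pytest.approx(r1.burn_fraction, abs=1e-12)
        assert r2.pa_burn_fraction == pytest.approx(r1.pa_burn_fraction, abs=1e-12)
        for field in ("burned_km2", "pa_km2", "pa_burned_km2"):
            assert getattr(r2, field) == pytest.approx(2 * getattr(r1, field), rel=1e-12)


def record(ident, burn, area=100.0, pa=0.0, pa_burned=0.0):
    return HRBurnRecord(ident, 2020, burn, burn * area, 340.0, pa, pa_burned,
                        pa_burned / pa if pa else float("nan"))


class TestCohortSummary:
    def test_38_of_48_affected_is_79_percent(self, rng):
        recs = [record(f"i{k}", 0.1 + 0.8 * rng.random()) for k in range(38)]
        recs += [record(f"z{k}", 0.0) for k in range(10)]
        summary = cohort_summary(recs)
        assert summary["n_HRs"] == 48
        assert summary["n_affected"] == 38
        assert summary["pct_affected"] == 79

    def test_all_zero(self):
        recs = [record(f"i{k}", 0.0) for k in range(5)]
        summary = cohort_summary(recs)
        assert summary["n_affected"] == 0
        assert math.isnan(summary["median_burn_fraction_affected"])

    def test_matches_bruteforce_summary_oracle(self, rng):
        burns = rng.random(15) * (rng.random(15) < 0.7)
        recs = [record(f"i{k}", float(b)) for k, b in enumerate(burns)]
        summary = cohort_summary(recs)
        affected = [b for b in burns if b > 0]
        assert summary["n_affected"] == len(affected)
        assert summary["pct_affected"] == round(100 * len(affected) / 15)
        if affected:
            assert summary["median_burn_fraction_affected"] == pytest.approx(np.median(affected))
        assert summary["total_burned_km2"] == pytest.approx(sum(b * 100.0 for b in burns))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cohort_summary([])
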