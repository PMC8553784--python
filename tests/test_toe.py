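"""Time-of-emergence chain: control statistics, smoothing, detection."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given
from hypothesis import strategies as st

from n15emerge import (
    SyntheticSpec,
    anomaly,
    boxcar_smooth,
    control_stats,
    emerged_fraction,
    emergence_curve,
    gen_control,
    gen_scenario,
    pattern_agreement,
    toe_map,
    toe_year,
)
from n15emerge.toe import STATUS_EMERGED, STATUS_MISSING, STATUS_NEVER, ToEMap

YEARS = np.arange(1801, 2101)


class TestControlStats:
    def test_pure_line_has_zero_noise_and_errors(self):
        vals = 2.0 + 0.01 * (YEARS - 1801)
        with pytest.raises(ValueError, match="zero interannual noise"):
            control_stats(YEARS, vals)

    def test_slope_and_mean_recovered_with_noise(self):
        rng = np.random.default_rng(11)
        vals = 3.0 + 0.02 * (YEARS - YEARS.mean()) + rng.normal(0, 0.5, YEARS.size)
        cs = control_stats(YEARS, vals)
        assert cs.slope == pytest.approx(0.02, abs=0.002)
        assert cs.mean == pytest.approx(3.0, abs=0.1)

    def test_white_noise_sd_recovered(self):
        # Monte-Carlo oracle: mean estimated SD over many replicates ~ 1
        rng = np.random.default_rng(7)
        sds = [
            control_stats(YEARS, rng.normal(0.0, 1.0, YEARS.size)).noise_sd
            for _ in range(200)
        ]
        assert np.mean(sds) == pytest.approx(1.0, abs=0.02)

    def test_ar1_marginal_sd_matches_closed_form(self):
        # AR(1) with phi=0.6 and innovation sd 0.8 has marginal sd
        # 0.8 / sqrt(1 - 0.36) = 1.0
        spec = SyntheticSpec(nlat=1, nlon=1, phi=0.6, innovation_sd=0.8, seed=5)
        sds = []
        for s in range(60):
            vals = gen_control(spec, seed=s).to_numpy()[:, 0, 0]
            sds.append(control_stats(YEARS, vals).noise_sd)
        assert np.mean(sds) == pytest.approx(1.0, abs=0.07)

    def test_short_control_rejected(self):
        with pytest.raises(ValueError, match=">= 30"):
            control_stats(np.arange(2000, 2020), np.random.default_rng(0).normal(size=20))


class TestAnomaly:
    def test_control_anomalies_center_on_zero_with_no_trend(self):
        rng = np.random.default_rng(3)
        vals = 5.0 + 0.01 * (YEARS - 1801) + rng.normal(0, 1.0, YEARS.size)
        cs = control_stats(YEARS, vals)
        a = anomaly(YEARS, vals, cs)
        assert abs(a.mean()) < 1e-10
        x = YEARS - YEARS.mean()
        assert abs(np.dot(x, a) / np.dot(x, x)) < 1e-10

    def test_step_change_becomes_step_anomaly(self):
        rng = np.random.default_rng(4)
        ctrl = rng.normal(0.0, 1.0, YEARS.size)
        cs = control_stats(YEARS, ctrl)
        scen = cs.trendline(YEARS) + np.where(YEARS >= 2000, 5.0, 0.0)
        a = anomaly(YEARS, scen, cs)
        np.testing.assert_allclose(a, np.where(YEARS >= 2000, 5.0, 0.0), atol=1e-12)

    def test_linear_drift_difference_recovered(self):
        # scenario drifting at b' against control fit with slope b has
        # anomaly slope b' - b
        rng = np.random.default_rng(5)
        ctrl = 1.0 + 0.01 * (YEARS - YEARS.mean()) + rng.normal(0, 0.2, YEARS.size)
        cs = control_stats(YEARS, ctrl)
        scen = 1.0 + 0.03 * (YEARS - YEARS.mean())
        a = anomaly(YEARS, scen, cs)
        x = YEARS - YEARS.mean()
        got = np.dot(x, a - a.mean()) / np.dot(x, x)
        assert got == pytest.approx(0.03 - cs.slope, abs=1e-12)


class TestBoxcar:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(boxcar_smooth(np.full(50, 3.0), 11), 3.0)

    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=30)
        np.testing.assert_array_equal(boxcar_smooth(x, 1), x)

    def test_interior_impulse_becomes_plateau(self):
        x = np.zeros(41)
        x[20] = 11.0
        out = boxcar_smooth(x, 11)
        np.testing.assert_allclose(out[15:26], 1.0)
        np.testing.assert_allclose(out[:15], 0.0)
        np.testing.assert_allclose(out[26:], 0.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            boxcar_smooth(np.zeros(20), 10)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_direct_convolution_oracle(self, seed):
        x = np.random.default_rng(seed).normal(size=60)
        out = boxcar_smooth(x, 11)
        n = x.size
        expected = np.empty(n)
        for i in range(n):  # direct windowed mean with symmetric shrink
            h = min(5, i, n - 1 - i)
            expected[i] = x[i - h : i + h + 1].mean()
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_preserves_length_and_axis(self):
        x = np.random.default_rng(1).normal(size=(40, 3, 2))
        out = boxcar_smooth(x, 11, axis=0)
        assert out.shape == x.shape


class TestToeYear:
    def test_zero_anomaly_never_emerges(self):
        assert toe_year(YEARS, np.zeros(YEARS.size), 1.0) is None

    def test_permanent_step_emerges_at_step_year(self):
        a = np.where(YEARS >= 2040, 3.0, 0.0)
        assert toe_year(YEARS, a, 1.0, k=2.0) == 2040

    def test_temporary_excursion_rejected(self):
        a = np.zeros(YEARS.size)
        a[(YEARS >= 2030) & (YEARS <= 2035)] = 5.0
        a[YEARS >= 2050] = 5.0
        assert toe_year(YEARS, a, 1.0, k=2.0) == 2050

    def test_negative_anomalies_also_emerge(self):
        a = np.where(YEARS >= 2010, -3.0, 0.0)
        assert toe_year(YEARS, a, 1.0, k=2.0) == 2010

    def test_threshold_is_strict(self):
        a = np.full(YEARS.size, 2.0)
        assert toe_year(YEARS, a, 1.0, k=2.0) is None  # equal is not exceed
        assert toe_year(YEARS, a * 1.001, 1.0, k=2.0) == YEARS[0]


class TestToeMap:
    def test_single_cell_grid_reduces_to_toe_year(self):
        spec = SyntheticSpec(nlat=1, nlon=1, ramp_rate=-0.05, onset_year=2000, seed=9)
        ctrl = gen_control(spec)
        scen = gen_scenario(spec)
        tm = toe_map(scen["tracer"], ctrl)

        cyears = ctrl["year"].to_numpy()
        cs = control_stats(cyears, ctrl.to_numpy()[:, 0, 0])
        a = anomaly(cyears, scen["tracer"].to_numpy()[:, 0, 0], cs)
        expected = toe_year(cyears, boxcar_smooth(a, 11), cs.noise_sd, 2.0)
        got = tm.toe.to_numpy()[0, 0]
        assert got == expected

    def test_control_realization_mostly_never_emerges(self):
        spec = SyntheticSpec(nlat=8, nlon=16, ramp_rate=0.0, seed=21)
        ctrl = gen_control(spec)
        scen = gen_scenario(spec)
        tm = toe_map(scen["tracer"], ctrl)
        frac_spurious = float(np.mean(tm.status.to_numpy() == STATUS_EMERGED))
        assert frac_spurious < 0.10

    def test_trend_only_where_amplitude_nonzero(self):
        amp = np.zeros((8, 16))
        amp[:, :8] = 1.0
        spec = SyntheticSpec(
            nlat=8, nlon=16, ramp_rate=-0.06, amplitude=amp, seed=13,
            innovation_sd=0.05,
        )
        tm = toe_map(gen_scenario(spec)["tracer"], gen_control(spec))
        status = tm.status.to_numpy()
        assert np.all(status[:, :8] == STATUS_EMERGED)
        # spurious emergences in the trend-free half stay near the
        # method's small false-positive rate at k=2
        assert np.mean(status[:, 8:] == STATUS_NEVER) > 0.85

    def test_masked_cells_flagged_missing(self):
        spec = SyntheticSpec(nlat=4, nlon=4, seed=2)
        ctrl = gen_control(spec)
        scen = gen_scenario(spec)
        ctrl[:, 0, 0] = np.nan
        tm = toe_map(scen["tracer"], ctrl)
        assert tm.status.to_numpy()[0, 0] == STATUS_MISSING
        assert np.isnan(tm.toe.to_numpy()[0, 0])

    def test_geometry_mismatch_rejected(self):
        a = gen_control(SyntheticSpec(nlat=4, nlon=4, seed=1))
        b = gen_control(SyntheticSpec(nlat=4, nlon=8, seed=1))
        with pytest.raises(ValueError):
            toe_map(a, b)

    def test_roundtrip_through_dataset(self, tmp_path):
        spec = SyntheticSpec(nlat=4, nlon=8, ramp_rate=-0.05, seed=6)
        tm = toe_map(gen_scenario(spec)["tracer"], gen_control(spec))
        ds = tm.to_dataset()
        back = ToEMap.from_dataset(ds)
        np.testing.assert_array_equal(
            np.nan_to_num(back.toe.to_numpy(), nan=-9),
            np.nan_to_num(tm.toe.to_numpy(), nan=-9),
        )


class TestEmergedFraction:
    def _map_from_arrays(self, lats, toe_vals, status):
        coords = {"lat": lats, "lon": [0.0]}
        shape = (len(lats), 1)
        w = np.cos(np.deg2rad(np.asarray(lats)))[:, None] * np.ones(shape)
        return ToEMap(
            toe=xr.DataArray(np.asarray(toe_vals, dtype=float).reshape(shape),
                             coords=coords, dims=("lat", "lon")),
            status=xr.DataArray(np.asarray(status, dtype="i1").reshape(shape),
                                coords=coords, dims=("lat", "lon")),
            weights=xr.DataArray(w, coords=coords, dims=("lat", "lon")),
            region=xr.DataArray(np.ones(shape, bool), coords=coords, dims=("lat", "lon")),
        )

    def test_no_emergence_is_zero_percent(self):
        tm = self._map_from_arrays([0.0, 30.0], [np.nan, np.nan], [1, 1])
        assert emerged_fraction(tm, 2100) == 0.0

    def test_all_emerged_is_100_percent(self):
        tm = self._map_from_arrays([0.0, 30.0], [2040, 2050], [0, 0])
        assert emerged_fraction(tm, 2050) == 100.0
        assert emerged_fraction(tm, 2045) < 100.0

    def test_two_cell_hand_weights(self):
        # cells at 0 and 60 deg: weights 1 and 0.5 -> emerged cell at the
        # equator alone contributes 1 / 1.5 of the area
        tm = self._map_from_arrays([0.0, 60.0], [2040, np.nan], [0, 1])
        assert emerged_fraction(tm, 2100) == pytest.approx(100.0 / 1.5)

    def test_curve_monotone_nondecreasing(self):
        spec = SyntheticSpec(nlat=8, nlon=8, ramp_rate=-0.04, seed=17)
        tm = toe_map(gen_scenario(spec)["tracer"], gen_control(spec))
        curve = emergence_curve(tm, range(1990, 2101, 10))
        assert (curve["percent"].diff().dropna() >= 0).all()

    def test_empty_region_rejected(self):
        tm = self._map_from_arrays([0.0], [2040], [2])
        with pytest.raises(ValueError):
            emerged_fraction(tm, 2100)


class TestPatternAgreement:
    def test_identical_fields_correlate_perfectly(self):
        a = np.random.default_rng(0).normal(size=(6, 8))
        assert pattern_agreement(a, a) == pytest.approx(1.0)

    def test_negated_field_anticorrelates(self):
        a = np.random.default_rng(1).normal(size=(6, 8))
        assert pattern_agreement(a, -a) == pytest.approx(-1.0)

    def test_rank_invariance_under_monotone_transform(self):
        a = np.random.default_rng(2).normal(size=(6, 8))
        assert pattern_agreement(a, np.exp(a)) == pytest.approx(1.0)

    def test_masked_cells_excluded_and_minimum_enforced(self):
        a = np.array([[1.0, 2.0], [np.nan, 4.0]])
        b = np.array([[2.0, 3.0], [1.0, np.nan]])
        with pytest.raises(ValueError, match="at least 3"):
            pattern_agreement(a, b)
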