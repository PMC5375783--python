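import math

import numpy as np
import pytest

from thermaseg.core import (
    DegenerateInputError,
    RadiometricMeta,
    RegionStats,
    ThermalMatrix,
    Thermogram,
    region_stats,
    spot_size,
    stabilization_time,
    to_thermal,
)

META = RadiometricMeta(t_min_c=24.04, t_max_c=36.5)


def _tg(pixels):
    return Thermogram(np.asarray(pixels, dtype=int), META)


class TestToThermal:
    def test_affine_endpoints_and_midpoint(self):
        tg = _tg([[0, 128], [255, 64]])
        th = to_thermal(tg)
        span = 36.5 - 24.04
        assert th.temps[0, 0] == pytest.approx(24.04)
        assert th.temps[1, 0] == pytest.approx(36.5)
        # independent hand calculation: 24.04 + (128/255)*12.46
        assert th.temps[0, 1] == pytest.approx(24.04 + 128 / 255 * span, abs=1e-12)

    def test_observed_max_gray_maps_to_scene_max(self):
        # calibration uses the observed maximum (200), not the nominal 255
        th = to_thermal(_tg([[0, 100], [200, 50]]))
        assert th.temps[1, 0] == pytest.approx(36.5)
        assert th.temps[0, 1] == pytest.approx(24.04 + 0.5 * (36.5 - 24.04))

    def test_order_preserving(self, rng):
        px = rng.integers(0, 256, size=(12, 12))
        th = to_thermal(_tg(px))
        flat_g, flat_t = px.ravel(), th.temps.ravel()
        order = np.argsort(flat_g, kind="stable")
        assert np.all(np.diff(flat_t[order]) >= 0)
        assert th.temps.max() == pytest.approx(36.5)

    def test_all_zero_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            to_thermal(_tg(np.zeros((4, 4))))


class TestRegionStats:
    def test_two_pixel_example(self):
        th = ThermalMatrix(np.array([[25.0, 27.0], [99.0, 99.0]]), META)
        mask = np.array([[True, True], [False, False]])
        st = region_stats(th, mask)
        assert (st.avg, st.max, st.min, st.sd) == (26.0, 27.0, 25.0, 1.0)
        assert st.pixel_count == 2

    def test_constant_full_mask(self):
        th = ThermalMatrix(np.full((3, 3), 30.0), META)
        st = region_stats(th, np.ones((3, 3), bool))
        assert (st.avg, st.max, st.min, st.sd) == (30.0, 30.0, 30.0, 0.0)

    def test_matches_naive_loop(self, rng):
        temps = rng.uniform(20, 40, size=(5, 5))
        mask = rng.random((5, 5)) < 0.6
        mask[0, 0] = True
        st = region_stats(ThermalMatrix(temps, META), mask)
        vals = [temps[i, j] for i in range(5) for j in range(5) if mask[i, j]]
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
        assert st.avg == pytest.approx(mean)
        assert st.max == pytest.approx(max(vals))
        assert st.min == pytest.approx(min(vals))
        assert st.sd == pytest.approx(sd)
        assert st.pixel_count == len(vals)

    def test_empty_mask_rejected(self):
        th = ThermalMatrix(np.full((2, 2), 30.0), META)
        with pytest.raises(ValueError):
            region_stats(th, np.zeros((2, 2), bool))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            RegionStats(avg=10, max=5, min=1, sd=0.1, pixel_count=3)
        with pytest.raises(ValueError):
            RegionStats(avg=3, max=5, min=1, sd=0.1, pixel_count=0)


class TestSpotSize:
    def test_theoretical_spot_at_protocol_distance(self):
        assert spot_size(1.36, 1.2, 1) == pytest.approx(0.001632)

    def test_mfov_safety_factor(self):
        # 3x safety margin: 0.004896 m, i.e. about half a centimeter
        assert spot_size(1.36, 1.2, 3) == pytest.approx(0.004896)

    def test_linear_in_each_argument(self):
        base = spot_size(1.36, 1.2)
        assert spot_size(2 * 1.36, 1.2) == pytest.approx(2 * base)
        assert spot_size(1.36, 3 * 1.2) == pytest.approx(3 * base)

    @pytest.mark.parametrize("ifov,dist,k", [(0, 1.2, 1), (1.36, 0, 1), (1.36, 1.2, 0)])
    def test_degenerate_inputs_rejected(self, ifov, dist, k):
        with pytest.raises(ValueError):
            spot_size(ifov, dist, k)


class TestStabilizationTime:
    @staticmethod
    def _oracle(series, tol):
        """Independent scan: first time whose trailing slopes all stay flat."""
        for i in range(len(series) - 1):
            ok = True
            for j in range(i, len(series) - 1):
                (t0, v0), (t1, v1) = series[j], series[j + 1]
                if abs((v1 - v0) / (t1 - t0)) > tol:
                    ok = False
                    break
            if ok:
                return series[i][0]
        return math.inf

    def test_exponential_cooldown_matches_slope_scan(self):
        # body-surface cool-down toward room equilibrium
        series = [(t, 30.0 + 6.41 * math.exp(-t / 10.0)) for t in range(0, 41)]
        expected = self._oracle(series, 0.05)
        assert stabilization_time(series, 0.05) == expected
        assert 20 <= expected <= 30  # flattens near the 25-minute mark

    def test_constant_series_stable_immediately(self):
        series = [(0, 31.0), (5, 31.0), (10, 31.0)]
        assert stabilization_time(series, 0.05) == 0

    def test_steep_linear_decline_never_stabilizes(self):
        series = [(t, 40.0 - 0.5 * t) for t in range(0, 30, 5)]
        assert stabilization_time(series, 0.05) == math.inf

    def test_short_or_unsorted_series_rejected(self):
        with pytest.raises(ValueError):
            stabilization_time([(0, 30.0), (1, 30.0)])
        with pytest.raises(ValueError):
            stabilization_time([(0, 30.0), (2, 30.0), (1, 30.0)])


class TestDomainTypes:
    def test_meta_invariants(self):
        with pytest.raises(ValueError):
            RadiometricMeta(t_min_c=30.0, t_max_c=25.0)
        with pytest.raises(ValueError):
            RadiometricMeta(t_min_c=20.0, t_max_c=30.0, emissivity=0.0)

    def test_thermogram_bounds(self):
        with pytest.raises(ValueError):
            Thermogram(np.array([[0, 300]]), META)
        with pytest.raises(ValueError):
            Thermogram(np.empty((0, 3), dtype=int), META)
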