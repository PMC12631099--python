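import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from groupdens.rem import (
    RemParameters,
    day_range,
    dpl_percent_change,
    identify_contacts,
    linear_speed,
    rarefy_track,
    rem_density,
    rem_variance,
    speed_sensitivity,
    trapping_rate,
)
from groupdens.synthetic import GPSTrack, expected_trapping_rate

from .conftest import frames, make_tag


def _frames_with_counts(counts, distance=5.0):
    return frames("cam0", counts, distance=distance)


class TestIdentifyContacts:
    def test_reentry_after_blank(self):
        y, contacts = identify_contacts(_frames_with_counts([1, 1, 0, 1]))
        assert y == 2
        assert [ts for ts, _ in contacts] == [0.0, 3.0]

    def test_increment_bookkeeping(self):
        y, _ = identify_contacts(_frames_with_counts([1, 2, 2]))
        assert y == 2

    def test_gate_applied_at_first_qualifying_frame(self):
        from groupdens.observations import PhotoRecord

        photos = [
            PhotoRecord("cam0", 0.0, 1, [make_tag(26.5, max_distance=30.0)]),
            PhotoRecord("cam0", 1.0, 2, [make_tag(20.0)]),
        ]
        y, contacts = identify_contacts(photos, gate=25.0)
        assert y == 1
        assert contacts[0][0] == 1.0  # registered at the 20 m frame

    def test_departures_then_arrivals(self):
        # 2 in view, 1 leaves, then a new arrival brings it back to 2
        y, _ = identify_contacts(_frames_with_counts([2, 1, 2]))
        assert y == 3

    def test_unsorted_raises(self):
        photos = _frames_with_counts([1, 1])
        photos.reverse()
        with pytest.raises(ValueError):
            identify_contacts(photos)

    def test_reset_gap(self):
        photos = _frames_with_counts([1, 1])
        photos[1].timestamp = 500.0
        assert identify_contacts(photos)[0] == 1
        assert identify_contacts(photos, reset_gap=60.0)[0] == 2


class TestTrappingRate:
    def test_simple_rate(self):
        rate, cv, _ = trapping_rate([3, 1], [2.0, 2.0], B=100, seed=0)
        assert rate == pytest.approx(1.0)
        assert np.isfinite(cv)

    def test_all_zero_flagged(self):
        rate, cv, _ = trapping_rate([0, 0], [1.0, 1.0], B=50, seed=0)
        assert rate == 0.0
        assert math.isnan(cv)

    def test_zero_effort_raises(self):
        with pytest.raises(ValueError):
            trapping_rate([1], [0.0])

    def test_seed_determinism(self):
        a = trapping_rate([3, 1, 5], [1.0, 2.0, 1.5], B=100, seed=7)
        b = trapping_rate([3, 1, 5], [1.0, 2.0, 1.5], B=100, seed=7)
        assert a[1] == b[1]


class TestLinearSpeed:
    def test_one_meter_per_second(self):
        gps = GPSTrack(np.array([[0.0, 0.0, 0.0], [60.0, 60.0, 0.0]]), 60.0)
        assert linear_speed(gps).speed_active == pytest.approx(1.0)

    def test_stationary(self):
        gps = GPSTrack(np.array([[0.0, 5.0, 5.0], [60.0, 5.0, 5.0], [120.0, 5.0, 5.0]]), 60.0)
        assert linear_speed(gps).speed_active == 0.0

    def test_right_angle_rarefaction_arithmetic(self):
        # 1 m/s along two perpendicular legs; 2 h sampling sees the hypotenuse
        fixes = np.array([[0.0, 0.0, 0.0], [3600.0, 3600.0, 0.0], [7200.0, 3600.0, 3600.0]])
        gps = GPSTrack(fixes, 3600.0)
        assert linear_speed(gps).speed_active == pytest.approx(1.0)
        coarse = rarefy_track(gps, 7200.0)
        assert linear_speed(coarse).speed_active == pytest.approx(math.sqrt(2) / 2, rel=1e-9)

    def test_duplicate_timestamps_raise(self):
        with pytest.raises(ValueError):
            GPSTrack(np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), 60.0)

    def test_needs_two_fixes(self):
        gps = GPSTrack(np.array([[0.0, 0.0, 0.0], [60.0, 1.0, 0.0]]), 60.0)
        gps.fixes = gps.fixes[:1]
        with pytest.raises(ValueError):
            linear_speed(gps)


class TestRarefy:
    def _track(self, n=15, interval=3600.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) * interval
        xy = np.cumsum(rng.normal(0, 500, size=(n, 2)), axis=0)
        return GPSTrack(np.column_stack([t, xy]), interval)

    def test_identity(self):
        gps = self._track()
        out = rarefy_track(gps, 3600.0)
        assert np.array_equal(out.fixes, gps.fixes)

    def test_fourteen_hourly_to_two_hourly(self):
        gps = self._track(n=14)
        assert len(rarefy_track(gps, 7200.0).fixes) == 7

    def test_non_multiple_raises(self):
        with pytest.raises(ValueError):
            rarefy_track(self._track(), 5400.0)

    @given(seed=st.integers(0, 1000), k=st.sampled_from([2, 3, 4, 6]))
    @settings(max_examples=30, deadline=None)
    def test_dpl_non_increasing(self, seed, k):
        gps = self._track(n=25, seed=seed)
        fine = linear_speed(gps).dpl
        coarse = linear_speed(rarefy_track(gps, k * 3600.0)).dpl
        assert coarse <= fine + 1e-9


class TestDplChange:
    @pytest.mark.parametrize(
        "dpl,ref,expected",
        [(7303.0, 3588.0, 103.5), (2713.0, 3588.0, -24.4), (3588.0, 3588.0, 0.0)],
    )
    def test_printed_values(self, dpl, ref, expected):
        assert round(dpl_percent_change(dpl, ref), 1) == expected

    def test_bad_reference(self):
        with pytest.raises(ValueError):
            dpl_percent_change(100.0, 0.0)


class TestDayRange:
    def test_printed_day_range(self):
        # 1.38 m/s for ~59 min of movement per day gives the printed 4.9 km
        assert day_range(1.38, 1.0, 3551.0) == pytest.approx(4.9, rel=1e-3)

    def test_zero_moving(self):
        assert day_range(1.38, 0.0, 3600.0) == 0.0

    def test_linearity(self):
        assert day_range(2.0, 0.5, 1000.0) == 2 * day_range(1.0, 0.5, 1000.0)


class TestRemDensity:
    def test_hand_evaluation(self):
        p = RemParameters(trapping_rate=1.0, day_range_km=1.0, r_km=0.01, theta=1e-12)
        assert rem_density(p) == pytest.approx(157.0796, rel=1e-4)

    def test_zero_rate(self):
        p = RemParameters(trapping_rate=0.0, day_range_km=1.0, r_km=0.01, theta=0.7)
        assert rem_density(p) == 0.0

    def test_inverse_speed(self):
        a = RemParameters(trapping_rate=1.0, day_range_km=1.0, r_km=0.01, theta=0.7)
        b = RemParameters(trapping_rate=1.0, day_range_km=2.0, r_km=0.01, theta=0.7)
        assert rem_density(a) == pytest.approx(2 * rem_density(b))

    def test_zero_speed_raises(self):
        p = RemParameters(trapping_rate=1.0, day_range_km=0.0, r_km=0.01, theta=0.7)
        with pytest.raises(ValueError):
            rem_density(p)

    def test_roundtrip_with_expected_rate(self):
        # rem_density(expected_trapping_rate(D)) == D exactly
        for d in (0.5, 2.0, 11.0):
            rate = expected_trapping_rate(d, 4.9, 0.012, 0.74)
            p = RemParameters(trapping_rate=rate, day_range_km=4.9, r_km=0.012, theta=0.74)
            assert rem_density(p) == pytest.approx(d, rel=1e-12)


class TestExpectedRate:
    def test_hand_evaluation(self):
        assert expected_trapping_rate(1.0, 4.9, 0.012, 0.74) == pytest.approx(
            0.05128, rel=1e-3
        )

    def test_degenerate_zero(self):
        assert expected_trapping_rate(1.0, 4.9, 0.0, 0.0) == 0.0

    def test_linearity_in_density(self):
        assert expected_trapping_rate(2.0, 4.9, 0.012, 0.74) == pytest.approx(
            2 * expected_trapping_rate(1.0, 4.9, 0.012, 0.74)
        )


TABLE2 = {
    # fix regime: (speed m/s, S1 density, S2 density)
    "1 s": (4.170, 0.422, 0.309),
    "1 s smoothed": (3.770, 0.467, 0.342),
    "30 s": (2.800, 0.629, 0.461),
    "60 s": (2.530, 0.696, 0.510),
    "5 min": (2.020, 0.872, 0.639),
    "15 min": (1.670, 1.050, 0.772),
    "1 h": (1.380, 1.280, 0.940),
    "2 h": (1.040, 1.690, 1.240),
}


class TestSpeedSensitivity:
    def test_identity_at_baseline(self):
        out = speed_sensitivity(1.28, 1.38, [1.38])
        assert out[0]["density"] == pytest.approx(1.28)

    @pytest.mark.parametrize("area,baseline", [("S1", 1.28), ("S2", 0.94)])
    def test_all_printed_columns_within_one_percent(self, area, baseline):
        idx = 1 if area == "S1" else 2
        speeds = [v[0] for v in TABLE2.values()]
        out = speed_sensitivity(baseline, 1.38, speeds)
        for row, (regime, vals) in zip(out, TABLE2.items()):
            assert row["density"] == pytest.approx(vals[idx], rel=0.01), regime

    def test_bad_baseline(self):
        with pytest.raises(ValueError):
            speed_sensitivity(1.0, 0.0, [1.0])


class TestRemVariance:
    def test_single_component(self):
        p = RemParameters(
            trapping_rate=1.0, day_range_km=1.0, r_km=0.01, theta=0.7, cv_rate=0.3
        )
        assert rem_variance(p).cv == pytest.approx(0.3)

    def test_two_components_quadrature(self):
        p = RemParameters(
            trapping_rate=1.0, day_range_km=1.0, r_km=0.01, theta=0.7,
            cv_rate=0.3, cv_speed=0.4,
        )
        assert rem_variance(p).cv == pytest.approx(0.5)

    def test_theta_enters_through_two_plus_theta(self):
        p = RemParameters(
            trapping_rate=1.0, day_range_km=1.0, r_km=0.01, theta=0.7, se_theta=0.27
        )
        assert rem_variance(p).cv == pytest.approx(0.27 / 2.7)

    def test_lognormal_ci_brackets_estimate(self):
        p = RemParameters(
            trapping_rate=1.0, day_range_km=1.0, r_km=0.01, theta=0.7, cv_rate=0.3
        )
        est = rem_variance(p)
        assert est.ci_low < est.density < est.ci_high
        # lognormal CI is multiplicative-symmetric
        assert est.ci_high / est.density == pytest.approx(est.density / est.ci_low)
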