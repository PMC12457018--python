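"""Pull-mode VO2 mass balance, RMR window rule and stress statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from paceline.config import GeneratorConfig
from paceline.respirometry import (
    CorruptTraceError,
    RespTrace,
    VO2Series,
    compute_vo2,
    correct_baseline,
    extract_rmr,
    mass_correct,
    stress_response,
    summarize_session,
)
from paceline.synthetic import generate_trace


def _flat_trace(n=1200, feo2=0.2075, feco2=0.0024, flow=700.0, baseline_s=300,
                events=(), wvp=0.0):
    t = np.arange(float(n))
    channel = np.where(t < baseline_s, "baseline", "test")
    return RespTrace(
        t=t,
        FeO2=np.where(t < baseline_s, 0.2095, feo2),
        FeCO2=np.where(t < baseline_s, 0.0004, feco2),
        FiO2=0.2095, FiCO2=0.0004,
        flow=np.full(n, flow), channel=channel, events=events, WVP=wvp,
    )


class TestComputeVO2:
    def test_no_consumer_gives_zero(self):
        tr = _flat_trace(feo2=0.2095, feco2=0.0004)
        assert np.allclose(compute_vo2(tr).vo2, 0.0)

    def test_hand_mass_balance_84_ml_per_h(self):
        # flow 700 ml/min dry, delta O2 0.0020, delta CO2 0.0020 (RQ = 1):
        # the dilution terms cancel exactly and VO2 = 1.4 ml/min = 84 ml/h
        tr = _flat_trace()
        vo2 = compute_vo2(tr).vo2
        assert vo2[0] == pytest.approx(84.0, abs=1e-9)

    def test_linear_in_flow(self):
        full = compute_vo2(_flat_trace(flow=700.0)).vo2[0]
        half = compute_vo2(_flat_trace(flow=350.0)).vo2[0]
        assert half == pytest.approx(full / 2.0, rel=1e-12)

    def test_dry_correction_scales_flow(self):
        wet = compute_vo2(_flat_trace(wvp=2.0)).vo2[0]
        dry = compute_vo2(_flat_trace(wvp=0.0)).vo2[0]
        assert wet == pytest.approx(dry * (101.325 - 2.0) / 101.325, rel=1e-12)

    def test_rq_assumption_used_when_co2_missing(self):
        tr = _flat_trace()
        tr.FeCO2 = None
        with pytest.raises(ValueError):
            compute_vo2(tr)
        v = compute_vo2(tr, rq_assumption=1.0).vo2[0]
        # single-gas form with RQ=1: FR * dO2 / 1
        assert v == pytest.approx(700.0 * 0.0020 * 60.0, rel=1e-12)

    def test_negative_vo2_warns(self):
        tr = _flat_trace(feo2=0.2115)  # excurrent above incurrent
        with pytest.warns(UserWarning):
            compute_vo2(tr)


class TestCorrectBaseline:
    def test_zero_offset_identity(self):
        tr = _flat_trace(feo2=0.2095, feco2=0.0004)
        out = correct_baseline(tr)
        assert np.allclose(out.FeO2, tr.FeO2)

    def test_constant_offset_removed(self):
        clean = _flat_trace()
        shifted = _flat_trace()
        shifted.FeO2 = shifted.FeO2 + 5e-4
        shifted.FeCO2 = shifted.FeCO2 + 5e-5
        v_clean = compute_vo2(correct_baseline(clean)).vo2
        v_shift = compute_vo2(correct_baseline(shifted)).vo2
        assert np.allclose(v_clean, v_shift, atol=1e-9)

    def test_two_segments_interpolate_midpoint(self):
        n = 2000
        t = np.arange(float(n))
        channel = np.where((t < 300) | (t >= 1700), "baseline", "test")
        a, b = 4e-4, 8e-4
        offset = np.where(t < 300, a, b)
        base_level = np.where(channel == "baseline", 0.2095, 0.2075)
        tr = RespTrace(t=t, FeO2=base_level + offset, FeCO2=np.full(n, 0.0024),
                       FiO2=0.2095, FiCO2=0.0004, flow=np.full(n, 700.0),
                       channel=channel)
        out = correct_baseline(tr)
        # segment mids at 149.5 and 1849.5; their centre carries (a+b)/2
        i = np.searchsorted(t, (149.5 + 1849.5) / 2.0)
        assert tr.FeO2[i] - out.FeO2[i] == pytest.approx((a + b) / 2.0, abs=1e-6)
        # and exactly the linear interpolant at that sample
        expected = a + (b - a) * (t[i] - 149.5) / (1849.5 - 149.5)
        assert tr.FeO2[i] - out.FeO2[i] == pytest.approx(expected, rel=1e-9)

    def test_missing_baseline_errors(self):
        tr = _flat_trace(baseline_s=0)
        with pytest.raises(CorruptTraceError):
            correct_baseline(tr)


class TestExtractRMR:
    def test_constant_series(self):
        v = VO2Series(t=np.arange(2000.0), vo2=np.full(2000, 84.0))
        assert extract_rmr(v, events=(1800.0,)) == pytest.approx(84.0)

    def test_single_dip_found(self):
        t = np.arange(2000.0)
        vo2 = np.full(2000, 84.0)
        vo2[1400:1431] = 60.0  # 31 samples = one full 30-s window
        v = VO2Series(t=t, vo2=vo2)
        assert extract_rmr(v, events=(1800.0,)) == pytest.approx(60.0)

    def test_dip_before_search_span_ignored(self):
        t = np.arange(2000.0)
        vo2 = np.full(2000, 84.0)
        vo2[300:360] = 40.0  # well before the last-10-min span
        v = VO2Series(t=t, vo2=vo2)
        assert extract_rmr(v, events=(1800.0,)) == pytest.approx(84.0)

    def test_insufficient_span_errors(self):
        v = VO2Series(t=np.arange(100.0), vo2=np.full(100, 84.0))
        with pytest.raises(CorruptTraceError):
            extract_rmr(v, events=(90.0,))

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(80, 200)
        t = np.cumsum(rng.uniform(0.5, 2.0, n))
        vo2 = rng.normal(80.0, 10.0, n)
        event = float(t[-1] - rng.uniform(0.0, 20.0))
        v = VO2Series(t=t, vo2=vo2)
        try:
            got = extract_rmr(v, events=(event,), discard_minutes=0.2,
                              window_seconds=10.0, search_minutes=1.5)
        except CorruptTraceError:
            return
        lo = max(t[0] + 0.2 * 60, event - 1.5 * 60)
        tt = t[(t >= lo) & (t <= event)]
        xx = vo2[(t >= lo) & (t <= event)]
        best = np.inf
        for i in range(len(tt)):
            if tt[i] + 10.0 > tt[-1] + 1e-9:
                continue
            sel = (tt >= tt[i]) & (tt <= tt[i] + 10.0)
            best = min(best, xx[sel].mean())
        assert got == pytest.approx(best, rel=1e-12)


class TestMassCorrect:
    def test_hand_value(self):
        assert mass_correct(84.0, 100.0) == pytest.approx(2.6565, abs=2e-4)

    def test_unit_mass_identity(self):
        assert mass_correct(3.14, 1.0) == pytest.approx(3.14)

    def test_kleiber_scaling(self):
        assert mass_correct(84.0, 50.0) / mass_correct(84.0, 100.0) == pytest.approx(
            2.0**0.75, rel=1e-12)

    def test_invalid_mass(self):
        with pytest.raises(ValueError):
            mass_correct(84.0, 0.0)


class TestStressResponse:
    def _series(self, values):
        t = np.arange(0.0, len(values))
        return VO2Series(t=t, vo2=np.asarray(values, dtype=float))

    def test_flat_at_resting(self):
        v = self._series([84.0] * 61)
        assert stress_response(v, 0.0, 84.0) == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_step_to_1p5_resting(self):
        v = self._series([126.0] * 61)
        smax, sint = stress_response(v, 0.0, 84.0)
        assert (smax, sint) == pytest.approx((50.0, 50.0), abs=1e-9)

    def test_triangle_decay(self):
        r = 84.0
        t = np.arange(0.0, 61.0)
        v = VO2Series(t=t, vo2=2.0 * r - r * t / 60.0)
        smax, sint = stress_response(v, 0.0, r)
        assert (smax, sint) == pytest.approx((100.0, 50.0), abs=1e-9)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        base = 80.0 + rng.uniform(-10, 30, 61)
        v1 = self._series(base)
        v2 = self._series(base * c)
        assert stress_response(v1, 0.0, 80.0) == pytest.approx(
            stress_response(v2, 0.0, 80.0 * c), rel=1e-9)

    def test_truncated_window_errors(self):
        v = self._series([84.0] * 30)
        with pytest.raises(CorruptTraceError):
            stress_response(v, 0.0, 84.0)


class TestSessionSummary:
    CFG = GeneratorConfig(sensor_noise_sd=0.0, sensor_offset=0.0,
                          activity_bout_rate=0.0, water_vapour_pressure=0.0)

    def test_constant_vo2_recovers_84(self):
        params = dict(rmr=84.0 / 100**0.75, body_mass_g=100.0,
                      stress_max_pct=0.0, stress_integral_pct=0.0)
        tr = generate_trace(params, self.CFG, seed=1)
        s = summarize_session(tr, 100.0)
        assert s.rmr_raw == pytest.approx(84.0, rel=0.01)
        assert s.rmr == pytest.approx(mass_correct(s.rmr_raw, 100.0))

    def test_two_alarms_averaged_and_peak_recovered(self):
        params = dict(rmr=2.7, body_mass_g=90.0, stress_max_pct=40.0,
                      stress_integral_pct=25.0)
        tr = generate_trace(params, self.CFG, seed=2)
        s = summarize_session(tr, 90.0)
        assert s.n_alarms_used == 2
        assert s.stress_max == pytest.approx(40.0, rel=0.05)

    def test_single_alarm_degenerate_mean(self):
        cfg = GeneratorConfig(sensor_noise_sd=0.0, sensor_offset=0.0,
                              activity_bout_rate=0.0, alarm_times=(1800.0,))
        params = dict(rmr=2.7, body_mass_g=90.0, stress_max_pct=40.0,
                      stress_integral_pct=25.0)
        s = summarize_session(generate_trace(params, cfg, seed=3), 90.0)
        assert s.n_alarms_used == 1

    def test_sensor_offset_roundtrip(self):
        cfg = GeneratorConfig(sensor_noise_sd=0.0, sensor_offset=5e-4,
                              activity_bout_rate=0.0, water_vapour_pressure=0.0)
        params = dict(rmr=84.0 / 100**0.75, body_mass_g=100.0,
                      stress_max_pct=0.0, stress_integral_pct=0.0)
        s = summarize_session(generate_trace(params, cfg, seed=4), 100.0)
        assert s.rmr_raw == pytest.approx(84.0, rel=0.01)


def test_washout_time_constant_is_volume_over_flow():
    # chamber washes in from ambient toward steady state with tau = V / F
    cfg = GeneratorConfig(sensor_noise_sd=0.0, sensor_offset=0.0,
                          activity_bout_rate=0.0, water_vapour_pressure=0.0)
    params = dict(rmr=84.0 / 100**0.75, body_mass_g=100.0,
                  stress_max_pct=0.0, stress_integral_pct=0.0)
    tr = generate_trace(params, cfg, seed=5)
    ss_value = tr.FeO2[1700]  # equilibrated (> 15 tau after start)
    gap = tr.FeO2 - ss_value
    # the chamber is only visible on the test channel (after the baseline
    # segment), while the decay is still ongoing
    sel = (tr.t >= 320) & (tr.t <= 650)
    slope = np.polyfit(tr.t[sel], np.log(np.abs(gap[sel])), 1)[0]
    assert -1.0 / slope == pytest.approx(1000.0 / 700.0 * 60.0, rel=0.02)


def test_trace_frame_roundtrip():
    cfg = GeneratorConfig()
    params = dict(rmr=2.7, body_mass_g=90.0, stress_max_pct=30.0, stress_integral_pct=10.0)
    tr = generate_trace(params, cfg, seed=6)
    back = RespTrace.from_frame(tr.to_frame())
    assert np.allclose(back.FeO2, tr.FeO2)
    assert back.events == tr.events
    assert list(back.channel[:3]) == ["baseline"] * 3
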