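import numpy as np
import pandas as pd
import pytest

from cardiomea.beats import BeatTable, exclude_by_mode, find_beats
from cardiomea.geometry import distance
from cardiomea.io import Recording
from cardiomea.metrics import (
    beat_amplitude,
    beat_intervals,
    compute_property_maps,
    conduction_velocity,
    local_activation_time,
    raw_peak_times,
    time_lag_map,
    upstroke_velocity,
)


def _table(toy_cfg, peak_times, rec=None, polarity=-1):
    """Beat table with given per-electrode peak time lists (ms at 1 kHz)."""
    peaks = {}
    for label, times in peak_times.items():
        times = np.asarray(times, dtype=float)
        peaks[label] = np.column_stack([times, times, np.full(times.size, 300.0)])
    t = BeatTable(cfg=toy_cfg, peaks=peaks,
                  polarity={l: polarity for l in toy_cfg.labels},
                  included=frozenset(peak_times))
    return exclude_by_mode(t)


def test_time_lag_subtracts_per_beat_minimum(toy_cfg):
    table = _table(toy_cfg, {"A1": [100.0], "B1": [105.0], "A2": [112.0], "B2": [103.0]})
    lag = time_lag_map(table)
    assert lag.loc[0, "A1"] == 0.0
    assert lag.loc[0, "B1"] == 5.0
    assert lag.loc[0, "A2"] == 12.0
    assert lag.loc[0, "B2"] == 3.0


def test_simultaneous_peaks_give_zero_lags(toy_cfg):
    table = _table(toy_cfg, {l: [500.0] for l in toy_cfg.labels})
    assert (time_lag_map(table).to_numpy() == 0).all()


def test_radial_wave_lag_matches_distance_over_speed(radial_clean, radial_clean_table, cfg120):
    rec, gt = radial_clean
    lag = time_lag_map(radial_clean_table)
    expect = gt.peak_times - gt.peak_times.min(axis=1, keepdims=True)
    cols = [list(cfg120.labels).index(l) for l in lag.columns]
    err = lag.to_numpy() - expect[:, cols]
    assert np.max(np.abs(err)) <= rec.dt  # within one sample


def _pulse_recording(toy_cfg):
    """Piecewise-linear pulse: up-ramp slope 50 uV/ms into a peak at 500 ms,
    plateau 8 ms, then steepest down-slope starting 8 ms after the peak."""
    t = np.arange(0.0, 1500.0, 1.0)
    v = np.zeros_like(t)
    up = (t >= 494) & (t <= 500)
    v[up] = 50.0 * (t[up] - 494.0)  # reaches 300 at the peak
    v[(t > 500) & (t <= 508)] = 300.0  # flat top (derivative 0)
    down = (t > 508) & (t <= 514)
    v[down] = 300.0 - 50.0 * (t[down] - 508.0)
    return Recording(time=t, voltages=np.tile(v, (4, 1)), cfg=toy_cfg)


def test_lat_found_at_steepest_downslope_after_peak(toy_cfg):
    rec = _pulse_recording(toy_cfg)
    table = _table(toy_cfg, {l: [500.0] for l in toy_cfg.labels}, polarity=+1)
    lat_raw = local_activation_time(rec, table, normalized=False, refine=False)
    # steepest descent starts 8 ms after the peak; first maximal-downslope sample is at +9
    assert lat_raw.loc[0, "A1"] == pytest.approx(509.0, abs=1.0)


def test_normalized_lat_equals_time_lag_for_shifted_copies(toy_cfg):
    t = np.arange(0.0, 2000.0, 1.0)
    shifts = {"A1": 0, "B1": 4, "A2": 9, "B2": 2}
    base = -300.0 * np.exp(-0.5 * ((t - 600.0) / 3.0) ** 2)
    volts = np.vstack([np.roll(base, s) for s in shifts.values()])
    rec = Recording(time=t, voltages=volts, cfg=toy_cfg)
    table = find_beats(rec)
    lat = local_activation_time(rec, table)
    lag = time_lag_map(table)
    assert np.max(np.abs(lat.to_numpy() - lag.to_numpy())) < 0.05


def test_monotone_rise_after_peak_flags_missing(toy_cfg):
    t = np.arange(0.0, 1200.0, 1.0)
    v = np.where(t < 500, 0.0, (t - 500.0))  # rises forever after "peak"
    rec = Recording(time=t, voltages=np.tile(v, (4, 1)), cfg=toy_cfg)
    table = _table(toy_cfg, {l: [500.0] for l in toy_cfg.labels}, polarity=+1)
    lat_raw = local_activation_time(rec, table, normalized=False)
    assert lat_raw.isna().all().all()


def test_upstroke_is_exact_on_linear_ramp(toy_cfg):
    rec = _pulse_recording(toy_cfg)
    table = _table(toy_cfg, {l: [500.0] for l in toy_cfg.labels}, polarity=+1)
    dvdt = upstroke_velocity(rec, table)
    assert dvdt.loc[0, "A1"] == pytest.approx(50.0)


def test_upstroke_scales_linearly(toy_cfg):
    rec = _pulse_recording(toy_cfg)
    doubled = Recording(time=rec.time, voltages=2 * rec.voltages, cfg=toy_cfg)
    table = _table(toy_cfg, {l: [500.0] for l in toy_cfg.labels}, polarity=+1)
    a = upstroke_velocity(rec, table).loc[0, "A1"]
    b = upstroke_velocity(doubled, table).loc[0, "A1"]
    assert b == pytest.approx(2 * a)


def test_amplitude_sums_both_lobes(toy_cfg):
    t = np.arange(0.0, 1200.0, 1.0)
    v = 120.0 * np.exp(-0.5 * ((t - 491.0) / 3.0) ** 2) - 300.0 * np.exp(-0.5 * ((t - 500.0) / 3.0) ** 2)
    rec = Recording(time=t, voltages=np.tile(v, (4, 1)), cfg=toy_cfg)
    table = _table(toy_cfg, {l: [500.0] for l in toy_cfg.labels})
    amp = beat_amplitude(rec, table)
    assert amp.loc[0, "A1"] == pytest.approx(420.0, rel=0.02)


def test_amplitude_of_purely_negative_spike(toy_cfg):
    t = np.arange(0.0, 1200.0, 1.0)
    v = -300.0 * np.exp(-0.5 * ((t - 500.0) / 3.0) ** 2)
    rec = Recording(time=t, voltages=np.tile(v, (4, 1)), cfg=toy_cfg)
    table = _table(toy_cfg, {l: [500.0] for l in toy_cfg.labels})
    assert beat_amplitude(rec, table).loc[0, "A1"] == pytest.approx(300.0, rel=0.01)


def test_amplitude_invariant_under_voltage_offset(toy_cfg):
    t = np.arange(0.0, 1200.0, 1.0)
    v = -300.0 * np.exp(-0.5 * ((t - 500.0) / 3.0) ** 2)
    rec = Recording(time=t, voltages=np.tile(v, (4, 1)), cfg=toy_cfg)
    shifted = Recording(time=t, voltages=rec.voltages + 150.0, cfg=toy_cfg)
    table = _table(toy_cfg, {l: [500.0] for l in toy_cfg.labels})
    np.testing.assert_allclose(
        beat_amplitude(rec, table).to_numpy(), beat_amplitude(shifted, table).to_numpy()
    )


def test_intervals_are_successive_differences():
    times = pd.DataFrame({"A1": [0.0, 1000.0, 2100.0]})
    iv = beat_intervals(times)
    np.testing.assert_allclose(iv["A1"], [1000.0, 1100.0])


def test_single_beat_gives_empty_intervals():
    iv = beat_intervals(pd.DataFrame({"A1": [500.0]}))
    assert iv["A1"].size == 0


def test_constant_pacing_interval_recovered(radial_clean, radial_clean_table):
    rec, gt = radial_clean
    lat_raw = local_activation_time(rec, radial_clean_table, normalized=False)
    iv = beat_intervals(lat_raw.fillna(raw_peak_times(radial_clean_table)))
    period = 60000.0 / gt.spec.bpm
    for v in iv.values():
        np.testing.assert_allclose(v, period, atol=rec.dt)


def test_cv_arithmetic(toy_cfg):
    lat = pd.DataFrame({"A1": [0.0], "B1": [2.0], "A2": [4.0], "B2": [0.5]})
    cv = conduction_velocity(lat, toy_cfg)
    assert np.isnan(cv.loc[0, "A1"])  # reference electrode undefined
    assert cv.loc[0, "B1"] == pytest.approx(100.0)  # 200 um / 2 ms
    assert cv.loc[0, "A2"] == pytest.approx(50.0)


def test_cv_zero_delta_lat_flagged_not_infinite(toy_cfg):
    lat = pd.DataFrame({"A1": [0.0], "B1": [0.0], "A2": [2.0], "B2": [1.0]})
    cv = conduction_velocity(lat, toy_cfg)
    # two zero-LAT electrodes: one is the reference, the other undefined
    assert np.isnan(cv.loc[0, "A1"]) and np.isnan(cv.loc[0, "B1"])
    assert np.isfinite(cv.loc[0, "A2"])


def test_cv_recovers_wave_speed(radial_clean, radial_clean_table):
    rec, gt = radial_clean
    maps = compute_property_maps(rec, radial_clean_table)
    med = np.nanmedian(maps.cv.to_numpy())
    assert abs(med - gt.spec.speed) / gt.spec.speed < 0.10


def test_per_beat_minima_are_exactly_zero(radial_clean, radial_clean_table):
    rec, _ = radial_clean
    maps = compute_property_maps(rec, radial_clean_table)
    assert (maps.time_lag.min(axis=1) == 0.0).all()
    assert (maps.lat.min(axis=1) == 0.0).all()


def test_offset_and_common_shift_invariance(radial_clean, radial_clean_table):
    rec, _ = radial_clean
    maps = compute_property_maps(rec, radial_clean_table)
    shifted = Recording(time=rec.time, voltages=rec.voltages + 77.0, cfg=rec.cfg)
    maps2 = compute_property_maps(shifted, radial_clean_table)
    for name in ("time_lag", "lat", "dvdt_max", "amplitude", "cv"):
        a = getattr(maps, name).to_numpy()
        b = getattr(maps2, name).to_numpy()
        np.testing.assert_allclose(a, b, equal_nan=True)
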