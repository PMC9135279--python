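import numpy as np
import pytest

from cardiomea.beats import (
    AnalysisError,
    BeatDetectParams,
    BeatTable,
    FilterSpec,
    apply_filter,
    detect_beats,
    exclude_by_mode,
    find_beats,
    silence,
    unsilence,
)
from cardiomea.io import Recording

from conftest import spike_train_recording


# --- filtering -------------------------------------------------------------


def test_lowpass_passes_slow_sinusoid(toy_cfg):
    t = np.arange(0, 2000.0, 1.0)
    v = 100.0 * np.sin(2 * np.pi * 5e-3 * t)  # 5 Hz
    rec = Recording(time=t, voltages=np.tile(v, (4, 1)), cfg=toy_cfg)
    out = apply_filter(rec, FilterSpec("lowpass", 100.0))
    mid = slice(200, -200)
    atten = 1 - np.max(np.abs(out.voltages[0][mid])) / np.max(np.abs(v[mid]))
    assert atten < 0.01


def test_highpass_removes_dc_offset(toy_cfg):
    t = np.arange(0, 5000.0, 1.0)
    rec = Recording(time=t, voltages=np.full((4, t.size), 250.0), cfg=toy_cfg)
    out = apply_filter(rec, FilterSpec("highpass", 0.5))
    assert abs(np.mean(out.voltages)) < 1.0


def test_bandpass_low_must_be_below_high():
    with pytest.raises(ValueError):
        FilterSpec("bandpass", (100.0, 0.5))


def test_cutoff_beyond_nyquist_rejected(toy_cfg):
    t = np.arange(0, 1000.0, 1.0)
    rec = Recording(time=t, voltages=np.zeros((4, t.size)), cfg=toy_cfg)
    with pytest.raises(ValueError, match="Nyquist"):
        apply_filter(rec, FilterSpec("lowpass", 600.0))


# --- detection -------------------------------------------------------------


def test_spike_train_fully_detected(toy_cfg):
    times = 500.0 + 1000.0 * np.arange(10)
    rec = spike_train_recording(toy_cfg, times)
    table = detect_beats(rec)
    for label in toy_cfg.labels:
        assert len(table.peaks[label]) == 10
        np.testing.assert_allclose(table.peak_times(label), times, atol=1.0)


def test_flat_noise_yields_no_peaks(toy_cfg):
    rec = spike_train_recording(toy_cfg, [], total_ms=3000.0, noise=10.0, seed=5)
    table = detect_beats(rec)
    assert all(len(table.peaks[l]) == 0 for l in toy_cfg.labels)


def test_min_distance_keeps_larger_of_close_pair(toy_cfg):
    t = np.arange(0, 2000.0, 1.0)
    v = np.zeros_like(t)
    v[500] = -200.0
    v[600] = -350.0  # 100 ms later, larger
    rec = Recording(time=t, voltages=np.tile(v, (4, 1)), cfg=toy_cfg)
    table = detect_beats(rec, BeatDetectParams(min_distance=250.0, refine=False))
    times = table.peak_times("A1")
    assert len(times) == 1 and times[0] == 600.0


def test_auto_polarity_matches_dominant_lobe(toy_cfg):
    times = 500.0 + 1000.0 * np.arange(5)
    neg = spike_train_recording(toy_cfg, times, sign=-1.0)
    pos = spike_train_recording(toy_cfg, times, sign=+1.0)
    assert all(p == -1 for p in detect_beats(neg).polarity.values())
    assert all(p == +1 for p in detect_beats(pos).polarity.values())


def test_detected_times_match_schedule_under_noise(cfg120):
    from cardiomea import generate_recording, radial_spec

    spec = radial_spec(cfg120, cfg120.coords["F7"], speed=300.0, bpm=40.0,
                       n_beats=6, noise_sigma=30.0, seed=2)  # S/N = 10
    rec, gt = generate_recording(spec)
    table = find_beats(rec, BeatDetectParams(filter=FilterSpec("lowpass", 100.0)))
    for ci, label in enumerate(cfg120.labels):
        if label not in table.included:
            continue
        got = table.peak_times(label)
        want = gt.peak_times[:, ci]
        assert np.max(np.abs(got - want)) <= 2 * rec.dt


# --- exclusion and silencing ----------------------------------------------


def _table_with_counts(toy_cfg, counts):
    peaks = {}
    for label, n in zip(toy_cfg.labels, counts):
        times = 500.0 + 1000.0 * np.arange(n)
        peaks[label] = np.column_stack([times, times, np.full(n, 300.0)])
    return BeatTable(cfg=toy_cfg, peaks=peaks,
                     polarity={l: -1 for l in toy_cfg.labels},
                     included=frozenset(toy_cfg.labels))


def test_mode_exclusion_drops_deviant_electrode(toy_cfg):
    table = exclude_by_mode(_table_with_counts(toy_cfg, [30, 30, 30, 29]))
    assert table.n_beats == 30
    assert table.excluded_auto == {"B2"}
    assert table.included == {"A1", "B1", "A2"}


def test_mode_exclusion_keeps_all_when_equal(toy_cfg):
    table = exclude_by_mode(_table_with_counts(toy_cfg, [12, 12, 12, 12]))
    assert table.excluded_auto == frozenset()
    assert table.n_beats == 12


def test_bimodal_tie_resolves_to_larger_count(toy_cfg):
    table = exclude_by_mode(_table_with_counts(toy_cfg, [30, 30, 15, 15]))
    assert table.n_beats == 30
    assert table.excluded_auto == {"A2", "B2"}


def test_mode_exclusion_idempotent(toy_cfg):
    once = exclude_by_mode(_table_with_counts(toy_cfg, [30, 30, 30, 29]))
    twice = exclude_by_mode(once)
    assert once.included == twice.included
    assert once.excluded_auto == twice.excluded_auto
    assert once.n_beats == twice.n_beats


def test_all_zero_counts_is_analysis_error(toy_cfg):
    with pytest.raises(AnalysisError, match="no usable"):
        exclude_by_mode(_table_with_counts(toy_cfg, [0, 0, 0, 0]))


def test_silence_and_unsilence_round_trip(toy_cfg):
    base = exclude_by_mode(_table_with_counts(toy_cfg, [10, 10, 10, 10]))
    quiet = silence(base, ["B1"])
    assert quiet.silenced_manual == {"B1"}
    assert quiet.included == {"A1", "A2", "B2"}
    back = unsilence(quiet, ["B1"])
    assert back.included == base.included
    assert back.excluded_auto == base.excluded_auto
    assert back.silenced_manual == frozenset()
    assert back.n_beats == base.n_beats


def test_silence_unknown_label_errors(toy_cfg):
    base = exclude_by_mode(_table_with_counts(toy_cfg, [10, 10, 10, 10]))
    with pytest.raises(KeyError, match="Z9"):
        silence(base, ["Z9"])


def test_silence_all_is_analysis_error(toy_cfg):
    base = exclude_by_mode(_table_with_counts(toy_cfg, [10, 10, 10, 10]))
    with pytest.raises(AnalysisError):
        silence(base, list(toy_cfg.labels))


def test_partition_invariant_after_silencing(toy_cfg):
    table = silence(exclude_by_mode(_table_with_counts(toy_cfg, [10, 10, 10, 9])), ["A1"])
    union = table.included | table.excluded_auto | table.silenced_manual
    assert union == set(toy_cfg.labels)
    assert not (table.included & table.silenced_manual)
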