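"""Signal filtering, per-electrode beat detection, and electrode curation.

A cardiomyocyte monolayer's field potential shows one sharp R-wave-like spike
per beat. Detection is scipy peak finding on each electrode trace, controlled
by two parameters users actually tune on noisy cultures: a minimum peak
height (uV) and a minimum peak separation (ms). Extracellular R-like spikes
are usually negative-going, but inverted electrodes occur, so polarity is
resolved per electrode: "auto" searches both orientations and keeps the one
with the larger median peak amplitude.

Electrode curation happens in two stages. Automated exclusion computes the
per-electrode beat-count mode across the array and drops every electrode
whose count deviates from it, leaving a rectangular beats x electrodes
problem. Manual silencing removes named electrodes regardless of count (it
takes precedence over inclusion) and is reversible; the mode/exclusion pass
is recomputed over the remaining electrodes.

Peak times are refined to sub-sample precision by a parabolic fit through the
three samples around each detected peak (``refine=False`` restores plain
sample-index times); spatial metrics downstream divide by time differences,
so unbiased, low-jitter peak times matter more here than in rate statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
from scipy import signal as _sig

from .io import Recording

__all__ = [
    "FilterSpec",
    "BeatDetectParams",
    "BeatTable",
    "AnalysisError",
    "apply_filter",
    "detect_beats",
    "exclude_by_mode",
    "silence",
    "unsilence",
    "find_beats",
]


class AnalysisError(RuntimeError):
    """Raised when an analysis stage cannot proceed (e.g. no usable electrodes)."""


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth filter: kind, cutoff(s) in Hz, order."""

    kind: Literal["lowpass", "highpass", "bandpass"]
    cutoff_hz: float | tuple[float, float]
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "bandpass":
            lo, hi = self.cutoff_hz  # type: ignore[misc]
            if not lo < hi:
                raise ValueError(f"bandpass cutoffs must satisfy low < high, got {self.cutoff_hz}")
        elif not np.isscalar(self.cutoff_hz):
            raise ValueError(f"{self.kind} filter takes a single cutoff")


@dataclass(frozen=True)
class BeatDetectParams:
    """Peak-detection parameters (defaults suit ~100 uV+ field potentials)."""

    min_height: float = 100.0  # uV
    min_distance: float = 250.0  # ms
    polarity: Literal["negative", "positive", "auto"] = "auto"
    filter: FilterSpec | None = None
    refine: bool = True

    def __post_init__(self) -> None:
        if self.min_height <= 0 or self.min_distance <= 0:
            raise ValueError("min_height and min_distance must be positive")


@dataclass(frozen=True, eq=False)
class BeatTable:
    """Detected beats per electrode plus the curation state of the array.

    ``peaks[label]`` is an (n, 3) array of (sample_index, time_ms, amplitude_uV)
    for every raw detection on that electrode; curation never discards raw
    peaks, it only moves labels between ``included``, ``excluded_auto`` and
    ``silenced_manual`` (which always partition ``cfg.labels``). After
    :func:`exclude_by_mode`, ``n_beats`` is the dataset-wide beat count and
    every included electrode has exactly that many peaks.
    """

    cfg: "object"
    peaks: dict[str, np.ndarray]
    polarity: dict[str, int]
    included: frozenset[str]
    excluded_auto: frozenset[str] = frozenset()
    silenced_manual: frozenset[str] = frozenset()
    n_beats: int | None = None
    params: BeatDetectParams = field(default_factory=BeatDetectParams)

    @property
    def included_ordered(self) -> tuple[str, ...]:
        """Included labels in acquisition channel order."""
        return tuple(l for l in self.cfg.labels if l in self.included)

    def counts(self) -> dict[str, int]:
        return {l: len(self.peaks[l]) for l in self.cfg.labels}

    def peak_times(self, label: str) -> np.ndarray:
        return self.peaks[label][:, 1]


def apply_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase (forward-backward) Butterworth filtering of every electrode."""
    nyq = rec.sample_rate / 2.0
    cut = np.atleast_1d(np.asarray(spec.cutoff_hz, dtype=float))
    if np.any(cut <= 0) or np.any(cut >= nyq):
        raise ValueError(f"cutoff(s) {spec.cutoff_hz} Hz must lie in (0, Nyquist={nyq:g} Hz)")
    wn = (float(cut[0]), float(cut[1])) if spec.kind == "bandpass" else float(cut[0])
    sos = _sig.butter(spec.order, wn, btype=spec.kind, fs=rec.sample_rate, output="sos")
    filt = _sig.sosfiltfilt(sos, rec.voltages, axis=1)
    return Recording(time=rec.time, voltages=filt, cfg=rec.cfg, source=rec.source)


def _refine_peak(w: np.ndarray, i: int, time: np.ndarray) -> tuple[float, float]:
    """Sub-sample peak time/height by a parabola through (i-1, i, i+1)."""
    if i == 0 or i == len(w) - 1:
        return float(time[i]), float(w[i])
    y0, y1, y2 = w[i - 1], w[i], w[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep the sample
        return float(time[i]), float(w[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = time[1] - time[0]
    return float(time[i] + delta * dt), float(y1 - 0.25 * (y0 - y2) * delta)


def _find_on(w: np.ndarray, params: BeatDetectParams, dt: float) -> np.ndarray:
    dist = max(1, int(round(params.min_distance / dt)))
    idx, _ = _sig.find_peaks(w, height=params.min_height, distance=dist)
    return idx


def detect_beats(rec: Recording, params: BeatDetectParams | None = None) -> BeatTable:
    """Detect R-wave-like peaks on every electrode (pre-exclusion table).

    Zero peaks on an electrode is a valid outcome; the mode-based exclusion
    pass handles it downstream.
    """
    params = params or BeatDetectParams()
    if rec.time[-1] - rec.time[0] < 2 * params.min_distance:
        raise AnalysisError("recording shorter than twice the minimum peak distance")
    work = rec if params.filter is None else apply_filter(rec, params.filter)
    peaks: dict[str, np.ndarray] = {}
    polarity: dict[str, int] = {}
    for row, label in enumerate(rec.cfg.labels):
        v = work.voltages[row]
        if params.polarity == "positive":
            pol = 1
        elif params.polarity == "negative":
            pol = -1
        else:
            ip = _find_on(v, params, rec.dt)
            im = _find_on(-v, params, rec.dt)
            mp = np.median(v[ip]) if ip.size else 0.0
            mm = np.median(-v[im]) if im.size else 0.0
            pol = 1 if mp >= mm else -1
        w = pol * v
        idx = _find_on(w, params, rec.dt)
        if params.refine:
            rows = [(_i, *_refine_peak(w, _i, rec.time)) for _i in idx]
        else:
            rows = [(_i, float(rec.time[_i]), float(w[_i])) for _i in idx]
        peaks[label] = np.array(rows, dtype=float).reshape(-1, 3)
        polarity[label] = pol
    return BeatTable(
        cfg=rec.cfg, peaks=peaks, polarity=polarity,
        included=frozenset(rec.cfg.labels), params=params,
    )


def _beat_count_mode(counts: Iterable[int]) -> int:
    """Mode of beat counts; ties broken toward the larger count."""
    vals, freq = np.unique(np.fromiter(counts, dtype=int), return_counts=True)
    best = vals[freq == freq.max()]
    return int(best.max())


def exclude_by_mode(table: BeatTable) -> BeatTable:
    """Exclude electrodes whose beat count deviates from the dataset mode."""
    active = [l for l in table.cfg.labels if l not in table.silenced_manual]
    if not active:
        raise AnalysisError("no usable electrodes: all are silenced")
    counts = {l: len(table.peaks[l]) for l in active}
    mode = _beat_count_mode(counts.values())
    if mode == 0:
        raise AnalysisError("no usable electrodes: modal beat count is zero")
    included = frozenset(l for l in active if counts[l] == mode)
    excluded = frozenset(l for l in active if counts[l] != mode)
    return replace(table, included=included, excluded_auto=excluded, n_beats=mode)


def silence(table: BeatTable, labels: Iterable[str]) -> BeatTable:
    """Manually silence electrodes and recompute exclusion over the rest."""
    labels = set(labels)
    for l in labels:
        if l not in table.cfg.labels:
            raise KeyError(f"cannot silence unknown electrode {l!r}")
    return exclude_by_mode(
        replace(table, silenced_manual=frozenset(table.silenced_manual | labels))
    )


def unsilence(table: BeatTable, labels: Iterable[str]) -> BeatTable:
    """Reverse manual silencing (the analogue of re-running beat finding)."""
    labels = set(labels)
    for l in labels:
        if l not in table.cfg.labels:
            raise KeyError(f"cannot un-silence unknown electrode {l!r}")
    return exclude_by_mode(
        replace(table, silenced_manual=frozenset(table.silenced_manual - labels))
    )


def find_beats(
    rec: Recording,
    params: BeatDetectParams | None = None,
    silenced: Iterable[str] = (),
) -> BeatTable:
    """Detection + silencing + mode exclusion in one call (the usual entry point)."""
    table = detect_beats(rec, params)
    silenced = set(silenced)
    if silenced:
        return silence(table, silenced)
    return exclude_by_mode(table)
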