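"""Per-beat, per-electrode field-potential property maps.

All maps are beats x electrodes pandas DataFrames (rows = beat index,
columns = included electrode labels in channel order, NaN = undefined):

* **time lag** — R-peak time minus the per-beat minimum over electrodes; the
  earliest (pacemaker) electrode reads exactly 0 ms.
* **LAT** — local activation time: the instant of the maximal negative
  derivative (intrinsicoid deflection) after the R peak, normalized per beat
  the same way as the time lag.
* **dV/dt_max** — maximum upstroke slope before the R peak, backward finite
  differences, uV/ms.
* **amplitude** — positive plus negative excursion around the R peak (max
  minus min of the raw trace in a short window), uV.
* **beat intervals** — successive event-time differences per electrode, ms.
* **CV** — conduction velocity: electrode distance from the per-beat
  zero-LAT reference divided by the LAT difference, um/ms.

Derivative-based metrics operate on the polarity-oriented trace (negated for
negative-going electrodes) so "upstroke" and "downstroke" have a consistent
meaning regardless of the recorded sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beats import BeatTable
from .geometry import ElectrodeConfig, distance
from .io import Recording

__all__ = [
    "PropertyMaps",
    "time_lag_map",
    "raw_peak_times",
    "local_activation_time",
    "upstroke_velocity",
    "beat_amplitude",
    "beat_intervals",
    "conduction_velocity",
    "compute_property_maps",
]

#: search window after the R peak for the LAT downstroke, ms (capped at half
#: the minimum beat interval so it never reaches the next beat or the T wave
#: dominates; see methods note)
LAT_WINDOW_MS = 150.0
#: search window before the R peak for the maximum upstroke slope, ms
DVDT_WINDOW_MS = 50.0
#: half-width of the amplitude window around the R peak, ms
AMP_WINDOW_MS = 25.0


def _frame(table: BeatTable, values: np.ndarray) -> pd.DataFrame:
    cols = table.included_ordered
    return pd.DataFrame(values, columns=list(cols), index=pd.RangeIndex(table.n_beats, name="beat"))


def raw_peak_times(table: BeatTable) -> pd.DataFrame:
    """R-peak times (ms) as a beats x electrodes frame."""
    if table.n_beats is None:
        raise ValueError("beat table not finalized: run exclude_by_mode first")
    cols = table.included_ordered
    data = np.column_stack([table.peak_times(l) for l in cols]) if cols else np.empty((0, 0))
    return _frame(table, data)


def time_lag_map(table: BeatTable) -> pd.DataFrame:
    """Normalized pacemaker time lag: per-beat peak time minus its minimum."""
    t = raw_peak_times(table)
    return t.sub(t.min(axis=1), axis=0)


def _beat_window_samples(table: BeatTable, rec: Recording) -> int:
    """Half the minimum beat interval, in samples (LAT window cap)."""
    t = raw_peak_times(table).to_numpy()
    if t.shape[0] >= 2:
        min_iv = float(np.nanmin(np.diff(t, axis=0)))
    else:
        min_iv = rec.time[-1] - rec.time[0]
    return max(2, int(round(min(LAT_WINDOW_MS, min_iv / 2.0) / rec.dt)))


def _refine_argext(d: np.ndarray, j: int, t: np.ndarray) -> float:
    """Sub-sample location of a local extremum of sequence d (parabolic)."""
    if j == 0 or j == len(d) - 1:
        return float(t[j])
    y0, y1, y2 = d[j - 1], d[j], d[j + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(t[j])
    delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    return float(t[j] + delta * (t[1] - t[0]))


def local_activation_time(
    rec: Recording, table: BeatTable, *, normalized: bool = True, refine: bool = True
) -> pd.DataFrame:
    """LAT map: time of maximal negative derivative after each R peak.

    ``normalized=False`` returns raw LAT times (ms); the default subtracts the
    per-beat minimum (same convention as the time-lag map). A beat whose
    search window is truncated by the end of the recording, or whose window
    contains no negative derivative, is NaN.
    """
    if table.n_beats is None:
        raise ValueError("beat table not finalized: run exclude_by_mode first")
    win = _beat_window_samples(table, rec)
    cols = table.included_ordered
    out = np.full((table.n_beats, len(cols)), np.nan)
    dt = rec.dt
    for ci, label in enumerate(cols):
        w = table.polarity[label] * rec.trace(label)
        d = np.diff(w) / dt  # d[i] = backward difference at sample i+1
        for b, (pidx, _, _) in enumerate(table.peaks[label][:, :3]):
            i0 = int(pidx)
            hi = i0 + win
            if hi > len(d):
                continue  # truncated by recording end
            seg = d[i0:hi]  # derivatives at samples i0+1 .. i0+win
            if seg.size < 2 or np.min(seg) >= 0:
                continue  # monotone non-decreasing: no intrinsicoid deflection
            j = int(np.argmin(seg))
            t_at = rec.time[i0 + 1 + j]
            if refine:
                t_at = _refine_argext(-seg, j, rec.time[i0 + 1 : hi + 1])
            out[b, ci] = t_at
    df = _frame(table, out)
    if normalized:
        df = df.sub(df.min(axis=1), axis=0)
    return df


def upstroke_velocity(rec: Recording, table: BeatTable) -> pd.DataFrame:
    """dV/dt_max: maximum backward-difference slope before each R peak, uV/ms."""
    if table.n_beats is None:
        raise ValueError("beat table not finalized: run exclude_by_mode first")
    win = max(2, int(round(DVDT_WINDOW_MS / rec.dt)))
    cols = table.included_ordered
    out = np.full((table.n_beats, len(cols)), np.nan)
    for ci, label in enumerate(cols):
        w = table.polarity[label] * rec.trace(label)
        d = np.diff(w) / rec.dt
        for b, (pidx, _, _) in enumerate(table.peaks[label][:, :3]):
            i0 = int(pidx)
            lo = max(0, i0 - win)
            seg = d[lo:i0]  # slopes ending at samples lo+1 .. i0
            if seg.size < 1:
                continue
            out[b, ci] = float(np.max(seg))
    return _frame(table, out)


def beat_amplitude(rec: Recording, table: BeatTable) -> pd.DataFrame:
    """Peak-to-peak excursion (positive lobe + |negative lobe|) around the R peak, uV."""
    if table.n_beats is None:
        raise ValueError("beat table not finalized: run exclude_by_mode first")
    win = max(1, int(round(AMP_WINDOW_MS / rec.dt)))
    cols = table.included_ordered
    out = np.full((table.n_beats, len(cols)), np.nan)
    for ci, label in enumerate(cols):
        v = rec.trace(label)
        for b, (pidx, _, _) in enumerate(table.peaks[label][:, :3]):
            i0 = int(pidx)
            seg = v[max(0, i0 - win) : i0 + win + 1]
            out[b, ci] = float(np.max(seg) - np.min(seg))
    return _frame(table, out)


def beat_intervals(event_times: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-electrode beat-to-beat intervals (ms): diff of successive event times.

    ``event_times`` is a beats x electrodes frame (typically raw LAT times,
    falling back to R-peak times where LAT is undefined).
    """
    return {
        label: np.diff(event_times[label].to_numpy())
        for label in event_times.columns
    }


def _cv_reference(lat_row: pd.Series, cfg: ElectrodeConfig) -> str | None:
    """Reference electrode for CV: the zero-LAT electrode nearest the centroid
    of all zero-LAT electrodes (ties broken by channel order)."""
    finite = lat_row.dropna()
    if finite.empty:
        return None
    zeros = [l for l in finite.index if finite[l] == finite.min()]
    pts = np.array([cfg.coords[l] for l in zeros])
    centroid = pts.mean(axis=0)
    d = np.hypot(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    order = {l: i for i, l in enumerate(cfg.labels)}
    best = min(zip(zeros, d), key=lambda ld: (ld[1], order[ld[0]]))
    return best[0]


def conduction_velocity(lat: pd.DataFrame, cfg: ElectrodeConfig) -> pd.DataFrame:
    """CV map: distance from the per-beat reference electrode over delta-LAT, um/ms.

    The reference electrode (LAT 0) is NaN by construction, as is any
    non-reference electrode with delta-LAT == 0 (undefined, not infinite).
    """
    out = pd.DataFrame(np.nan, index=lat.index, columns=lat.columns)
    for b in lat.index:
        row = lat.loc[b]
        ref = _cv_reference(row, cfg)
        if ref is None:
            continue
        for l in lat.columns:
            dl = row[l] - row[ref]
            if np.isfinite(dl) and dl > 0:
                out.loc[b, l] = distance(cfg, ref, l) / dl
    return out


@dataclass
class PropertyMaps:
    """Bundle of every per-beat property map plus the interval vectors."""

    time_lag: pd.DataFrame
    lat: pd.DataFrame
    lat_raw: pd.DataFrame
    dvdt_max: pd.DataFrame
    amplitude: pd.DataFrame
    cv: pd.DataFrame
    intervals: dict[str, np.ndarray]
    fpd: pd.DataFrame | None = None

    def interval_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals)


def compute_property_maps(rec: Recording, table: BeatTable) -> PropertyMaps:
    """Compute all property maps for a curated beat table."""
    lag = time_lag_map(table)
    lat_raw = local_activation_time(rec, table, normalized=False)
    lat = lat_raw.sub(lat_raw.min(axis=1), axis=0)
    event_times = lat_raw.fillna(raw_peak_times(table))
    return PropertyMaps(
        time_lag=lag,
        lat=lat,
        lat_raw=lat_raw,
        dvdt_max=upstroke_velocity(rec, table),
        amplitude=beat_amplitude(rec, table),
        cv=conduction_velocity(lat, rec.cfg),
        intervals=beat_intervals(event_times),
    )
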