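"""Field potential duration via the trapezoid T-wave-endpoint method.

The FPD is the field-potential analogue of the QT interval: the time from
the R-wave-like peak to the end of the repolarization (T) wave. The T-wave
end is notoriously ill-defined on a sampled, noisy trace; the trapezoid
method makes it reproducible. With the T deflection oriented positive:

1. find the T peak as the most prominent deflection from baseline in a
   window after the R peak (default 120-500 ms, truncated 50 ms before the
   next beat);
2. fix point 1 at (x_m, y_m), the maximum downslope (most negative dV/dt)
   on the return-to-baseline limb after the T peak;
3. fix point 2 at (x_r, y_r), a configurable 50-200 ms past the T peak
   (default 150 ms);
4. slide a mobile point (x_i, y_i) along the trace between them and take
   the T end as the x_i maximizing the trapezoid area

       A(x_i) = 0.5 * (y_m - y_i) * (2*x_r - x_i - x_m).

The area is affine in y, so the endpoint is invariant under voltage scaling
and offset, and negative T waves are handled by mirroring. The candidate set
is finite (every sample between x_m and x_r), so an exhaustive scan is both
the implementation and its own reference.

On noisy traces the T limb is smoothed (Savitzky-Golay) before derivative
and area evaluation; the R-peak time itself comes from the beat table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .beats import BeatTable
from .io import Recording

__all__ = ["TWaveFit", "FpdParams", "detect_t_wave", "t_wave_end", "fpd_map"]


@dataclass(frozen=True)
class FpdParams:
    """Tunable parameters of T-wave detection and endpoint search."""

    t_search_ms: tuple[float, float] = (120.0, 500.0)  # window after R peak
    r_offset_ms: float = 150.0  # distal fixed point, 50-200 ms past T peak
    min_t_amplitude: float = 20.0  # uV; below this the T wave is "missing"
    smooth_ms: float = 41.0  # Savitzky-Golay window, sized to the T-wave timescale; 0 disables
    guard_ms: float = 50.0  # truncate search this far before the next beat

    def __post_init__(self) -> None:
        if not 50.0 <= self.r_offset_ms <= 200.0:
            raise ValueError("distal fixed point must sit 50-200 ms past the T peak")


@dataclass(frozen=True)
class TWaveFit:
    """One T-wave endpoint determination (times in ms, voltages in uV)."""

    t_peak: float
    x_m: float
    y_m: float
    x_r: float
    y_r: float
    t_end: float
    fpd: float


def _smooth(seg: np.ndarray, dt: float, smooth_ms: float) -> np.ndarray:
    if smooth_ms <= 0:
        return seg
    n = int(round(smooth_ms / dt)) | 1  # odd
    if n < 5 or n >= seg.size:
        return seg
    return savgol_filter(seg, n, polyorder=2)


def detect_t_wave(
    rec: Recording, table: BeatTable, params: FpdParams | None = None
) -> pd.DataFrame:
    """T-peak times (ms) per electrode/beat; NaN where no T wave is found."""
    params = params or FpdParams()
    if table.n_beats is None:
        raise ValueError("beat table not finalized: run exclude_by_mode first")
    cols = table.included_ordered
    out = np.full((table.n_beats, len(cols)), np.nan)
    for ci, label in enumerate(cols):
        for b in range(table.n_beats):
            fit = _t_fit(rec, table, label, b, params, want="peak")
            if fit is not None:
                out[b, ci] = fit
    return pd.DataFrame(out, columns=list(cols), index=pd.RangeIndex(table.n_beats, name="beat"))


def t_wave_end(
    time: np.ndarray,
    volt: np.ndarray,
    t_peak: float,
    r_offset_ms: float = 150.0,
    *,
    sign: float = 1.0,
) -> TWaveFit | None:
    """Trapezoid-method T endpoint on a single trace segment.

    ``volt`` is the (already smoothed, if desired) trace on ``time``; ``sign``
    mirrors negative T waves (+1 if the T deflection is positive-going).
    Returns None for a degenerate flat tail.
    """
    dt = time[1] - time[0]
    w = sign * volt
    ip = int(np.argmin(np.abs(time - t_peak)))
    ir = int(np.argmin(np.abs(time - (t_peak + r_offset_ms))))
    if ir <= ip + 2:
        return None
    d = np.diff(w[ip : ir + 1]) / dt
    if d.size == 0 or np.min(d) >= 0:
        return None
    im = ip + 1 + int(np.argmin(d))  # max downslope on the return limb
    if ir <= im:
        return None
    x_m, y_m = float(time[im]), float(w[im])
    x_r, y_r = float(time[ir]), float(w[ir])
    xi = time[im : ir + 1]
    yi = w[im : ir + 1]
    if np.allclose(yi, yi[0]):
        return None  # flat tail: every trapezoid has the same (zero) height
    area = 0.5 * (y_m - yi) * (2.0 * x_r - xi - x_m)
    iend = im + int(np.argmax(area))
    return TWaveFit(
        t_peak=float(t_peak), x_m=x_m, y_m=sign * y_m, x_r=x_r, y_r=sign * y_r,
        t_end=float(time[iend]), fpd=np.nan,
    )


def _t_fit(rec, table, label, b, params: FpdParams, want: str):
    """Shared T-peak + endpoint machinery for one electrode/beat."""
    peaks = table.peaks[label]
    r_idx = int(peaks[b, 0])
    r_time = peaks[b, 1]
    dt = rec.dt
    lo = r_idx + int(round(params.t_search_ms[0] / dt))
    hi = r_idx + int(round(params.t_search_ms[1] / dt))
    if b + 1 < len(peaks):  # keep clear of the next beat
        hi = min(hi, int(peaks[b + 1, 0]) - int(round(params.guard_ms / dt)))
    # leave room for the distal fixed point past the T peak
    hi_full = min(len(rec.time) - 1, hi + int(round(params.r_offset_ms / dt)) + 1)
    if hi <= lo + 4 or hi_full <= hi:
        return None
    v = rec.trace(label)[lo : hi_full + 1].astype(float)
    t = rec.time[lo : hi_full + 1]
    v = _smooth(v, dt, params.smooth_ms)
    base = float(np.median(v))
    dev = v[: hi - lo + 1] - base
    j = int(np.argmax(np.abs(dev)))
    if abs(dev[j]) < params.min_t_amplitude:
        return None
    t_peak = float(t[j])
    if want == "peak":
        return t_peak
    sign = 1.0 if dev[j] >= 0 else -1.0
    fit = t_wave_end(t, v, t_peak, params.r_offset_ms, sign=sign)
    if fit is None:
        return None
    return TWaveFit(
        t_peak=fit.t_peak, x_m=fit.x_m, y_m=fit.y_m, x_r=fit.x_r, y_r=fit.y_r,
        t_end=fit.t_end, fpd=fit.t_end - float(r_time),
    )


def fpd_map(
    rec: Recording, table: BeatTable, params: FpdParams | None = None
) -> pd.DataFrame:
    """FPD (ms) per electrode/beat: T-wave endpoint minus R-peak time.

    Beats with no detectable T wave, a truncated search window, or a
    degenerate flat tail carry NaN.
    """
    params = params or FpdParams()
    if table.n_beats is None:
        raise ValueError("beat table not finalized: run exclude_by_mode first")
    cols = table.included_ordered
    out = np.full((table.n_beats, len(cols)), np.nan)
    for ci, label in enumerate(cols):
        for b in range(table.n_beats):
            fit = _t_fit(rec, table, label, b, params, want="end")
            if fit is not None and fit.fpd > 0:
                out[b, ci] = fit.fpd
    return pd.DataFrame(out, columns=list(cols), index=pd.RangeIndex(table.n_beats, name="beat"))
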