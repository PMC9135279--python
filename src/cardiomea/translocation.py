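"""Pacemaker translocation detection and quiescent-period compilation.

The pacemaker region of a cardiomyocyte monolayer is not always spatially
stable: between beats it can jump to a different part of the culture. A
*translocation* is a displacement of the per-beat pacemaker location between
consecutive beats that strictly exceeds a distance threshold (default
500 um). The run of beats between two translocations, during which the
pacemaker stays put, is a *quiescent period*, reported both in beats and in
seconds.

Censoring rules: the first closed period is dropped (its true start is
unknown — the pacemaker may have settled there long before the recording
began) and the trailing, still-open period at the end of the recording never
counts (its end is unobserved). Displacement is measured between
consecutive-beat locations, not against a period anchor, so slow drift below
the threshold never triggers; anchor-based displacement is available behind
a flag for exploration.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import hypot

import numpy as np
import pandas as pd

from .geometry import ElectrodeConfig

__all__ = [
    "TranslocationParams",
    "QuiescentPeriod",
    "pacemaker_location_per_beat",
    "detect_translocations",
    "batch_translocations",
]


@dataclass(frozen=True)
class TranslocationParams:
    threshold: float = 500.0  # um; strictly exceeded to count as a jump
    anchor_based: bool = False  # measure displacement from the period anchor


@dataclass(frozen=True)
class QuiescentPeriod:
    """A closed run of beats with a stationary pacemaker."""

    start_beat: int
    end_beat: int
    duration: float  # s, beat_time(end) - beat_time(start)
    location: tuple[float, float]  # mean pacemaker location over the period, um
    source: str = ""

    @property
    def n_beats(self) -> int:
        return self.end_beat - self.start_beat + 1


def pacemaker_location_per_beat(
    lag_maps: pd.DataFrame, cfg: ElectrodeConfig
) -> np.ndarray:
    """Per-beat pacemaker location: centroid of the minimum-lag electrode(s), um."""
    out = np.full((len(lag_maps), 2), np.nan)
    for i, b in enumerate(lag_maps.index):
        row = lag_maps.loc[b].dropna()
        if row.empty:
            continue
        winners = row.index[row == row.min()]
        pts = np.array([cfg.coords[l] for l in winners])
        out[i] = pts.mean(axis=0)
    return out


def detect_translocations(
    locations: np.ndarray,
    beat_times_ms: np.ndarray,
    params: TranslocationParams | None = None,
) -> list[QuiescentPeriod]:
    """Scan per-beat pacemaker locations for threshold-exceeding jumps.

    Returns the closed quiescent periods after censoring (first closed period
    excluded, trailing open period dropped). An empty list is a valid result.
    """
    params = params or TranslocationParams()
    locations = np.asarray(locations, dtype=float).reshape(-1, 2)
    beat_times_ms = np.asarray(beat_times_ms, dtype=float)
    if len(locations) != len(beat_times_ms):
        raise ValueError("locations and beat times differ in length")
    if len(locations) < 2:
        raise ValueError("need at least 2 beats to detect translocations")
    periods: list[QuiescentPeriod] = []
    start = 0
    anchor = locations[0]
    for b in range(1, len(locations)):
        ref = anchor if params.anchor_based else locations[b - 1]
        d = hypot(locations[b, 0] - ref[0], locations[b, 1] - ref[1])
        if d > params.threshold:
            periods.append(_close(start, b - 1, locations, beat_times_ms))
            start = b
            anchor = locations[b]
    # the trailing open period [start, end] is censored; so is the first closed one
    return periods[1:]


def _close(start: int, end: int, loc: np.ndarray, t_ms: np.ndarray) -> QuiescentPeriod:
    return QuiescentPeriod(
        start_beat=start,
        end_beat=end,
        duration=float((t_ms[end] - t_ms[start]) / 1000.0),
        location=tuple(loc[start : end + 1].mean(axis=0)),
    )


def batch_translocations(
    runs: list[tuple[str, np.ndarray, np.ndarray]],
    params: TranslocationParams | None = None,
) -> list[QuiescentPeriod]:
    """Pool quiescent periods over many recordings.

    ``runs`` is a list of (source tag, per-beat locations, beat times in ms);
    provenance is retained on each pooled period. See
    :func:`cardiomea.pipeline.batch_quiescent_periods` for the file-level
    driver that starts from a batch manifest.
    """
    if not runs:
        raise ValueError("empty batch: no recordings to pool")
    pooled: list[QuiescentPeriod] = []
    for tag, loc, t_ms in runs:
        for p in detect_translocations(loc, t_ms, params):
            pooled.append(QuiescentPeriod(
                start_beat=p.start_beat, end_beat=p.end_beat, duration=p.duration,
                location=p.location, source=tag,
            ))
    return pooled
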