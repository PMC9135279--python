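"""End-to-end drivers composing the analysis stages.

The canonical workflow is: read the recording, find beats (filter, detect,
curate electrodes), compute the per-beat property maps, estimate the
pacemaker origin per beat, run the statistics of interest, and export a
multi-tab workbook. These helpers wire that sequence together for the CLI,
the batch driver and the acceptance/regression harnesses; each stage remains
individually importable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import beats as _beats
from . import distance_stats as _ds
from . import fpd as _fpd
from . import metrics as _metrics
from . import origin as _origin
from . import translocation as _tr
from .beats import BeatDetectParams, BeatTable
from .io import BatchManifest, Recording, read_recording, write_results_workbook
from .metrics import PropertyMaps
from .origin import OriginEstimate
from .translocation import QuiescentPeriod, TranslocationParams

__all__ = ["AnalysisResult", "analyze_recording", "batch_quiescent_periods", "results_tables"]


@dataclass
class AnalysisResult:
    """Everything one recording yields."""

    recording: Recording
    beat_table: BeatTable
    maps: PropertyMaps
    origins: list[OriginEstimate | None] = field(default_factory=list)
    quiescent_periods: list[QuiescentPeriod] = field(default_factory=list)
    pacemaker_locations: np.ndarray | None = None

    @property
    def beat_rate_bpm(self) -> float:
        """Dataset beat rate from the pacemaker-referenced event times."""
        t = _metrics.raw_peak_times(self.beat_table).min(axis=1).to_numpy()
        if t.size < 2:
            return float("nan")
        return 60000.0 / float(np.mean(np.diff(t)))


def analyze_recording(
    rec: Recording,
    params: BeatDetectParams | None = None,
    silenced: Iterable[str] = (),
    *,
    with_fpd: bool = True,
    with_origin: bool = True,
    translocation_params: TranslocationParams | None = None,
) -> AnalysisResult:
    """Run the full per-recording pipeline."""
    table = _beats.find_beats(rec, params, silenced)
    # derivative-based metrics run on the same (filtered) trace detection saw
    work = rec if params is None or params.filter is None else _beats.apply_filter(rec, params.filter)
    maps = _metrics.compute_property_maps(work, table)
    if with_fpd:
        maps.fpd = _fpd.fpd_map(work, table)
    res = AnalysisResult(recording=rec, beat_table=table, maps=maps)
    if with_origin:
        res.origins = _origin.estimate_origin(maps.time_lag, rec.cfg)
    loc = _tr.pacemaker_location_per_beat(maps.time_lag, rec.cfg)
    res.pacemaker_locations = loc
    pm_times = _metrics.raw_peak_times(table).min(axis=1).to_numpy()
    if len(loc) >= 2:
        res.quiescent_periods = _tr.detect_translocations(loc, pm_times, translocation_params)
    return res


def results_tables(res: AnalysisResult) -> dict[str, pd.DataFrame]:
    """Workbook tabs for :func:`cardiomea.io.write_results_workbook`."""
    m = res.maps
    tables: dict[str, pd.DataFrame] = {
        "pacemaker": m.time_lag,
        "lat": m.lat,
        "dvdt_max": m.dvdt_max,
        "cv": m.cv,
        "amplitude": m.amplitude,
        "interval": m.interval_frame(),
    }
    if m.fpd is not None:
        tables["fpd"] = m.fpd
    if res.origins:
        rows = [
            {"beat": e.beat, "h_um": e.h, "k_um": e.k, "r_um": e.r,
             "residual_um": e.residual, "at_bounds": e.at_bounds}
            for e in res.origins if e is not None
        ]
        if rows:
            tables["origin"] = pd.DataFrame(rows).set_index("beat")
    return tables


def property_distance_report(
    res: AnalysisResult, sigma: float = 3.0, cv_model: str = "satexp"
) -> dict[str, _ds.PropertyDistanceResult]:
    """Property-vs-distance regressions for the standard four properties."""
    m = res.maps
    out = {
        "time_lag": _ds.regress(m.time_lag, res.origins, res.recording.cfg,
                                kind="linear", sigma=sigma, name="time_lag"),
        "lat": _ds.regress(m.lat, res.origins, res.recording.cfg,
                           kind="linear", sigma=sigma, name="lat"),
        "dvdt_max": _ds.regress(m.dvdt_max, res.origins, res.recording.cfg,
                                kind="linear", sigma=sigma, name="dvdt_max"),
        "cv": _ds.regress(m.cv, res.origins, res.recording.cfg,
                          kind=("satexp" if cv_model == "satexp" else "linear"),
                          sigma=sigma, name="cv"),
    }
    return out


def batch_quiescent_periods(
    manifest: BatchManifest,
    params: BeatDetectParams | None = None,
    translocation_params: TranslocationParams | None = None,
) -> list[QuiescentPeriod]:
    """Detect and pool quiescent periods for every recording in a manifest."""
    if len(manifest) == 0:
        raise ValueError("empty batch manifest")
    runs = []
    for entry in manifest.entries:
        rec = read_recording(entry.path, entry.cfg_name)
        table = _beats.find_beats(rec, params)
        lag = _metrics.time_lag_map(table)
        loc = _tr.pacemaker_location_per_beat(lag, rec.cfg)
        pm_times = _metrics.raw_peak_times(table).min(axis=1).to_numpy()
        runs.append((entry.path, loc, pm_times))
    return _tr.batch_translocations(runs, translocation_params)


def export_workbook(res: AnalysisResult, path, params: dict | None = None) -> None:
    write_results_workbook(results_tables(res), path, params=params)
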