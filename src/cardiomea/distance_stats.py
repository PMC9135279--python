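"""Property-distance relationships: regression of each electrophysiological
property against distance from the estimated pacemaker origin.

If a stem-cell-derived monolayer recapitulates early cardiac development,
properties such as conduction velocity should vary systematically with
distance from the pacemaking region. Per beat, each electrode contributes a
point (x, y): x = Euclidean distance from the beat's fitted origin (h, k) to
the electrode, y = the property value there. Time lag, LAT and dV/dt_max get
ordinary least-squares lines; CV saturates with distance and gets an
asymptotic-exponential model

    y = c * (1 - exp(-x / lam)) + y0

fit by nonlinear least squares (a linear fallback is selectable). Goodness
of fit is R^2 = 1 - SS_res/SS_tot per beat; beats are ranked by R^2 (ties
broken by beat index) and the top 10 plus the mean over beats reported.

A single-pass sigma rule removes gross outliers before fitting: values
farther than ``sigma`` standard deviations from the property's mean (both
computed once, per property across all beats) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geometry import ElectrodeConfig
from .origin import OriginEstimate

__all__ = ["BeatFit", "PropertyDistanceResult", "exclude_outliers", "regress"]


def exclude_outliers(values: np.ndarray, sigma: float) -> np.ndarray:
    """Boolean mask of values within ``sigma`` SDs of the mean (single pass).

    Mean and SD are computed on the full finite sample; a constant sample
    (SD = 0) and ``sigma = inf`` both retain everything. NaNs are masked out.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.any() or not np.isfinite(sigma):
        return finite
    mu = float(np.mean(x[finite]))
    sd = float(np.std(x[finite]))
    if sd == 0:
        return finite
    return finite & (np.abs(x - mu) <= sigma * sd)


@dataclass(frozen=True)
class BeatFit:
    beat: int
    params: tuple[float, ...]
    r2: float
    n_points: int


@dataclass
class PropertyDistanceResult:
    property: str
    kind: str  # "linear" or "satexp"
    sigma_used: float
    per_beat: list[BeatFit] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def top10(self) -> list[BeatFit]:
        return sorted(self.per_beat, key=lambda f: (-f.r2, f.beat))[:10]

    @property
    def mean_r2(self) -> float:
        if not self.per_beat:
            return float("nan")
        return float(np.mean([f.r2 for f in self.per_beat]))


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else float("-inf")
    return 1.0 - ss_res / ss_tot


def _satexp(x, c, lam, y0):
    return c * (1.0 - np.exp(-x / lam)) + y0


def regress(
    prop: pd.DataFrame,
    origins: list[OriginEstimate | None],
    cfg: ElectrodeConfig,
    kind: str = "linear",
    sigma: float = 3.0,
    name: str = "",
) -> PropertyDistanceResult:
    """Per-beat regression of a property map against distance from the origin.

    ``prop`` is a beats x electrodes frame; ``origins`` the per-beat origin
    estimates (None entries are skipped). Beats with fewer than 4 retained
    points, or a non-converging nonlinear fit, are skipped with a note in
    ``n_excluded`` bookkeeping.
    """
    if kind not in ("linear", "satexp"):
        raise ValueError(f"unknown regression kind {kind!r}")
    res = PropertyDistanceResult(property=name or kind, kind=kind, sigma_used=sigma)
    # outlier pass: one mask over the whole property, not per beat
    allvals = prop.to_numpy().ravel()
    keep_flat = exclude_outliers(allvals, sigma)
    res.n_excluded = int(np.isfinite(allvals).sum() - keep_flat.sum())
    keep = keep_flat.reshape(prop.shape)
    coords = np.array([cfg.coords[l] for l in prop.columns])
    for i, b in enumerate(prop.index):
        est = origins[i] if i < len(origins) else None
        if est is None:
            continue
        y = prop.loc[b].to_numpy(dtype=float)
        m = keep[i] & np.isfinite(y)
        if m.sum() < 4:
            continue
        x = np.hypot(coords[m, 0] - est.h, coords[m, 1] - est.k)
        yv = y[m]
        if kind == "linear":
            a, b0 = np.polyfit(x, yv, 1)
            fit = BeatFit(int(b), (float(a), float(b0)), _r2(yv, a * x + b0), int(m.sum()))
        else:
            try:
                span = max(yv.max() - yv.min(), 1e-9)
                p0 = (span, max(float(np.median(x)), 1e-3), float(yv.min()))
                popt, _ = curve_fit(_satexp, x, yv, p0=p0, maxfev=5000)
            except RuntimeError:
                continue  # non-convergence: beat skipped
            fit = BeatFit(int(b), tuple(float(p) for p in popt),
                          _r2(yv, _satexp(x, *popt)), int(m.sum()))
        res.per_beat.append(fit)
    return res
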