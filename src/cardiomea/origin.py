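"""Pacemaker-origin estimation from the time-lag wavefront.

For each beat the normalized time-lag map defines an activation surface over
the electrode grid: the pacemaker sits at its minimum and activation spreads
outward. Isochrones (level sets of the lag surface) approximate the
propagating wavefront; for a radially spreading wave they are circular arcs
centered on the origin. The estimator therefore:

1. interpolates the lag map piecewise-linearly onto the electrode grid and
   extracts contour polylines at a fixed set of lag levels (deciles of the
   per-beat lag distribution);
2. keeps the level whose polyline carries the most vertices (the richest
   wavefront sample);
3. fits a circle ``r = sqrt((x-h)^2 + (y-k)^2)`` to those vertices by
   bounded nonlinear least squares, with the center constrained to the MEA
   bounding box and the radius to (0, array diagonal].

The fitted center (h, k) is the estimated pacemaker origin. Planar waves
(nearly straight isochrones) push the center to the box boundary; the
estimate is then flagged as bound-limited and its residual reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from contourpy import contour_generator
from scipy.optimize import least_squares

from .geometry import ElectrodeConfig

__all__ = [
    "OriginEstimate",
    "extract_wavefront",
    "fit_circle",
    "estimate_origin",
    "circumcircle",
]

#: contour levels as quantiles of the per-beat lag distribution
_LEVELS = np.arange(0.1, 1.0, 0.1)


class DegenerateWavefrontError(RuntimeError):
    """Raised when the lag surface has no usable level sets (all lags equal)."""


@dataclass(frozen=True)
class OriginEstimate:
    """A fitted pacemaker origin for one beat (coordinates in um)."""

    h: float
    k: float
    r: float
    residual: float  # RMS radial misfit, um
    wavefront: np.ndarray  # (n, 2) points used for the fit
    beat: int = -1
    at_bounds: bool = False  # center clamped to the array boundary


def extract_wavefront(
    lag_row: pd.Series, cfg: ElectrodeConfig, levels: np.ndarray | None = None
) -> np.ndarray:
    """Vertices of the most populous lag contour for one beat, as (n, 2) um.

    ``lag_row`` maps electrode label -> normalized lag (ms); NaN electrodes
    are ignored. Raises :class:`DegenerateWavefrontError` when every finite
    lag is identical (a flat surface has no level sets).
    """
    finite = lag_row.dropna()
    if len(finite) < 6:
        raise DegenerateWavefrontError("fewer than 6 electrodes with finite lag")
    vals = finite.to_numpy(dtype=float)
    if np.allclose(vals, vals[0]):
        raise DegenerateWavefrontError("degenerate wavefront: all lags equal")
    xs = sorted({cfg.coords[l][0] for l in cfg.labels})
    ys = sorted({cfg.coords[l][1] for l in cfg.labels})
    xi = {x: i for i, x in enumerate(xs)}
    yi = {y: i for i, y in enumerate(ys)}
    grid = np.full((len(ys), len(xs)), np.nan)
    for label, lag in finite.items():
        x, y = cfg.coords[label]
        grid[yi[y], xi[x]] = lag
    gen = contour_generator(
        x=np.asarray(xs), y=np.asarray(ys), z=np.ma.masked_invalid(grid),
        line_type="SeparateCode",
    )
    q = np.quantile(vals, levels if levels is not None else _LEVELS)
    best: np.ndarray | None = None
    for level in np.unique(q):
        lines, _ = gen.lines(float(level))
        for poly in lines:
            if best is None or len(poly) > len(best):
                best = np.asarray(poly)
    if best is None or len(best) < 3:
        raise DegenerateWavefrontError("no contour with enough vertices")
    return best


def circumcircle(p: np.ndarray) -> tuple[float, float, float] | None:
    """Closed-form circumcircle of 3 points; None if collinear."""
    (ax, ay), (bx, by), (cx, cy) = p
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if d == 0:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    return ux, uy, float(np.hypot(ax - ux, ay - uy))


def fit_circle(
    points: np.ndarray,
    cfg: ElectrodeConfig | None = None,
    *,
    init_toward: tuple[float, float] | None = None,
    beat: int = -1,
) -> OriginEstimate:
    """Bounded least-squares circle fit to wavefront points.

    Minimizes sum_i (||p_i - (h,k)|| - r)^2. With a config, (h, k) is
    constrained to the array bounding box and r to (0, diagonal]; without
    one, the fit is unconstrained. Initialization is deterministic: the point
    centroid (pulled halfway toward ``init_toward`` if given, e.g. the
    pacemaker electrode) with r0 = mean distance to it.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("need at least 3 points to fit a circle")
    h0, k0 = pts.mean(axis=0)
    if init_toward is not None:
        h0 = 0.5 * (h0 + init_toward[0])
        k0 = 0.5 * (k0 + init_toward[1])
    r0 = float(np.mean(np.hypot(pts[:, 0] - h0, pts[:, 1] - k0)))
    if cfg is not None:
        x0, y0, x1, y1 = cfg.bounding_box
        lb = np.array([x0, y0, 1e-9])
        ub = np.array([x1, y1, cfg.diagonal])
        p_init = np.clip([h0, k0, max(r0, 1.0)], lb + 1e-9, ub - 1e-9)
        bounds = (lb, ub)
    else:
        p_init = np.array([h0, k0, max(r0, 1e-6)])
        bounds = (-np.inf, np.inf)

    def resid(p):
        return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

    sol = least_squares(resid, p_init, bounds=bounds, method="trf",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success:
        raise RuntimeError(f"circle fit did not converge: {sol.message}")
    h, k, r = sol.x
    at_bounds = False
    if cfg is not None:
        tol = 1e-6
        at_bounds = bool(
            h - lb[0] < tol or ub[0] - h < tol or k - lb[1] < tol or ub[1] - k < tol
        )
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return OriginEstimate(h=float(h), k=float(k), r=float(r), residual=rms,
                          wavefront=pts, beat=beat, at_bounds=at_bounds)


def estimate_origin(
    lag_maps: pd.DataFrame, cfg: ElectrodeConfig
) -> list[OriginEstimate | None]:
    """Per-beat pacemaker origin estimates from a normalized lag map.

    Beats whose wavefront extraction fails (degenerate surface, too few
    electrodes) carry None; downstream statistics skip them.
    """
    out: list[OriginEstimate | None] = []
    for b in lag_maps.index:
        row = lag_maps.loc[b]
        try:
            pts = extract_wavefront(row, cfg)
        except DegenerateWavefrontError:
            out.append(None)
            continue
        finite = row.dropna()
        pm = finite.idxmin()
        out.append(fit_circle(pts, cfg, init_toward=cfg.coords[pm], beat=int(b)))
    return out
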