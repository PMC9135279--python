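"""Microelectrode-array geometry: electrode configurations and distances.

A planar MEA is a grid of extracellular electrodes. Every spatial metric in
this package (conduction velocity, pacemaker origin, translocation distance)
reduces to Euclidean distances between electrode centers, so the geometry is
kept as an explicit, auditable table: one row per electrode with its label,
acquisition channel index and center coordinates in micrometers.

The coordinate frame puts (0, 0) at the top-left electrode, x increasing
rightward and y increasing downward. Coordinates are electrode centers; the
electrode diameter is metadata only and enters no computation.

Registered layouts ship as plain CSV tables under ``cardiomea/layouts``
(schema: ``label,channel_index,x_um,y_um``). The 120-electrode table follows
the manufacturer's octagonal 12x12 grid (triangular corner cuts, row letters
skipping "I") with channel 1 = electrode F7; the full channel order beyond
that anchor is a documented package convention. New layouts are added by
dropping another CSV into the registry via :func:`register_layout`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from math import hypot

__all__ = [
    "ElectrodeConfig",
    "ConfigNotFoundError",
    "UnknownElectrodeError",
    "build_config",
    "register_layout",
    "registered_configs",
    "distance",
]


class ConfigNotFoundError(KeyError):
    """Raised when an electrode configuration name is not registered."""


class UnknownElectrodeError(KeyError):
    """Raised when an electrode label is not part of a configuration."""


@dataclass(frozen=True)
class ElectrodeConfig:
    """An MEA layout: labels in channel order plus center coordinates (um)."""

    name: str
    pitch: float
    diameter: float
    labels: tuple[str, ...]
    coords: dict[str, tuple[float, float]] = field(repr=False)

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of electrode centers, um."""
        xs = [xy[0] for xy in self.coords.values()]
        ys = [xy[1] for xy in self.coords.values()]
        return (min(xs), min(ys), max(xs), max(ys))

    @property
    def diagonal(self) -> float:
        x0, y0, x1, y1 = self.bounding_box
        return hypot(x1 - x0, y1 - y0)

    def require(self, label: str) -> tuple[float, float]:
        try:
            return self.coords[label]
        except KeyError:
            raise UnknownElectrodeError(
                f"electrode {label!r} is not part of configuration {self.name!r}"
            ) from None

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")
        if set(self.labels) != set(self.coords):
            raise ValueError("labels and coordinate map disagree")
        pts = list(self.coords.values())
        if len(set(pts)) != len(pts):
            raise ValueError("electrode coordinates are not unique")
        if any(x < 0 or y < 0 for x, y in pts):
            raise ValueError("electrode coordinates must be non-negative")


def _load_layout_csv(text: str, name: str, pitch: float, diameter: float) -> ElectrodeConfig:
    rows = [r for r in csv.reader(text.splitlines()) if r and not r[0].startswith("#")]
    header, body = rows[0], rows[1:]
    if header != ["label", "channel_index", "x_um", "y_um"]:
        raise ValueError(f"bad layout table header for {name!r}: {header}")
    body.sort(key=lambda r: int(r[1]))
    labels = tuple(r[0] for r in body)
    coords = {r[0]: (float(r[2]), float(r[3])) for r in body}
    return ElectrodeConfig(name=name, pitch=pitch, diameter=diameter, labels=labels, coords=coords)


def _builtin(name: str) -> ElectrodeConfig:
    text = resources.files("cardiomea.layouts").joinpath(f"{name}.csv").read_text()
    return _load_layout_csv(text, name, pitch=200.0, diameter=30.0)


_REGISTRY: dict[str, ElectrodeConfig] = {}


def register_layout(cfg: ElectrodeConfig) -> None:
    """Add (or replace) a configuration in the registry."""
    _REGISTRY[cfg.name] = cfg


def registered_configs() -> tuple[str, ...]:
    return tuple(sorted(set(_REGISTRY) | {"mcs_120", "mcs_60"}))


def build_config(name: str) -> ElectrodeConfig:
    """Return a validated electrode configuration by registered name.

    ``"mcs_120"`` and ``"mcs_60"`` (200 um pitch, 30 um diameter) are built in.
    """
    if name in _REGISTRY:
        return _REGISTRY[name]
    if name in ("mcs_120", "mcs_60"):
        cfg = _builtin(name)
        _REGISTRY[name] = cfg
        return cfg
    raise ConfigNotFoundError(
        f"unknown electrode configuration {name!r}; registered: {registered_configs()}"
    )


def distance(cfg: ElectrodeConfig, a: str, b: str) -> float:
    """Euclidean center-to-center distance between electrodes ``a`` and ``b``, um."""
    xa, ya = cfg.require(a)
    xb, yb = cfg.require(b)
    return hypot(xa - xb, ya - yb)
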