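"""Reading MEA ASCII exports, batch manifests, and writing results workbooks.

Recordings arrive as column-wise plain-text tables produced by the vendor's
ASCII conversion tool: the first column is time in milliseconds (fractional
for rates above 1 kHz), followed by one voltage column per electrode (uV) in
acquisition channel order (column 2 is electrode F7 for the 120-electrode
layout). Leading lines that fail numeric parsing are treated as headers and
skipped; both tab and whitespace delimiters are accepted. The decimal
separator is always ".".

Results are written to a single multi-tab ``.xlsx`` workbook, one tab per
computed property, first row = electrode labels, first column = beat index.
Batch manifests are ``.xlsx`` spreadsheets with columns ``file`` and
``config`` (one recording per row).
"""

from __future__ import annotations

import io as _stdio
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import ElectrodeConfig, build_config

__all__ = [
    "Recording",
    "BatchEntry",
    "BatchManifest",
    "FormatError",
    "read_recording",
    "write_results_workbook",
    "read_results_workbook",
    "read_batch_manifest",
    "write_batch_manifest",
]

#: relative tolerance on the uniformity of the sampling step
_DT_RTOL = 1e-4


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


@dataclass
class Recording:
    """A multichannel MEA recording bound to an electrode configuration.

    ``voltages`` is electrodes x samples in uV, row order = ``cfg.labels``
    (acquisition channel order); ``time`` is in ms, strictly increasing with a
    uniform step.
    """

    time: np.ndarray
    voltages: np.ndarray
    cfg: ElectrodeConfig
    source: str = "<memory>"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.shape[0] != self.cfg.n_electrodes:
            raise FormatError(
                f"{self.source}: expected {self.cfg.n_electrodes} voltage rows "
                f"for {self.cfg.name!r}, found {self.voltages.shape[0]}"
            )
        if self.voltages.shape[1] != self.time.size:
            raise FormatError(f"{self.source}: time/voltage length mismatch")
        dt = np.diff(self.time)
        if self.time.size < 2 or np.any(dt <= 0):
            raise FormatError(f"{self.source}: time column must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > _DT_RTOL * dt[0]:
            raise FormatError(f"{self.source}: sampling step is not uniform")

    @property
    def dt(self) -> float:
        """Sampling step, ms."""
        return float(self.time[1] - self.time[0])

    @property
    def sample_rate(self) -> float:
        """Sampling rate, Hz."""
        return 1000.0 / self.dt

    def trace(self, label: str) -> np.ndarray:
        return self.voltages[self.cfg.labels.index(label)]


def read_recording(path: str | os.PathLike, cfg: ElectrodeConfig | str) -> Recording:
    """Read a column-wise ASCII export into a :class:`Recording`.

    Leading non-numeric lines are skipped; the numeric body must have exactly
    ``1 + cfg.n_electrodes`` columns (time + one per electrode).
    """
    if isinstance(cfg, str):
        cfg = build_config(cfg)
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    for start, line in enumerate(lines):
        fields = line.split()
        if fields:
            try:
                [float(f) for f in fields]
                break
            except ValueError:
                continue
    else:
        raise FormatError(f"{path}: no numeric data found")
    body = "".join(lines[start:])
    try:
        data = np.loadtxt(_stdio.StringIO(body), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse numeric body ({exc})") from exc
    ncol = data.shape[1]
    if ncol != 1 + cfg.n_electrodes:
        raise FormatError(
            f"{path}: expected {1 + cfg.n_electrodes} columns "
            f"(time + {cfg.n_electrodes} electrodes for {cfg.name!r}), found {ncol}"
        )
    return Recording(time=data[:, 0], voltages=data[:, 1:].T, cfg=cfg, source=str(path))


# ---------------------------------------------------------------------------
# results workbook


def write_results_workbook(
    results: Mapping[str, pd.DataFrame],
    path: str | os.PathLike,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write computed property tables to a multi-tab ``.xlsx`` workbook.

    ``results`` maps tab name (e.g. ``"pacemaker"``, ``"lat"``, ``"cv"``) to a
    beats x electrodes DataFrame. A ``parameters`` provenance tab records the
    full parameter set when ``params`` is given.
    """
    results = {k: v for k, v in results.items() if v is not None}
    if not results:
        raise ValueError("no computed results to write")
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name, df in results.items():
            pd.DataFrame(df).to_excel(writer, sheet_name=name[:31])
        if params:
            prov = pd.DataFrame(
                {"parameter": list(params), "value": [repr(v) for v in params.values()]}
            )
            prov.to_excel(writer, sheet_name="parameters", index=False)


def read_results_workbook(path: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Read back a results workbook (inverse of :func:`write_results_workbook`)."""
    sheets = pd.read_excel(path, sheet_name=None, index_col=0)
    sheets.pop("parameters", None)
    return sheets


# ---------------------------------------------------------------------------
# batch manifests


@dataclass(frozen=True)
class BatchEntry:
    path: str
    cfg_name: str
    params: dict[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class BatchManifest:
    entries: tuple[BatchEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)


def read_batch_manifest(path: str | os.PathLike) -> BatchManifest:
    """Read a batch manifest spreadsheet (columns ``file``, ``config``).

    Extra columns are carried through as per-file parameters. Paths are
    resolved relative to the manifest's directory, must exist, and must be
    distinct; every config name must be registered.
    """
    path = Path(path)
    df = pd.read_excel(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "file" not in cols or "config" not in cols:
        raise FormatError(f"{path}: manifest needs 'file' and 'config' columns, found {list(df.columns)}")
    entries: list[BatchEntry] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        fpath = str(row[cols["file"]])
        if not os.path.isabs(fpath):
            fpath = str(path.parent / fpath)
        if fpath in seen:
            raise FormatError(f"{path}: row {i + 1}: duplicate file {fpath!r}")
        seen.add(fpath)
        if not os.path.exists(fpath):
            raise FormatError(f"{path}: row {i + 1}: file not found: {fpath!r}")
        cfg_name = str(row[cols["config"]])
        build_config(cfg_name)  # raises ConfigNotFoundError on unknown names
        extra = {
            c: row[cols[c]]
            for c in cols
            if c not in ("file", "config") and pd.notna(row[cols[c]])
        }
        entries.append(BatchEntry(path=fpath, cfg_name=cfg_name, params=extra))
    return BatchManifest(entries=tuple(entries))


def write_batch_manifest(entries: list[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write a minimal batch manifest from (file, config) pairs."""
    pd.DataFrame(entries, columns=["file", "config"]).to_excel(path, index=False)
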