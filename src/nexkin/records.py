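"""Time-course records and their on-disk CSV + JSON-sidecar format.

A :class:`TimeCourseRecord` is the unit of exchange between the generator
and the analysis stages: one observable time course — a fluorescence
trace, a hydrolyzed-GTP quench series, or an intact-fraction decay — plus
the experiment metadata needed to analyze it.  On disk it is a two-column
CSV (``time_s,signal``) with a ``<name>.meta.json`` sidecar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TimeCourseRecord", "read_timecourse", "write_timecourse"]

SCHEMA_TAG = "nexkin-timecourse-1"


@dataclass
class TimeCourseRecord:
    """One observable time course plus experiment metadata."""

    time_s: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.shape != self.signal.shape or self.time_s.ndim != 1:
            raise ValueError("time_s and signal must be 1-D arrays of equal length")
        if np.any(self.time_s < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be strictly increasing")

    def __eq__(self, other):
        if not isinstance(other, TimeCourseRecord):
            return NotImplemented
        return (
            np.array_equal(self.time_s, other.time_s)
            and np.array_equal(self.signal, other.signal)
            and self.meta == other.meta
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")


def write_timecourse(record: TimeCourseRecord, path) -> None:
    """Write CSV (17 significant digits, lossless) and JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,signal\n")
        for t, s in zip(record.time_s, record.signal):
            fh.write(f"{t:.17g},{s:.17g}\n")
    meta = dict(record.meta)
    meta["schema"] = SCHEMA_TAG
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True, default=float)


def read_timecourse(path) -> TimeCourseRecord:
    """Read a CSV time course; malformed rows are rejected by line number.

    A missing metadata sidecar produces a warning and a metadata-free
    record, which is still usable for bare exponential fits.
    """
    path = Path(path)
    times, signals = [], []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        cols = [c.strip() for c in header.split(",")]
        if cols != ["time_s", "signal"]:
            raise ValueError(
                f"{path}:1: expected header 'time_s,signal', got {header!r}"
            )
        for lineno, line in enumerate(fh, 2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns (time_s,signal), "
                    f"got {len(parts)}"
                )
            try:
                t, s = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
            if t < 0:
                raise ValueError(f"{path}:{lineno}: negative time {t}")
            times.append(t)
            signals.append(s)
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            meta = json.load(fh)
        meta.pop("schema", None)
    else:
        warnings.warn(
            f"no metadata sidecar for {path}; record is metadata-free",
            stacklevel=2,
        )
    return TimeCourseRecord(np.array(times), np.array(signals), meta)
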