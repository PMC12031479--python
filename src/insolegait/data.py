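"""Domain types and tabular I/O for insole ground-reaction-force recordings.

A recording is one foot's total vertical force sampled at 100 Hz during a
walking bout.  Missing samples (device faults) are carried as NaN in memory
and as empty fields on disk; they are never silently zero-filled.

The on-disk dialect is deliberately minimal and open: one CSV per foot with
columns ``sample_index,force_N`` plus a JSON sidecar holding the recording
metadata (subject, side, side role, body mass, days after surgery).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: standard gravity used to convert body mass to body weight (N)
GRAVITY = 9.81

#: the only supported sampling rate, Hz
SAMPLE_RATE_HZ = 100

#: names of the twelve stance-phase parameters, in report order
PARAMETER_NAMES = (
    "F_mean_TP",
    "F_total_max",
    "F_trendline_max_slope",
    "F_trendline_TP_slope",
    "L1_trendline_max",
    "L1_trendline_TP",
    "L2_trendline_max",
    "L2_trendline_TP",
    "Time_inter_max",
    "Time_inter_max_normalized",
    "Time_inter_TP",
    "Time_inter_TP_normalized",
)

#: parameters that require more than one surviving maximum
INTER_MAX_PARAMETERS = (
    "F_trendline_max_slope",
    "L1_trendline_max",
    "L2_trendline_max",
    "Time_inter_max",
    "Time_inter_max_normalized",
)


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class SideRole(str, Enum):
    INJURED = "injured"
    HEALTHY = "healthy"


class RecordingError(ValueError):
    """Raised for malformed recording files or invalid metadata."""


@dataclass
class RawRecording:
    """One foot's 100 Hz vertical force trace plus study metadata.

    ``forces`` holds newtons with NaN marking missing samples; sample ``k``
    of the array corresponds to raw sample index ``start_index + k``.
    """

    subject_id: str
    side: Side
    side_role: SideRole
    body_mass_kg: float
    days_after_surgery: int
    forces: np.ndarray
    sample_rate_hz: float = SAMPLE_RATE_HZ
    start_index: int = 0

    def __post_init__(self) -> None:
        self.side = Side(self.side)
        self.side_role = SideRole(self.side_role)
        if self.sample_rate_hz != SAMPLE_RATE_HZ:
            raise RecordingError(
                f"only {SAMPLE_RATE_HZ} Hz recordings are supported, "
                f"got {self.sample_rate_hz} Hz"
            )
        if not self.body_mass_kg > 0:
            raise RecordingError(f"body_mass_kg must be > 0, got {self.body_mass_kg}")
        if self.days_after_surgery < 0:
            raise RecordingError("days_after_surgery must be >= 0")
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 1:
            raise RecordingError("forces must be one-dimensional")
        with np.errstate(invalid="ignore"):
            if np.any(self.forces < 0):
                raise RecordingError("forces must be >= 0 N (or missing)")

    @property
    def n_samples(self) -> int:
        return self.forces.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class StanceEvent:
    """A contiguous above-threshold load event in raw samples.

    ``start_index``/``end_index`` are inclusive raw sample indices of the
    source recording.  ``samples`` holds the force sequence in newtons with
    bridged interior gaps already linearly interpolated, so the grid is
    uniform for downstream filtering and resampling.
    """

    source: RawRecording
    start_index: int
    end_index: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.end_index < self.start_index:
            raise ValueError("end_index must be >= start_index")
        if self.samples.size != self.end_index - self.start_index + 1:
            raise ValueError("samples length inconsistent with index range")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.source.sample_rate_hz

    @property
    def start_time_s(self) -> float:
        return self.start_index / self.source.sample_rate_hz


@dataclass
class NormalizedStance:
    """A stance phase resampled to 100 equidistant samples in %bodyweight.

    Two aligned variants are kept: ``y_filtered`` (Gaussian-smoothed, used
    for shape/landmark detection) and ``y_unfiltered`` (used to read off
    force values at the detected indices).  Internal indexing is 0-based,
    0..99; index ``i`` maps to absolute time
    ``stance_start_s + (i / 99) * duration_s``.
    """

    y_unfiltered: np.ndarray
    y_filtered: np.ndarray
    duration_s: float
    stance_start_s: float
    subject_id: str = ""
    side: Side = Side.LEFT
    side_role: SideRole = SideRole.HEALTHY
    days_after_surgery: int = 0

    def __post_init__(self) -> None:
        self.y_unfiltered = np.asarray(self.y_unfiltered, dtype=float)
        self.y_filtered = np.asarray(self.y_filtered, dtype=float)
        for name in ("y_unfiltered", "y_filtered"):
            arr = getattr(self, name)
            if arr.size != 100:
                raise ValueError(f"{name} must have exactly 100 entries, got {arr.size}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    def abs_time(self, index: float) -> float:
        """Absolute time (s) of normalized index 0..99."""
        return self.stance_start_s + (index / 99.0) * self.duration_s


# ---------------------------------------------------------------------------
# recording files
# ---------------------------------------------------------------------------

_HEADER = "sample_index,force_N"


def read_recording(
    path: str | Path,
    *,
    subject_id: str,
    side: Side | str,
    side_role: SideRole | str,
    body_mass_kg: float,
    days_after_surgery: int,
) -> RawRecording:
    """Read one foot's force trace from a ``sample_index,force_N`` CSV.

    Empty force fields are preserved as missing (NaN), never as 0 N.
    Raises :class:`RecordingError` naming the offending line for malformed
    rows, non-contiguous indices, or an empty file.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise RecordingError(f"{path}: empty file")
    start = 0
    if lines[0].strip().lower().replace(" ", "") == _HEADER.lower():
        start = 1
    rows: list[tuple[int, float]] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise RecordingError(f"{path}: line {lineno}: expected 2 fields, got {len(parts)}")
        try:
            idx = int(parts[0])
        except ValueError as exc:
            raise RecordingError(f"{path}: line {lineno}: bad sample index {parts[0]!r}") from exc
        raw = parts[1].strip()
        if raw == "" or raw.lower() in {"nan", "na"}:
            force = math.nan
        else:
            try:
                force = float(raw)
            except ValueError as exc:
                raise RecordingError(f"{path}: line {lineno}: bad force value {raw!r}") from exc
        rows.append((idx, force))
    if not rows:
        raise RecordingError(f"{path}: no data rows")
    indices = np.array([r[0] for r in rows])
    if np.any(np.diff(indices) != 1):
        bad = int(np.flatnonzero(np.diff(indices) != 1)[0])
        raise RecordingError(
            f"{path}: sample indices must be strictly increasing and unit-spaced "
            f"(violation after index {indices[bad]})"
        )
    return RawRecording(
        subject_id=subject_id,
        side=Side(side),
        side_role=SideRole(side_role),
        body_mass_kg=body_mass_kg,
        days_after_surgery=days_after_surgery,
        forces=np.array([r[1] for r in rows]),
        start_index=int(indices[0]),
    )


def write_recording(rec: RawRecording, path: str | Path, *, sidecar: bool = True) -> None:
    """Write a recording to CSV (+ JSON metadata sidecar).

    Missing samples become empty fields.  The sidecar is ``<path>.json``.
    """
    path = Path(path)
    out = [_HEADER]
    for k, f in enumerate(rec.forces):
        cell = "" if math.isnan(f) else repr(float(f))
        out.append(f"{rec.start_index + k},{cell}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
    if sidecar:
        write_sidecar(rec, path.with_suffix(path.suffix + ".json"))


def write_sidecar(rec: RawRecording, path: str | Path) -> None:
    meta = {
        "subject_id": rec.subject_id,
        "side": rec.side.value,
        "side_role": rec.side_role.value,
        "body_mass_kg": rec.body_mass_kg,
        "days_after_surgery": rec.days_after_surgery,
        "sample_rate_hz": rec.sample_rate_hz,
    }
    Path(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_sidecar(path: str | Path) -> dict:
    meta = json.loads(Path(path).read_text(encoding="utf-8"))
    rate = meta.get("sample_rate_hz", SAMPLE_RATE_HZ)
    if rate != SAMPLE_RATE_HZ:
        raise RecordingError(f"{path}: declared rate {rate} Hz is not supported")
    return meta


def read_recording_with_sidecar(path: str | Path) -> RawRecording:
    """Read a per-foot CSV together with its ``<name>.csv.json`` sidecar."""
    path = Path(path)
    meta = read_sidecar(path.with_suffix(path.suffix + ".json"))
    return read_recording(
        path,
        subject_id=meta["subject_id"],
        side=meta["side"],
        side_role=meta["side_role"],
        body_mass_kg=meta["body_mass_kg"],
        days_after_surgery=meta["days_after_surgery"],
    )


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

_TABLE_META_COLUMNS = ("subject_id", "side", "side_role", "days_after_surgery",
                       "n_strides", "regular_ratio")


def write_parameter_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-visit parameter table as CSV.

    One row per (subject, visit, side); absent parameters (omission rule for
    single-maximum strides, failed turning-point detection) are written as
    empty cells, never as zeros.
    """
    if table.empty:
        raise ValueError("parameter table is empty")
    cols = [c for c in _TABLE_META_COLUMNS if c in table.columns]
    cols += [p for p in PARAMETER_NAMES if p in table.columns]
    table.loc[:, cols].to_csv(path, index=False, na_rep="")


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" in df.columns:
        df["subject_id"] = df["subject_id"].astype(str)
    return df
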