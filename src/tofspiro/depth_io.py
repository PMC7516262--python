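"""Data model and on-disk formats for depth video and cohort tables.

A recording is a directory of 16-bit binary PGM frames (one per depth map,
integer millimetres, 0 = no return) plus a ``meta.json`` sidecar holding the
sensor geometry and per-frame timestamps.  Cohort tables are plain CSV.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import CohortFormatError, SequenceFormatError

__all__ = [
    "SensorGeometry",
    "DepthFrame",
    "DepthSequence",
    "SubjectRecord",
    "write_sequence",
    "read_sequence",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]

_FRAME_RE = re.compile(r"frame_(\d+)\.pgm$")
_MAX_DEPTH_MM = 65535  # 16-bit PGM ceiling


@dataclass(frozen=True)
class SensorGeometry:
    """Optical and timing parameters of the time-of-flight depth sensor.

    Defaults describe a 224x171-pixel sensor with a 62° (vertical) by 45°
    (horizontal) field of view running at 45 Hz with 2 mm depth
    quantization, seated 350 mm from the subject.
    """

    n_rows: int = 224
    n_cols: int = 171
    fov_vertical_deg: float = 62.0
    fov_horizontal_deg: float = 45.0
    frame_rate_hz: float = 45.0
    depth_quantum_mm: float = 2.0
    nominal_distance_mm: float = 350.0

    def __post_init__(self) -> None:
        for name in (
            "n_rows",
            "n_cols",
            "fov_vertical_deg",
            "fov_horizontal_deg",
            "frame_rate_hz",
            "depth_quantum_mm",
            "nominal_distance_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SensorGeometry.{name} must be positive")
        if self.fov_vertical_deg >= 180 or self.fov_horizontal_deg >= 180:
            raise ValueError("field of view must be below 180 degrees")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def sampling_interval_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    def pixel_pitch_mm(self, distance_mm: float) -> tuple[float, float]:
        """(row, col) footprint of one pixel on a plane at ``distance_mm``."""
        dv = 2.0 * distance_mm * math.tan(math.radians(self.fov_vertical_deg) / 2)
        dh = 2.0 * distance_mm * math.tan(math.radians(self.fov_horizontal_deg) / 2)
        return dv / self.n_rows, dh / self.n_cols

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "fov_vertical_deg": self.fov_vertical_deg,
            "fov_horizontal_deg": self.fov_horizontal_deg,
            "frame_rate_hz": self.frame_rate_hz,
            "depth_quantum_mm": self.depth_quantum_mm,
            "nominal_distance_mm": self.nominal_distance_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorGeometry":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            fov_vertical_deg=float(d["fov_vertical_deg"]),
            fov_horizontal_deg=float(d["fov_horizontal_deg"]),
            frame_rate_hz=float(d["frame_rate_hz"]),
            depth_quantum_mm=float(d["depth_quantum_mm"]),
            nominal_distance_mm=float(d["nominal_distance_mm"]),
        )


@dataclass
class DepthFrame:
    """One depth map: per-pixel sensor-to-surface distance in millimetres.

    ``validity`` is False where the sensor produced no return; ``depth`` is
    undefined (conventionally 0) at those pixels.
    """

    depth: np.ndarray
    timestamp: float
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2:
            raise ValueError("depth must be a 2-D array")
        if self.validity is None:
            self.validity = np.ones(self.depth.shape, dtype=bool)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != self.depth.shape:
                raise ValueError("validity shape must match depth shape")
        if np.any(self.depth[self.validity] <= 0):
            raise ValueError("valid depths must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass
class DepthSequence:
    """Time-ordered stack of depth frames with the sensor geometry."""

    frames: list[DepthFrame]
    geometry: SensorGeometry = field(default_factory=SensorGeometry)

    def __post_init__(self) -> None:
        shape = self.geometry.shape
        for k, f in enumerate(self.frames):
            if f.shape != shape:
                raise ValueError(
                    f"frame {k} shape {f.shape} does not match geometry {shape}"
                )
        ts = np.array([f.timestamp for f in self.frames])
        if len(ts) > 1:
            dt = np.diff(ts)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            nominal = self.geometry.sampling_interval_s
            if np.any(np.abs(dt - nominal) > 0.01 * nominal):
                raise ValueError(
                    "frame spacing departs from 1/frame_rate by more than 1%"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[DepthFrame]:
        return iter(self.frames)

    def __getitem__(self, k: int) -> DepthFrame:
        return self.frames[k]

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])

    @property
    def duration_s(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return self.frames[-1].timestamp - self.frames[0].timestamp


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort row: anthropometrics plus reference spirometry.

    Heights are cm, BMI kg/m², volumes mL.  ``group`` is ``healthy`` or
    ``AFL`` (airflow limitation).  Optional anterior-thorax indices carry the
    depth-camera measurement for the same subject.
    """

    subject_id: str
    height: float
    bmi: float
    fvc_spirometer: float
    fev1_spirometer: float
    group: str
    fvc_anterior: float | None = None
    fev1_anterior: float | None = None

    def __post_init__(self) -> None:
        if not 100 < self.height < 230:
            raise ValueError(f"height {self.height} cm outside (100, 230)")
        if not 10 < self.bmi < 60:
            raise ValueError(f"bmi {self.bmi} outside (10, 60)")
        if self.fvc_spirometer <= 0 or self.fev1_spirometer <= 0:
            raise ValueError("spirometer volumes must be positive")
        if self.fev1_spirometer > self.fvc_spirometer:
            raise ValueError("FEV1 cannot exceed FVC")
        if self.group not in ("healthy", "AFL"):
            raise ValueError(f"group must be 'healthy' or 'AFL', got {self.group!r}")

    @property
    def fev1_percent_spirometer(self) -> float:
        return 100.0 * self.fev1_spirometer / self.fvc_spirometer


COHORT_COLUMNS = [
    "subject_id",
    "height",
    "bmi",
    "fvc_spirometer",
    "fev1_spirometer",
    "group",
]
_OPTIONAL_COLUMNS = ["fvc_anterior", "fev1_anterior"]


def write_sequence(seq: DepthSequence, path: str | Path) -> Path:
    """Write a depth sequence as 16-bit PGM frames plus ``meta.json``.

    Depth is stored as integer millimetres (rounded), invalid pixels as 0.
    Round-trips with :func:`read_sequence` to 1 mm.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(seq.frames))))
    for k, frame in enumerate(seq.frames):
        depth = np.round(frame.depth).astype(np.int64)
        depth[~frame.validity] = 0
        if depth.max(initial=0) > _MAX_DEPTH_MM:
            raise SequenceFormatError(
                f"frame {k}: depth {depth.max()} mm exceeds 16-bit PGM range"
            )
        if np.any(depth[frame.validity] < 1):
            # valid sub-0.5 mm depths would collide with the invalid sentinel
            raise SequenceFormatError(f"frame {k}: valid depth rounds to 0 mm")
        Image.fromarray(depth.astype(np.uint16)).save(
            path / f"frame_{k:0{width}d}.pgm"
        )
    meta = seq.geometry.to_dict()
    meta["timestamps_s"] = [float(f.timestamp) for f in seq.frames]
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_sequence(path: str | Path) -> DepthSequence:
    """Read a depth sequence written by :func:`write_sequence`.

    Frames are ordered by the numeric index in their filename regardless of
    directory listing order; 0-valued pixels are flagged invalid.  Missing
    timestamps are regenerated from the frame rate.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SequenceFormatError(f"missing sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    geometry = SensorGeometry.from_dict(meta)

    entries: list[tuple[int, Path]] = []
    for p in path.iterdir():
        m = _FRAME_RE.search(p.name)
        if m:
            entries.append((int(m.group(1)), p))
    if not entries:
        raise SequenceFormatError(f"no PGM frames in {path}")
    entries.sort()

    timestamps = meta.get("timestamps_s")
    if timestamps is None:
        timestamps = [k / geometry.frame_rate_hz for k in range(len(entries))]
    if len(timestamps) != len(entries):
        raise SequenceFormatError(
            f"{len(timestamps)} timestamps for {len(entries)} frames"
        )

    frames = []
    for (k, p), ts in zip(entries, timestamps):
        raw = np.asarray(Image.open(p), dtype=np.int64)
        if raw.shape != geometry.shape:
            raise SequenceFormatError(
                f"{p.name}: shape {raw.shape} does not match geometry "
                f"{geometry.shape}"
            )
        validity = raw > 0
        frames.append(
            DepthFrame(depth=np.where(validity, raw, 0.0).astype(float),
                       timestamp=float(ts), validity=validity)
        )
    return DepthSequence(frames=frames, geometry=geometry)


def _record_from_row(row: pd.Series, index: int) -> SubjectRecord:
    kwargs = {}
    for col in COHORT_COLUMNS + _OPTIONAL_COLUMNS:
        if col not in row.index:
            continue
        value = row[col]
        if col in ("subject_id", "group"):
            kwargs[col] = str(value)
        else:
            if pd.isna(value):
                if col in _OPTIONAL_COLUMNS:
                    kwargs[col] = None
                    continue
                raise CohortFormatError(f"row {index}: missing value in '{col}'")
            try:
                kwargs[col] = float(value)
            except (TypeError, ValueError) as exc:
                raise CohortFormatError(
                    f"row {index}: non-numeric value {value!r} in '{col}'"
                ) from exc
    try:
        return SubjectRecord(**kwargs)
    except ValueError as exc:
        raise CohortFormatError(f"row {index}: {exc}") from exc


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort CSV into validated :class:`SubjectRecord` objects.

    Required columns: ``subject_id,height,bmi,fvc_spirometer,
    fev1_spirometer,group``; ``fvc_anterior``/``fev1_anterior`` are picked up
    when present.  Invariant violations are rejected with the row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing columns: {', '.join(missing)}")
    return [_record_from_row(row, i) for i, (_, row) in enumerate(df.iterrows())]


def write_cohort(records: Sequence[SubjectRecord], path: str | Path) -> Path:
    """Write subject records as a cohort CSV (deterministic formatting)."""
    path = Path(path)
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "height": f"{r.height:.2f}",
            "bmi": f"{r.bmi:.3f}",
            "fvc_spirometer": f"{r.fvc_spirometer:.2f}",
            "fev1_spirometer": f"{r.fev1_spirometer:.2f}",
            "group": r.group,
        }
        if r.fvc_anterior is not None:
            row["fvc_anterior"] = f"{r.fvc_anterior:.6f}"
        if r.fev1_anterior is not None:
            row["fev1_anterior"] = f"{r.fev1_anterior:.6f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
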