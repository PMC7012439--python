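"""Reading and writing contour sequences and motion tables.

File schemas
------------
Contour JSON: one object per ROI::

    {"roi": str, "pixel_spacing": [dr, dc], "frame_interval_ms": float,
     "units": "mm" | "pixel",
     "frames": [{"index": int, "points": [[x, y], ...]}, ...]}

Contour CSV: header ``roi,frame,point_index,x,y``; one contour is the block of
rows sharing (roi, frame). The CSV dialect carries no metadata, so pixel
spacing / frame interval / units are supplied by the caller.

Motion CSV: header ``roi,frame,direction,magnitude_mm`` with direction in
{superior, inferior, anterior, posterior}; summary rows use ``frame = "max"``.

Coordinates are stored in mm in a right-handed frame with +y superior and
+x anterior. Inputs flagged ``units: "pixel"`` are converted at read time by
pure scaling (x by the column spacing, y by the row spacing); pass
``flip_y=True`` for image-convention input where the row index grows
inferiorly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PointSet

__all__ = [
    "DIRECTIONS",
    "ContourFormatError",
    "ContourSequence",
    "MotionTable",
    "read_contour_sequence",
    "write_contour_sequence",
    "read_motion_table",
    "write_motion_table",
    "logger",
    "log_registration",
]

#: Anatomical direction order used throughout the package.
DIRECTIONS = ("superior", "inferior", "anterior", "posterior")

logger = logging.getLogger("swallowreg")


class ContourFormatError(ValueError):
    """A file does not conform to the documented contour/motion schema."""


@dataclass
class ContourSequence:
    """Frames of one ROI's closed contour over a cine acquisition.

    All frames share the pixel spacing and coordinate frame; frame indices
    are the original cine frame numbers and must be strictly increasing.
    """

    roi_name: str
    frames: list[PointSet]
    pixel_spacing: tuple[float, float] = (1.0, 1.0)  # (row, col) mm/px
    frame_interval_ms: float = 160.0
    frame_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError(
                f"ROI '{self.roi_name}': a sequence needs >= 2 frames, got {len(self.frames)}"
            )
        dr, dc = self.pixel_spacing
        if not (dr > 0 and dc > 0):
            raise ValueError(f"ROI '{self.roi_name}': pixel_spacing must be > 0")
        if not self.frame_indices:
            self.frame_indices = list(range(len(self.frames)))
        if len(self.frame_indices) != len(self.frames):
            raise ValueError(
                f"ROI '{self.roi_name}': {len(self.frame_indices)} frame indices "
                f"for {len(self.frames)} frames"
            )
        idx = np.asarray(self.frame_indices)
        if np.any(np.diff(idx) <= 0):
            raise ValueError(f"ROI '{self.roi_name}': frame indices must be strictly increasing")
        for fi, ps in zip(self.frame_indices, self.frames):
            if not isinstance(ps, PointSet):
                raise TypeError(f"ROI '{self.roi_name}' frame {fi}: frames must be PointSet")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class MotionTable:
    """Per-frame directional motion magnitudes (mm) for one ROI.

    ``magnitudes[k, d]`` is the mean displacement of in-ROI grid points in
    direction ``DIRECTIONS[d]``, measured from the first contoured frame to
    frame ``k``. The first row is therefore all zeros. ``summary`` is the
    per-direction maximum over frames, the quantity used to characterize each
    structure's motion over the swallowing cycle.
    """

    roi_name: str
    frame_indices: list[int]
    magnitudes: np.ndarray  # (n_frames, 4), DIRECTIONS order

    def __post_init__(self) -> None:
        mags = np.asarray(self.magnitudes, dtype=np.float64)
        if mags.ndim != 2 or mags.shape[1] != 4:
            raise ValueError(f"magnitudes must be (n_frames, 4), got {mags.shape}")
        if mags.shape[0] != len(self.frame_indices):
            raise ValueError("magnitudes rows must match frame_indices")
        if np.any(mags < -1e-9):
            raise ValueError("motion magnitudes must be non-negative")
        if np.any(np.abs(mags[0]) > 1e-9):
            raise ValueError("first contoured frame must have all-zero magnitudes")
        self.magnitudes = np.clip(mags, 0.0, None)

    @property
    def summary(self) -> np.ndarray:
        """Per-direction maximum over frames (mm), in DIRECTIONS order."""
        return self.magnitudes.max(axis=0)


# ---------------------------------------------------------------------------
# contour I/O

def _points_from_record(points, where: str) -> np.ndarray:
    try:
        arr = np.asarray(points, dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ContourFormatError(f"{where}: non-numeric point data") from exc
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ContourFormatError(f"{where}: points must be a list of [x, y] pairs")
    if arr.shape[0] < 3:
        raise ContourFormatError(f"{where}: a contour needs >= 3 points, got {arr.shape[0]}")
    if not np.all(np.isfinite(arr)):
        raise ContourFormatError(f"{where}: non-finite coordinates")
    return arr


def _to_mm(pts: np.ndarray, units: str, pixel_spacing, flip_y: bool, where: str) -> np.ndarray:
    if units not in ("mm", "pixel"):
        raise ContourFormatError(f"{where}: unknown units {units!r} (expected 'mm' or 'pixel')")
    if units == "pixel":
        dr, dc = pixel_spacing
        pts = pts * np.array([dc, dr], dtype=np.float64)
    if flip_y:
        pts = pts * np.array([1.0, -1.0])
    return pts


def read_contour_sequence(
    path,
    format: str | None = None,
    *,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
    frame_interval_ms: float = 160.0,
    units: str = "mm",
    flip_y: bool = False,
) -> ContourSequence:
    """Read one ROI's contour sequence from JSON or CSV.

    The keyword arguments supply metadata for the CSV dialect (which stores
    none); for JSON they are overridden by the file's own fields.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        return _read_json(path, flip_y=flip_y)
    if fmt == "csv":
        return _read_csv(
            path,
            pixel_spacing=pixel_spacing,
            frame_interval_ms=frame_interval_ms,
            units=units,
            flip_y=flip_y,
        )
    raise ValueError(f"unknown format {fmt!r} (expected 'json' or 'csv')")


def _read_json(path: Path, flip_y: bool) -> ContourSequence:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ContourFormatError(f"{path}: invalid JSON: {exc}") from exc
    for key in ("roi", "pixel_spacing", "frames"):
        if key not in doc:
            raise ContourFormatError(f"{path}: missing required key {key!r}")
    roi = str(doc["roi"])
    spacing = tuple(float(v) for v in doc["pixel_spacing"])
    if len(spacing) != 2 or not all(v > 0 for v in spacing):
        raise ContourFormatError(f"{path}: pixel_spacing must be two positive numbers")
    interval = float(doc.get("frame_interval_ms", 160.0))
    units = str(doc.get("units", "mm"))
    frames, indices = [], []
    for rec_no, rec in enumerate(doc["frames"]):
        where = f"{path}: frames[{rec_no}]"
        if "index" not in rec or "points" not in rec:
            raise ContourFormatError(f"{where}: needs 'index' and 'points'")
        pts = _points_from_record(rec["points"], where)
        pts = _to_mm(pts, units, spacing, flip_y, where)
        try:
            frames.append(PointSet(pts, closed=bool(rec.get("closed", True))))
        except ValueError as exc:
            raise ContourFormatError(f"{where}: {exc}") from exc
        indices.append(int(rec["index"]))
    try:
        return ContourSequence(roi, frames, spacing, interval, indices)
    except ValueError as exc:
        raise ContourFormatError(f"{path}: {exc}") from exc


def _read_csv(path: Path, *, pixel_spacing, frame_interval_ms, units, flip_y) -> ContourSequence:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ContourFormatError(f"{path}: unreadable CSV: {exc}") from exc
    required = {"roi", "frame", "point_index", "x", "y"}
    if not required.issubset(df.columns):
        missing = sorted(required - set(df.columns))
        raise ContourFormatError(f"{path}: missing columns {missing}")
    rois = df["roi"].unique()
    if len(rois) != 1:
        raise ContourFormatError(
            f"{path}: expected a single ROI per file, found {sorted(map(str, rois))}"
        )
    roi = str(rois[0])
    frames, indices = [], []
    for fi, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("point_index")
        where = f"{path}: roi {roi!r} frame {fi}"
        pts = _points_from_record(grp[["x", "y"]].to_numpy(), where)
        pts = _to_mm(pts, units, pixel_spacing, flip_y, where)
        try:
            frames.append(PointSet(pts))
        except ValueError as exc:
            raise ContourFormatError(f"{where}: {exc}") from exc
        indices.append(int(fi))
    try:
        return ContourSequence(roi, frames, tuple(pixel_spacing), frame_interval_ms, indices)
    except ValueError as exc:
        raise ContourFormatError(f"{path}: {exc}") from exc


def write_contour_sequence(seq: ContourSequence, path, format: str | None = None) -> None:
    """Write a contour sequence (always in mm units)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        doc = {
            "roi": seq.roi_name,
            "pixel_spacing": list(seq.pixel_spacing),
            "frame_interval_ms": seq.frame_interval_ms,
            "units": "mm",
            "frames": [
                {"index": int(fi), "points": ps.points.tolist(), "closed": ps.closed}
                for fi, ps in zip(seq.frame_indices, seq.frames)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    elif fmt == "csv":
        rows = []
        for fi, ps in zip(seq.frame_indices, seq.frames):
            for pi, (x, y) in enumerate(ps.points):
                rows.append((seq.roi_name, int(fi), pi, x, y))
        pd.DataFrame(rows, columns=["roi", "frame", "point_index", "x", "y"]).to_csv(
            path, index=False, float_format="%.12g"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# motion-table I/O

def write_motion_table(table: MotionTable, path) -> None:
    """Write a motion table as CSV: one row per (frame, direction) + summary rows."""
    rows = []
    for fi, mags in zip(table.frame_indices, table.magnitudes):
        for d, m in zip(DIRECTIONS, mags):
            rows.append((table.roi_name, str(int(fi)), d, m))
    for d, m in zip(DIRECTIONS, table.summary):
        rows.append((table.roi_name, "max", d, m))
    pd.DataFrame(rows, columns=["roi", "frame", "direction", "magnitude_mm"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_motion_table(path) -> MotionTable:
    df = pd.read_csv(path, dtype={"frame": str})
    required = {"roi", "frame", "direction", "magnitude_mm"}
    if not required.issubset(df.columns):
        raise ContourFormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    rois = df["roi"].unique()
    if len(rois) != 1:
        raise ContourFormatError(f"{path}: expected a single ROI, found {list(rois)}")
    body = df[df["frame"] != "max"]
    indices = sorted(body["frame"].astype(int).unique())
    mags = np.zeros((len(indices), 4))
    pos = {fi: k for k, fi in enumerate(indices)}
    dpos = {d: j for j, d in enumerate(DIRECTIONS)}
    for _, row in body.iterrows():
        if row["direction"] not in dpos:
            raise ContourFormatError(f"{path}: unknown direction {row['direction']!r}")
        mags[pos[int(row["frame"])], dpos[row["direction"]]] = float(row["magnitude_mm"])
    return MotionTable(str(rois[0]), indices, mags)


def log_registration(
    roi: str,
    frame_from: int,
    frame_to: int,
    n_iterations: int,
    error_mm: float,
    seconds: float,
    status: str,
) -> None:
    """Emit one structured log line per pair registration (batch bookkeeping)."""
    logger.info(
        "registration roi=%s pair=%d->%d iters=%d error_mm=%.4f time_s=%.2f status=%s",
        roi, frame_from, frame_to, n_iterations, error_mm, seconds, status,
    )
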