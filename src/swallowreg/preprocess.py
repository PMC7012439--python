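"""Contour preprocessing for point-set registration.

Before two contours are matched, each is resampled to a uniform arc-length
spacing tied to the in-plane image resolution (default 1 mm, the pixel size
of the cine acquisition) and the pair is rescaled into a shared unit box.
Working in the unit box makes the annealing temperatures and the thin-plate
regularization weight dimensionless; the inverse scaling restores physical
millimetre coordinates afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PointSet",
    "UnitBoxScaling",
    "resample_contour",
    "to_unit_box",
    "from_unit_box",
]


@dataclass(frozen=True)
class PointSet:
    """An ordered set of 2D points in millimetres.

    Parameters
    ----------
    points : (N, 2) array_like
        Vertex coordinates in mm. At least three points are required.
    closed : bool
        Whether the polyline wraps around (a closed contour). Defaults to
        True, since delineated ROIs are closed outlines.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (N, 2), got shape {pts.shape}")
        if pts.shape[0] < 3:
            raise ValueError(f"a point set needs >= 3 points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        nxt = np.roll(pts, -1, axis=0) if self.closed else pts[1:]
        ref = pts if self.closed else pts[:-1]
        if np.any(np.all(ref == nxt, axis=1)):
            raise ValueError("consecutive duplicate points in contour")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    @property
    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corners of the axis-aligned bounding box."""
        return self.points.min(axis=0), self.points.max(axis=0)

    def perimeter(self) -> float:
        """Total polyline length (including the closing segment if closed)."""
        poly = self._vertices_with_closure()
        return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())

    def _vertices_with_closure(self) -> np.ndarray:
        if self.closed:
            return np.vstack([self.points, self.points[:1]])
        return self.points


@dataclass(frozen=True)
class UnitBoxScaling:
    """Isotropic similarity mapping mm coordinates into the unit box.

    ``forward(x) = (x - offset) / scale`` and ``inverse`` undoes it exactly.
    The scale is the larger bounding-box extent, so shapes are preserved
    (one scalar scale, no per-axis stretch).
    """

    offset: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        off = np.asarray(self.offset, dtype=np.float64).reshape(2)
        if not np.all(np.isfinite(off)):
            raise ValueError("offset must be finite")
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")
        object.__setattr__(self, "offset", off)
        object.__setattr__(self, "scale", float(self.scale))

    @classmethod
    def from_points(cls, *point_arrays: np.ndarray) -> "UnitBoxScaling":
        """Scaling whose unit box covers the union of the given point arrays.

        Computing one scaling from both members of a registration pair keeps
        source and target in a common frame and avoids anisotropic distortion
        of the anatomical axes.
        """
        pts = np.vstack([np.asarray(a, dtype=np.float64) for a in point_arrays])
        lo = pts.min(axis=0)
        extent = float((pts.max(axis=0) - lo).max())
        if extent <= 0:
            raise ValueError("degenerate bounding box: all points coincide")
        return cls(offset=lo, scale=extent)

    def forward(self, xy: np.ndarray) -> np.ndarray:
        return (np.asarray(xy, dtype=np.float64) - self.offset) / self.scale

    def inverse(self, uv: np.ndarray) -> np.ndarray:
        return np.asarray(uv, dtype=np.float64) * self.scale + self.offset


def resample_contour(raw: PointSet, spacing: float) -> PointSet:
    """Resample a contour to uniform arc-length spacing.

    The polyline of ``raw`` is traversed and new vertices are placed at equal
    arc-length steps of ``total_length / round(total_length / spacing)``, so
    the actual step is the closest divisor of the perimeter to the requested
    spacing. Closed contours are resampled cyclically starting from a
    deterministic vertex (lowest y, then lowest x) so repeated runs are
    bit-identical.

    Parameters
    ----------
    raw : PointSet
        Input contour (vertices in mm).
    spacing : float
        Target arc-length spacing in mm; the default pipeline uses the
        in-plane pixel size (1 mm).
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    pts = raw.points
    if raw.closed:
        start = int(np.lexsort((pts[:, 0], pts[:, 1]))[0])
        pts = np.roll(pts, -start, axis=0)
        poly = np.vstack([pts, pts[:1]])
    else:
        poly = pts
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(cum[-1])
    if total < 2.0 * spacing:
        raise ValueError(
            f"degenerate contour: total length {total:.3g} mm < 2 x spacing {spacing:.3g} mm"
        )
    n = max(int(round(total / spacing)), 3)
    if raw.closed:
        s = np.arange(n) * (total / n)
    else:
        n = max(n, 2)
        s = np.arange(n + 1) * (total / n)
    x = np.interp(s, cum, poly[:, 0])
    y = np.interp(s, cum, poly[:, 1])
    return PointSet(np.column_stack([x, y]), closed=raw.closed)


def to_unit_box(ps: PointSet) -> tuple[PointSet, UnitBoxScaling]:
    """Rescale a point set into the unit box; returns the scaled set and the scaling."""
    scaling = UnitBoxScaling.from_points(ps.points)
    return PointSet(scaling.forward(ps.points), closed=ps.closed), scaling


def from_unit_box(ps: PointSet, scaling: UnitBoxScaling) -> PointSet:
    """Exact inverse of :func:`to_unit_box` under the given scaling."""
    return PointSet(scaling.inverse(ps.points), closed=ps.closed)
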