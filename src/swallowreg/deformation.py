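"""Deformation vector fields on uniform grids, and transform concatenation.

The registration returns analytic mm-space transforms; applying one to a
uniform grid over the ROI yields a deformation vector at each grid point.
Motion between non-adjacent frames is obtained by concatenating the chain of
consecutive-frame transforms: each grid point is pushed through the
transforms in order by analytic re-evaluation at the moved position, which
avoids the interpolation error a gridded-vector composition would incur.
Grid points inside the ROI contour (boundary inclusive) form the mask over
which motion statistics are taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .preprocess import PointSet
from .tpsrpm import TpsTransform

__all__ = [
    "Grid",
    "DeformationField",
    "make_grid",
    "inside_mask",
    "evaluate_field",
    "concatenate_transforms",
    "field_to_csv",
]


@dataclass(frozen=True)
class Grid:
    """Axis-aligned uniform grid; ``shape = (nx, ny)`` point counts along x, y."""

    origin: np.ndarray  # (2,) mm
    spacing: float      # mm
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=np.float64).reshape(2))
        if self.spacing <= 0:
            raise ValueError(f"grid spacing must be > 0, got {self.spacing}")
        nx, ny = self.shape
        if nx < 1 or ny < 1:
            raise ValueError(f"grid shape must be >= 1 per axis, got {self.shape}")
        object.__setattr__(self, "shape", (int(nx), int(ny)))

    @property
    def xs(self) -> np.ndarray:
        return self.origin[0] + self.spacing * np.arange(self.shape[0])

    @property
    def ys(self) -> np.ndarray:
        return self.origin[1] + self.spacing * np.arange(self.shape[1])

    def points(self) -> np.ndarray:
        """All grid points as (nx*ny, 2), x-index-major order."""
        X, Y = np.meshgrid(self.xs, self.ys, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])


@dataclass(frozen=True)
class DeformationField:
    """Displacement vectors (mm) on a grid plus the ROI-inside mask."""

    grid: Grid
    vectors: np.ndarray  # (nx, ny, 2)
    inside: np.ndarray   # (nx, ny) bool

    def __post_init__(self) -> None:
        vec = np.asarray(self.vectors, dtype=np.float64)
        ins = np.asarray(self.inside, dtype=bool)
        nx, ny = self.grid.shape
        if vec.shape != (nx, ny, 2):
            raise ValueError(f"vectors shape {vec.shape} != grid shape {(nx, ny, 2)}")
        if ins.shape != (nx, ny):
            raise ValueError(f"inside-mask shape {ins.shape} != grid shape {(nx, ny)}")
        if not np.all(np.isfinite(vec)):
            raise ValueError("deformation vectors must be finite")
        object.__setattr__(self, "vectors", vec)
        object.__setattr__(self, "inside", ins)

    def inside_vectors(self) -> np.ndarray:
        """(M, 2) displacement vectors at the in-ROI grid points."""
        return self.vectors[self.inside]


def make_grid(contour: PointSet, spacing: float = 1.0, margin: float = 2.0) -> Grid:
    """Uniform grid covering the contour bounding box expanded by ``margin``.

    The origin is the expanded bbox minimum snapped *down* to a multiple of
    ``spacing``, which makes the grid deterministic and independent of small
    bbox perturbations within one spacing cell.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    lo, hi = contour.bbox
    lo = lo - margin
    hi = hi + margin
    origin = np.floor(lo / spacing) * spacing
    n = np.ceil((hi - origin) / spacing - 1e-9).astype(int) + 1
    return Grid(origin, float(spacing), (int(n[0]), int(n[1])))


def inside_mask(grid: Grid, contour: PointSet) -> np.ndarray:
    """Boolean (nx, ny) mask of grid points inside the closed contour.

    Points exactly on the boundary count as inside, so the contour's own
    vertices contribute to motion statistics.
    """
    poly = Polygon(contour.points)
    pts = grid.points()
    mask = shapely.intersects_xy(poly, pts[:, 0], pts[:, 1])
    return mask.reshape(grid.shape)


def evaluate_field(transform: TpsTransform, grid: Grid, contour: PointSet) -> DeformationField:
    """Deformation vectors ``f(g) - g`` on the grid, masked by the contour."""
    pts = grid.points()
    disp = transform(pts) - pts
    return DeformationField(grid, disp.reshape(grid.shape + (2,)), inside_mask(grid, contour))


def concatenate_transforms(
    transforms: Sequence[TpsTransform],
    grid: Grid,
    contour_at_start: PointSet,
) -> DeformationField:
    """Compose an ordered chain of frame-to-frame transforms on the grid.

    Each grid point ``g`` is pushed through the transforms in order,
    ``p <- f_k(p)``, and the field stores ``p - g``. An empty chain yields
    the zero field. The inside mask comes from the contour at the chain's
    start frame — the frame whose ROI the resulting motion describes.
    """
    pts = grid.points()
    p = pts.copy()
    for f in transforms:
        p = f(p)
    disp = p - pts
    return DeformationField(
        grid, disp.reshape(grid.shape + (2,)), inside_mask(grid, contour_at_start)
    )


def field_to_csv(field: DeformationField, path) -> None:
    """Flat-CSV export: row, col, x_mm, y_mm, dx_mm, dy_mm, inside."""
    nx, ny = field.grid.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = field.grid.points()
    pd.DataFrame({
        "row": jj.ravel(),
        "col": ii.ravel(),
        "x_mm": pts[:, 0],
        "y_mm": pts[:, 1],
        "dx_mm": field.vectors[..., 0].ravel(),
        "dy_mm": field.vectors[..., 1].ravel(),
        "inside": field.inside.ravel().astype(int),
    }).to_csv(path, index=False, float_format="%.12g")
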