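"""Directional motion quantification over the swallowing cycle.

Each grid-point displacement is orthogonally decomposed onto the
superior-inferior and anterior-posterior axes of the sagittal plane and
rectified into four non-negative magnitudes (superior, inferior, anterior,
posterior) — a point contributes only to the direction it actually moves.
The per-ROI magnitude in a direction is the mean over grid points inside the
ROI; per-frame motion is always measured against the first contoured frame
(pre-swallow rest), and the per-direction maximum over frames summarizes the
structure's motion.

Contours are expected in a right-handed mm frame with +y superior and +x
anterior (the default :class:`AnatomicalFrame`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .deformation import DeformationField, inside_mask, make_grid
from .io import DIRECTIONS, ContourSequence, MotionTable
from .tpsrpm import TpsTransform

__all__ = [
    "AnatomicalFrame",
    "decompose_vector",
    "decompose_vectors",
    "roi_motion",
    "motion_timecourse",
    "plot_timecourse",
]


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal anatomical axes of the sagittal image plane."""

    si_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    ap_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        si = np.asarray(self.si_axis, dtype=np.float64).reshape(2)
        ap = np.asarray(self.ap_axis, dtype=np.float64).reshape(2)
        for name, ax in (("si_axis", si), ("ap_axis", ap)):
            if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit vector")
        if abs(float(si @ ap)) > 1e-9:
            raise ValueError("si_axis and ap_axis must be orthogonal")
        object.__setattr__(self, "si_axis", si)
        object.__setattr__(self, "ap_axis", ap)


def decompose_vectors(v: np.ndarray, frame: AnatomicalFrame | None = None) -> np.ndarray:
    """Rectified directional components of displacement vectors.

    Returns an (..., 4) array in DIRECTIONS order. For each vector exactly
    one of each opposed pair (superior/inferior, anterior/posterior) is
    nonzero, and the pair sums to the absolute axis component.
    """
    frame = frame or AnatomicalFrame()
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("displacement vectors must be finite")
    s = v @ frame.si_axis
    a = v @ frame.ap_axis
    return np.stack(
        [np.maximum(s, 0.0), np.maximum(-s, 0.0), np.maximum(a, 0.0), np.maximum(-a, 0.0)],
        axis=-1,
    )


def decompose_vector(v, frame: AnatomicalFrame | None = None) -> tuple[float, float, float, float]:
    """(superior, inferior, anterior, posterior) magnitudes of one vector, mm."""
    out = decompose_vectors(np.asarray(v, dtype=np.float64).reshape(2), frame)
    return tuple(float(x) for x in out)


def roi_motion(
    field: DeformationField,
    frame: AnatomicalFrame | None = None,
    roi_name: str = "",
) -> np.ndarray:
    """Mean rectified directional motion over in-ROI grid points, (4,) mm."""
    vin = field.inside_vectors()
    if vin.shape[0] == 0:
        raise ValueError(
            f"no grid points inside ROI{f' {roi_name!r}' if roi_name else ''}; "
            "check grid spacing vs contour size"
        )
    return decompose_vectors(vin, frame).mean(axis=0)


def motion_timecourse(
    seq: ContourSequence,
    transforms: Sequence[TpsTransform],
    frame: AnatomicalFrame | None = None,
    grid_spacing: float = 1.0,
    margin: float = 2.0,
) -> MotionTable:
    """Per-frame directional motion of one ROI from its chain of transforms.

    ``transforms[k]`` must map frame ``k`` to frame ``k+1`` (consecutive
    contoured frames, in mm). For each frame the chain from the initial frame
    is composed on the initial-frame ROI grid and averaged inside the ROI;
    the initial frame row is exactly zero.
    """
    if len(transforms) != seq.n_frames - 1:
        raise ValueError(
            f"need {seq.n_frames - 1} transforms for {seq.n_frames} frames, "
            f"got {len(transforms)}"
        )
    grid = make_grid(seq.frames[0], grid_spacing, margin)
    mask = inside_mask(grid, seq.frames[0])
    if not mask.any():
        raise ValueError(f"no grid points inside ROI {seq.roi_name!r} at the initial frame")
    pts0 = grid.points()
    p = pts0.copy()
    mags = np.zeros((seq.n_frames, 4))
    for k in range(1, seq.n_frames):
        p = transforms[k - 1](p)
        disp = (p - pts0).reshape(grid.shape + (2,))
        fld = DeformationField(grid, disp, mask)
        mags[k] = roi_motion(fld, frame, roi_name=seq.roi_name)
    return MotionTable(seq.roi_name, list(seq.frame_indices), mags)


def plot_timecourse(table: MotionTable, path) -> None:
    """Save a direction-vs-frame motion plot for one ROI (PNG/PDF by suffix)."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(7, 4))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    for j, d in enumerate(DIRECTIONS):
        ax.plot(table.frame_indices, table.magnitudes[:, j], marker="o", ms=3, label=d)
    ax.set_xlabel("contoured frame")
    ax.set_ylabel("motion magnitude (mm)")
    ax.set_title(f"{table.roi_name}: displacement from initial frame")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
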