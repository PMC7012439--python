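"""Registration-error measurement and automatic failure detection.

The error of one pair registration is the symmetric mean closest-point
distance between the deformed (registered) contour and the reference manual
contour: the average, over the points of each contour, of the distance to the
other contour's polyline, with the two directed means averaged. Index-wise
pairing is not used because arc-length resampling destroys any vertex
correspondence between frames.

Most successful registrations show sub-millimetre error; errors above the
suspect threshold (default 1 mm) mark registrations worth review and errors
above the failure threshold (default 2 mm) mark failures — e.g. the "reflex"
mode of narrow elongate contours, where one long side is matched onto the
opposite side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LinearRing, LineString

from .preprocess import PointSet

__all__ = [
    "registration_error",
    "classify_error",
    "classify_run",
    "RegistrationReport",
    "RunSummary",
    "reports_to_csv",
    "reports_from_csv",
]

STATUSES = ("ok", "suspect", "failed")


def _boundary(ps: PointSet):
    return LinearRing(ps.points) if ps.closed else LineString(ps.points)


def _mean_distance(points: np.ndarray, line) -> float:
    geoms = shapely.points(points[:, 0], points[:, 1])
    return float(shapely.distance(geoms, line).mean())


def registration_error(deformed: PointSet, reference: PointSet) -> float:
    """Symmetric mean closest-point distance between two contours, in mm.

    Zero iff the contours coincide; symmetric in its arguments; invariant
    under a common rigid motion of both contours.
    """
    d_to_r = _mean_distance(deformed.points, _boundary(reference))
    r_to_d = _mean_distance(reference.points, _boundary(deformed))
    return 0.5 * (d_to_r + r_to_d)


def classify_error(error_mm: float, suspect_mm: float = 1.0, fail_mm: float = 2.0) -> str:
    """Map an error to ok / suspect / failed. Boundary values take the lower status."""
    if not (0 < suspect_mm <= fail_mm):
        raise ValueError(f"need 0 < suspect ({suspect_mm}) <= fail ({fail_mm})")
    if error_mm < 0:
        raise ValueError(f"error must be >= 0, got {error_mm}")
    if error_mm <= suspect_mm:
        return "ok"
    if error_mm <= fail_mm:
        return "suspect"
    return "failed"


@dataclass(frozen=True)
class RegistrationReport:
    roi_name: str
    frame_from: int
    frame_to: int
    error_mm: float
    status: str = "ok"


@dataclass
class RunSummary:
    """Counts by status plus the registrations needing manual attention."""

    counts: dict[str, int]
    reports: list[RegistrationReport]
    suspect: list[RegistrationReport]
    failed: list[RegistrationReport]

    @property
    def n(self) -> int:
        return len(self.reports)

    def to_json(self, path=None) -> str:
        doc = {
            "n_registrations": self.n,
            "counts": self.counts,
            "suspect": [vars(r) for r in self.suspect],
            "failed": [vars(r) for r in self.failed],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def classify_run(
    reports: Iterable[RegistrationReport],
    suspect_mm: float = 1.0,
    fail_mm: float = 2.0,
) -> RunSummary:
    """Re-classify every report against the thresholds and summarize.

    Returns the per-status counts and the suspect/failed registrations, which
    are the candidates for manual parameter tuning.
    """
    out: list[RegistrationReport] = []
    for r in reports:
        status = classify_error(r.error_mm, suspect_mm, fail_mm)
        out.append(RegistrationReport(r.roi_name, r.frame_from, r.frame_to, r.error_mm, status))
    counts = {s: sum(1 for r in out if r.status == s) for s in STATUSES}
    return RunSummary(
        counts=counts,
        reports=out,
        suspect=[r for r in out if r.status == "suspect"],
        failed=[r for r in out if r.status == "failed"],
    )


def reports_to_csv(reports: Sequence[RegistrationReport], path) -> None:
    pd.DataFrame(
        [(r.roi_name, r.frame_from, r.frame_to, r.error_mm, r.status) for r in reports],
        columns=["roi", "frame_from", "frame_to", "error_mm", "status"],
    ).to_csv(path, index=False, float_format="%.12g")


def reports_from_csv(path) -> list[RegistrationReport]:
    df = pd.read_csv(path)
    return [
        RegistrationReport(str(r.roi), int(r.frame_from), int(r.frame_to),
                           float(r.error_mm), str(r.status))
        for r in df.itertuples()
    ]
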