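"""Modified thin-plate-spline robust point matching (TPS-RPM).

Registers two 2D contour point sets by alternating two closed-form updates
under a deterministic-annealing schedule:

* **softassign** — a fuzzy correspondence matrix between target points
  ``x_i`` and warped source points ``f(v_j)`` is formed from Gaussian
  affinities at temperature ``T`` and driven toward doubly stochastic by
  alternating row/column (Sinkhorn) normalization. An extra outlier row and
  column, kept at a fixed high temperature, lets points in *either* set opt
  out of matching — the "modified" symmetric-outlier treatment that makes
  frame-to-frame contour registration robust to partial overlap.
* **TPS update** — given correspondences, each source point's virtual target
  is the correspondence-weighted mean of the target points and the optimal
  thin-plate-spline warp is the minimizer of the weighted squared residual
  plus ``lam`` times the TPS bending energy, obtained by one dense linear
  solve.

Annealing lowers ``T`` geometrically while the regularization weight is tied
to ``T`` (``lam = lambda_init * T * K``), so the transform is near-rigid
early — avoiding local optima under large deformations — and increasingly
non-rigid as correspondences sharpen toward binary.

All matching happens in unit-box coordinates; :func:`register_pair` wraps
resampling, shared unit-box scaling, annealed matching, and the exact
conjugation of the solved transform back to millimetre coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .preprocess import PointSet, UnitBoxScaling, resample_contour
from .validation import classify_error, registration_error

__all__ = [
    "tps_kernel",
    "TpsTransform",
    "CorrespondenceMatrix",
    "AnnealingSchedule",
    "tps_solve",
    "softassign_update",
    "anneal_register",
    "register_pair",
    "similarity_conjugate",
    "RegistrationResult",
]


def tps_kernel(r2: np.ndarray) -> np.ndarray:
    """Thin-plate radial basis U(r) = r^2 log r on squared distances, U(0) = 0.

    Evaluated as ``0.5 * r2 * log(r2)`` to avoid the square root.
    """
    r2 = np.asarray(r2, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = 0.5 * r2 * np.log(r2)
    return np.where(r2 > 0.0, u, 0.0)


@dataclass(frozen=True)
class TpsTransform:
    """Analytic 2D thin-plate-spline warp: affine part + radial-basis part.

    ``f(x) = affine @ x + translation + sum_j U(|x - v_j|) w_j`` with control
    points ``v_j`` and warp coefficients ``w_j`` satisfying the TPS side
    conditions (zero sum and zero first moment), which guarantee affine
    behavior far from the control points.
    """

    control_points: np.ndarray  # (K, 2)
    affine: np.ndarray          # (2, 2)
    translation: np.ndarray     # (2,)
    warp_coeffs: np.ndarray     # (K, 2)

    def __post_init__(self) -> None:
        for name, shape in (("control_points", (-1, 2)), ("warp_coeffs", (-1, 2))):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} must be (K, 2)")
            object.__setattr__(self, name, arr)
        if self.control_points.shape != self.warp_coeffs.shape:
            raise ValueError("control_points and warp_coeffs must have matching shapes")
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=np.float64).reshape(2, 2))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=np.float64).reshape(2))

    @classmethod
    def identity(cls, control_points: np.ndarray) -> "TpsTransform":
        cp = np.asarray(control_points, dtype=np.float64)
        return cls(cp, np.eye(2), np.zeros(2), np.zeros_like(cp))

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        """Evaluate the warp at query points (M, 2) -> (M, 2)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        out = xy @ self.affine.T + self.translation
        if self.warp_coeffs.size:
            r2 = cdist(xy, self.control_points, "sqeuclidean")
            out = out + tps_kernel(r2) @ self.warp_coeffs
        return out

    def side_condition_residual(self) -> float:
        """Max abs violation of sum(w) = 0 and sum(w x v) = 0."""
        s0 = np.abs(self.warp_coeffs.sum(axis=0)).max(initial=0.0)
        s1 = np.abs(self.warp_coeffs.T @ self.control_points).max(initial=0.0)
        return float(max(s0, s1))

    def bending_energy(self) -> float:
        """TPS bending energy trace(w^T K w) over the control points."""
        if not self.warp_coeffs.size:
            return 0.0
        K = tps_kernel(cdist(self.control_points, self.control_points, "sqeuclidean"))
        return float(np.sum(self.warp_coeffs * (K @ self.warp_coeffs)))


@dataclass(frozen=True)
class CorrespondenceMatrix:
    """(N+1) x (K+1) fuzzy assignment; row/column 0 are the outlier bins.

    Rows 1..N index target points, columns 1..K index source points. After
    Sinkhorn normalization each inner row and column sums to ~1 including its
    outlier entry.
    """

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
            raise ValueError("correspondence matrix must be (N+1, K+1) with N, K >= 1")
        if np.any(m < 0):
            raise ValueError("correspondence entries must be non-negative")
        object.__setattr__(self, "m", m)

    @property
    def inner(self) -> np.ndarray:
        """(N, K) block of real point-to-point correspondences."""
        return self.m[1:, 1:]

    @property
    def source_outlier_mass(self) -> np.ndarray:
        """Per-source-point mass in the outlier row (K,)."""
        return self.m[0, 1:]

    @property
    def target_outlier_mass(self) -> np.ndarray:
        """Per-target-point mass in the outlier column (N,)."""
        return self.m[1:, 0]

    def source_weights(self) -> np.ndarray:
        """Total inner correspondence mass per source point (K,)."""
        return self.inner.sum(axis=0)

    def virtual_targets(self, target_points: np.ndarray) -> np.ndarray:
        """Correspondence-weighted mean target per source point (K, 2)."""
        X = np.asarray(target_points, dtype=np.float64)
        w = self.source_weights()
        num = self.inner.T @ X
        return num / np.maximum(w, 1e-300)[:, None]

    def normalization_deviation(self) -> float:
        """Max abs deviation of inner row/column sums from 1."""
        rdev = np.abs(self.m[1:, :].sum(axis=1) - 1.0).max()
        cdev = np.abs(self.m[:, 1:].sum(axis=0) - 1.0).max()
        return float(max(rdev, cdev))


@dataclass(frozen=True)
class AnnealingSchedule:
    """Deterministic-annealing schedule and solver knobs.

    Temperatures are squared unit-box distances. ``t_init`` / ``t_final``
    default to data-driven values: ``t_init_factor`` times the mean squared
    source-target distance, and ``t_final_factor`` times the squared
    resampling spacing in unit-box units. The default ``t_final_factor`` of
    0.1 cools the correspondence spread well below the point spacing, so the
    final assignment is effectively binary and the curvature bias of fuzzy
    along-contour averaging vanishes. ``lambda_init`` scales the temperature-annealed TPS
    regularization; the outlier row/column temperature stays fixed at
    ``t_init``.
    """

    t_init: float | None = None
    t_final: float | None = None
    rate: float = 0.93
    inner_iters: int = 3
    lambda_init: float = 1.0
    lambda_affine_init: float = 0.01
    t_init_factor: float = 1.0
    t_final_factor: float = 0.1
    sinkhorn_tol: float = 1e-3
    sinkhorn_max_sweeps: int = 30

    def __post_init__(self) -> None:
        if not (0.0 < self.rate < 1.0):
            raise ValueError(f"rate must be in (0, 1), got {self.rate}")
        if self.inner_iters < 1:
            raise ValueError("inner_iters must be >= 1")
        if self.lambda_init <= 0:
            raise ValueError("lambda_init must be > 0")
        if self.lambda_affine_init < 0:
            raise ValueError("lambda_affine_init must be >= 0")
        if self.t_init is not None and self.t_final is not None and not (
            self.t_final < self.t_init
        ):
            raise ValueError("t_final must be < t_init")


#: identity affine in [translation; linear rows] coordinates, one column per axis
_A_IDENTITY = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])


def tps_solve(
    source,
    virtual_targets: np.ndarray,
    weights: np.ndarray | None = None,
    lam: float = 0.0,
    lam_affine: float = 0.0,
) -> TpsTransform:
    """Closed-form regularized TPS fit.

    Minimizes
    ``sum_j w_j |f(v_j) - y_j|^2 + lam * bending(f) + lam_affine * |A - I|^2``
    in one dense linear solve; at ``lam = lam_affine = 0`` with distinct
    points the solution interpolates the targets exactly. The warp
    coefficients are parameterized in the null space of the side conditions
    (QR of the polynomial basis), so ``sum w = 0`` and the first moment
    vanish by construction, and the affine anchor — the second annealed
    regularizer of the robust-point-matching formulation, which keeps the
    linear part near identity while correspondences are still diffuse and so
    prevents the high-temperature collapse/reflection ambiguity — applies to
    the 2x2 linear part only (the translation stays free).

    Source points with weight below 1e-8 are dropped from the solve (pure
    outliers carry no information).

    Parameters
    ----------
    source : PointSet or (K, 2) array
        Control points ``v_j``.
    virtual_targets : (K, 2) array
        Per-control-point target coordinates ``y_j``.
    weights : (K,) array, optional
        Non-negative per-point weights; defaults to all ones.
    lam : float
        Bending-energy regularization weight (>= 0).
    lam_affine : float
        Affine-anchor regularization weight (>= 0).
    """
    V = source.points if isinstance(source, PointSet) else np.asarray(source, dtype=np.float64)
    Y = np.asarray(virtual_targets, dtype=np.float64)
    if V.ndim != 2 or V.shape[1] != 2 or Y.shape != V.shape:
        raise ValueError("source and virtual_targets must both be (K, 2)")
    K = V.shape[0]
    w = np.ones(K) if weights is None else np.asarray(weights, dtype=np.float64)
    if w.shape != (K,):
        raise ValueError("weights must be (K,)")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if lam < 0 or lam_affine < 0:
        raise ValueError("regularization weights must be >= 0")
    keep = w > 1e-8
    if keep.sum() < 3:
        raise ValueError("need >= 3 source points with positive weight")
    Vk, Yk, wk = V[keep], Y[keep], w[keep]
    k = Vk.shape[0]
    P = np.column_stack([np.ones(k), Vk])
    Q, _ = np.linalg.qr(P, mode="complete")
    Q2 = Q[:, 3:]  # (k, k-3) orthonormal basis of the side-condition null space
    Kmat = tps_kernel(cdist(Vk, Vk, "sqeuclidean"))
    sw = np.sqrt(wk)
    B = np.column_stack([Kmat @ Q2, P]) * sw[:, None]
    m = k - 3
    A = B.T @ B
    if lam > 0 and m > 0:
        A[:m, :m] += lam * (Q2.T @ Kmat @ Q2)
    D = np.diag([0.0, 1.0, 1.0])
    if lam_affine > 0:
        A[m:, m:] += lam_affine * D
    rhs = B.T @ (sw[:, None] * Yk)
    if lam_affine > 0:
        rhs[m:, :] += lam_affine * (D @ _A_IDENTITY)
    try:
        sol = scipy.linalg.solve(A, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular TPS system (degenerate/collinear control points); "
            "use lam > 0 to regularize"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError(
            "non-finite TPS solution (near-singular system); use lam > 0 to regularize"
        )
    coeffs = Q2 @ sol[:m] if m > 0 else np.zeros_like(Vk)
    a = sol[m:]
    return TpsTransform(Vk, a[1:].T, a[0], coeffs)


def softassign_update(
    warped_source: np.ndarray,
    target,
    T: float,
    outlier_T: float,
    tol: float = 1e-3,
    max_sweeps: int = 30,
) -> CorrespondenceMatrix:
    """One softassign correspondence update at temperature ``T``.

    Inner entries are initialized as ``exp(-|x_i - f(v_j)|^2 / (2T)) / T``;
    the outlier column (targets opting out) uses a Gaussian at the fixed
    ``outlier_T`` around the warped-source centroid, and the outlier row
    (sources opting out) one around the target centroid. Alternating
    row/column normalization then runs until the inner sums are within
    ``tol`` of 1 or ``max_sweeps`` sweeps.
    """
    W = np.atleast_2d(np.asarray(warped_source, dtype=np.float64))
    X = target.points if isinstance(target, PointSet) else np.atleast_2d(
        np.asarray(target, dtype=np.float64))
    if not (np.all(np.isfinite(W)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite coordinates in softassign input")
    if T <= 0 or outlier_T <= 0:
        raise ValueError("temperatures must be > 0")
    N, K = X.shape[0], W.shape[0]
    m = np.zeros((N + 1, K + 1))
    d2 = cdist(X, W, "sqeuclidean")
    m[1:, 1:] = np.exp(-d2 / (2.0 * T)) / T
    c_w = W.mean(axis=0)
    c_t = X.mean(axis=0)
    m[1:, 0] = np.exp(-((X - c_w) ** 2).sum(axis=1) / (2.0 * outlier_T)) / outlier_T
    m[0, 1:] = np.exp(-((W - c_t) ** 2).sum(axis=1) / (2.0 * outlier_T)) / outlier_T
    for _ in range(max_sweeps):
        rs = m[1:, :].sum(axis=1)
        m[1:, :] /= np.maximum(rs, 1e-300)[:, None]
        cs = m[:, 1:].sum(axis=0)
        m[:, 1:] /= np.maximum(cs, 1e-300)[None, :]
        rdev = np.abs(m[1:, :].sum(axis=1) - 1.0).max()
        cdev = np.abs(m[:, 1:].sum(axis=0) - 1.0).max()
        if max(rdev, cdev) < tol:
            break
    return CorrespondenceMatrix(m)


def anneal_register(
    source: PointSet,
    target: PointSet,
    schedule: AnnealingSchedule | None = None,
) -> tuple[TpsTransform, CorrespondenceMatrix, list[dict]]:
    """Run the full annealed softassign/TPS alternation in unit-box coordinates.

    At each temperature, ``inner_iters`` alternations of
    :func:`softassign_update` and :func:`tps_solve` are performed: each source
    point's virtual target is its correspondence-weighted mean of target
    points, its weight the total inner mass, and the regularization is
    ``lam = lambda_init * T * K``. The outer loop cools ``T`` by ``rate``
    from ``t_init`` down to ``t_final`` with no early stopping, so the run is
    fully deterministic.

    Returns the final transform, the final correspondence matrix, and a list
    of per-iteration diagnostics (temperature, weighted residual, outlier
    masses, bending energy).
    """
    sched = schedule or AnnealingSchedule()
    V = source.points
    X = target.points
    t0 = sched.t_init
    if t0 is None:
        t0 = sched.t_init_factor * float(cdist(X, V, "sqeuclidean").mean())
    tf = sched.t_final
    if tf is None:
        tf = sched.t_final_factor * max(t0 * 1e-3, 1e-12)
    if not (tf < t0):
        raise ValueError(f"resolved t_final {tf:.3g} must be < t_init {t0:.3g}")
    outlier_T = t0
    f = TpsTransform.identity(V)
    corr: CorrespondenceMatrix | None = None
    diagnostics: list[dict] = []
    T = t0
    outer = 0
    while T > tf * (1.0 + 1e-12) and outer < 2000:
        for inner in range(sched.inner_iters):
            warped = f(V)
            corr = softassign_update(
                warped, X, T, outlier_T,
                tol=sched.sinkhorn_tol, max_sweeps=sched.sinkhorn_max_sweeps,
            )
            w = corr.source_weights()
            Y = corr.virtual_targets(X)
            lam = sched.lambda_init * T * V.shape[0]
            lam_affine = sched.lambda_affine_init * T * V.shape[0]
            try:
                f = tps_solve(V, Y, w, lam, lam_affine)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"TPS solve failed at T={T:.3g} (outer {outer}, inner {inner}): {exc}"
                ) from exc
            res = f(V) - Y
            wsum = float(w.sum())
            diagnostics.append({
                "T": T,
                "outer": outer,
                "inner": inner,
                "residual": float(np.sqrt((w[:, None] * res**2).sum() / max(wsum, 1e-300))),
                "source_outlier_mass": float(corr.source_outlier_mass.sum()),
                "target_outlier_mass": float(corr.target_outlier_mass.sum()),
                "bending_energy": f.bending_energy(),
            })
        T *= sched.rate
        outer += 1
    assert corr is not None
    return f, corr, diagnostics


def similarity_conjugate(transform: TpsTransform, scaling: UnitBoxScaling) -> TpsTransform:
    """Conjugate a unit-box TPS by the unit-box scaling, returning a mm-space TPS.

    For the similarity ``u = (x - o)/s`` the map
    ``x -> o + s * f_unit((x - o)/s)`` is again an exact thin-plate spline:
    the kernel rescaling ``U(r/s) = U(r)/s^2 - (log s / s^2) r^2`` produces a
    quadratic cross-term whose non-affine part cancels by the TPS side
    conditions, leaving only a constant shift.
    """
    s = scaling.scale
    o = scaling.offset
    V_mm = scaling.inverse(transform.control_points)
    w_mm = transform.warp_coeffs / s
    # constant from sum_j w_j |x - v_j|^2 = sum_j w_j |v_j|^2 (side conditions)
    C = (transform.warp_coeffs * (V_mm**2).sum(axis=1)[:, None]).sum(axis=0)
    translation = o + s * transform.translation - transform.affine @ o - (np.log(s) / s) * C
    return TpsTransform(V_mm, transform.affine.copy(), translation, w_mm)


@dataclass
class RegistrationResult:
    """Outcome of one frame-pair contour registration (mm coordinates)."""

    transform: TpsTransform            # mm -> mm
    transform_unit: TpsTransform       # unit box -> unit box
    scaling: UnitBoxScaling
    correspondence: CorrespondenceMatrix
    diagnostics: list[dict]
    error_mm: float
    status: str
    source_resampled: PointSet
    target_resampled: PointSet

    @property
    def n_iterations(self) -> int:
        return len(self.diagnostics)


def register_pair(
    source: PointSet,
    target: PointSet,
    spacing: float = 1.0,
    schedule: AnnealingSchedule | None = None,
    suspect_mm: float = 1.0,
    fail_mm: float = 2.0,
) -> RegistrationResult:
    """Register two raw mm contours and return the mm-space transform.

    Pipeline: arc-length resampling of both contours at ``spacing``; one
    shared unit-box scaling from the union bounding box; annealed TPS-RPM in
    the unit box (with ``t_final`` defaulting to the squared resampling
    spacing in unit-box units); exact conjugation of the solved transform
    back to mm. The registration error of the deformed source against the
    target reference is computed and classified, never raised — failures are
    flagged for review, matching unattended batch use.
    """
    rs = resample_contour(source, spacing)
    rt = resample_contour(target, spacing)
    scaling = UnitBoxScaling.from_points(rs.points, rt.points)
    su = PointSet(scaling.forward(rs.points), closed=rs.closed)
    tu = PointSet(scaling.forward(rt.points), closed=rt.closed)
    sched = schedule or AnnealingSchedule()
    if sched.t_final is None:
        sched = dataclasses.replace(
            sched, t_final=sched.t_final_factor * (spacing / scaling.scale) ** 2
        )
    f_unit, corr, diag = anneal_register(su, tu, sched)
    f_mm = similarity_conjugate(f_unit, scaling)
    deformed = PointSet(f_mm(rs.points), closed=rs.closed)
    err = registration_error(deformed, rt)
    status = classify_error(err, suspect_mm, fail_mm)
    return RegistrationResult(
        transform=f_mm,
        transform_unit=f_unit,
        scaling=scaling,
        correspondence=corr,
        diagnostics=diag,
        error_mm=err,
        status=status,
        source_resampled=rs,
        target_resampled=rt,
    )
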