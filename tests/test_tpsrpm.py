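"""TPS solve, softassign, annealed registration."""

import numpy as np
import pytest

from swallowreg.preprocess import PointSet, UnitBoxScaling, to_unit_box
from swallowreg.synthetic import blob, ellipse
from swallowreg.tpsrpm import (
    AnnealingSchedule,
    anneal_register,
    register_pair,
    similarity_conjugate,
    softassign_update,
    tps_solve,
)


def brute_force_tps(control, targets):
    """Independent interpolation oracle: explicit-loop kernel + lstsq on the
    stacked interpolation and side-condition equations."""
    k = len(control)
    K = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            r = np.hypot(*(control[i] - control[j]))
            K[i, j] = 0.0 if r == 0 else r * r * np.log(r)
    P = np.column_stack([np.ones(k), control])
    A = np.zeros((k + 3, k + 3))
    A[:k, :k] = K
    A[:k, k:] = P
    A[k:, :k] = P.T
    rhs = np.vstack([targets, np.zeros((3, 2))])
    sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
    c, a = sol[:k], sol[k:]

    def f(xy):
        xy = np.atleast_2d(xy)
        out = np.empty_like(xy)
        for m, q in enumerate(xy):
            u = np.zeros(2)
            for j in range(k):
                r = np.hypot(*(q - control[j]))
                if r > 0:
                    u += r * r * np.log(r) * c[j]
            out[m] = a[0] + a[1:].T @ q + u
        return out

    return f


class TestTpsSolve:
    def test_identity_targets_give_identity(self, rng):
        V = rng.uniform(0, 1, (10, 2))
        f = tps_solve(V, V, lam=0.5)
        np.testing.assert_allclose(f.affine, np.eye(2), atol=1e-8)
        np.testing.assert_allclose(f.translation, 0.0, atol=1e-8)
        np.testing.assert_allclose(f.warp_coeffs, 0.0, atol=1e-8)

    def test_pure_translation_has_zero_bending(self, rng):
        V = rng.uniform(0, 1, (10, 2))
        t = np.array([0.3, -0.7])
        f = tps_solve(V, V + t, lam=2.0)
        np.testing.assert_allclose(f.affine, np.eye(2), atol=1e-8)
        np.testing.assert_allclose(f.translation, t, atol=1e-8)
        np.testing.assert_allclose(f.warp_coeffs, 0.0, atol=1e-8)

    @pytest.mark.parametrize("k", [5, 12, 27, 50])
    def test_interpolation_matches_brute_force_oracle(self, k, rng):
        V = rng.uniform(0, 1, (k, 2))
        Y = V + rng.normal(0, 0.15, (k, 2))
        f = tps_solve(V, Y, lam=0.0)
        assert np.abs(f(V) - Y).max() < 1e-6
        oracle = brute_force_tps(V, Y)
        q = rng.uniform(-0.2, 1.2, (7, 2))
        np.testing.assert_allclose(f(q), oracle(q), atol=1e-6)

    def test_side_conditions_hold(self, rng):
        V = rng.uniform(0, 1, (20, 2))
        Y = V + rng.normal(0, 0.1, (20, 2))
        w = rng.uniform(0.1, 2.0, 20)
        f = tps_solve(V, Y, w, lam=0.01)
        assert f.side_condition_residual() < 1e-8

    def test_large_lam_limit_is_weighted_affine(self, rng):
        # lam -> inf forces zero warp; compare against a weighted LS affine oracle
        V = rng.uniform(0, 1, (15, 2))
        Y = V @ np.array([[1.1, 0.2], [-0.1, 0.9]]).T + [0.05, -0.02]
        Y += rng.normal(0, 0.05, Y.shape)
        w = rng.uniform(0.5, 1.5, 15)
        f = tps_solve(V, Y, w, lam=1e6)
        sw = np.sqrt(w)[:, None]
        P = np.column_stack([np.ones(15), V])
        a = np.linalg.lstsq(P * sw, Y * sw, rcond=None)[0]
        np.testing.assert_allclose(f.warp_coeffs, 0.0, atol=1e-4)
        np.testing.assert_allclose(f.translation, a[0], atol=1e-4)
        np.testing.assert_allclose(f.affine, a[1:].T, atol=1e-4)

    def test_collinear_without_regularization_raises(self):
        V = np.column_stack([np.linspace(0, 1, 6), np.zeros(6)])
        with pytest.raises(np.linalg.LinAlgError, match="lam"):
            tps_solve(V, V + [0.1, 0.2], lam=0.0)

    def test_low_weight_points_are_dropped(self, rng):
        V = rng.uniform(0, 1, (10, 2))
        Y = V + 0.1
        w = np.ones(10)
        w[3] = 0.0  # pure outlier: must not influence the fit
        f = tps_solve(V, Y, w, lam=0.0)
        assert f.control_points.shape == (9, 2)
        np.testing.assert_allclose(f(V[3:4]), Y[3:4], atol=1e-6)  # rides the translation

    def test_affine_anchor_pulls_linear_part_to_identity(self, rng):
        V = rng.uniform(0, 1, (12, 2))
        Y = V @ np.array([[0.5, 0.0], [0.0, 0.5]]).T  # shrink
        f = tps_solve(V, Y, lam=1e6, lam_affine=1e9)
        np.testing.assert_allclose(f.affine, np.eye(2), atol=1e-2)


class TestSoftassign:
    def test_nearest_neighbor_limit(self):
        # two well-separated matched pairs: as T -> 0 the inner block becomes
        # diagonal; a small constant fraction stays in the fixed-temperature
        # outlier bins, so the diagonal is near 1 and off-diagonal vanishes
        W = np.array([[0.0, 0.0], [10.0, 0.0]])
        X = np.array([[0.0, 0.0], [10.0, 0.0]])
        m = softassign_update(W, X, T=1e-4, outlier_T=50.0)
        inner = m.inner
        assert inner[0, 0] > 0.95 and inner[1, 1] > 0.95
        assert inner[0, 1] < 1e-6 and inner[1, 0] < 1e-6

    def test_sinkhorn_normalization(self, rng):
        W = rng.uniform(0, 1, (20, 2))
        X = rng.uniform(0, 1, (25, 2))
        m = softassign_update(W, X, T=0.05, outlier_T=0.1)
        assert m.normalization_deviation() < 1e-3
        assert np.all(m.m >= 0)

    def test_far_target_goes_to_outlier_column(self):
        # a target much farther than sqrt(T) from every warped source has
        # zero inner affinity; its whole row mass lands in the outlier bin
        W = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        X = np.vstack([W, [[8.0, 8.0]]])
        m = softassign_update(W, X, T=0.01, outlier_T=30.0)
        assert m.target_outlier_mass[3] > 0.99

    def test_symmetric_targets_share_mass(self):
        W = np.array([[0.0, 0.0], [5.0, 5.0], [-5.0, 5.0]])
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])  # equidistant from source 0
        m = softassign_update(W, X, T=0.5, outlier_T=10.0)
        np.testing.assert_allclose(m.inner[0, 0], m.inner[1, 0], atol=1e-9)

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError, match="finite"):
            softassign_update(np.array([[np.inf, 0.0]]), np.zeros((2, 2)), 1.0, 1.0)


def _unit_blob(seed=0, n_pts=60):
    rng = np.random.default_rng(seed)
    pts = blob(rng, 1.0, n=n_pts)
    ps, _ = to_unit_box(PointSet(pts))
    return ps


class TestAnnealRegister:
    def test_identical_sets_recover_identity(self):
        # recovered transform is the identity on the control points; the
        # fixed-temperature outlier bins retain only a few-percent floor
        # (their Sinkhorn equilibrium mass scales with sqrt(T_final))
        ps = _unit_blob(1)
        f, corr, diag = anneal_register(ps, ps)
        assert np.abs(f(ps.points) - ps.points).max() < 1e-4
        assert corr.target_outlier_mass.max() < 0.05
        assert corr.source_outlier_mass.max() < 0.05

    def test_mild_affine_recovery(self):
        ps = _unit_blob(2)
        th = np.radians(15.0)
        A = 1.05 * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        target = PointSet(ps.points @ A.T + [0.05, -0.03])
        f, _, _ = anneal_register(ps, target)
        err = np.linalg.norm(f(ps.points) - target.points, axis=1)
        assert err.max() < 1e-2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_smooth_warp_with_outliers_in_both_sets(self, seed):
        # scattered cloud under a smooth TPS warp with 30% spurious points in
        # each set (kept clear of true points, so they are genuinely
        # spurious): >= 90% of true pairs must receive their maximum
        # correspondence, and the outlier bins must discriminate spurious
        # from true points. A scattered cloud is used because a closed
        # uniformly-resampled contour admits cyclic-shift matches that are
        # equally good at the contour level (the curve-matching aperture
        # degeneracy), which would confound the outlier check.
        from scipy.spatial.distance import cdist

        def spurious(rng, real, n, clearance=0.12):
            pts = []
            while len(pts) < n:
                cand = rng.uniform(0, 1, (1, 2))
                if cdist(cand, real).min() > clearance:
                    pts.append(cand[0])
            return np.array(pts)

        rng = np.random.default_rng(seed)
        src = rng.uniform(0.1, 0.9, (40, 2))
        ctrl = rng.uniform(0, 1, (4, 2))
        delta = rng.normal(0, 1.0, (4, 2))
        probe = tps_solve(ctrl, ctrl + delta, lam=1e-4)
        peak = np.linalg.norm(probe(src) - src, axis=1).max()
        true_f = tps_solve(ctrl, ctrl + delta * (0.06 / peak), lam=1e-4)
        tgt = true_f(src)
        src_full = np.vstack([src, spurious(rng, src, 12)])
        tgt_full = np.vstack([tgt, spurious(rng, tgt, 12)])
        f, corr, _ = anneal_register(PointSet(src_full), PointSet(tgt_full))
        inner = corr.inner  # rows: targets, cols: sources
        hits = sum(np.argmax(inner[:, j]) == j for j in range(len(src)))
        assert hits >= 0.9 * len(src)
        # spurious points hold far more outlier-bin mass than typical true
        # points (median: a missed pair may itself carry high bin mass)
        for bin_mass in (corr.source_outlier_mass, corr.target_outlier_mass):
            assert bin_mass[40:].mean() > 0.25
            assert bin_mass[40:].mean() > 5.0 * np.median(bin_mass[:40])

    def test_rigidity_anneals_bending_grows_as_t_falls(self, rng):
        src = _unit_blob(4, n_pts=50).points
        ctrl = rng.uniform(0, 1, (4, 2))
        true_f = tps_solve(ctrl, ctrl + rng.normal(0, 0.06, (4, 2)), lam=1e-4)
        f, _, diag = anneal_register(PointSet(src), PointSet(true_f(src)))
        assert diag[0]["bending_energy"] <= diag[-1]["bending_energy"] + 1e-12

    def test_deterministic(self):
        ps = _unit_blob(5)
        tgt = PointSet(ps.points + [0.1, 0.05])
        f1, c1, _ = anneal_register(ps, tgt)
        f2, c2, _ = anneal_register(ps, tgt)
        assert np.array_equal(f1.warp_coeffs, f2.warp_coeffs)
        assert np.array_equal(f1.affine, f2.affine)
        assert np.array_equal(c1.m, c2.m)


class TestRegisterPair:
    def test_identical_contours_give_identity_mm(self):
        base = PointSet(ellipse(14.0, 10.0))
        res = register_pair(base, base)
        rs = res.source_resampled
        disp = np.linalg.norm(res.transform(rs.points) - rs.points, axis=1)
        assert disp.max() < 0.01

    def test_translation_recovered_everywhere(self):
        base = PointSet(ellipse(14.0, 10.0))
        shifted = PointSet(base.points + [0.0, 5.0])
        res = register_pair(base, shifted)
        disp = res.transform(res.source_resampled.points) - res.source_resampled.points
        assert np.abs(disp - [0.0, 5.0]).max() < 0.1

    def test_elongate_contour_exposes_residual_diagnostics(self):
        # aspect >= 8:1; diagnostics must expose the final residual for flagging
        base = PointSet(ellipse(20.0, 2.5))
        res = register_pair(base, PointSet(base.points + [6.0, 0.0]))
        assert res.diagnostics
        assert "residual" in res.diagnostics[-1]
        assert res.status in ("ok", "suspect", "failed")

    def test_conjugation_matches_direct_evaluation(self, rng):
        base = PointSet(ellipse(14.0, 10.0, center=(40.0, 60.0)))
        tgt = PointSet(base.points + [2.0, 3.0])
        res = register_pair(base, tgt)
        s, o = res.scaling.scale, res.scaling.offset
        q = rng.uniform([20, 40], [60, 80], (30, 2))
        direct = o + s * res.transform_unit((q - o) / s)
        np.testing.assert_allclose(res.transform(q), direct, atol=1e-6)


class TestSimilarityConjugate:
    def test_closed_form_equals_scale_evaluate_unscale(self, rng):
        V = rng.uniform(0, 1, (15, 2))
        Y = V + rng.normal(0, 0.1, (15, 2))
        f = tps_solve(V, Y, lam=1e-3)
        scaling = UnitBoxScaling(offset=np.array([30.0, -12.0]), scale=45.0)
        g = similarity_conjugate(f, scaling)
        x = scaling.inverse(rng.uniform(-0.3, 1.3, (40, 2)))
        direct = scaling.inverse(f(scaling.forward(x)))
        np.testing.assert_allclose(g(x), direct, atol=1e-6)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            AnnealingSchedule(rate=1.2)
        with pytest.raises(ValueError):
            AnnealingSchedule(t_init=0.1, t_final=0.2)
        with pytest.raises(ValueError):
            AnnealingSchedule(inner_iters=0)
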