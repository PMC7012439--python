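"""Synthetic scene generator and its analytic ground truth."""

import numpy as np
import pytest
from shapely.geometry import LinearRing

from swallowreg.synthetic import (
    MotionModel,
    RoiSpec,
    SyntheticSpec,
    default_scene,
    generate_pair,
    generate_roi,
    generate_scene,
    reflex_pair,
)


def _ramp_roi(superior=10.0, peak=4):
    return RoiSpec("roi", "ellipse", (14.0, 10.0), (0.0, 0.0),
                   MotionModel(superior=superior, peak_frame=peak))


class TestGenerateRoi:
    def test_zero_amplitude_zero_noise_frames_identical(self):
        roi = RoiSpec("r", "ellipse", (10.0, 6.0), (0.0, 0.0), MotionModel())
        out = generate_roi(roi, n_frames=5, noise_sd=0.0, seed=0)
        for f in out.sequence.frames[1:]:
            np.testing.assert_array_equal(f.points, out.sequence.frames[0].points)
        np.testing.assert_allclose(out.truth_table.magnitudes, 0.0)

    def test_translation_ramp_truth_summary_exact(self):
        out = generate_roi(_ramp_roi(10.0, 4), n_frames=8, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(out.truth_table.summary[0], 10.0, atol=1e-12)
        # the peak-frame row carries the full amplitude
        np.testing.assert_allclose(out.truth_table.magnitudes[4, 0], 10.0, atol=1e-12)
        # motion is pure translation: truth equals the displacement profile
        for k in range(8):
            d = out.spec.motion.displacement(k, 8)
            np.testing.assert_allclose(
                out.truth_table.magnitudes[k, 0], max(d[1], 0.0), atol=1e-12
            )

    def test_first_frame_is_rest(self):
        out = generate_roi(_ramp_roi(), n_frames=6, noise_sd=0.3, seed=1)
        np.testing.assert_allclose(out.truth_table.magnitudes[0], 0.0)
        d0 = out.spec.motion.displacement(0, 6)
        np.testing.assert_allclose(d0, 0.0)

    def test_two_phase_model_reaches_both_amplitudes(self):
        roi = RoiSpec("r", "ellipse", (14.0, 10.0), (0.0, 0.0),
                      MotionModel(superior=8.0, inferior=5.0, peak_frame=5))
        out = generate_roi(roi, n_frames=16, noise_sd=0.0, seed=0)
        assert out.truth_table.summary[0] == pytest.approx(8.0)
        assert out.truth_table.summary[1] == pytest.approx(5.0, abs=0.8)

    def test_peak_frame_is_argmax(self):
        out = generate_roi(_ramp_roi(10.0, 4), n_frames=10, noise_sd=0.0, seed=0)
        si = out.truth_table.magnitudes[:, 0] + out.truth_table.magnitudes[:, 1]
        assert int(np.argmax(si)) == 4

    def test_outlier_fraction_adds_points(self):
        clean = generate_roi(_ramp_roi(), n_frames=4, noise_sd=0.0, seed=0)
        dirty = generate_roi(_ramp_roi(), n_frames=4, noise_sd=0.0,
                             outlier_fraction=0.25, seed=0)
        n0 = clean.sequence.frames[0].n
        assert dirty.sequence.frames[0].n == n0 + round(0.25 * n0)


class TestScene:
    def test_same_seed_bit_identical(self):
        spec = default_scene(seed=7, n_frames=6)
        a, b = generate_scene(spec), generate_scene(spec)
        assert list(a) == list(b)
        for name in a:
            for fa, fb in zip(a[name].sequence.frames, b[name].sequence.frames):
                assert np.array_equal(fa.points, fb.points)

    def test_different_seeds_differ(self):
        a = generate_scene(default_scene(seed=0, n_frames=4))
        b = generate_scene(default_scene(seed=1, n_frames=4))
        name = next(iter(a))
        assert not np.array_equal(
            a[name].sequence.frames[1].points, b[name].sequence.frames[1].points
        )

    def test_default_scene_has_seven_rois_with_study_names(self):
        spec = default_scene()
        assert len(spec.rois) == 7
        names = {r.name for r in spec.rois}
        assert "pharyngeal_constrictor" in names and "larynx" in names
        pc = next(r for r in spec.rois if r.name == "pharyngeal_constrictor")
        assert pc.size[0] / pc.size[1] >= 8.0  # narrow elongate
        larynx = next(r for r in spec.rois if r.name == "larynx")
        assert larynx.motion.superior == pytest.approx(18.4)

    def test_contours_remain_simple_polygons(self):
        # jittered contours must not self-intersect (hand contours never do)
        for sd in (0.2, 0.5):
            scene = generate_scene(default_scene(seed=0, n_frames=8, noise_sd=sd))
            for sr in scene.values():
                for ps in sr.sequence.frames:
                    assert LinearRing(ps.points).is_simple

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticSpec(rois=(), n_frames=1)
        with pytest.raises(ValueError):
            SyntheticSpec(rois=(), outlier_fraction=1.0)


class TestPairs:
    def test_pair_reproducible(self):
        s1, t1, _ = generate_pair(3, "smooth")
        s2, t2, _ = generate_pair(3, "smooth")
        assert np.array_equal(s1.points, s2.points)
        assert np.array_equal(t1.points, t2.points)

    def test_warp_amplitude_bounded(self):
        for seed in range(5):
            src, _, warp = generate_pair(seed, "smooth", max_amplitude_mm=15.0,
                                         noise_sd=0.0)
            disp = np.linalg.norm(warp(src.points) - src.points, axis=1)
            assert disp.max() <= 15.0 + 1e-6

    def test_hard_family_has_elongated_members(self):
        aspects = []
        for seed in range(8):
            src, _, _ = generate_pair(seed, "hard", noise_sd=0.0)
            lo, hi = src.bbox
            ext = hi - lo
            aspects.append(max(ext) / min(ext))
        assert max(aspects) >= 4.0

    def test_unknown_family_raises(self):
        with pytest.raises(ValueError, match="family"):
            generate_pair(0, "nope")

    def test_reflex_pair_is_narrow_elongate(self):
        src, tgt = reflex_pair()
        lo, hi = src.bbox
        ext = hi - lo
        assert max(ext) / min(ext) >= 8.0
        assert tgt.n > src.n  # spurious points present on the target frame
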