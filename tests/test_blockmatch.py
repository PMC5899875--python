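import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryoreg.blockmatch import (AffineTransform, BlockMatchConfig, BlockMatchSet,
                                abs_ncc, block_displacement_field,
                                fit_transform_trimmed, register_affine_multiscale)
from cryoreg.volume_io import Volume

from conftest import landmark_error_mm


def textured_volume(seed=0, shape=(48, 40, 40), spacing=0.25):
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter

    data = gaussian_filter(rng.standard_normal(shape), 2.0)
    data = 128 + 100 * data / np.abs(data).max()
    return Volume(data, (spacing,) * 3)


SMALL_CFG = BlockMatchConfig(block_size=8, search_size=14, block_overlap=3,
                             n_levels=2, n_iterations=10)


class TestAbsNcc:
    def test_self_correlation(self, rng):
        b = rng.uniform(0, 255, (6, 6, 6))
        assert abs_ncc(b, b) == pytest.approx(1.0)

    def test_polarity_invariance(self, rng):
        b = rng.uniform(0, 255, (6, 6, 6))
        assert abs_ncc(b, 255 - b) == pytest.approx(1.0)

    def test_independent_blocks_near_zero(self):
        rng = np.random.default_rng(99)
        a = rng.uniform(0, 255, (20, 20, 20))
        b = rng.uniform(0, 255, (20, 20, 20))
        score = abs_ncc(a, b)
        # oracle: direct correlation formula on the same data
        fa, fb = a.ravel() - a.mean(), b.ravel() - b.mean()
        direct = abs(float((fa * fb).sum()) / np.sqrt((fa**2).sum() * (fb**2).sum()))
        assert score == pytest.approx(direct)
        assert score < 0.1

    def test_zero_variance_signalled(self):
        with pytest.raises(ZeroDivisionError):
            abs_ncc(np.full((4, 4, 4), 7.0), np.ones((4, 4, 4)))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            abs_ncc(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)))

    @settings(max_examples=25, deadline=None)
    @given(gain=st.floats(-3, 3).filter(lambda g: abs(g) > 0.01),
           offset=st.floats(-50, 50))
    def test_symmetric_and_affine_intensity_invariant(self, gain, offset):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 255, (5, 5, 5))
        b = rng.uniform(0, 255, (5, 5, 5))
        assert abs_ncc(a, b) == pytest.approx(abs_ncc(b, a))
        assert abs_ncc(gain * a + offset, b) == pytest.approx(abs_ncc(a, b), abs=1e-9)


class TestBlockDisplacementField:
    def test_exact_integer_shift(self):
        ref = textured_volume(1)
        shifted = np.roll(ref.data, 2, axis=0)  # mov(y) = ref(y - 2 vox): content moved +2
        mov = Volume(shifted, ref.spacing)
        matches = block_displacement_field(ref, mov, SMALL_CFG)
        # interior blocks all report exactly 2 voxels * spacing along x
        disp = matches.displacements
        expected = np.array([2 * ref.spacing[0], 0, 0])
        frac = (np.linalg.norm(disp - expected, axis=1) < 1e-9).mean()
        assert frac > 0.8

    def test_zero_displacement_for_identical(self):
        ref = textured_volume(2)
        matches = block_displacement_field(ref, ref, SMALL_CFG)
        assert np.allclose(matches.displacements, 0.0)
        assert np.allclose(matches.scores, 1.0)

    def test_contrast_inverted_shift(self):
        ref = textured_volume(3)
        mov = Volume(np.roll(255 - ref.data, 3, axis=1), ref.spacing)
        matches = block_displacement_field(ref, mov, SMALL_CFG)
        expected = np.array([0, 3 * ref.spacing[1], 0])
        frac = (np.linalg.norm(matches.displacements - expected, axis=1) < 1e-9).mean()
        assert frac > 0.8

    def test_grid_mismatch_rejected(self):
        ref = textured_volume(1)
        mov = Volume(np.zeros((10, 10, 10)), ref.spacing)
        with pytest.raises(ValueError):
            block_displacement_field(ref, mov, SMALL_CFG)

    def test_variance_filter_keeps_fraction(self):
        ref = textured_volume(4)
        cfg = BlockMatchConfig(block_size=8, search_size=14, block_overlap=3,
                               variance_keep_fraction=0.25)
        m_quarter = block_displacement_field(ref, ref, cfg)
        m_all = block_displacement_field(
            ref, ref, BlockMatchConfig(block_size=8, search_size=14, block_overlap=3,
                                       variance_keep_fraction=1.0))
        assert len(m_quarter) < len(m_all)
        assert m_quarter.variances.min() >= np.median(m_all.variances) - 1e-12


def _matches_from_transform(t: AffineTransform, n=60, seed=0, outlier_frac=0.0):
    rng = np.random.default_rng(seed)
    src = rng.uniform(0, 20, (n, 3))
    dst = t.apply(src)
    n_out = int(outlier_frac * n)
    if n_out:
        dst[:n_out] += rng.uniform(-15, 15, (n_out, 3))
    disp = dst - src
    return BlockMatchSet(src, disp, np.ones(n), np.ones(n))


class TestFitTransformTrimmed:
    def test_pure_translation(self):
        t = AffineTransform.from_translation([1.0, -2.0, 0.5])
        fit = fit_transform_trimmed(_matches_from_transform(t), "affine", 0.0)
        assert np.allclose(fit.matrix, np.eye(3), atol=1e-9)
        assert np.allclose(fit.translation, t.translation, atol=1e-9)

    def test_outlier_robustness(self):
        truth = AffineTransform(np.array([[1.02, 0.03, 0.0],
                                          [-0.02, 0.98, 0.01],
                                          [0.0, 0.01, 1.01]]), [0.5, -0.3, 0.2])
        matches = _matches_from_transform(truth, n=100, seed=7, outlier_frac=0.3)
        fit = fit_transform_trimmed(matches, "affine", 0.5)
        assert np.abs(fit.matrix - truth.matrix).max() < 0.01
        assert np.linalg.norm(fit.translation - truth.translation) < 0.1

    def test_rigid_rotation_recovery(self):
        ang = np.radians(10.0)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0],
                        [0, 0, 1]])
        truth = AffineTransform(rot, [1.0, 0.0, -0.5])
        fit = fit_transform_trimmed(_matches_from_transform(truth, seed=3), "rigid", 0.2)
        recovered_angle = np.degrees(np.arctan2(fit.matrix[1, 0], fit.matrix[0, 0]))
        assert recovered_angle == pytest.approx(10.0, abs=0.1)
        # rigid constraint: linear part is a rotation
        assert np.allclose(fit.matrix @ fit.matrix.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(fit.matrix) == pytest.approx(1.0)

    def test_no_rejection_equals_ordinary_least_squares(self):
        truth = AffineTransform(np.array([[1.1, 0.0, 0.05],
                                          [0.02, 0.9, 0.0],
                                          [0.0, 0.0, 1.0]]), [2.0, 1.0, 0.0])
        matches = _matches_from_transform(truth, n=40, seed=5)
        rng = np.random.default_rng(8)
        matches.displacements += rng.normal(0, 0.05, matches.displacements.shape)
        fit = fit_transform_trimmed(matches, "affine", 0.0)
        # oracle: normal equations on the same pairs
        src = matches.centers
        dst = matches.centers + matches.displacements
        hom = np.hstack([src, np.ones((len(src), 1))])
        sol = np.linalg.solve(hom.T @ hom, hom.T @ dst)
        assert np.allclose(fit.matrix, sol[:3].T, atol=1e-10)
        assert np.allclose(fit.translation, sol[3], atol=1e-10)

    def test_insufficient_matches(self):
        m = BlockMatchSet(np.zeros((2, 3)), np.zeros((2, 3)), np.ones(2), np.ones(2))
        with pytest.raises(ValueError):
            fit_transform_trimmed(m, "affine", 0.0)

    def test_coplanar_centers_rejected(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 10, (20, 3))
        src[:, 2] = 1.0  # coplanar
        m = BlockMatchSet(src, np.zeros((20, 3)), np.ones(20), np.ones(20))
        with pytest.raises(ValueError, match="coplanar|singular"):
            fit_transform_trimmed(m, "affine", 0.0)


class TestRegisterAffineMultiscale:
    def test_self_registration_near_identity(self):
        ref = textured_volume(6)
        t = register_affine_multiscale(ref, ref, SMALL_CFG)
        assert np.abs(t.matrix - np.eye(3)).max() < 0.01
        assert np.linalg.norm(t.translation) < 0.5 * min(ref.spacing)

    def test_phantom_affine_recovery(self, affine_pair):
        cfg = BlockMatchConfig(block_size=12, search_size=18, block_overlap=3,
                               n_levels=3, n_iterations=20)
        t = register_affine_multiscale(affine_pair.ref, affine_pair.mov, cfg)
        err = landmark_error_mm(affine_pair, t)
        assert err < affine_pair.ref.spacing[0]  # < 1 voxel

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BlockMatchConfig(block_size=20, search_size=10)
        with pytest.raises(ValueError):
            BlockMatchConfig(variance_keep_fraction=0.0)
        with pytest.raises(ValueError):
            BlockMatchConfig(reject_fraction=1.0)
        with pytest.raises(ValueError):
            BlockMatchConfig(model="projective")


class TestAffineTransform:
    def test_compose_and_inverse(self, rng):
        a = AffineTransform(np.eye(3) + 0.05 * rng.standard_normal((3, 3)),
                            rng.standard_normal(3))
        b = AffineTransform(np.eye(3) + 0.05 * rng.standard_normal((3, 3)),
                            rng.standard_normal(3))
        pts = rng.uniform(-5, 5, (10, 3))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)))
        assert np.allclose(a.compose(a.inverse()).apply(pts), pts, atol=1e-9)

    def test_json_roundtrip(self, tmp_path):
        t = AffineTransform(np.diag([1.1, 0.9, 1.0]), [1, 2, 3])
        t.to_json(tmp_path / "t.json")
        back = AffineTransform.from_json(tmp_path / "t.json")
        assert np.allclose(back.matrix, t.matrix)
        assert np.allclose(back.translation, t.translation)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(np.zeros((3, 3)), np.zeros(3))
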