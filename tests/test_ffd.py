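import numpy as np
import pytest

from cryoreg.blockmatch import AffineTransform
from cryoreg.ffd import (CostBreakdown, FFDConfig, FFDTransform, FoldingError,
                         _LevelProblem, bending_energy, compose_and_resample,
                         jacobian_det_map, jacobian_log_penalty, nmi, optimize_ffd,
                         total_cost)
from cryoreg.volume_io import Volume

from conftest import landmark_error_mm

SPACING = 0.2


def small_domain(shape=(20, 16, 14)):
    return Volume(np.zeros(shape), (SPACING,) * 3)


def lattice_positions(t: FFDTransform, axis: int) -> np.ndarray:
    """Physical positions of control points along one axis (mm)."""
    n = t.control_points.shape[axis]
    return ((np.arange(n) - 1) * t.grid_spacing[axis] * t.domain_spacing[axis]
            + t.domain_origin[axis])


def affine_ffd(domain, matrix, translation, grid_spacing=4.0) -> FFDTransform:
    """Encode the displacement of an affine map exactly on the lattice.

    Cubic B-splines reproduce linear functions when coefficients are the
    nodal values.
    """
    t = FFDTransform.identity(domain, grid_spacing)
    px, py, pz = (lattice_positions(t, a) for a in range(3))
    pos = np.stack(np.meshgrid(px, py, pz, indexing="ij"), axis=-1)
    disp = pos @ (np.asarray(matrix) - np.eye(3)).T + np.asarray(translation)
    return FFDTransform(disp, t.grid_spacing, t.domain_shape, t.domain_spacing,
                        t.domain_origin)


class TestNmi:
    def test_identical_images_give_2(self, rng):
        img = rng.integers(0, 256, (12, 12, 12)).astype(float)
        assert nmi(img, img) == pytest.approx(2.0)

    def test_inverted_image_gives_2(self, rng):
        img = rng.integers(0, 256, (12, 12, 12)).astype(float)
        assert nmi(img, 255 - img) == pytest.approx(2.0)

    def test_constructed_independence_gives_1(self):
        # I1 varies along x only, I2 along y only, balanced proportions:
        # the joint histogram is exactly the outer product of the marginals
        n = 16
        i1 = np.zeros((n, n, n))
        i1[n // 2:] = 100
        i2 = np.zeros((n, n, n))
        i2[:, n // 2:] = 200
        assert nmi(i1, i2) == pytest.approx(1.0)

    def test_bin_relabeling_invariance(self, rng):
        img = rng.integers(0, 200, (10, 10, 10)).astype(float)
        other = rng.integers(0, 256, (10, 10, 10)).astype(float)
        base = nmi(img, other)
        relabeled = (img * 1.27 + 3) % 256  # injective on the integer values present
        assert nmi(np.floor(relabeled), other) == pytest.approx(base, abs=1e-9)

    def test_range_bounds(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            a = r.integers(0, 256, (10, 10, 10)).astype(float)
            b = r.integers(0, 256, (10, 10, 10)).astype(float)
            val = nmi(a, b)
            assert 1.0 - 1e-9 <= val <= 2.0 + 1e-9

    def test_mask(self, rng):
        a = rng.integers(0, 256, (10, 10, 10)).astype(float)
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[:5] = True
        assert nmi(a, a, mask=mask) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            nmi(a, a, mask=np.zeros((10, 10, 10), dtype=bool))

    def test_degenerate_histogram(self):
        const = np.full((8, 8, 8), 42.0)
        with pytest.raises(ValueError):
            nmi(const, const)


class TestBendingEnergy:
    def test_identity_zero(self):
        t = FFDTransform.identity(small_domain(), 4.0)
        assert bending_energy(t) == pytest.approx(0.0, abs=1e-18)

    def test_affine_field_zero(self):
        m = np.array([[1.05, 0.02, 0.0], [0.0, 0.97, 0.01], [0.01, 0.0, 1.0]])
        t = affine_ffd(small_domain(), m, [0.4, -0.2, 0.1])
        n = np.prod(t.domain_shape)
        assert bending_energy(t) / n == pytest.approx(0.0, abs=1e-16)

    def test_quadratic_field_4n(self):
        # u_x(x) = x^2: coefficients are x_i^2 - h^2/3 (exact quadratic reproduction)
        domain = small_domain()
        t = FFDTransform.identity(domain, 4.0)
        px = lattice_positions(t, 0)
        h = t.grid_spacing[0] * t.domain_spacing[0]
        cp = np.zeros_like(t.control_points)
        cp[..., 0] = (px**2 - h**2 / 3.0)[:, None, None]
        t = FFDTransform(cp, t.grid_spacing, t.domain_shape, t.domain_spacing)
        n = np.prod(domain.shape)
        # d2(x^2)/dx2 = 2 everywhere -> squared = 4 per evaluation point
        assert bending_energy(t) == pytest.approx(4.0 * n, rel=1e-9)

    def test_finite_difference_oracle(self, rng):
        # compare analytic second derivatives of the deformation against
        # central differences at points whose FD stencils stay inside one
        # spline cell (the second derivative is only C0 at the knots)
        domain = small_domain((14, 12, 10))
        t = FFDTransform.identity(domain, 3.0)
        cp = 0.05 * rng.standard_normal(t.control_points.shape)
        t = FFDTransform(cp, t.grid_spacing, t.domain_shape, t.domain_spacing)
        from cryoreg import _bspline as bsp

        gs = np.asarray(t.grid_spacing)
        step_mm = gs * np.asarray(t.domain_spacing)
        h_vox = 0.05  # FD step in voxels
        pts = rng.uniform(3.0, np.asarray(domain.shape) - 4.0, size=(400, 3))
        # keep points whose stencil avoids the knots (multiples of gs)
        frac = (pts / gs) % 1.0
        keep = np.all((frac > 2.5 * h_vox / gs) & (frac < 1 - 2.5 * h_vox / gs), axis=1)
        pts = pts[keep]
        assert len(pts) > 100

        def field(p):
            return bsp.evaluate_at_points(cp, p, t.grid_spacing)

        h_mm = h_vox * np.asarray(t.domain_spacing)
        mults = {(0, 0): 1, (1, 1): 1, (2, 2): 1, (0, 1): 2, (0, 2): 2, (1, 2): 2}
        fd_total, analytic_total = 0.0, 0.0
        for (i, j), mult in mults.items():
            ei = np.zeros(3)
            ei[i] = h_vox
            if i == j:
                fd = (field(pts + ei) - 2 * field(pts) + field(pts - ei)) / h_mm[i] ** 2
            else:
                ej = np.zeros(3)
                ej[j] = h_vox
                fd = (field(pts + ei + ej) - field(pts + ei - ej)
                      - field(pts - ei + ej) + field(pts - ei - ej)) / (4 * h_mm[i] * h_mm[j])
            derivs = [0, 0, 0]
            derivs[i] += 1
            derivs[j] += 1
            exact = bsp.evaluate_at_points(cp, pts, t.grid_spacing, derivs=derivs,
                                           step_mm=step_mm)
            assert np.abs(fd - exact).max() < 1e-3 * max(np.abs(exact).max(), 1.0)
            fd_total += mult * float((fd**2).sum())
            analytic_total += mult * float((exact**2).sum())
        assert fd_total == pytest.approx(analytic_total, rel=2e-3)


class TestJacobian:
    def test_identity_penalty_zero(self):
        t = FFDTransform.identity(small_domain(), 4.0)
        assert jacobian_log_penalty(t) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_scale_penalty(self):
        for s in (2.0, 0.5):
            t = affine_ffd(small_domain(), np.eye(3) * s, [0, 0, 0])
            n = np.prod(t.domain_shape)
            # det J = s^3 at every point
            assert jacobian_log_penalty(t) == pytest.approx(3 * n * abs(np.log(s)), rel=1e-9)
        up = jacobian_log_penalty(affine_ffd(small_domain(), np.eye(3) * 2, [0, 0, 0]))
        down = jacobian_log_penalty(affine_ffd(small_domain(), np.eye(3) * 0.5, [0, 0, 0]))
        assert up == pytest.approx(down, rel=1e-9)

    def test_single_point_scale_log8(self):
        t = affine_ffd(Volume(np.zeros((1, 1, 1)), (SPACING,) * 3), np.eye(3) * 2, [0, 0, 0])
        assert jacobian_log_penalty(t) == pytest.approx(np.log(8.0), rel=1e-9)

    def test_det_map_identity_and_translation(self):
        t = FFDTransform.identity(small_domain(), 4.0)
        assert np.allclose(jacobian_det_map(t).data, 1.0)
        t = affine_ffd(small_domain(), np.eye(3), [1.0, 2.0, 3.0])
        assert np.allclose(jacobian_det_map(t).data, 1.0)

    def test_det_map_anisotropic_scale(self):
        t = affine_ffd(small_domain(), np.diag([1.1, 1.0, 1.0]), [0, 0, 0])
        det = jacobian_det_map(t).data
        assert np.allclose(det, 1.1, atol=1e-9)
        # oracle: central finite differences of the mapped coordinates
        disp = t.displacement_field()
        fd = 1.0 + (np.roll(disp[..., 0], -1, 0) - np.roll(disp[..., 0], 1, 0)) / (2 * SPACING)
        assert np.allclose(det[2:-2, 2:-2, 2:-2], fd[2:-2, 2:-2, 2:-2], atol=1e-9)

    def test_folding_reported_with_location(self):
        t = affine_ffd(small_domain(), np.diag([-1.0, 1.0, 1.0]), [0, 0, 0])
        with pytest.raises(FoldingError) as err:
            jacobian_log_penalty(t)
        assert err.value.location is not None


class TestTotalCost:
    def test_identity_self_cost_is_minus_two(self, rng):
        data = rng.integers(0, 256, (16, 12, 12)).astype(float)
        vol = Volume(data, (SPACING,) * 3)
        cfg = FFDConfig(w1=0.0, w2=0.0)
        t = FFDTransform.identity(vol, cfg.grid_spacing)
        cost = total_cost(vol, vol, t, cfg)
        assert cost.nmi == pytest.approx(2.0)
        assert cost.total == pytest.approx(-2.0)

    def test_identity_regularizers_zero(self, rng):
        data = rng.integers(0, 256, (16, 12, 12)).astype(float)
        vol = Volume(data, (SPACING,) * 3)
        cfg = FFDConfig(w1=0.045, w2=0.055)
        t = FFDTransform.identity(vol, cfg.grid_spacing)
        cost = total_cost(vol, vol, t, cfg)
        assert cost.be == pytest.approx(0.0, abs=1e-15)
        assert cost.jl == pytest.approx(0.0, abs=1e-12)

    def test_assembly_matches_term_recomputation(self, rng):
        ref = Volume(rng.integers(0, 256, (16, 12, 12)).astype(float), (SPACING,) * 3)
        mov = Volume(rng.integers(0, 256, (16, 12, 12)).astype(float), (SPACING,) * 3)
        cfg = FFDConfig(w1=0.045, w2=0.055, grid_spacing=4.0)
        t = FFDTransform.identity(ref, cfg.grid_spacing)
        cp = t.control_points + 0.02 * rng.standard_normal(t.control_points.shape)
        t = FFDTransform(cp, t.grid_spacing, t.domain_shape, t.domain_spacing)
        cost = total_cost(ref, mov, t, cfg)
        n = np.prod(ref.shape)
        warped = compose_and_resample(mov, None, t, ref)
        # independent term-by-term recomputation (same clamped-sampling NMI)
        be = bending_energy(t) / n
        jl = jacobian_log_penalty(t) / n
        assert cost.be == pytest.approx(be, rel=1e-9)
        assert cost.jl == pytest.approx(jl, rel=1e-9)
        expected = -(1 - 0.045 - 0.055) * cost.nmi + 0.045 * be + 0.055 * jl
        assert cost.total == pytest.approx(expected, rel=1e-12)


def assert_total_cost_gradient_ok(seed: int = 404) -> None:
    """Gradient vs central differences, one assertion per cost term.

    The data-term gradient is itself a central difference at the configured
    step, so it must match the total-cost oracle at that step to machine
    precision; the analytic BE/JL gradients are checked against small-step
    central differences of their own (smooth) functions to < 1e-3.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    ref = Volume(np.floor(rng.uniform(0, 256, (14, 12, 10))), (SPACING,) * 3)
    mov_data = np.clip(gaussian_filter(ref.data, 1.0) + rng.normal(0, 5, ref.shape), 0, 255)
    mov = Volume(mov_data, ref.spacing)
    t = FFDTransform.identity(ref, 4.0)
    cp = 0.03 * rng.standard_normal(t.control_points.shape)

    # data term at the optimizer's step
    cfg = FFDConfig(w1=0.0, w2=0.0, grid_spacing=4.0)
    prob = _LevelProblem(ref, mov, (4.0,) * 3, cfg, AffineTransform.identity())
    _, _, _, _, state = prob.cost(cp)
    g = prob.gradient(cp, state)
    d = prob.fd_step
    idx_rng = np.random.default_rng(0)
    for _ in range(12):
        idx = tuple(idx_rng.integers(0, s) for s in cp.shape)
        cp_p, cp_m = cp.copy(), cp.copy()
        cp_p[idx] += d
        cp_m[idx] -= d
        fd = (prob.cost(cp_p)[0] - prob.cost(cp_m)[0]) / (2 * d)
        assert abs(g[idx] - fd) <= 1e-9 * max(1.0, abs(fd))

    # analytic regularizer gradients vs small-step central differences.
    # |log|det|| has a kink at det = 1, so bias the field with a uniform
    # expansion to keep every evaluation point on one smooth branch.
    def make_t(arr):
        return FFDTransform(arr, t.grid_spacing, t.domain_shape, t.domain_spacing)

    scale_field = affine_ffd(ref, np.eye(3) * 1.1, [0, 0, 0], grid_spacing=4.0)
    cp = scale_field.control_points + cp
    be_grad = prob._be_gradient(cp)
    _, jac, det = prob._regularizers(cp)
    assert det.min() > 1.05  # away from the |log| kink
    jl_grad = prob._jl_gradient(jac, det)
    eps = 1e-4
    checked = 0
    for _ in range(12):
        idx = tuple(idx_rng.integers(0, s) for s in cp.shape)
        cp_p, cp_m = cp.copy(), cp.copy()
        cp_p[idx] += eps
        cp_m[idx] -= eps
        fd_be = (bending_energy(make_t(cp_p)) - bending_energy(make_t(cp_m))) / (2 * eps)
        fd_jl = (jacobian_log_penalty(make_t(cp_p))
                 - jacobian_log_penalty(make_t(cp_m))) / (2 * eps)
        for analytic, fd in ((be_grad[idx], fd_be), (jl_grad[idx], fd_jl)):
            if abs(fd) < 1e-8:
                continue
            assert abs(analytic - fd) / abs(fd) < 1e-3
            checked += 1
    assert checked >= 8


class TestGradient:
    def test_gradient_matches_central_differences(self):
        assert_total_cost_gradient_ok()


class TestOptimizeAndResample:
    def test_self_registration_stays_small(self, rng):
        from scipy.ndimage import gaussian_filter

        data = 128 + 80 * gaussian_filter(rng.standard_normal((24, 20, 20)), 2.0)
        vol = Volume(np.clip(data, 0, 255), (SPACING,) * 3)
        cfg = FFDConfig(n_levels=2, max_iterations=20)
        t = optimize_ffd(vol, vol, None, cfg)
        max_disp = np.linalg.norm(t.control_points, axis=-1).max()
        assert max_disp < 0.5 * SPACING

    def test_warp_recovery_improves_on_affine(self, warp_pair):
        pair = warp_pair
        cfg = FFDConfig(n_levels=3, max_iterations=80)
        ident = AffineTransform.identity()
        t = optimize_ffd(pair.ref, pair.mov, ident, cfg)
        pre = landmark_error_mm(pair, ident)
        post = landmark_error_mm(pair, ident, t)
        assert post < pair.ref.spacing[0]  # < 1 voxel
        assert post < pre
        # monotone descent within each level
        for trace in t.cost_trace:
            assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_compose_identity_exact_copy(self, rng):
        vol = Volume(rng.uniform(0, 255, (12, 10, 10)), (SPACING,) * 3)
        t = FFDTransform.identity(vol, 4.0)
        out = compose_and_resample(vol, AffineTransform.identity(), t, vol)
        assert np.allclose(out.data, vol.data, atol=1e-9)

    def test_whole_voxel_translation_exact(self, rng):
        vol = Volume(rng.uniform(0, 255, (12, 10, 10)), (SPACING,) * 3)
        shift = AffineTransform.from_translation([SPACING, 0, 0])
        out = compose_and_resample(vol, shift, None, vol)
        assert np.allclose(out.data[:-1], vol.data[1:], atol=1e-9)

    def test_one_step_beats_two_step(self):
        # analytic high-frequency moving image with a known smooth warp
        shape = (24, 20, 20)
        sp = (SPACING,) * 3

        def f(p):
            return (128 + 60 * np.sin(7.0 * p[..., 0]) * np.cos(6.0 * p[..., 1])
                    + 30 * np.sin(9.0 * p[..., 2]))

        idx = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                                   indexing="ij"), axis=-1)
        phys = idx * SPACING
        mov = Volume(f(phys), sp)
        out_grid = Volume(np.zeros(shape), sp)
        affine = AffineTransform.from_translation([0.07, -0.05, 0.03])
        domain = Volume(np.zeros(shape), sp)
        t = FFDTransform.identity(domain, 5.0)
        cp = t.control_points.copy()
        cp[..., 0] = 0.04
        cp[..., 1] = -0.03
        warp = FFDTransform(cp, t.grid_spacing, t.domain_shape, t.domain_spacing)

        one = compose_and_resample(mov, affine, warp, out_grid)
        half = compose_and_resample(mov, affine, None, out_grid)
        two = compose_and_resample(half, None, warp, out_grid)

        mapped = affine.apply((phys + warp.displacement_field()).reshape(-1, 3))
        truth = f(mapped.reshape(phys.shape))
        inner = (slice(2, -2),) * 3
        err_one = np.abs(one.data - truth)[inner].mean()
        err_two = np.abs(two.data - truth)[inner].mean()
        assert err_one < err_two


class TestConfigAndSerialization:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            FFDConfig(w1=0.5, w2=0.5)
        with pytest.raises(ValueError):
            FFDConfig(w1=-0.1)
        with pytest.raises(ValueError):
            FFDConfig(tolerance=0.0)
        with pytest.raises(ValueError):
            FFDConfig(grid_spacing=1.0)

    def test_ffd_json_roundtrip(self, tmp_path, rng):
        t = FFDTransform.identity(small_domain(), 4.0)
        cp = rng.standard_normal(t.control_points.shape)
        t = FFDTransform(cp, t.grid_spacing, t.domain_shape, t.domain_spacing)
        t.to_json(tmp_path / "f.json")
        back = FFDTransform.from_json(tmp_path / "f.json")
        assert np.allclose(back.control_points, cp)
        assert back.domain_shape == t.domain_shape

    def test_lattice_must_cover_domain(self):
        with pytest.raises(ValueError):
            FFDTransform(np.zeros((2, 2, 2, 3)), (4.0,) * 3, (20, 16, 14),
                         (SPACING,) * 3)
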