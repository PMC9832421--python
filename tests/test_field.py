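"""Deformation fields: evaluation, warping, rotation closure, cancellation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from zflex.basis import BasisSpec
from zflex.field import (
    AtomicModel,
    CoefficientSet,
    VolumeGrid,
    cancel_projection_component,
    deformation_magnitude,
    evaluate_field,
    inplane_subspace,
    molecular_mask,
    negate,
    rescale_coefficients,
    rotate_coefficients,
    warp_model,
    warp_volume,
    warp_volume_adjoint,
)

CONST = np.sqrt(3.0) / (2.0 * np.sqrt(np.pi))  # value of the (0,0,0) mode


@pytest.fixture
def rng():
    return np.random.default_rng(11)


def random_coeffs(spec, rng, scale=0.1, radius=48.0):
    return CoefficientSet(spec, rng.normal(size=(spec.size, 3)) * scale, radius)


class TestEvaluateField:
    def test_zero_coefficients(self, spec):
        c = CoefficientSet.zeros(spec, 50.0)
        g = evaluate_field(c, np.array([[0.1, 0.2, 0.3], [0, 0, 0]]))
        assert np.all(g == 0)

    def test_constant_mode_along_x(self, spec):
        c = CoefficientSet.zeros(spec, 50.0)
        c.alphas[0, 0] = 1.0  # alpha^x_{0,0,0}
        g = evaluate_field(c, np.array([0.3, -0.2, 0.1]))
        np.testing.assert_allclose(g, [CONST, 0, 0], atol=1e-12)

    def test_linearity(self, spec, rng):
        c1 = random_coeffs(spec, rng)
        c2 = random_coeffs(spec, rng)
        pts = rng.uniform(-0.5, 0.5, size=(30, 3))
        np.testing.assert_allclose(
            evaluate_field(c1 + c2, pts),
            evaluate_field(c1, pts) + evaluate_field(c2, pts),
            atol=1e-12,
        )


class TestWarpVolume:
    def test_zero_coefficients_is_identity(self, spec, scene48):
        phantom, _ = scene48
        out = warp_volume(phantom, CoefficientSet.zeros(spec, phantom.default_scale_radius))
        np.testing.assert_array_equal(out.values, phantom.values)

    def test_constant_field_translates_against_displacement(self, spec, scene48):
        # gather semantics: out(r) = in(r + d) == input shifted by -d voxels
        phantom, _ = scene48
        sr = phantom.default_scale_radius
        c = CoefficientSet.zeros(spec, sr)
        d_vox = 2.0
        c.alphas[0, 0] = d_vox * phantom.voxel_size / sr / CONST
        out = warp_volume(phantom, c)
        from scipy.ndimage import shift as nd_shift

        oracle = nd_shift(phantom.values, (-d_vox, 0, 0), order=1)
        # compare away from the ball boundary where the field switches off
        core = (slice(8, 40),) * 3
        dyn = phantom.values.max()
        assert np.abs(out.values[core] - oracle[core]).max() < 0.05 * dyn

    def test_first_order_inverse(self, spec, scene48, rng):
        phantom, _ = scene48
        sr = phantom.default_scale_radius
        c = CoefficientSet(spec, rng.normal(size=(spec.size, 3)) * 0.01, sr)
        back = warp_volume(warp_volume(phantom, c), negate(c))
        double = warp_volume(phantom, 2.0 * c)
        err_back = np.sqrt(((back.values - phantom.values) ** 2).mean())
        err_double = np.sqrt(((double.values - phantom.values) ** 2).mean())
        assert err_back < err_double

    def test_non_cubic_rejected(self):
        with pytest.raises(ValueError):
            VolumeGrid(np.zeros((8, 8, 9)), 1.0)

    def test_adjoint_dot_product_identity(self, spec, rng):
        box = 20
        c = CoefficientSet(spec, rng.normal(size=(spec.size, 3)) * 0.03, box)
        v = rng.normal(size=(box, box, box))
        y = rng.normal(size=(box, box, box))
        lhs = np.sum(warp_volume(VolumeGrid(v, 2.0), c).values * y)
        rhs = np.sum(v * warp_volume_adjoint(VolumeGrid(y, 2.0), c).values)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestWarpModel:
    def test_zero_coefficients(self, spec, scene48):
        _, model = scene48
        out = warp_model(model, CoefficientSet.zeros(spec, 48.0))
        np.testing.assert_array_equal(out.positions, model.positions)

    def test_single_atom_constant_field(self, spec):
        c = CoefficientSet.zeros(spec, 100.0)
        c.alphas[0, 1] = 0.1  # alpha^y_{0,0,0}
        mdl = AtomicModel(["C"], ["A"], [1], np.zeros((1, 3)))
        out = warp_model(mdl, c)
        np.testing.assert_allclose(out.positions[0], [0.0, 0.1 * CONST * 100.0, 0.0],
                                   atol=1e-10)

    def test_atoms_outside_ball_unmoved(self, spec):
        c = CoefficientSet.zeros(spec, 10.0)
        c.alphas[0, 0] = 1.0
        mdl = AtomicModel(["C"], ["A"], [1], np.array([[15.0, 0.0, 0.0]]))
        with pytest.warns(UserWarning, match="outside the unit ball"):
            out = warp_model(mdl, c)
        np.testing.assert_array_equal(out.positions, mdl.positions)

    def test_model_density_duality(self, spec, scene48, mode48):
        # density rendered from the (-c)-warped model tracks the c-warped map
        from zflex.synthdata import PhantomSpec, make_phantom

        phantom, model = scene48
        c = mode48 * 0.05
        warped_vol = warp_volume(phantom, c)
        moved = warp_model(model, negate(c))
        r = phantom.default_scale_radius
        sigmas = [0.06 * r, 0.07 * r, 0.055 * r]
        amps = [1.0, 0.8, 0.9]
        render = make_phantom(PhantomSpec(
            box=phantom.box, voxel_size=phantom.voxel_size,
            blobs=[(p, s, a) for p, s, a in zip(moved.positions, sigmas, amps)],
        ))[0]
        corr_pair = np.corrcoef(render.values.ravel(), warped_vol.values.ravel())[0, 1]
        corr_ref = np.corrcoef(render.values.ravel(), phantom.values.ravel())[0, 1]
        assert corr_pair > corr_ref


class TestRotation:
    def test_identity_rotation(self, spec, rng):
        c = random_coeffs(spec, rng)
        out = rotate_coefficients(c, np.eye(3))
        np.testing.assert_allclose(out.alphas, c.alphas, atol=1e-12)

    def test_constant_mode_rotates_vector_part_only(self, spec):
        c = CoefficientSet.zeros(spec, 50.0)
        c.alphas[0, 0] = 1.0
        A = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        out = rotate_coefficients(c, A)
        np.testing.assert_allclose(out.alphas[0], [0.0, 1.0, 0.0], atol=1e-12)
        assert np.abs(out.alphas[1:]).max() < 1e-12

    def test_round_trip(self, spec, rng):
        c = random_coeffs(spec, rng)
        A = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        back = rotate_coefficients(rotate_coefficients(c, A), A.T)
        np.testing.assert_allclose(back.alphas, c.alphas, atol=1e-10)

    def test_continuous_rotation_closure(self, spec, rng):
        # evaluate_field(rotate(c, A), r) == A @ evaluate_field(c, A^-1 r)
        worst = 0.0
        for _ in range(20):
            c = random_coeffs(spec, rng)
            A = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
            pts = rng.uniform(-0.57, 0.57, size=(40, 3))
            lhs = evaluate_field(rotate_coefficients(c, A), pts)
            rhs = evaluate_field(c, pts @ A) @ A.T
            worst = max(worst, np.abs(lhs - rhs).max())
        assert worst < 1e-8

    def test_grid_warp_less_closed_than_continuous(self, spec, scene32, rng):
        # on a voxel grid the same comparison picks up discretization error
        phantom, _ = scene32
        sr = phantom.default_scale_radius
        c = CoefficientSet(spec, rng.normal(size=(spec.size, 3)) * 0.02, sr)
        A = Rotation.from_rotvec([0.4, -0.2, 0.3]).as_matrix()
        cr = rotate_coefficients(c, A)
        # continuous-space error at the voxel centres
        pts = rng.uniform(-0.5, 0.5, size=(200, 3))
        cont = np.abs(evaluate_field(cr, pts) - evaluate_field(c, pts @ A) @ A.T).max()
        # grid route: warp the rotated volume with rotated coefficients
        # vs rotate the warped volume
        from scipy.ndimage import affine_transform

        center = phantom.box // 2
        def rot_vol(values, M):
            off = center - M @ np.full(3, center)
            return affine_transform(values, M, offset=off, order=1)

        warped_then_rot = rot_vol(warp_volume(phantom, c).values, A.T)
        rot_then_warped = warp_volume(
            VolumeGrid(rot_vol(phantom.values, A.T), phantom.voxel_size), cr
        ).values
        grid_err = np.abs(warped_then_rot - rot_then_warped).max() / phantom.values.max()
        assert grid_err > cont

    def test_non_rotation_rejected(self, spec, rng):
        c = random_coeffs(spec, rng)
        with pytest.raises(ValueError):
            rotate_coefficients(c, np.diag([1.0, 1.0, -1.0]))  # improper
        with pytest.raises(ValueError):
            rotate_coefficients(c, 2.0 * np.eye(3))


class TestCancellation:
    def test_z_direction_zeroes_z_column(self, spec, rng):
        c = random_coeffs(spec, rng)
        out = cancel_projection_component(c, np.array([0.0, 0.0, 1.0]))
        expected = c.copy()
        expected.alphas[:, 2] = 0.0
        np.testing.assert_allclose(out.alphas, expected.alphas, atol=1e-10)

    def test_zero_coefficients_stay_zero(self, spec, rng):
        c = CoefficientSet.zeros(spec, 50.0)
        d = rng.normal(size=3)
        out = cancel_projection_component(c, d)
        assert np.all(out.alphas == 0)

    def test_field_orthogonal_to_direction_and_idempotent(self, spec, rng):
        c = random_coeffs(spec, rng)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        out = cancel_projection_component(c, d)
        pts = rng.uniform(-0.57, 0.57, size=(100, 3))
        g = evaluate_field(out, pts)
        gmax = np.linalg.norm(g, axis=1).max()
        assert np.abs(g @ d).max() < 1e-8 * gmax
        again = cancel_projection_component(out, d)
        np.testing.assert_allclose(again.alphas, out.alphas, atol=1e-10)

    def test_never_increases_magnitude(self, spec, rng):
        for _ in range(5):
            c = random_coeffs(spec, rng)
            d = rng.normal(size=3)
            assert deformation_magnitude(cancel_projection_component(c, d)) \
                <= deformation_magnitude(c) + 1e-12

    def test_orthogonal_component_preserved(self, spec, rng):
        c = random_coeffs(spec, rng)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        out = cancel_projection_component(c, d)
        pts = rng.uniform(-0.5, 0.5, size=(50, 3))
        g0 = evaluate_field(c, pts)
        g1 = evaluate_field(out, pts)
        perp0 = g0 - np.outer(g0 @ d, d)
        np.testing.assert_allclose(g1, perp0, atol=1e-9)

    def test_zero_direction_rejected(self, spec, rng):
        with pytest.raises(ValueError):
            cancel_projection_component(random_coeffs(spec, rng), np.zeros(3))

    def test_inplane_subspace_matches_projection(self, spec, rng):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        U = inplane_subspace(spec, d)
        # columns orthonormal and invariant under the cancellation
        np.testing.assert_allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-10)
        y = rng.normal(size=U.shape[1])
        c = CoefficientSet.from_flat(spec, U @ y, 50.0)
        out = cancel_projection_component(c, d)
        np.testing.assert_allclose(out.flatten(), U @ y, atol=1e-10)


class TestRescale:
    def test_identity(self, spec, rng):
        c = random_coeffs(spec, rng)
        out = rescale_coefficients(c, 1.0)
        np.testing.assert_array_equal(out.alphas, c.alphas)

    def test_doubling(self, spec, rng):
        c = random_coeffs(spec, rng)
        out = rescale_coefficients(c, 2.0)
        np.testing.assert_array_equal(out.alphas, 2.0 * c.alphas)
        assert out.scale_radius == 2.0 * c.scale_radius

    def test_power_of_two_round_trip_bitwise(self, spec, rng):
        c = random_coeffs(spec, rng)
        back = rescale_coefficients(rescale_coefficients(c, 2.0), 0.5)
        np.testing.assert_array_equal(back.alphas, c.alphas)
        assert back.scale_radius == c.scale_radius

    def test_commutes_with_evaluation(self, spec, rng):
        c = random_coeffs(spec, rng)
        pts = rng.uniform(-0.5, 0.5, size=(20, 3))
        np.testing.assert_allclose(
            evaluate_field(rescale_coefficients(c, 3.0), pts),
            3.0 * evaluate_field(c, pts),
            rtol=1e-12,
        )

    def test_invalid_factor(self, spec, rng):
        with pytest.raises(ValueError):
            rescale_coefficients(random_coeffs(spec, rng), -1.0)


class TestRescaleProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(k=st.floats(0.1, 10.0), seed=st.integers(0, 100))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_round_trip_and_homogeneous_evaluation(self, k, seed):
        spec = BasisSpec(3, 2)
        r = np.random.default_rng(seed)
        c = CoefficientSet(spec, r.normal(size=(spec.size, 3)), 48.0)
        back = rescale_coefficients(rescale_coefficients(c, k), 1.0 / k)
        np.testing.assert_allclose(back.alphas, c.alphas, rtol=1e-12)
        assert back.scale_radius == pytest.approx(c.scale_radius, rel=1e-12)
        pts = r.uniform(-0.5, 0.5, size=(10, 3))
        np.testing.assert_allclose(
            evaluate_field(rescale_coefficients(c, k), pts),
            k * evaluate_field(c, pts), rtol=1e-10, atol=1e-12,
        )


class TestDeformationMagnitude:
    def test_zero(self, spec):
        assert deformation_magnitude(CoefficientSet.zeros(spec, 50.0)) == 0.0

    def test_constant_field_closed_form(self, spec):
        c = CoefficientSet.zeros(spec, 100.0)
        c.alphas[0, 0] = 0.05 / CONST  # |g| = 0.05 everywhere in the ball
        assert deformation_magnitude(c) == pytest.approx(5.0, rel=1e-9)

    def test_positive_homogeneity(self, spec, rng):
        c = random_coeffs(spec, rng)
        assert deformation_magnitude(2.0 * c) == pytest.approx(
            2.0 * deformation_magnitude(c), rel=1e-12
        )

    def test_masked_mean(self, spec, scene48, mode48):
        phantom, _ = scene48
        mask = molecular_mask(phantom)
        m = deformation_magnitude(mode48 * 0.05, mask)
        assert m > 0
        with pytest.raises(ValueError):
            deformation_magnitude(mode48, VolumeGrid(np.zeros((48,) * 3), 2.0))
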