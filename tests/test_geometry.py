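"""Grid geometry, rigid transforms and trilinear resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petcoreg.geometry import (
    ImageGeometry,
    RigidTransform,
    Volume,
    compose,
    invert,
    preset_geometry,
    resample_volume,
    trilinear_sample,
)


def brute_force_trilinear(values, cidx):
    """Independent 8-corner oracle: sum of corner values times weight products."""
    out = 0.0
    base = np.floor(cidx).astype(int)
    base = np.minimum(base, np.asarray(values.shape) - 2)
    d = cidx - base
    for cx in (0, 1):
        for cy in (0, 1):
            for cz in (0, 1):
                w = (
                    (d[0] if cx else 1 - d[0])
                    * (d[1] if cy else 1 - d[1])
                    * (d[2] if cz else 1 - d[2])
                )
                out += w * values[base[0] + cx, base[1] + cy, base[2] + cz]
    return out


class TestImageGeometry:
    def test_origin_addresses_first_voxel_center(self):
        g = ImageGeometry((4, 4, 4), (4.1, 4.1, 5.0))
        assert np.allclose(g.voxel_to_world((0, 0, 0)), (0, 0, 0))
        assert np.allclose(g.voxel_to_world((1, 1, 1)), (4.1, 4.1, 5.0))

    def test_presets_carry_scanner_spacings(self):
        assert preset_geometry("pet").spacing == (4.1, 4.1, 5.0)
        assert preset_geometry("ct1").spacing == (1.4, 1.4, 1.0)
        assert preset_geometry("ct5").spacing == (1.4, 1.4, 5.0)
        with pytest.raises(ValueError):
            preset_geometry("mri")

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ImageGeometry((4, 4, 4), (0.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            ImageGeometry((4, 0, 4), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            ImageGeometry((4, 4, 4), (1, 1, 1), direction=np.diag([1, 1, 2]))
        with pytest.raises(ValueError):  # improper (reflection)
            ImageGeometry((4, 4, 4), (1, 1, 1), direction=np.diag([1, 1, -1]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        idx=st.tuples(*[st.floats(-3, 20, allow_nan=False) for _ in range(3)]),
        origin=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
    )
    def test_world_voxel_round_trip(self, idx, origin):
        g = ImageGeometry((8, 8, 8), (4.1, 4.1, 5.0), origin=origin)
        back = g.world_to_voxel(g.voxel_to_world(np.asarray(idx)))
        assert np.allclose(back, idx, atol=1e-9)


class TestRigidTransform:
    def test_identity_and_composition_laws(self, rng):
        t = RigidTransform((10.0, -5.0, 3.0), (4.0, -2.0, 1.0), (7.0, 8.0, 9.0))
        pts = rng.normal(size=(100, 3)) * 50
        ident = RigidTransform.identity()
        assert np.allclose(compose(t, ident).apply(pts), t.apply(pts), atol=1e-12)
        assert invert(ident).is_identity
        assert np.allclose(compose(t, invert(t)).apply(pts), pts, atol=1e-9)
        assert np.allclose(t.apply_inverse(t.apply(pts)), pts, atol=1e-9)

    def test_rotation_matrix_proper(self):
        t = RigidTransform((33.0, -21.0, 80.0))
        R = t.matrix
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.isclose(np.linalg.det(R), 1.0)

    def test_compose_matches_sequential_application(self, rng):
        a = RigidTransform((3.0, 7.0, -2.0), (1.0, 2.0, 3.0), (5.0, -5.0, 0.0))
        b = RigidTransform((-8.0, 1.0, 4.0), (-2.0, 0.5, 1.5), (0.0, 3.0, -1.0))
        pts = rng.normal(size=(50, 3)) * 30
        assert np.allclose(compose(a, b).apply(pts), a.apply(b.apply(pts)), atol=1e-9)


class TestTrilinearSample:
    def test_grid_nodes_reproduce_stored_values(self, random_volume):
        g = random_volume.geometry
        for idx in [(0, 0, 0), (3, 2, 1), (11, 9, 7)]:
            p = g.voxel_to_world(idx)
            assert trilinear_sample(random_volume, p) == random_volume.values[idx]

    def test_midpoint_between_two_voxels(self):
        g = ImageGeometry((4, 3, 3), (1.0, 1.0, 1.0))
        vals = np.full(g.shape, 2.0)
        vals[2, 1, 1] = 4.0
        vals[1, 1, 1] = 2.0
        v = Volume(g, vals)
        assert trilinear_sample(v, (1.5, 1.0, 1.0)) == pytest.approx(3.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, random_volume, rng):
        g = random_volume.geometry
        cidx = rng.uniform([0, 0, 0], np.asarray(g.shape) - 1.001, size=(300, 3))
        pts = g.voxel_to_world(cidx)
        got = trilinear_sample(random_volume, pts)
        want = [brute_force_trilinear(random_volume.values, c) for c in cidx]
        assert np.allclose(got, want, atol=1e-12)

    def test_matches_scipy_map_coordinates(self, random_volume, rng):
        from scipy.ndimage import map_coordinates

        g = random_volume.geometry
        cidx = rng.uniform([0, 0, 0], np.asarray(g.shape) - 1.001, size=(200, 3))
        pts = g.voxel_to_world(cidx)
        got = trilinear_sample(random_volume, pts)
        want = map_coordinates(random_volume.values, cidx.T, order=1, mode="constant")
        assert np.allclose(got, want, atol=1e-9)

    def test_out_of_bounds_returns_fill(self, random_volume):
        g = random_volume.geometry
        outside = g.voxel_to_world((-1.2, 2.0, 2.0))
        assert trilinear_sample(random_volume, outside, fill=-7.0) == -7.0
        beyond = g.voxel_to_world((2.0, 2.0, g.shape[2] - 0.5))
        assert trilinear_sample(random_volume, beyond, fill=0.0) == 0.0


class TestResampleVolume:
    def test_identity_is_bit_exact(self, random_volume):
        out = resample_volume(random_volume, RigidTransform.identity(), random_volume.geometry)
        assert np.array_equal(out.values, random_volume.values)

    def test_integer_voxel_shift_is_exact(self, random_volume):
        g = random_volume.geometry
        t = RigidTransform.from_translation((g.spacing[0], 0.0, g.spacing[2]))
        out = resample_volume(random_volume, t, g)
        want = np.zeros(g.shape)
        want[1:, :, 1:] = random_volume.values[:-1, :, :-1]
        interior = np.zeros(g.shape, dtype=bool)
        interior[1:, :, 1:] = True
        assert np.abs(out.values - want)[interior].max() < 1e-12

    def test_half_voxel_shift_of_alternating_pattern(self):
        g = ImageGeometry((10, 3, 3), (1.0, 1.0, 1.0))
        vals = np.zeros(g.shape)
        vals[1::2] = 1.0
        v = Volume(g, vals)
        out = resample_volume(v, RigidTransform.from_translation((0.5, 0, 0)), g)
        assert np.allclose(out.values[1:9, 1, 1], 0.5, atol=1e-12)

    def test_convex_combination_bounds(self, rng):
        g = ImageGeometry((9, 9, 9), (2.0, 3.0, 2.5), origin=(-8, -12, -10))
        for _ in range(25):
            v = Volume(g, rng.random(g.shape))
            t = RigidTransform(
                rotation_deg=tuple(rng.uniform(-10, 10, 3)),
                translation=tuple(rng.uniform(-4, 4, 3)),
            )
            out = resample_volume(v, t, g, fill=0.0)
            assert out.values.max() <= v.values.max() + 1e-12
            assert out.values.min() >= min(v.values.min(), 0.0) - 1e-12

    def test_constant_volume_stays_constant_inside_footprint(self):
        g = ImageGeometry((12, 12, 12), (2.0, 2.0, 2.0), origin=(-11, -11, -11))
        v = Volume(g, np.full(g.shape, 3.25))
        out = resample_volume(v, RigidTransform.from_translation((0.7, -0.3, 1.1)), g)
        interior = np.zeros(g.shape, dtype=bool)
        interior[2:-2, 2:-2, 2:-2] = True
        assert np.allclose(out.values[interior], 3.25, atol=1e-12)

    def test_matches_simpleitk_resampler(self, random_volume):
        sitk = pytest.importorskip("SimpleITK")
        g = random_volume.geometry
        t = RigidTransform(
            rotation_deg=(2.0, -3.0, 1.5), translation=(1.3, -0.9, 2.1),
            center=(0.0, 0.0, 0.0),
        )
        ours = resample_volume(random_volume, t, g, fill=0.0)

        img = sitk.GetImageFromArray(random_volume.values.transpose(2, 1, 0))
        img.SetSpacing(g.spacing)
        img.SetOrigin(g.origin)
        inv = t.inverse()
        aff = sitk.AffineTransform(3)
        aff.SetCenter(inv.center)
        aff.SetMatrix(inv.matrix.ravel())
        aff.SetTranslation(inv.translation)
        res = sitk.Resample(img, img, aff, sitk.sitkLinear, 0.0)
        theirs = sitk.GetArrayFromImage(res).transpose(2, 1, 0)
        interior = np.zeros(g.shape, dtype=bool)
        interior[2:-2, 2:-2, 2:-2] = True
        assert np.allclose(ours.values[interior], theirs[interior], atol=1e-9)


class TestNifti:
    def test_round_trip_preserves_geometry_and_values(self, random_volume, tmp_path):
        from petcoreg.nifti import read_volume, write_volume

        path = tmp_path / "vol.nii.gz"
        write_volume(random_volume, path)
        back = read_volume(path)
        g0, g1 = random_volume.geometry, back.geometry
        assert g1.shape == g0.shape
        # NIfTI-1 stores the affine in float32: round trip to format precision
        assert np.allclose(g1.spacing, g0.spacing, atol=1e-5)
        assert np.allclose(g1.origin, g0.origin, atol=1e-4)
        assert np.allclose(g1.direction, g0.direction, atol=1e-6)
        assert np.allclose(back.values, random_volume.values, atol=1e-12)
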