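"""Fixed and background-adapted threshold segmentation."""

import numpy as np
import pytest

from petcoreg.geometry import ImageGeometry, Volume
from petcoreg.segmentation import (
    LesionVOI,
    adaptive_threshold_segment,
    calibrate_volume_reproducing_fraction,
    estimate_background,
    fixed_threshold_segment,
    voi_around_point,
    voi_full,
)


def brute_force_component_count(values, voi, threshold, seed):
    """Independent oracle: exhaustive scan + BFS flood fill (26-connectivity)."""
    sub = values[voi.slices()]
    above = sub >= threshold
    seed_local = tuple(s - o for s, o in zip(seed, voi.lo))
    if not above[seed_local]:
        return 0
    seen = {seed_local}
    frontier = [seed_local]
    while frontier:
        x, y, z = frontier.pop()
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    n = (x + dx, y + dy, z + dz)
                    if (
                        n not in seen
                        and all(0 <= n[i] < above.shape[i] for i in range(3))
                        and above[n]
                    ):
                        seen.add(n)
                        frontier.append(n)
    return len(seen)


def _cube_volume():
    g = ImageGeometry((12, 12, 12), (1.0, 1.0, 1.0))
    vals = np.zeros(g.shape)
    vals[4:8, 4:8, 4:8] = 10.0
    return Volume(g, vals)


class TestFixedThreshold:
    def test_cube_in_zero_background_is_exact(self):
        v = _cube_volume()
        m = fixed_threshold_segment(v, voi_full(v.geometry), 0.40)
        want = v.values == 10.0
        assert np.array_equal(m.mask, want)
        assert m.method == "T40"
        assert m.threshold == pytest.approx(4.0)

    def test_boundary_voxel_at_exact_fraction_included(self):
        g = ImageGeometry((8, 8, 8), (1.0, 1.0, 1.0))
        vals = np.zeros(g.shape)
        vals[3, 3, 3] = 10.0
        vals[3, 3, 4] = 4.0  # exactly 40 % of the maximum -> "at least" includes it
        v = Volume(g, vals)
        m = fixed_threshold_segment(v, voi_full(g), 0.40)
        assert m.mask[3, 3, 4]

    def test_voxel_count_matches_flood_fill_oracle(self, rng):
        g = ImageGeometry((9, 9, 9), (2.0, 2.0, 2.0))
        for trial in range(10):
            vals = rng.random(g.shape)
            vals[4, 4, 4] = 1.5  # unique max at the center
            v = Volume(g, vals)
            voi = voi_full(g)
            m = fixed_threshold_segment(v, voi, 0.50)
            want = brute_force_component_count(v.values, voi, 0.5 * 1.5, (4, 4, 4))
            assert m.n_voxels == want

    def test_nesting_of_thresholds(self, blurred_sphere):
        v, voi, _ = blurred_sphere(radius_mm=9.0, noise_sd=0.3, seed=4)
        m40 = fixed_threshold_segment(v, voi, 0.40)
        m50 = fixed_threshold_segment(v, voi, 0.50)
        m60 = fixed_threshold_segment(v, voi, 0.60)
        assert np.all(m50.mask >= m60.mask)
        assert np.all(m40.mask >= m50.mask)
        for m in (m40, m50, m60):
            assert m.mask[m.seed_index]

    def test_nonpositive_max_raises(self):
        g = ImageGeometry((6, 6, 6), (1.0, 1.0, 1.0))
        v = Volume(g, np.zeros(g.shape))
        with pytest.raises(ValueError, match="positive"):
            fixed_threshold_segment(v, voi_full(g), 0.40)


class TestBackgroundEstimate:
    def test_constant_background_recovered_exactly(self):
        g = ImageGeometry((16, 16, 16), (1.0, 1.0, 1.0))
        vals = np.full(g.shape, 2.5)
        vals[6:10, 6:10, 6:10] = 10.0
        v = Volume(g, vals)
        m = fixed_threshold_segment(v, voi_full(g), 0.40)
        assert estimate_background(v, m) == pytest.approx(2.5, abs=1e-12)

    def test_shell_outside_voi_raises(self):
        v = _cube_volume()
        tight = LesionVOI((4, 4, 4), (8, 8, 8))  # VOI == lesion, no room for a shell
        m = fixed_threshold_segment(v, tight, 0.40)
        with pytest.raises(ValueError, match="shell"):
            estimate_background(v, m)


class TestAdaptiveThreshold:
    def test_zero_background_reduces_to_fixed_fraction(self):
        v = _cube_volume()
        m = adaptive_threshold_segment(v, voi_full(v.geometry), volume_fraction=0.5)
        assert m.threshold == pytest.approx(5.0, abs=1e-12)
        assert m.converged

    def test_invariant_under_global_additive_offset(self, blurred_sphere):
        v, voi, _ = blurred_sphere(radius_mm=9.0)
        m0 = adaptive_threshold_segment(v, voi, volume_fraction=0.41)
        shifted = Volume(v.geometry, v.values + 3.7)
        m1 = adaptive_threshold_segment(shifted, voi, volume_fraction=0.41)
        assert np.array_equal(m0.mask, m1.mask)
        # fixed thresholding lacks this invariance (background-adapted vs fixed)
        f0 = fixed_threshold_segment(v, voi, 0.40)
        f1 = fixed_threshold_segment(shifted, voi, 0.40)
        assert not np.array_equal(f0.mask, f1.mask)

    def test_calibrated_volume_recovery_on_sphere(self, blurred_sphere):
        v, voi, truth = blurred_sphere(radius_mm=10.0, background_suv=1.0, lesion_suv=8.0)
        calib = [
            blurred_sphere(radius_mm=r) for r in (6.5, 9.0, 12.0, 15.0)
        ]
        f = calibrate_volume_reproducing_fraction(
            [(vol, vv, t.true_volume_ml) for vol, vv, t in calib]
        )
        assert 0.2 < f < 0.8
        m = adaptive_threshold_segment(v, voi, volume_fraction=f)
        mtv = m.n_voxels * v.geometry.voxel_volume_mm3 / 1000.0
        assert mtv == pytest.approx(truth.true_volume_ml, rel=0.15)

    def test_larger_fraction_gives_smaller_mask(self, blurred_sphere):
        v, voi, _ = blurred_sphere(radius_mm=9.0)
        sizes = [
            adaptive_threshold_segment(v, voi, volume_fraction=f).n_voxels
            for f in (0.3, 0.5, 0.7)
        ]
        assert sizes[0] > sizes[1] > sizes[2]

    def test_beats_t40_on_nonzero_background(self, blurred_sphere):
        # calibrated AT vs fixed 40 % on a blurred sphere over warm background
        v, voi, truth = blurred_sphere(radius_mm=12.0, background_suv=1.0, lesion_suv=8.0)
        calib = [blurred_sphere(radius_mm=r) for r in (6.5, 9.0, 15.0)]
        f = calibrate_volume_reproducing_fraction(
            [(vol, vv, t.true_volume_ml) for vol, vv, t in calib]
        )
        vox_ml = v.geometry.voxel_volume_mm3 / 1000.0
        at_err = abs(
            adaptive_threshold_segment(v, voi, volume_fraction=f).n_voxels * vox_ml
            - truth.true_volume_ml
        )
        t40_err = abs(
            fixed_threshold_segment(v, voi, 0.40).n_voxels * vox_ml - truth.true_volume_ml
        )
        assert at_err < t40_err


class TestCalibration:
    def test_too_few_phantoms_rejected(self, blurred_sphere):
        pair = blurred_sphere(radius_mm=9.0)
        with pytest.raises(ValueError, match="at least 3"):
            calibrate_volume_reproducing_fraction(
                [(pair[0], pair[1], pair[2].true_volume_ml)] * 2
            )

    def test_narrow_volume_span_rejected(self, blurred_sphere):
        triples = [
            (v, voi, t.true_volume_ml)
            for v, voi, t in (blurred_sphere(radius_mm=r) for r in (9.0, 10.0, 11.0))
        ]
        with pytest.raises(ValueError, match="decade"):
            calibrate_volume_reproducing_fraction(triples)


class TestVOI:
    def test_voi_clipped_to_grid(self):
        g = ImageGeometry((10, 10, 10), (2.0, 2.0, 2.0))
        voi = voi_around_point(g, (0.0, 0.0, 0.0), (30.0, 30.0, 30.0))
        assert voi.lo == (0, 0, 0) and voi.hi == (10, 10, 10)

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            LesionVOI((2, 2, 2), (2, 5, 5))
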