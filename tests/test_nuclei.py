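import numpy as np
import pytest

from embryoseg3d import (
    PhantomParams,
    PipelineConfig,
    ZGradientProfile,
    assign_slices,
    build_nuclei,
    find_center_slices,
    generate_phantom,
    is_center_slice,
    mean_z_gradient,
    segment_frame,
    z_gradient_profile,
)
from embryoseg3d.segment2d import Seed2D, Slice2D
from tests.conftest import STUDY_SPACING

DX = DY = 0.09


def footprint_slice(z, rows_cols, grays=100.0, dx=DX, dy=DY):
    px = np.asarray(rows_cols, dtype=int)
    g = np.full(len(px), float(grays)) if np.isscalar(grays) else np.asarray(grays)
    seed = Seed2D(z, int(px[0][0]), int(px[0][1]), float(g[0]))
    return Slice2D(z, px, g, seed, dx, dy)


def column_volume(z_profile, size=5):
    """A volume whose every (y, x) column carries the given z-profile."""
    return np.tile(np.asarray(z_profile, float)[:, None, None], (1, size, size))


class TestMeanZGradient:
    def test_constant_volume_gradient_zero(self):
        vol = np.full((6, 5, 5), 42.0)
        slc = footprint_slice(2, [[1, 1], [2, 2]])
        assert mean_z_gradient(vol, slc, 2) == 0.0

    def test_linear_ramp_gradient_is_slope(self):
        vol = column_volume(3.0 * np.arange(7))
        slc = footprint_slice(3, [[0, 0], [2, 3]])
        assert mean_z_gradient(vol, slc, 3) == pytest.approx(3.0)

    def test_border_plane_errors(self):
        vol = column_volume(np.arange(4))
        slc = footprint_slice(3, [[1, 1]])
        with pytest.raises(ValueError, match="undefined"):
            mean_z_gradient(vol, slc, 3)


class TestCenterRule:
    def gaussian_profile_volume(self, apex=5.0, sigma=1.6, n=11):
        z = np.arange(n)
        return column_volume(10 + 100 * np.exp(-((z - apex) ** 2) / (2 * sigma**2)))

    def test_sign_corrected_true_at_apex_only(self):
        vol = self.gaussian_profile_volume()
        hits = [
            z
            for z in range(1, vol.shape[0] - 2)
            if is_center_slice(z_gradient_profile(vol, footprint_slice(z, [[2, 2]])), "sign_corrected")
        ]
        assert hits == [5]

    def test_literal_rule_selects_steepest_descent_above_apex(self):
        """The verbatim inequality set cannot fire at a symmetric apex (the
        gradient from below is positive there); it fires above it instead."""
        vol = self.gaussian_profile_volume()
        apex_profile = z_gradient_profile(vol, footprint_slice(5, [[2, 2]]))
        assert not is_center_slice(apex_profile, "literal")
        hits = [
            z
            for z in range(1, vol.shape[0] - 2)
            if is_center_slice(z_gradient_profile(vol, footprint_slice(z, [[2, 2]])), "literal")
        ]
        assert hits and all(z > 5 for z in hits)

    def test_monotone_ramp_never_a_center(self):
        vol = column_volume(5.0 * np.arange(9))
        for z in range(1, 7):
            prof = z_gradient_profile(vol, footprint_slice(z, [[2, 2]]))
            assert not is_center_slice(prof, "literal")
            assert not is_center_slice(prof, "sign_corrected")

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            is_center_slice(ZGradientProfile(1.0, 0.0, -1.0), rule="bogus")


def one_sphere_segmentation(radius=1.6, peak=150.0):
    params = PhantomParams(
        n_nuclei=1,
        n_frames=1,
        noise_sigma=0.0,
        radius_range_um=(radius, radius),
        peak_intensity_range=(peak, peak),
        spacing=STUDY_SPACING,
        frame_shape=(25, 160, 160),
        seed=3,
    )
    stack, truth = generate_phantom(params)
    config = PipelineConfig(spacing=params.spacing)
    return segment_frame(stack.frame(0), config, 3.5), truth, params


class TestOnPhantoms:
    def test_one_sphere_one_center_near_true_plane(self):
        seg, truth, params = one_sphere_segmentation()
        assert seg.n_centers == 1
        assert len(seg.nuclei) == 1
        dz_eff = params.spacing.dz / 2
        true_plane = round(truth.z_um.iloc[0] / dz_eff)
        assert abs(seg.nuclei[0].center_z - true_plane) <= 1

    def test_each_nucleus_contains_exactly_one_center(self):
        seg, _, _ = one_sphere_segmentation(radius=2.5)
        n = seg.nuclei[0]
        hits = sum(1 for s in n.slices if s.z == n.center_z)
        assert hits == 1

    def test_center_plane_gradient_smaller_than_flanks(self):
        """|mean z-gradient| at the center plane is below its value two
        planes away, the property the center detector exploits."""
        params = PhantomParams(
            n_nuclei=1, n_frames=1, noise_sigma=0.0, radius_range_um=(2.0, 2.0),
            spacing=STUDY_SPACING, frame_shape=(25, 140, 140), seed=5,
        )
        stack, truth = generate_phantom(params)
        frame = stack.frame(0)
        zc = round(truth.z_um.iloc[0] / params.spacing.dz)
        rows_cols = [[int(truth.y_um.iloc[0] / DX) + d, int(truth.x_um.iloc[0] / DX)] for d in (-1, 0, 1)]
        g_center = abs(mean_z_gradient(frame, footprint_slice(zc, rows_cols), zc))
        g_flank = abs(mean_z_gradient(frame, footprint_slice(zc + 2, rows_cols), zc + 2))
        assert g_center < g_flank

    def test_fault_tolerance_to_missing_brightest_plane(self):
        """Erasing the single brightest plane must not lose the nucleus:
        the remaining 2D slices still assemble into a detection."""
        params = PhantomParams(
            n_nuclei=1, n_frames=1, noise_sigma=0.0, radius_range_um=(2.2, 2.2),
            spacing=STUDY_SPACING, frame_shape=(25, 160, 160), seed=3,
        )
        stack, truth = generate_phantom(params)
        frame = stack.frame(0).copy()
        zc = int(np.argmax(frame.max(axis=(1, 2))))
        frame[zc] = params.background_level
        config = PipelineConfig(spacing=params.spacing)
        seg = segment_frame(frame, config, 3.5)
        assert len(seg.nuclei) >= 1
        n = seg.nuclei[0]
        d = np.hypot(n.x_um - truth.x_um.iloc[0], n.y_um - truth.y_um.iloc[0])
        assert d < truth.radius_um.iloc[0]


class TestAssignment:
    def make_center(self, z, r, c, gray=150.0):
        return footprint_slice(z, [[r + dr, c + dc] for dr in (-1, 0, 1) for dc in (-1, 0, 1)], gray)

    def test_far_slices_discarded(self):
        center = self.make_center(10, 50, 50)
        far = footprint_slice(10, [[50, 90], [50, 91], [51, 90]])
        nuclei = assign_slices([center], [center, far], r_max_um=2.0, dz_eff=0.355)
        assert len(nuclei) == 1
        assert nuclei[0].n_slices == 1

    def test_equidistant_slice_goes_to_brighter_center(self):
        # dx = 0.125 makes the two center distances binary-exact ties
        def sl(z, r, c, gray):
            px = [[r + dr, c + dc] for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
            return footprint_slice(z, px, gray, dx=0.125, dy=0.125)

        bright = sl(10, 50, 40, 200.0)
        dim = sl(10, 50, 56, 100.0)
        middle = footprint_slice(11, [[49, 48], [50, 48], [51, 48]], 100.0, dx=0.125, dy=0.125)
        nuclei = assign_slices([bright, dim], [bright, dim, middle], r_max_um=20.0, dz_eff=0.355)
        winner = max(nuclei, key=lambda n: n.n_slices)
        assert winner.n_slices == 2
        assert winner.mean_gray > 100.0  # the brighter center got the tie

    def test_volume_and_radius_follow_slice_areas(self):
        center = self.make_center(10, 50, 50)
        extra = footprint_slice(11, [[50, 50 + d] for d in range(4)])
        nuclei = assign_slices([center], [center, extra], r_max_um=5.0, dz_eff=0.355)
        n = nuclei[0]
        expected_volume = (9 + 4) * DX * DY * 0.355
        assert n.volume_um3 == pytest.approx(expected_volume)
        assert n.radius_um == pytest.approx((3 * expected_volume / (4 * np.pi)) ** (1 / 3))

    def test_no_centers_yields_no_nuclei(self):
        assert assign_slices([], [footprint_slice(5, [[1, 1]])], 2.0, 0.355) == []


def test_multi_sphere_build_one_center_each(small_phantom):
    params, stack, truth = small_phantom
    config = PipelineConfig(spacing=params.spacing)
    seg = segment_frame(stack.frame(0), config, 3.5)
    assert seg.n_centers == params.n_nuclei
    assert len(seg.nuclei) == params.n_nuclei
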