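import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryoseg3d import GrowthParams, Seed2D, accept_pixel, find_seeds, region_grow, segment_plane, thin_slices
from embryoseg3d.segment2d import Slice2D
from embryoseg3d.validation import flood_fill_oracle, random_test_plane

DX = DY = 0.25


def blob(size, centers, sigmas, peaks, bg=10.0):
    rr, cc = np.mgrid[0:size, 0:size]
    img = np.full((size, size), bg)
    for (r0, c0), s, p in zip(centers, sigmas, peaks):
        img = img + p * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s**2))
    return img


class TestFindSeeds:
    def test_constant_plane_has_no_seeds(self):
        plane = np.full((20, 20), 50.0)
        assert find_seeds(plane, GrowthParams(background_threshold=50.0)) == []

    def test_single_blob_single_seed_at_peak(self):
        plane = blob(31, [(15, 15)], [4.0], [100.0])
        seeds = find_seeds(plane, GrowthParams(background_threshold=20.0))
        # brute-force reference: every pixel >= its 8 neighbours and above threshold
        brute = [
            (r, c)
            for r in range(31)
            for c in range(31)
            if plane[r, c] > 20.0
            and plane[r, c] == plane[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2].max()
        ]
        assert [(s.row, s.col) for s in seeds] == brute == [(15, 15)]
        assert seeds[0].gray == plane[15, 15]

    def test_two_separated_blobs_two_seeds(self):
        plane = blob(41, [(12, 12), (28, 30)], [3.0, 3.0], [90.0, 130.0])
        seeds = find_seeds(plane, GrowthParams(background_threshold=20.0))
        assert {(s.row, s.col) for s in seeds} == {(12, 12), (28, 30)}

    def test_plateau_contributes_one_seed(self):
        plane = np.full((15, 15), 5.0)
        plane[6:9, 6:9] = 80.0
        seeds = find_seeds(plane, GrowthParams(background_threshold=10.0))
        assert [(s.row, s.col) for s in seeds] == [(7, 7)]


class TestAcceptPixel:
    def test_equal_intensity_at_seed_is_accepted(self):
        assert accept_pixel(100.0, 100.0, 0.0, 2.0)

    def test_boundary_cases_follow_strict_inequality(self):
        # bound is exactly 0 at d == r: equal grays rejected
        assert not accept_pixel(150.0, 150.0, 2.0, 2.0)
        # bound 4*2*0.75 = 6 at d = r/2 for G_A = 150: a drop of 6 is
        # rejected, a drop of 5 accepted
        assert not accept_pixel(150.0, 144.0, 1.0, 2.0)
        assert accept_pixel(150.0, 145.0, 1.0, 2.0)

    def test_invalid_radius_errors(self):
        with pytest.raises(ValueError):
            accept_pixel(100.0, 100.0, 0.0, 0.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.floats(0.0, 255.0),
        st.floats(0.0, 255.0),
        st.floats(0.0, 10.0),
        st.floats(0.1, 5.0),
    )
    def test_beyond_radius_only_brighter_pixels_join(self, g_a, g_b, d, r):
        if d >= r and accept_pixel(g_a, g_b, d, r):
            assert g_b > g_a


class TestRegionGrow:
    def params(self, r=2.0, thr=15.0):
        return GrowthParams(r_max_um=r, background_threshold=thr, min_slice_area_px=1)

    def test_isolated_bright_pixel_grows_area_one(self):
        plane = np.full((11, 11), 10.0)
        plane[5, 5] = 200.0
        seed = Seed2D(0, 5, 5, 200.0)
        slc = region_grow(plane, seed, self.params(), DX, DY)
        assert slc.area_px == 1
        assert (slc.pixels == [[5, 5]]).all()

    def test_seed_is_inside_grown_region(self):
        plane = blob(25, [(12, 12)], [4.0], [120.0])
        seed = find_seeds(plane, self.params())[0]
        slc = region_grow(plane, seed, self.params(), DX, DY)
        assert [seed.row, seed.col] in slc.pixels.tolist()

    def test_matches_flood_fill_oracle_on_blob(self):
        plane = blob(25, [(12, 12)], [4.0], [120.0])
        params = self.params()
        seed = find_seeds(plane, params)[0]
        got = {tuple(p) for p in region_grow(plane, seed, params, DX, DY).pixels}
        want = flood_fill_oracle(plane, seed, params, DX, DY, 15.0)
        assert got == want

    @pytest.mark.parametrize("case_seed", range(8))
    def test_matches_flood_fill_oracle_on_random_planes(self, case_seed):
        rng = np.random.default_rng(case_seed)
        plane = random_test_plane(rng, size=40)
        thr = float(np.percentile(plane, 75))
        params = GrowthParams(r_max_um=float(rng.uniform(1, 3)), background_threshold=thr)
        seeds = find_seeds(plane, params)
        for seed in sorted(seeds, key=lambda s: -s.gray)[:2]:
            got = {tuple(p) for p in region_grow(plane, seed, params, DX, DY).pixels}
            want = flood_fill_oracle(plane, seed, params, DX, DY, thr)
            assert got == want

    def test_dim_blob_survives_next_to_bright_one(self):
        plane = blob(41, [(20, 12), (20, 28)], [3.5, 3.5], [180.0, 60.0])
        params = GrowthParams(r_max_um=2.5, background_threshold=15.0, min_slice_area_px=1)
        slices = segment_plane(plane, params, DX, DY)
        assert len(slices) == 2
        cols = sorted(s.centroid_rc[1] for s in slices)
        assert abs(cols[0] - 12) < 1.5 and abs(cols[1] - 28) < 1.5


class TestSegmentPlane:
    def test_empty_plane_gives_no_slices(self):
        assert segment_plane(np.full((16, 16), 7.0), GrowthParams(), DX, DY) == []

    def test_k_blobs_give_k_slices(self):
        plane = blob(61, [(15, 15), (15, 45), (45, 30)], [3.0] * 3, [90.0, 120.0, 150.0])
        params = GrowthParams(r_max_um=2.0, background_threshold=20.0, min_slice_area_px=4)
        slices = segment_plane(plane, params, DX, DY)
        assert len(slices) == 3
        for s in slices:
            assert [s.seed.row, s.seed.col] in s.pixels.tolist()

    def test_contested_pixels_resolved_deterministically(self):
        plane = blob(41, [(20, 15), (20, 25)], [4.0, 4.0], [120.0, 120.0])
        params = GrowthParams(r_max_um=3.0, background_threshold=15.0, min_slice_area_px=4)
        a = segment_plane(plane, params, DX, DY)
        b = segment_plane(plane, params, DX, DY)
        assert len(a) == len(b) == 2
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.pixels, sb.pixels)
        # no pixel claimed twice
        claimed = set()
        for s in a:
            for p in map(tuple, s.pixels):
                assert p not in claimed
                claimed.add(p)


def make_slice(pixels, z=0, gray=100.0, seed_at=0):
    pixels = np.asarray(pixels, dtype=int)
    grays = np.full(len(pixels), gray)
    seed = Seed2D(z, int(pixels[seed_at][0]), int(pixels[seed_at][1]), gray)
    return Slice2D(z, pixels, grays, seed, DX, DY)


class TestThinning:
    def test_single_slice_unchanged(self):
        s = make_slice([[2, 2], [2, 3], [3, 2]])
        out = thin_slices([s], (8, 8))
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].pixels, s.pixels)

    def test_touching_slices_become_disjoint_and_nonempty(self):
        a = make_slice([[4, c] for c in range(0, 5)] + [[3, c] for c in range(0, 5)], seed_at=2)
        b = make_slice([[4, c] for c in range(5, 10)] + [[5, c] for c in range(5, 10)], seed_at=7)
        out = thin_slices([a, b], (10, 10))
        assert all(s.area_px >= 1 for s in out)
        pa = {tuple(p) for p in out[0].pixels}
        pb = {tuple(p) for p in out[1].pixels}
        assert not pa & pb
        # 8-adjacency gap
        for r, c in pa:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    assert (r + dr, c + dc) not in pb

    def test_areas_never_increase(self):
        a = make_slice([[4, c] for c in range(0, 5)], seed_at=0)
        b = make_slice([[4, c] for c in range(5, 10)], seed_at=4)
        out = thin_slices([a, b], (10, 10))
        assert out[0].area_px <= a.area_px
        assert out[1].area_px <= b.area_px
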