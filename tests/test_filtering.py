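import numpy as np
import pandas as pd
import pytest

from embryoseg3d import FilterParams, Nucleus, classify_pair, filter_frame, merge_nuclei, pair_distances, select_deletion
from embryoseg3d.segment2d import Seed2D, Slice2D

from tests.test_temporal import row, table


def nucleus(nid=1, x=0.0, y=0.0, z=0.0, r=2.0, v=None, gray=100.0, slices=None):
    if v is None:
        v = 4.0 / 3.0 * np.pi * r**3
    return Nucleus(
        id=nid, x_um=x, y_um=y, z_um=z, radius_um=r, volume_um3=v,
        mean_gray=gray, slices=slices or [],
    )


class TestPairDistances:
    def test_identical_centers(self):
        a = pd.Series(row())
        assert pair_distances(a, a) == (0.0, 0.0)

    def test_pure_z_offset_has_zero_inplane_distance(self):
        a = pd.Series(row(z=0.0))
        b = pd.Series(row(z=2.0))
        assert pair_distances(a, b) == (pytest.approx(2.0), 0.0)

    def test_pythagorean_triple(self):
        a = pd.Series(row(x=0, y=0, z=0))
        b = pd.Series(row(x=3, y=4, z=12))
        big, small = pair_distances(a, b)
        assert big == pytest.approx(13.0)
        assert small == pytest.approx(5.0)


class TestClassifyPair:
    def test_coincident_centers_merge(self):
        a = pd.Series(row())
        assert classify_pair(a, a) == "merge"

    def test_vertical_split_merges(self):
        # R_A = R_B = 2, alpha 0.75, beta 0.45: D = 2 < 3, d = 0 < 1.8
        a = pd.Series(row(z=0.0))
        b = pd.Series(row(z=2.0))
        assert classify_pair(a, b) == "merge"

    def test_inplane_neighbour_deletes_one(self):
        # D = d = 2.5: below the alpha bound but beyond the beta bound
        a = pd.Series(row(x=0.0))
        b = pd.Series(row(x=2.5))
        assert classify_pair(a, b) == "delete_one"

    def test_separated_pair_kept(self):
        a = pd.Series(row(x=0.0))
        b = pd.Series(row(x=5.0))
        assert classify_pair(a, b) == "keep_both"

    def test_exact_beta_boundary_keeps_both(self):
        # d exactly beta * (R_A + R_B) = 1.8 with D < alpha bound
        a = pd.Series(row(x=0.0))
        b = pd.Series(row(x=1.8))
        assert classify_pair(a, b, FilterParams(alpha=0.75, beta=0.45)) == "keep_both"

    def test_out_of_range_params_warn(self):
        with pytest.warns(UserWarning):
            FilterParams(alpha=0.95)
        with pytest.warns(UserWarning):
            FilterParams(beta=0.2)


def pixel_slice(z, pixels, gray, dx=0.1):
    px = np.asarray(pixels, dtype=int)
    g = np.full(len(px), gray)
    return Slice2D(z, px, g, Seed2D(z, int(px[0][0]), int(px[0][1]), gray), dx, dx)


class TestMergeNuclei:
    def test_merging_duplicate_changes_nothing(self):
        s = [pixel_slice(4, [[1, 1], [1, 2], [2, 1]], 120.0)]
        a = nucleus(1, x=0.1, y=0.2, z=1.4, slices=s)
        b = nucleus(2, x=0.1, y=0.2, z=1.4, slices=list(s))
        merged = merge_nuclei(a, b, dz_eff=0.355)
        assert merged.id == 1
        assert merged.provenance == "merged"
        assert merged.volume_um3 == pytest.approx(3 * 0.1 * 0.1 * 0.355)
        assert merged.mean_gray == pytest.approx(120.0)

    def test_sliceless_duplicate_merge_is_idempotent(self):
        a = nucleus(1, v=10.0)
        b = nucleus(2, v=10.0)
        merged = merge_nuclei(a, b)
        assert merged.volume_um3 == pytest.approx(10.0)

    def test_merged_volume_bounded_by_sum(self):
        a = nucleus(1, x=0.0, v=10.0, r=1.5)
        b = nucleus(2, x=1.0, v=8.0, r=1.3)
        merged = merge_nuclei(a, b)
        assert merged.volume_um3 <= 18.0 + 1e-9
        assert merged.volume_um3 > 10.0

    def test_slice_union_recomputes_properties(self):
        a = nucleus(1, slices=[pixel_slice(4, [[0, 0], [0, 1]], 100.0)])
        b = nucleus(2, slices=[pixel_slice(4, [[0, 1], [0, 2]], 100.0), pixel_slice(5, [[0, 0]], 80.0)])
        merged = merge_nuclei(a, b, dz_eff=0.355)
        # union on plane 4 has 3 pixels, plane 5 has 1
        assert merged.volume_um3 == pytest.approx(4 * 0.1 * 0.1 * 0.355)
        assert len(merged.slices) == 2


class TestSelectDeletion:
    def test_smaller_volume_loses(self):
        a = pd.Series(row(1, v=30.0))
        b = pd.Series(row(2, v=10.0))
        assert select_deletion(a, b) == 2

    def test_volume_tie_dimmer_loses(self):
        a = pd.Series(row(1, v=10.0, gray=90.0))
        b = pd.Series(row(2, v=10.0, gray=120.0))
        assert select_deletion(a, b) == 1

    def test_full_tie_larger_id_loses(self):
        a = pd.Series(row(1, v=10.0))
        b = pd.Series(row(2, v=10.0))
        assert select_deletion(a, b) == 2


class TestFilterFrame:
    def test_separated_nuclei_untouched(self):
        t = table(row(1, x=0), row(2, x=10), row(3, x=20))
        out = filter_frame(t)
        assert len(out) == 3

    def test_chain_merges_transitively(self):
        t = table(row(1, x=0.0, z=0.0), row(2, x=0.3, z=1.2), row(3, x=0.6, z=2.4))
        out = filter_frame(t)
        assert len(out) == 1
        assert out.provenance.iloc[0] == "merged"
        assert out.nucleus_id.iloc[0] == 1

    def test_dim_fragment_beside_true_nucleus_deleted(self):
        big = row(1, x=0.0, v=33.5, gray=150.0)
        frag = row(2, x=2.0, r=1.0, v=2.0, gray=60.0)  # D=2 < 2.25, d=2 > 1.35
        out = filter_frame(table(big, frag))
        assert out.nucleus_id.tolist() == [1]
        assert out.volume_um3.iloc[0] == pytest.approx(33.5)

    def test_idempotent_fixed_point(self):
        rng = np.random.default_rng(5)
        rows = [
            row(i, x=rng.uniform(0, 12), y=rng.uniform(0, 12), z=rng.uniform(0, 6),
                r=rng.uniform(1, 2.5), v=rng.uniform(4, 60), gray=rng.uniform(50, 200))
            for i in range(12)
        ]
        once = filter_frame(table(*rows))
        twice = filter_frame(once)
        pd.testing.assert_frame_equal(once, twice)
        assert len(once) <= 12

    def test_no_triggering_pair_remains(self):
        rng = np.random.default_rng(6)
        rows = [
            row(i, x=rng.uniform(0, 10), y=rng.uniform(0, 10), z=rng.uniform(0, 5),
                r=rng.uniform(1, 2.5), v=rng.uniform(4, 60))
            for i in range(10)
        ]
        out = filter_frame(table(*rows))
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert classify_pair(out.iloc[i], out.iloc[j]) == "keep_both"
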