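"""2D slice segmentation: local-maximum seeds and modified region growing.

Each z-plane is segmented independently.  Seeds are 8-neighbourhood intensity
maxima above a background threshold; each seed grows into a connected 2D
slice under a distance-dependent acceptance rule: a frontier pixel B joins
the region when it has an already-accepted 4-neighbour A with

    G_A - G_B  <  4 * (G_A / g_ref + 1) * (1 - (d_BS / r)^2)

where ``d_BS`` is the physical distance from B to the seed and ``r`` the
largest nucleus radius seen in earlier frames.  The bound shrinks to zero as
``d_BS -> r``, so growth decays with distance from the seed instead of using
one fixed threshold -- this is what keeps a dim nucleus from being swallowed
("eclipsed") by a brighter neighbour's flank.  The rule is brightness
adaptive through ``G_A / g_ref``; ``g_ref`` defaults to 150 (8-bit-like
data) and is configurable for other bit depths.

A pixel joins whenever *some* accepted 4-neighbour admits it, which makes
the grown region the unique least fixed point of the acceptance relation:
the result does not depend on frontier iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage
from skimage.filters import threshold_otsu

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class Seed2D:
    """A 2D local-maximum seed on plane ``z``."""

    z: int
    row: int
    col: int
    gray: float


@dataclass
class GrowthParams:
    """Region-growing settings.

    ``r_max_um`` is the largest nucleus radius observed in previous time
    points (for the first frame, half the largest expected diameter, 3.5 um).
    ``background_threshold`` of ``None`` means per-plane Otsu.
    ``min_slice_area_px`` defaults to 12 px, which at ~0.1 um/px sampling is
    ~0.1 um^2 -- below the pole cross-section of the smallest target nucleus
    but large enough to reject speckle fragments.
    """

    r_max_um: float = 3.5
    min_slice_area_px: int = 12
    background_threshold: float | None = None
    eq12_gray_ref: float = 150.0

    def __post_init__(self) -> None:
        if self.r_max_um <= 0:
            raise ValueError("r_max_um must be positive")


@dataclass
class Slice2D:
    """A connected 2D pixel region on one z-plane, grown from one seed."""

    z: int
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    grays: np.ndarray  # (n,) intensities
    seed: Seed2D
    dx: float
    dy: float
    # derived, filled in __post_init__
    area_px: int = field(init=False)
    area_um2: float = field(init=False)
    equiv_radius_um: float = field(init=False)
    mean_gray: float = field(init=False)
    centroid_rc: tuple[float, float] = field(init=False)
    centroid_um: tuple[float, float] = field(init=False)  # (x_um, y_um)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        self.grays = np.asarray(self.grays, dtype=float)
        if len(self.pixels) == 0:
            raise ValueError("slice must contain at least one pixel")
        self.area_px = len(self.pixels)
        self.area_um2 = self.area_px * self.dx * self.dy
        self.equiv_radius_um = float(np.sqrt(self.area_um2 / np.pi))
        self.mean_gray = float(self.grays.mean())
        w = np.clip(self.grays, 1e-12, None)
        r_c = float(np.average(self.pixels[:, 0], weights=w))
        c_c = float(np.average(self.pixels[:, 1], weights=w))
        self.centroid_rc = (r_c, c_c)
        self.centroid_um = (c_c * self.dx, r_c * self.dy)

    @property
    def total_intensity(self) -> float:
        return float(self.grays.sum())

    def restricted_to(self, keep_mask: np.ndarray) -> "Slice2D":
        """A copy containing only pixels where ``keep_mask[row, col]``."""
        sel = keep_mask[self.pixels[:, 0], self.pixels[:, 1]]
        return Slice2D(self.z, self.pixels[sel], self.grays[sel], self.seed, self.dx, self.dy)


def find_seeds(plane: np.ndarray, params: GrowthParams, z: int = 0) -> list[Seed2D]:
    """All 8-neighbourhood maxima above the background threshold.

    A plateau (connected set of equal local-maximum pixels) contributes a
    single seed at the component pixel nearest its centroid.
    """
    plane = np.asarray(plane, dtype=float)
    thr = params.background_threshold
    if thr is None:
        thr = _safe_otsu(plane)
    mx = ndimage.maximum_filter(plane, size=3, mode="nearest")
    mask = (plane >= mx) & (plane > thr)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return []
    all_rows, all_cols = np.nonzero(mask)
    comp = labels[all_rows, all_cols]
    order = np.argsort(comp, kind="stable")
    all_rows, all_cols, comp = all_rows[order], all_cols[order], comp[order]
    starts = np.searchsorted(comp, np.arange(1, n + 2))
    seeds = []
    for k in range(n):
        rows = all_rows[starts[k] : starts[k + 1]]
        cols = all_cols[starts[k] : starts[k + 1]]
        if len(rows) == 1:
            r, c = int(rows[0]), int(cols[0])
        else:
            rc, cc = rows.mean(), cols.mean()
            d2 = (rows - rc) ** 2 + (cols - cc) ** 2
            best = np.lexsort((cols, rows, d2))[0]
            r, c = int(rows[best]), int(cols[best])
        seeds.append(Seed2D(z, r, c, float(plane[r, c])))
    seeds.sort(key=lambda s: (s.row, s.col))
    return seeds


def _safe_otsu(plane: np.ndarray) -> float:
    if np.ptp(plane) == 0:
        return float(plane.flat[0])  # constant plane: threshold excludes everything
    return float(threshold_otsu(plane))


def accept_pixel(
    g_a: float, g_b: float, d_bs_um: float, r_um: float, gray_ref: float = 150.0
) -> bool:
    """Distance-dependent growth criterion for candidate pixel B.

    ``g_a``: gray of the in-region neighbour; ``g_b``: candidate's gray;
    ``d_bs_um``: candidate-to-seed distance.  For ``d_bs_um >= r_um`` the
    bound is <= 0, so only candidates strictly brighter than their in-region
    neighbour can still join.
    """
    if r_um <= 0:
        raise ValueError("r_um must be positive")
    bound = 4.0 * (g_a / gray_ref + 1.0) * (1.0 - (d_bs_um / r_um) ** 2)
    return (g_a - g_b) < bound


@njit(cache=True)
def _grow_core(plane, seed_row, seed_col, r, thr, gray_ref, dx, dy):  # pragma: no cover
    """Worklist least-fixed-point growth (compiled inner loop).

    Semantics identical to the flood-fill oracle: a pixel joins when some
    already-accepted 4-neighbour admits it under the distance-dependent
    bound; pixels are revisited whenever a neighbour joins.
    """
    h, w = plane.shape
    in_region = np.zeros((h, w), dtype=np.bool_)
    in_region[seed_row, seed_col] = True
    cap = h * w * 8 + 8
    stack_r = np.empty(cap, dtype=np.int64)
    stack_c = np.empty(cap, dtype=np.int64)
    n = 0
    for k in range(4):
        nr = seed_row + (-1 if k == 0 else 1 if k == 1 else 0)
        nc = seed_col + (-1 if k == 2 else 1 if k == 3 else 0)
        if 0 <= nr < h and 0 <= nc < w:
            stack_r[n] = nr
            stack_c[n] = nc
            n += 1
    while n > 0:
        n -= 1
        br = stack_r[n]
        bc = stack_c[n]
        if in_region[br, bc]:
            continue
        g_b = plane[br, bc]
        if g_b <= thr:
            continue
        d2 = ((bc - seed_col) * dx) ** 2 + ((br - seed_row) * dy) ** 2
        if d2 > r * r:
            continue
        decay = 1.0 - d2 / (r * r)
        joined = False
        for k in range(4):
            ar = br + (-1 if k == 0 else 1 if k == 1 else 0)
            ac = bc + (-1 if k == 2 else 1 if k == 3 else 0)
            if 0 <= ar < h and 0 <= ac < w and in_region[ar, ac]:
                g_a = plane[ar, ac]
                if g_a - g_b < 4.0 * (g_a / gray_ref + 1.0) * decay:
                    joined = True
                    break
        if joined:
            in_region[br, bc] = True
            for k in range(4):
                nr = br + (-1 if k == 0 else 1 if k == 1 else 0)
                nc = bc + (-1 if k == 2 else 1 if k == 3 else 0)
                if 0 <= nr < h and 0 <= nc < w and not in_region[nr, nc]:
                    if n < cap:
                        stack_r[n] = nr
                        stack_c[n] = nc
                        n += 1
    return in_region


def region_grow(
    plane: np.ndarray,
    seed: Seed2D,
    params: GrowthParams,
    dx: float,
    dy: float,
    background_threshold: float | None = None,
) -> Slice2D:
    """Grow one seed into a connected 2D slice.

    Worklist computation of the least fixed point of the acceptance relation
    (a pixel is re-examined whenever a neighbour joins).  Growth is confined
    to ``d_BS <= r_max_um`` and to pixels above the background threshold.
    """
    plane = np.asarray(plane, dtype=np.float64)
    r = params.r_max_um
    thr = background_threshold
    if thr is None:
        thr = params.background_threshold
    if thr is None:
        thr = -np.inf
    # growth cannot leave the d <= r disk: work on the cropped window
    h, w = plane.shape
    rx, ry = int(np.ceil(r / dx)), int(np.ceil(r / dy))
    r0, r1 = max(seed.row - ry, 0), min(seed.row + ry + 1, h)
    c0, c1 = max(seed.col - rx, 0), min(seed.col + rx + 1, w)
    window = np.ascontiguousarray(plane[r0:r1, c0:c1])
    in_region = _grow_core(
        window, seed.row - r0, seed.col - c0, float(r), float(thr),
        float(params.eq12_gray_ref), float(dx), float(dy),
    )
    rows, cols = np.nonzero(in_region)
    rows = rows + r0
    cols = cols + c0
    order = np.lexsort((cols, rows))
    pixels = np.column_stack([rows[order], cols[order]])
    return Slice2D(seed.z, pixels, plane[pixels[:, 0], pixels[:, 1]], seed, dx, dy)


def _resolve_contested(regions: list[Slice2D], shape, dx: float, dy: float) -> list[Slice2D]:
    """Assign each multiply-claimed pixel to one region.

    Winner: smallest physical distance to the claiming seed; ties broken by
    brighter seed, then lower (row, col) of the seed.
    """
    if not regions:
        return []
    claim_count = np.zeros(shape, dtype=np.int32)
    for reg in regions:
        claim_count[reg.pixels[:, 0], reg.pixels[:, 1]] += 1
    if claim_count.max() <= 1:
        return regions
    # flatten all claims on contested pixels and pick one winner per pixel
    flat_idx, reg_idx, dists, seed_gray, seed_rc = [], [], [], [], []
    for i, reg in enumerate(regions):
        rows, cols = reg.pixels[:, 0], reg.pixels[:, 1]
        contested = claim_count[rows, cols] > 1
        if not contested.any():
            continue
        rr, cc = rows[contested], cols[contested]
        s = reg.seed
        flat_idx.append(rr.astype(np.int64) * shape[1] + cc)
        reg_idx.append(np.full(len(rr), i))
        dists.append(np.hypot((cc - s.col) * dx, (rr - s.row) * dy))
        seed_gray.append(np.full(len(rr), s.gray))
        seed_rc.append(np.full(len(rr), s.row * shape[1] + s.col))
    flat_idx = np.concatenate(flat_idx)
    reg_idx = np.concatenate(reg_idx)
    dists = np.concatenate(dists)
    seed_gray = np.concatenate(seed_gray)
    seed_rc = np.concatenate(seed_rc)
    order = np.lexsort((seed_rc, -seed_gray, dists, flat_idx))
    first = np.ones(len(order), dtype=bool)
    first[1:] = flat_idx[order][1:] != flat_idx[order][:-1]
    winner = np.full(shape[0] * shape[1], -1, dtype=np.int64)
    winner[flat_idx[order][first]] = reg_idx[order][first]
    out = []
    for i, reg in enumerate(regions):
        rows, cols = reg.pixels[:, 0], reg.pixels[:, 1]
        flat = rows.astype(np.int64) * shape[1] + cols
        sel = (claim_count[rows, cols] <= 1) | (winner[flat] == i)
        if not sel.any():
            continue
        trimmed = Slice2D(reg.z, reg.pixels[sel], reg.grays[sel], reg.seed, dx, dy)
        comp = _seed_component(trimmed)
        if comp is not None:
            out.append(comp)
    return out


def _seed_component(reg: Slice2D) -> Slice2D | None:
    """Keep the 4-connected component of the region containing its seed."""
    rows, cols = reg.pixels[:, 0], reg.pixels[:, 1]
    r0, c0 = rows.min(), cols.min()
    mask = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    mask[rows - r0, cols - c0] = True
    labels, _ = ndimage.label(mask, structure=_STRUCT4)
    sr, sc = reg.seed.row - r0, reg.seed.col - c0
    if not (0 <= sr < mask.shape[0] and 0 <= sc < mask.shape[1]) or labels[sr, sc] == 0:
        return None
    keep = labels[rows - r0, cols - c0] == labels[sr, sc]
    return Slice2D(reg.z, reg.pixels[keep], reg.grays[keep], reg.seed, reg.dx, reg.dy)


def thin_slices(slices: list[Slice2D], shape) -> list[Slice2D]:
    """Separate touching slices by one conditional erosion at their contacts.

    A pixel of slice i that is 8-adjacent to a pixel of any other slice is
    removed (the seed pixel is never removed), so touching slices end up
    disjoint with a gap; isolated slices are returned unchanged.
    """
    if len(slices) < 2:
        return list(slices)
    occupancy = np.zeros(shape, dtype=np.int32)
    for i, reg in enumerate(slices):
        occupancy[reg.pixels[:, 0], reg.pixels[:, 1]] = i + 1
    # a labelled pixel touches another slice iff its 8-neighbourhood holds a
    # different non-zero label: detectable from one max- and one min-filter
    big = np.where(occupancy == 0, np.iinfo(np.int32).max, occupancy)
    mn = ndimage.minimum_filter(big, size=3, mode="constant", cval=np.iinfo(np.int32).max)
    mx = ndimage.maximum_filter(occupancy, size=3, mode="constant", cval=0)
    contact = (occupancy > 0) & ((mx > occupancy) | (mn < occupancy))
    out = []
    for i, reg in enumerate(slices):
        keep = ~contact
        keep[reg.seed.row, reg.seed.col] = True
        sel = keep[reg.pixels[:, 0], reg.pixels[:, 1]]
        if not sel.any():
            out.append(reg)  # fully in contact: leave as grown
            continue
        trimmed = Slice2D(reg.z, reg.pixels[sel], reg.grays[sel], reg.seed, reg.dx, reg.dy)
        comp = _seed_component(trimmed)
        out.append(comp if comp is not None else trimmed)
    return out


def segment_plane(
    plane: np.ndarray,
    params: GrowthParams,
    dx: float,
    dy: float,
    z: int = 0,
) -> list[Slice2D]:
    """Seeds -> grown regions -> contested-pixel resolution -> thinning.

    Slices smaller than ``min_slice_area_px`` are dropped.
    """
    plane = np.asarray(plane, dtype=float)
    thr = params.background_threshold
    if thr is None:
        thr = _safe_otsu(plane)
    seeds = find_seeds(plane, params, z=z)
    regions = [region_grow(plane, s, params, dx, dy, background_threshold=thr) for s in seeds]
    regions = _resolve_contested(regions, plane.shape, dx, dy)
    regions = [r for r in regions if r.area_px >= params.min_slice_area_px]
    return thin_slices(regions, plane.shape)
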