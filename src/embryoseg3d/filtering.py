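"""Within-frame pairwise nucleus filtering (merge / delete geometry rules).

Residual false positives come in two geometric flavours.  A nucleus split
across planes yields two detections stacked almost vertically: the full 3D
separation D_AB is small *and* the in-plane separation d_AB is small — the
pair is merged.  A spurious detection beside a real nucleus sits at small
D_AB but with a large in-plane offset — one of the pair is deleted (the
smaller/dimmer one).  With radii R_A, R_B:

    merge      iff  D_AB < alpha * (R_A + R_B)  and  d_AB < beta * (R_A + R_B)
    delete_one iff  D_AB < alpha * (R_A + R_B)  and  d_AB > beta * (R_A + R_B)

alpha in (0.6, 0.9), beta in (0.35, 0.6); defaults are the range midpoints.
Equality at the beta bound satisfies neither strict inequality, so the pair
is kept.  Pairs are processed in ascending D_AB and the rules re-applied
until no pair triggers, so the output is a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nuclei import Nucleus
from .segment2d import Slice2D


@dataclass
class FilterParams:
    alpha: float = 0.75
    beta: float = 0.45

    def __post_init__(self) -> None:
        if not (0.6 < self.alpha < 0.9):
            warnings.warn(
                f"alpha={self.alpha} outside the validated range (0.6, 0.9)", stacklevel=2
            )
        if not (0.35 < self.beta < 0.6):
            warnings.warn(
                f"beta={self.beta} outside the validated range (0.35, 0.6)", stacklevel=2
            )


def pair_distances(a, b) -> tuple[float, float]:
    """(full 3D distance, in-plane x-y distance) between two nucleus rows."""
    dx = a.x_um - b.x_um
    dy = a.y_um - b.y_um
    dz = a.z_um - b.z_um
    d_inplane = float(np.hypot(dx, dy))
    return float(np.sqrt(dx**2 + dy**2 + dz**2)), d_inplane


def classify_pair(a, b, params: FilterParams | None = None) -> str:
    """One of ``merge``, ``delete_one``, ``keep_both``."""
    params = params or FilterParams()
    big_d, small_d = pair_distances(a, b)
    r_sum = a.radius_um + b.radius_um
    if big_d >= params.alpha * r_sum:
        return "keep_both"
    if small_d < params.beta * r_sum:
        return "merge"
    if small_d > params.beta * r_sum:
        return "delete_one"
    return "keep_both"  # exactly on the beta bound: neither strict rule fires


def _sphere_intersection_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the intersection of two spheres with radii r1, r2 at distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * np.pi * r**3
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12.0 * d)
    )


def _union_volume(v_a: float, v_b: float, r_a: float, r_b: float, d: float) -> float:
    """Sum of volumes minus the sphere-overlap volume, kept within the
    geometric bounds [max(V_A, V_B), V_A + V_B] (radius and volume fields
    need not be perfectly consistent)."""
    v = v_a + v_b - _sphere_intersection_volume(r_a, r_b, d)
    return float(min(max(v, v_a, v_b), v_a + v_b))


def merge_nuclei(a: Nucleus, b: Nucleus, dz_eff: float | None = None) -> Nucleus:
    """Merge two nuclei that are parts of one.

    With pixel slices available the merged nucleus is recomputed from the
    per-plane union of slice pixels.  Without slices (e.g. predicted rows)
    the merged volume is V_A + V_B minus the analytic sphere-overlap volume,
    which leaves a merge-with-duplicate unchanged and respects
    V_merged <= V_A + V_B.
    """
    new_id = min(a.id, b.id)
    if a.slices and b.slices and dz_eff is not None:
        by_z: dict[int, list[Slice2D]] = {}
        for s in list(a.slices) + list(b.slices):
            by_z.setdefault(s.z, []).append(s)
        merged_slices = []
        for z, group in sorted(by_z.items()):
            if len(group) == 1:
                merged_slices.append(group[0])
                continue
            seen: dict[tuple[int, int], float] = {}
            for s in group:
                for (r, c), g in zip(s.pixels, s.grays):
                    seen[(int(r), int(c))] = float(g)
            pixels = np.array(sorted(seen), dtype=int)
            grays = np.array([seen[tuple(p)] for p in pixels])
            seed = max((s.seed for s in group), key=lambda sd: (sd.gray, -sd.row, -sd.col))
            merged_slices.append(Slice2D(z, pixels, grays, seed, group[0].dx, group[0].dy))
        from .nuclei import _nucleus_from_slices

        out = _nucleus_from_slices(new_id, merged_slices, dz_eff)
        out.provenance = "merged"
        return out

    d = float(np.linalg.norm(a.center_um - b.center_um))
    v = _union_volume(a.volume_um3, b.volume_um3, a.radius_um, b.radius_um, d)
    w = np.array([a.volume_um3, b.volume_um3])
    centers = np.stack([a.center_um, b.center_um])
    z_um, y_um, x_um = np.average(centers, axis=0, weights=w)
    return Nucleus(
        id=new_id,
        x_um=float(x_um),
        y_um=float(y_um),
        z_um=float(z_um),
        radius_um=float((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)),
        volume_um3=float(v),
        mean_gray=float(np.average([a.mean_gray, b.mean_gray], weights=w)),
        slices=[],
        provenance="merged",
        center_z=a.center_z if a.volume_um3 >= b.volume_um3 else b.center_z,
    )


def select_deletion(a, b) -> int:
    """Which nucleus_id of a delete_one pair to drop.

    Smaller volume loses; ties by smaller mean gray, then larger id.
    """
    ka = (a.volume_um3, a.mean_gray, -int(a.nucleus_id))
    kb = (b.volume_um3, b.mean_gray, -int(b.nucleus_id))
    return int(a.nucleus_id) if ka < kb else int(b.nucleus_id)


def _merge_rows(a: pd.Series, b: pd.Series) -> dict:
    d, _ = pair_distances(a, b)
    v = _union_volume(a.volume_um3, b.volume_um3, a.radius_um, b.radius_um, d)
    w = np.array([a.volume_um3, b.volume_um3])
    return {
        "nucleus_id": int(min(a.nucleus_id, b.nucleus_id)),
        "t": int(a.t),
        "x_um": float(np.average([a.x_um, b.x_um], weights=w)),
        "y_um": float(np.average([a.y_um, b.y_um], weights=w)),
        "z_um": float(np.average([a.z_um, b.z_um], weights=w)),
        "radius_um": float((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)),
        "volume_um3": float(v),
        "mean_gray": float(np.average([a.mean_gray, b.mean_gray], weights=w)),
        "n_slices": int(max(a.n_slices, b.n_slices)),
        "provenance": "merged",
    }


def _first_triggering_pair(table: pd.DataFrame, params: FilterParams):
    """Lowest-D_AB pair classifying as merge/delete_one, or None.

    Vectorized scan; ties on D broken by the (id_A, id_B) pair for
    determinism.
    """
    n = len(table)
    xyz = table[["x_um", "y_um", "z_um"]].to_numpy()
    rad = table["radius_um"].to_numpy()
    diff = xyz[:, None, :] - xyz[None, :, :]
    big_d = np.linalg.norm(diff, axis=2)
    small_d = np.linalg.norm(diff[:, :, :2], axis=2)
    r_sum = rad[:, None] + rad[None, :]
    trig = (big_d < params.alpha * r_sum) & (small_d != params.beta * r_sum)
    trig &= np.triu(np.ones((n, n), dtype=bool), k=1)
    if not trig.any():
        return None
    ids = table["nucleus_id"].to_numpy()
    ii, jj = np.nonzero(trig)
    order = np.lexsort((ids[jj], ids[ii], big_d[ii, jj]))
    i, j = int(ii[order[0]]), int(jj[order[0]])
    verdict = "merge" if small_d[i, j] < params.beta * (rad[i] + rad[j]) else "delete_one"
    return i, j, verdict


def filter_frame(table: pd.DataFrame, params: FilterParams | None = None) -> pd.DataFrame:
    """Apply the merge/delete rules transitively until no pair triggers."""
    params = params or FilterParams()
    table = table.copy().reset_index(drop=True)
    while len(table) >= 2:
        hit = _first_triggering_pair(table, params)
        if hit is None:
            break
        i, j, verdict = hit
        a, b = table.iloc[i], table.iloc[j]
        if verdict == "merge":
            merged = _merge_rows(a, b)
            table = table.drop(index=[i, j]).reset_index(drop=True)
            table = pd.concat([table, pd.DataFrame([merged])], ignore_index=True)
        else:
            loser = select_deletion(a, b)
            table = table[table["nucleus_id"] != loser].reset_index(drop=True)
    return table.sort_values("nucleus_id", kind="stable").reset_index(drop=True)
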