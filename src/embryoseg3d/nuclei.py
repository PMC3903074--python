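"""Assemble 3D nuclei from per-plane 2D slices.

Each nucleus is identified by a single *center slice*: the 2D slice lying on
the plane of the nucleus's z-center, found from the z-axial gradient of the
mean gray value over the slice's pixel footprint.  With the forward
difference G(Z) = mean(I(Z+1) - I(Z)), a bright nucleus gives G > 0 below
its center and G < 0 above it.

Two detection rules are available:

``sign_corrected`` (default)
    The slice's footprint-mean intensity is a z-local maximum:
    G(Z-1) >= 0 and G(Z) <= 0 (not both zero).  Localizes the center plane
    to within one plane on symmetric profiles.

``literal``
    G(Z+1) < 0, G(Z-1) < 0, G(Z) < G(Z-1), G(Z) < G(Z+1) applied verbatim.
    On a symmetric axial profile these inequalities select the plane of
    steepest descent *above* the center (offset ~ radius/2), not the center
    itself; the variant is kept so the behaviour can be audited.

Remaining slices are attached to their nearest center (3D physical
distance), and per-nucleus position, radius, volume and brightness follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segment2d import Slice2D

CENTER_RULES = ("sign_corrected", "literal")


@dataclass
class Nucleus:
    """A detected nucleus: a center slice plus its assigned slices."""

    id: int
    x_um: float
    y_um: float
    z_um: float
    radius_um: float
    volume_um3: float
    mean_gray: float
    slices: list[Slice2D] = field(default_factory=list)
    provenance: str = "segmented"
    center_z: int | None = None

    @property
    def n_slices(self) -> int:
        return max(len(self.slices), 1)

    @property
    def center_um(self) -> np.ndarray:
        return np.array([self.z_um, self.y_um, self.x_um])


@dataclass(frozen=True)
class ZGradientProfile:
    """Mean z-axial gradients around a slice's plane Z (forward differences).

    ``g_below`` = G(Z-1), ``g_at`` = G(Z), ``g_above`` = G(Z+1).
    """

    g_below: float
    g_at: float
    g_above: float


def mean_z_gradient(volume: np.ndarray, slc: Slice2D, z: int) -> float:
    """Mean forward difference I(z+1) - I(z) over the slice's footprint."""
    if z < 0 or z + 1 >= volume.shape[0]:
        raise ValueError(f"gradient undefined at plane {z} of {volume.shape[0]}")
    rows, cols = slc.pixels[:, 0], slc.pixels[:, 1]
    return float(np.mean(volume[z + 1, rows, cols] - volume[z, rows, cols]))


def z_gradient_profile(volume: np.ndarray, slc: Slice2D) -> ZGradientProfile:
    """Gradient triple around the slice's own plane (must be interior)."""
    z = slc.z
    if z < 1 or z + 2 >= volume.shape[0]:
        raise ValueError(f"gradient profile undefined for border plane {z}")
    return ZGradientProfile(
        g_below=mean_z_gradient(volume, slc, z - 1),
        g_at=mean_z_gradient(volume, slc, z),
        g_above=mean_z_gradient(volume, slc, z + 1),
    )


def is_center_slice(profile: ZGradientProfile, rule: str = "sign_corrected") -> bool:
    """Does the gradient profile mark this slice as a nucleus center?"""
    if rule == "literal":
        return (
            profile.g_above < 0
            and profile.g_below < 0
            and profile.g_at < profile.g_below
            and profile.g_at < profile.g_above
        )
    if rule == "sign_corrected":
        return (
            profile.g_below >= 0
            and profile.g_at <= 0
            and not (profile.g_below == 0 and profile.g_at == 0)
        )
    raise ValueError(f"unknown center rule {rule!r}; choose from {CENTER_RULES}")


def _footprints_overlap(a: Slice2D, b: Slice2D) -> bool:
    pa = {(int(r), int(c)) for r, c in a.pixels}
    return any((int(r), int(c)) in pa for r, c in b.pixels)


def find_center_slices(
    volume: np.ndarray, slices: list[Slice2D], rule: str = "sign_corrected"
) -> list[Slice2D]:
    """All center slices, with vertical duplicates resolved.

    When two qualifying slices on adjacent planes overlap vertically, the one
    with larger mean gray wins (ties: lower z, then lexicographic seed).
    """
    qualifying = []
    z_max = volume.shape[0]
    for slc in slices:
        if slc.z < 1 or slc.z + 2 >= z_max:
            continue
        if is_center_slice(z_gradient_profile(volume, slc), rule):
            qualifying.append(slc)
    qualifying.sort(key=lambda s: (-s.mean_gray, s.z, s.seed.row, s.seed.col))
    kept: list[Slice2D] = []
    for cand in qualifying:
        suppressed = any(
            abs(cand.z - k.z) <= 1 and _footprints_overlap(cand, k) for k in kept
        )
        if not suppressed:
            kept.append(cand)
    kept.sort(key=lambda s: (s.z, s.seed.row, s.seed.col))
    return kept


def _nucleus_from_slices(nucleus_id: int, members: list[Slice2D], dz_eff: float,
                         center_z: int | None = None) -> Nucleus:
    w = np.array([max(s.total_intensity, 1e-12) for s in members])
    xs = np.array([s.centroid_um[0] for s in members])
    ys = np.array([s.centroid_um[1] for s in members])
    zs = np.array([s.z * dz_eff for s in members])
    volume = float(sum(s.area_um2 for s in members) * dz_eff)
    radius = float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))
    areas = np.array([s.area_px for s in members], dtype=float)
    grays = np.array([s.mean_gray for s in members])
    return Nucleus(
        id=nucleus_id,
        x_um=float(np.average(xs, weights=w)),
        y_um=float(np.average(ys, weights=w)),
        z_um=float(np.average(zs, weights=w)),
        radius_um=radius,
        volume_um3=volume,
        mean_gray=float(np.average(grays, weights=areas)),
        slices=sorted(members, key=lambda s: s.z),
        provenance="segmented",
        center_z=center_z,
    )


def assign_slices(
    centers: list[Slice2D],
    all_slices: list[Slice2D],
    r_max_um: float,
    dz_eff: float,
) -> list[Nucleus]:
    """Attach every non-center slice to its nearest center and build nuclei.

    A slice joins the nearest center (3D physical centroid distance) only if
    that distance and the z-gap are both below ``r_max_um``; otherwise it is
    discarded.  Equidistant ties go to the brighter center.
    """
    if not centers:
        return []
    center_set = {id(c) for c in centers}
    c_xyz = np.array(
        [[c.centroid_um[0], c.centroid_um[1], c.z * dz_eff] for c in centers]
    )
    c_gray = np.array([c.mean_gray for c in centers])
    members: list[list[Slice2D]] = [[c] for c in centers]
    for slc in all_slices:
        if id(slc) in center_set:
            continue
        p = np.array([slc.centroid_um[0], slc.centroid_um[1], slc.z * dz_eff])
        d = np.linalg.norm(c_xyz - p, axis=1)
        z_gap = np.abs(c_xyz[:, 2] - p[2])
        # nearest admissible center; ties to the brighter center
        order = np.lexsort((-c_gray, d))
        best = order[0]
        if d[best] < r_max_um and z_gap[best] < r_max_um:
            members[best].append(slc)
    return [
        _nucleus_from_slices(i + 1, m, dz_eff, center_z=centers[i].z)
        for i, m in enumerate(members)
    ]


def build_nuclei(
    volume: np.ndarray,
    slices: list[Slice2D],
    r_max_um: float,
    dz_eff: float,
    rule: str = "sign_corrected",
) -> list[Nucleus]:
    """Center-slice detection followed by slice assignment."""
    centers = find_center_slices(volume, slices, rule=rule)
    return assign_slices(centers, slices, r_max_um, dz_eff)
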