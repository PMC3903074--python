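"""Synthetic embryo phantoms with ground truth.

Generates time-lapse stacks of fluorescently-labelled nucleus look-alikes:
soft-edged spherical blobs (truncated Gaussian profile, sigma = radius / 2)
sampled on an anisotropic voxel grid, with per-nucleus brightness
heterogeneity, bounded inter-frame motion, optional divisions, optional
top-of-embryo crowding with z-flattening, and sensor noise.  Every rendered
nucleus is recorded in a ground-truth table so each pipeline stage can be
scored without real data.

Ground-truth tables are DataFrames with columns
``t, gt_id, x_um, y_um, z_um, radius_um, peak_intensity, parent_id, hidden``.
``hidden`` marks nuclei whose signal was erased by :func:`ablate_frame`
(present in truth, absent from the image — the gap the temporal predictor
must fill).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TimeLapseStack, VoxelSpacing

GT_COLUMNS = [
    "t",
    "gt_id",
    "x_um",
    "y_um",
    "z_um",
    "radius_um",
    "peak_intensity",
    "parent_id",
    "hidden",
]

#: Gaussian blobs are rendered out to this many sigmas ( = 1.25 radii).
TRUNCATION_SIGMAS = 2.5


@dataclass
class PhantomParams:
    """Knobs of the phantom generator.

    Defaults emulate the imaging conditions this pipeline targets: 0.71 µm
    plane spacing, 90 s frame interval, nucleus diameters 1.8–7 µm, and
    8-bit-like gray levels.  In-plane sampling is 0.09 µm/px, typical of a
    confocal embryo protocol (512 px across a ~46 µm field).
    """

    n_nuclei: int = 10
    n_frames: int = 3
    radius_range_um: tuple[float, float] = (0.9, 3.5)
    frame_shape: tuple[int, int, int] = (31, 320, 320)  # (z, y, x)
    spacing: VoxelSpacing = field(default_factory=lambda: VoxelSpacing(0.09, 0.09, 0.71))
    time_step_s: float = 90.0
    peak_intensity_range: tuple[float, float] = (80.0, 200.0)
    background_level: float = 10.0
    noise_sigma: float = 2.0
    poisson_noise: bool = False
    max_displacement_um: float = 0.5
    division_rate: float = 0.0
    crowding_mode: str = "uniform"  # "uniform" | "top-crowded"
    min_separation_factor: float = 1.0  # centres >= factor * (r_i + r_j) apart
    z_flatten: float = 0.6  # z-extent scale of crowded nuclei
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range_um[0] <= 0:
            raise ValueError("radii must be positive")
        if self.crowding_mode not in {"uniform", "top-crowded"}:
            raise ValueError(f"unknown crowding_mode {self.crowding_mode!r}")
        if self.n_frames < 1 or self.n_nuclei < 1:
            raise ValueError("need at least one frame and one nucleus")


def _extent_um(params: PhantomParams) -> np.ndarray:
    z, y, x = params.frame_shape
    s = params.spacing
    return np.array([(z - 1) * s.dz, (y - 1) * s.dy, (x - 1) * s.dx])


def _min_sep(params: PhantomParams, r_i: float, r_j: float) -> float:
    factor = params.min_separation_factor
    if params.crowding_mode == "top-crowded":
        factor = min(factor, 0.5)  # crowding: partial overlap allowed
    return factor * (r_i + r_j)


def _place_initial(params: PhantomParams, rng: np.random.Generator):
    ext = _extent_um(params)
    nuclei = []
    for i in range(params.n_nuclei):
        r = rng.uniform(*params.radius_range_um)
        peak = rng.uniform(*params.peak_intensity_range)
        placed = False
        for _ in range(20000):
            lo = np.array([r, r, r])
            hi = ext - r
            if np.any(hi <= lo):
                break
            c = rng.uniform(lo, hi)
            if params.crowding_mode == "top-crowded":
                z_lo = max(r, 0.7 * ext[0])
                if z_lo >= ext[0] - r:
                    break
                c[0] = rng.uniform(z_lo, ext[0] - r)
            ok = all(
                np.linalg.norm(c - n["center"]) >= _min_sep(params, r, n["radius"])
                and np.linalg.norm(c - n["center"]) > 0
                for n in nuclei
            )
            if ok:
                placed = True
                break
        if not placed:
            raise ValueError("cannot place without full overlap: frame too crowded for n_nuclei")
        nuclei.append({"gt_id": i, "center": c, "radius": r, "peak": peak, "parent": -1})
    return nuclei


def _move(params: PhantomParams, rng: np.random.Generator, nuclei):
    """Bounded random walk keeping nuclei inside the frame and separated."""
    ext = _extent_um(params)
    out = []
    for n in nuclei:
        r = n["radius"]
        new_c = n["center"]
        for _ in range(50):
            direction = rng.normal(size=3)
            norm = np.linalg.norm(direction)
            if norm == 0:
                continue
            step = direction / norm * rng.uniform(0, params.max_displacement_um)
            cand = np.clip(n["center"] + step, [r, r, r], np.maximum(ext - r, [r, r, r]))
            ok = all(
                np.linalg.norm(cand - m["center"]) >= _min_sep(params, r, m["radius"])
                for m in out
            )
            if ok:
                new_c = cand
                break
        out.append({**n, "center": new_c})
    return out


def _divide(params: PhantomParams, rng: np.random.Generator, nuclei, next_id: int):
    """Replace dividing nuclei by two daughters at +/- offset along a random axis."""
    out = []
    for n in nuclei:
        if rng.uniform() < params.division_rate:
            r_child = n["radius"] / 2.0 ** (1.0 / 3.0)  # volume-conserving split
            direction = rng.normal(size=3)
            direction /= max(np.linalg.norm(direction), 1e-12)
            offset = 0.7 * r_child * direction
            ext = _extent_um(params)
            for sign in (+1.0, -1.0):
                c = np.clip(
                    n["center"] + sign * offset,
                    [r_child] * 3,
                    np.maximum(ext - r_child, [r_child] * 3),
                )
                out.append(
                    {
                        "gt_id": next_id,
                        "center": c,
                        "radius": r_child,
                        "peak": n["peak"],
                        "parent": n["gt_id"],
                    }
                )
                next_id += 1
        else:
            out.append(n)
    return out, next_id


def render_nucleus(
    frame: np.ndarray,
    spacing: VoxelSpacing,
    center_um,
    radius_um: float,
    peak: float,
    z_flatten: float = 1.0,
) -> None:
    """Add one truncated-Gaussian blob (in place) to a (z, y, x) frame.

    ``z_flatten`` < 1 compresses the blob along z (crowded, flattened nuclei).
    """
    sigma = radius_um / 2.0
    cz, cy, cx = center_um
    ext_z = TRUNCATION_SIGMAS * sigma * z_flatten
    ext_xy = TRUNCATION_SIGMAS * sigma
    z0 = max(int(np.floor((cz - ext_z) / spacing.dz)), 0)
    z1 = min(int(np.ceil((cz + ext_z) / spacing.dz)), frame.shape[0] - 1)
    y0 = max(int(np.floor((cy - ext_xy) / spacing.dy)), 0)
    y1 = min(int(np.ceil((cy + ext_xy) / spacing.dy)), frame.shape[1] - 1)
    x0 = max(int(np.floor((cx - ext_xy) / spacing.dx)), 0)
    x1 = min(int(np.ceil((cx + ext_xy) / spacing.dx)), frame.shape[2] - 1)
    if z1 < z0 or y1 < y0 or x1 < x0:
        return
    zz = (np.arange(z0, z1 + 1) * spacing.dz - cz) / z_flatten
    yy = np.arange(y0, y1 + 1) * spacing.dy - cy
    xx = np.arange(x0, x1 + 1) * spacing.dx - cx
    d2 = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    blob = peak * np.exp(-d2 / (2.0 * sigma**2))
    blob[d2 > (TRUNCATION_SIGMAS * sigma) ** 2] = 0.0
    frame[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1] += blob


def _render_frame(params: PhantomParams, nuclei, rng: np.random.Generator) -> np.ndarray:
    frame = np.full(params.frame_shape, params.background_level, dtype=float)
    flat = params.z_flatten if params.crowding_mode == "top-crowded" else 1.0
    for n in nuclei:
        render_nucleus(frame, params.spacing, n["center"], n["radius"], n["peak"], flat)
    if params.poisson_noise:
        frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
    if params.noise_sigma > 0:
        frame = frame + rng.normal(0.0, params.noise_sigma, size=frame.shape)
    return np.clip(frame, 0.0, None)


def generate_phantom(params: PhantomParams) -> tuple[TimeLapseStack, pd.DataFrame]:
    """Render a phantom time-lapse and its ground-truth table.

    Deterministic for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    nuclei = _place_initial(params, rng)
    next_id = params.n_nuclei
    frames = []
    records = []
    for t in range(params.n_frames):
        if t > 0:
            nuclei = _move(params, rng, nuclei)
            nuclei, next_id = _divide(params, rng, nuclei, next_id)
        frames.append(_render_frame(params, nuclei, rng))
        for n in nuclei:
            records.append(
                {
                    "t": t,
                    "gt_id": n["gt_id"],
                    "x_um": n["center"][2],
                    "y_um": n["center"][1],
                    "z_um": n["center"][0],
                    "radius_um": n["radius"],
                    "peak_intensity": n["peak"],
                    "parent_id": n["parent"],
                    "hidden": False,
                }
            )
    truth = pd.DataFrame(records, columns=GT_COLUMNS)
    stack = TimeLapseStack(np.stack(frames), params.spacing, params.time_step_s)
    return stack, truth


def ablate_frame(
    stack: TimeLapseStack,
    truth: pd.DataFrame,
    t: int,
    gt_id: int,
    background_level: float | None = None,
) -> tuple[TimeLapseStack, pd.DataFrame]:
    """Erase one nucleus's signal at frame ``t``; mark it hidden in truth.

    The blob's voxels are replaced by ``background_level`` (frame median when
    omitted), producing exactly the single-frame detection gap the
    bi-directional predictor is meant to fill.
    """
    sel = (truth["t"] == t) & (truth["gt_id"] == gt_id)
    if not sel.any():
        raise ValueError(f"gt_id {gt_id} not present at t={t}")
    row = truth.loc[sel].iloc[0]
    voxels = stack.voxels.copy()
    frame = voxels[t]
    if background_level is None:
        background_level = float(np.median(frame))
    sigma = row.radius_um / 2.0
    s = stack.spacing
    zz = np.arange(frame.shape[0]) * s.dz - row.z_um
    yy = np.arange(frame.shape[1]) * s.dy - row.y_um
    xx = np.arange(frame.shape[2]) * s.dx - row.x_um
    d2 = zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    mask = d2 <= (TRUNCATION_SIGMAS * sigma) ** 2
    frame[mask] = background_level
    truth = truth.copy()
    truth.loc[sel, "hidden"] = True
    return TimeLapseStack(voxels, stack.spacing, stack.time_step_s), truth


def inject_transient_nucleus(
    stack: TimeLapseStack,
    t: int,
    center_um,
    radius_um: float,
    peak: float,
) -> TimeLapseStack:
    """Render a spurious blob into a single frame (a planted false positive)."""
    voxels = stack.voxels.copy()
    render_nucleus(voxels[t], stack.spacing, center_um, radius_um, peak)
    return TimeLapseStack(voxels, stack.spacing, stack.time_step_s)
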