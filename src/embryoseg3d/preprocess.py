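"""Plane smoothing by mean-curvature flow and z-sampling doubling.

The smoothing stage evolves each z-plane's intensity surface under its own
mean curvature (a level-set formulation: every iso-intensity contour moves
with speed proportional to its curvature).  This removes speckle noise while
preserving, and mildly sharpening, blob edges.  Smoothing is strictly 2D
per-plane: with plane spacing several times the pixel size, 3D curvature is
ill-conditioned.

The interpolation stage inserts the average of each adjacent pair of
(smoothed) planes between them, turning a Z-plane frame into 2Z-1 planes and
halving the effective plane spacing (0.71 um -> 0.355 um for the targeted
protocol), so that small nuclei span enough planes to be assembled from 2D
slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_EPS = 1e-8


@dataclass
class PreprocessParams:
    """Smoothing/interpolation settings.

    ``iterations`` defaults to 6; in very crowded frames (late stages, ~500
    cells) 4 iterations preserve more inter-nucleus contrast.  ``time_step``
    is the explicit-scheme step size; 0.2 is stable for the finite
    difference stencil used here (the 2D explicit diffusion limit is 0.25).
    ``presmooth_sigma_px`` regularizes the scheme with one Gaussian blur
    before the curvature iterations: curvature flow moves features at speed
    proportional to the gradient magnitude, so low-amplitude sensor noise
    on flat regions is nearly stationary under the flow alone and would
    survive as spurious intensity maxima.
    """

    iterations: int = 6
    time_step: float = 0.2
    presmooth_sigma_px: float = 1.0
    interpolate: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")
        if self.presmooth_sigma_px < 0:
            raise ValueError("presmooth_sigma_px must be >= 0")


def _curvature_step(img: np.ndarray, dt: float) -> np.ndarray:
    """One explicit Euler step of I_t = kappa * |grad I| on the last two axes.

    Neumann (replicated-edge) boundaries via ``np.gradient``.
    """
    ax_y, ax_x = img.ndim - 2, img.ndim - 1
    iy = np.gradient(img, axis=ax_y)
    ix = np.gradient(img, axis=ax_x)
    ixx = np.gradient(ix, axis=ax_x)
    iyy = np.gradient(iy, axis=ax_y)
    ixy = np.gradient(ix, axis=ax_y)
    num = ixx * iy**2 - 2.0 * ix * iy * ixy + iyy * ix**2
    den = ix**2 + iy**2 + _EPS
    return img + dt * num / den


def curvature_smooth(plane: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Smooth a 2D plane (or a (z, y, x) batch of planes) by curvature flow.

    The output range is clipped to the input's [min, max] so the smoothing is
    an intensity-range contraction (no new global extrema).
    """
    plane = np.asarray(plane, dtype=float)
    if not np.all(np.isfinite(plane)):
        raise ValueError("plane contains non-finite pixels")
    if params.iterations == 0:
        return plane.copy()
    lo, hi = float(plane.min()), float(plane.max())
    out = plane.copy()
    if params.presmooth_sigma_px > 0:
        sigma = (params.presmooth_sigma_px,) * 2
        if out.ndim == 3:
            sigma = (0.0,) + sigma
        out = np.clip(ndimage.gaussian_filter(out, sigma=sigma, mode="nearest"), lo, hi)
    for _ in range(params.iterations):
        out = np.clip(_curvature_step(out, params.time_step), lo, hi)
    return out


def interpolate_planes(frame: np.ndarray) -> np.ndarray:
    """Insert the mean of each adjacent plane pair: Z planes -> 2Z - 1.

    Original planes land on even output indices; effective plane spacing is
    halved.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3:
        raise ValueError("expected a (z, y, x) volume")
    z = frame.shape[0]
    if z < 2:
        raise ValueError("need at least 2 planes to interpolate")
    out = np.empty((2 * z - 1,) + frame.shape[1:], dtype=float)
    out[::2] = frame
    out[1::2] = 0.5 * (frame[:-1] + frame[1:])
    return out


def preprocess_frame(frame: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Smooth every plane, then (optionally) double the z-sampling.

    When ``params.interpolate`` is set the caller must halve its plane
    spacing for all downstream physical-coordinate math
    (:meth:`VoxelSpacing.with_halved_z`).
    """
    smoothed = curvature_smooth(np.asarray(frame, dtype=float), params)
    if params.interpolate:
        return interpolate_planes(smoothed)
    return smoothed
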