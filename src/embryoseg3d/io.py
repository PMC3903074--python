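"""Image-stack and nucleus-table I/O, plus the coordinate conventions.

Conventions owned by this module
--------------------------------
* Voxel indices are 0-based ``(t, z, y, x)``.
* Physical coordinates are micrometres: ``x_um = col * dx``, ``y_um = row * dy``,
  ``z_um = plane * dz``.  Plane spacing ``dz`` may greatly exceed the in-plane
  pixel size (anisotropic confocal stacks).
* Nucleus tables are plain :class:`pandas.DataFrame` objects with the fixed
  column set :data:`NUCLEUS_COLUMNS`, written as CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Fixed CSV header for nucleus tables.
NUCLEUS_COLUMNS = [
    "nucleus_id",
    "t",
    "x_um",
    "y_um",
    "z_um",
    "radius_um",
    "volume_um3",
    "mean_gray",
    "n_slices",
    "provenance",
]

PROVENANCE_VALUES = frozenset({"segmented", "predicted", "merged"})

#: Default per-plane file-name dialect: ``<anything>-t<T>-p<Z>.tif``.
DEFAULT_PLANE_PATTERN = r".*-t(?P<t>\d+)-p(?P<z>\d+)\.tiff?$"


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel spacing in micrometres.

    ``dz`` (plane spacing) typically exceeds ``dx``/``dy``; the confocal
    protocol this package targets uses 0.71 µm plane spacing.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError("voxel spacing components must be strictly positive")

    def with_halved_z(self) -> "VoxelSpacing":
        """Spacing after z-doubling interpolation (dz → dz / 2)."""
        return replace(self, dz=self.dz / 2.0)


@dataclass
class TimeLapseStack:
    """A 4D single-channel time-lapse image, indexed ``(t, z, y, x)``."""

    voxels: np.ndarray
    spacing: VoxelSpacing
    time_step_s: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"expected a (t, z, y, x) array, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack contains non-finite intensities")
        if np.min(self.voxels) < 0:
            raise ValueError("stack contains negative intensities")
        if self.time_step_s <= 0:
            raise ValueError("time_step_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def frame(self, t: int) -> np.ndarray:
        return self.voxels[t]


def _read_per_plane(paths, matches, spacing, time_step_s):
    by_t: dict[int, dict[int, Path]] = {}
    for path, m in zip(paths, matches):
        t, z = int(m.group("t")), int(m.group("z"))
        by_t.setdefault(t, {})[z] = path
    t_values = sorted(by_t)
    frames = []
    dtype = None
    shape = None
    for t in t_values:
        planes = by_t[t]
        z_values = sorted(planes)
        z_min, z_max = z_values[0], z_values[-1]
        for z in range(z_min, z_max + 1):
            if z not in planes:
                raise ValueError(f"missing plane in frame t={t}: no file for z={z}")
        imgs = []
        for z in range(z_min, z_max + 1):
            img = tifffile.imread(planes[z])
            if dtype is None:
                dtype, shape = img.dtype, img.shape
            if img.dtype != dtype:
                raise ValueError(
                    f"mixed bit depths: t={t}, z={z} has dtype {img.dtype}, expected {dtype}"
                )
            if img.shape != shape:
                raise ValueError(f"plane shape mismatch at t={t}, z={z}")
            imgs.append(img)
        frames.append(np.stack(imgs))
    n_planes = {f.shape[0] for f in frames}
    if len(n_planes) > 1:
        raise ValueError(f"frames have differing plane counts: {sorted(n_planes)}")
    return TimeLapseStack(np.stack(frames), spacing, time_step_s)


def read_stack(
    path,
    spacing: VoxelSpacing,
    time_step_s: float,
    plane_pattern: str = DEFAULT_PLANE_PATTERN,
) -> TimeLapseStack:
    """Read a time-lapse stack from TIFF files.

    ``path`` may be a single multi-page TIFF (one time point), or a directory
    holding either per-plane TIFFs matching ``plane_pattern`` (a regex with
    named groups ``t`` and ``z``) or one multi-page TIFF per time point
    (sorted by file name).  Intensities are preserved bit-exactly.
    """
    path = Path(path)
    if path.is_file():
        vol = tifffile.imread(path)
        if vol.ndim == 2:
            vol = vol[None]
        if vol.ndim != 3:
            raise ValueError(f"expected a 2D/3D TIFF, got ndim={vol.ndim}")
        return TimeLapseStack(vol[None], spacing, time_step_s)

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"})
    if not files:
        raise ValueError(f"no planes found in {path}")
    rx = re.compile(plane_pattern)
    matches = [rx.match(p.name) for p in files]
    if all(m is not None for m in matches):
        return _read_per_plane(files, matches, spacing, time_step_s)

    frames = [tifffile.imread(p) for p in files]
    dtypes = {f.dtype for f in frames}
    if len(dtypes) > 1:
        raise ValueError(f"mixed bit depths across frames: {sorted(map(str, dtypes))}")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"frames have differing shapes: {sorted(shapes)}")
    return TimeLapseStack(np.stack(frames), spacing, time_step_s)


def write_stack(stack: TimeLapseStack, directory, per_plane: bool = True) -> None:
    """Write a stack as TIFFs readable by :func:`read_stack`.

    With ``per_plane=True`` files are named ``frame-t{T:03d}-p{Z:03d}.tif``
    (the default dialect); otherwise one multi-page TIFF per time point.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in range(stack.n_frames):
        if per_plane:
            for z in range(stack.voxels.shape[1]):
                tifffile.imwrite(directory / f"frame-t{t:03d}-p{z:03d}.tif", stack.voxels[t, z])
        else:
            tifffile.imwrite(directory / f"frame-{t:03d}.tif", stack.voxels[t])


def empty_nucleus_table() -> pd.DataFrame:
    """A nucleus table with the documented header and zero rows."""
    return pd.DataFrame(
        {
            "nucleus_id": pd.Series(dtype=int),
            "t": pd.Series(dtype=int),
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "z_um": pd.Series(dtype=float),
            "radius_um": pd.Series(dtype=float),
            "volume_um3": pd.Series(dtype=float),
            "mean_gray": pd.Series(dtype=float),
            "n_slices": pd.Series(dtype=int),
            "provenance": pd.Series(dtype=object),
        }
    )


def validate_nucleus_table(table: pd.DataFrame, *, line_offset: int | None = None) -> None:
    """Raise ``ValueError`` on the first invariant-violating row.

    ``line_offset`` shifts the reported index to a file line number (header is
    line 1) when validating data just read from CSV.
    """
    missing = [c for c in NUCLEUS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"nucleus table is missing columns: {missing}")
    for i, row in enumerate(table.itertuples(index=False)):
        where = f"line {i + line_offset}" if line_offset is not None else f"row {i}"
        if not row.radius_um > 0:
            raise ValueError(f"malformed nucleus table {where}: radius_um must be > 0")
        if not row.volume_um3 > 0:
            raise ValueError(f"malformed nucleus table {where}: volume_um3 must be > 0")
        if not row.n_slices >= 1:
            raise ValueError(f"malformed nucleus table {where}: n_slices must be >= 1")
        if row.provenance not in PROVENANCE_VALUES:
            raise ValueError(
                f"malformed nucleus table {where}: provenance {row.provenance!r} "
                f"not in {sorted(PROVENANCE_VALUES)}"
            )
    dup = table.duplicated(subset=["t", "nucleus_id"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        where = f"line {i + line_offset}" if line_offset is not None else f"row {i}"
        raise ValueError(f"malformed nucleus table {where}: duplicate nucleus_id within a time point")


def write_nucleus_table(table: pd.DataFrame, path) -> None:
    """Write a nucleus table as CSV (floats at 6 significant digits)."""
    validate_nucleus_table(table)
    table = table[NUCLEUS_COLUMNS]
    table.to_csv(path, index=False, float_format="%.6g")


def read_nucleus_table(path) -> pd.DataFrame:
    """Read a nucleus table CSV written by :func:`write_nucleus_table`."""
    table = pd.read_csv(path)
    # header is line 1, first data row is line 2
    validate_nucleus_table(table, line_offset=2)
    table["nucleus_id"] = table["nucleus_id"].astype(int)
    table["t"] = table["t"].astype(int)
    table["n_slices"] = table["n_slices"].astype(int)
    return table
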