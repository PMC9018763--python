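"""Volume container, NIfTI I/O, preprocessing, and sliding-window plumbing.

The internal axis convention everywhere in this package is ``(z, y, x)``
with 0-based indices and half-open windows.  NIfTI files store data in
``(x, y, z)`` order, so arrays are transposed on read/write and the header
spacing/origin triplets are reversed to match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class Volume:
    """A 3D scalar field with physical spacing.

    Parameters
    ----------
    voxels:
        3D array in ``(z, y, x)`` order.
    spacing:
        Per-axis voxel size ``(sz, sy, sx)`` in mm; all components > 0.
    origin:
        Physical coordinate (mm) of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError(f"Volume requires a 3D array, got ndim={self.voxels.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.voxels.shape):
            raise ValueError(f"degenerate shape {self.voxels.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        """Same geometry, new data (shape must match)."""
        if voxels.shape != self.voxels.shape:
            raise ValueError(f"shape mismatch {voxels.shape} vs {self.voxels.shape}")
        return replace(self, voxels=voxels)


@dataclass(frozen=True)
class Window:
    """A half-open axis-aligned box ``[start, start + size)`` in voxel indices."""

    start: tuple[int, int, int]
    size: tuple[int, int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(s, s + d) for s, d in zip(self.start, self.size))  # type: ignore[return-value]

    @property
    def stop(self) -> tuple[int, int, int]:
        return tuple(s + d for s, d in zip(self.start, self.size))  # type: ignore[return-value]


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI image into the internal (z, y, x) convention."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    origin_xyz = img.affine[:3, 3]
    return Volume(
        voxels=np.ascontiguousarray(data.T),
        spacing=tuple(float(z) for z in zooms[::-1]),
        origin=tuple(float(o) for o in origin_xyz[::-1]),
    )


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1; integer arrays are stored as uint16."""
    data = v.voxels.T  # back to (x, y, z)
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    sx, sy, sz = v.spacing[::-1]
    ox, oy, oz = v.origin[::-1]
    affine = np.array(
        [[sx, 0, 0, ox], [0, sy, 0, oy], [0, 0, sz, oz], [0, 0, 0, 1.0]]
    )
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def resample_isotropic(v: Volume, target_mm: float = 0.4, *, labels: bool = False) -> Volume:
    """Resample to isotropic spacing ``target_mm``.

    Output shape per axis is ``round(shape * spacing / target_mm)``.  Images
    are interpolated trilinearly; with ``labels=True`` nearest-neighbor is
    used so label codes are never mixed.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    in_shape = v.shape
    out_shape = tuple(
        max(1, int(round(n * s / target_mm))) for n, s in zip(in_shape, v.spacing)
    )
    if out_shape == in_shape and all(abs(s - target_mm) < 1e-12 for s in v.spacing):
        return replace(v, spacing=(target_mm,) * 3)
    # Sample the input at the physical positions of the output voxel centers,
    # keeping voxel (0,0,0) anchored at the origin.
    grids = np.meshgrid(
        *[
            np.arange(n_out) * (target_mm / s)
            for n_out, s in zip(out_shape, v.spacing)
        ],
        indexing="ij",
    )
    order = 0 if labels else 1
    out = ndimage.map_coordinates(
        v.voxels.astype(v.voxels.dtype if labels else np.float32),
        np.stack([g.ravel() for g in grids]),
        order=order,
        mode="nearest",
    ).reshape(out_shape)
    return Volume(voxels=out, spacing=(target_mm,) * 3, origin=v.origin)


def clip_normalize(v: Volume, lo: float = 0.0, hi: float = 2500.0) -> Volume:
    """Clamp intensities to [lo, hi] and rescale linearly to [0, 1]."""
    if hi <= lo:
        raise ValueError(f"require hi > lo, got lo={lo}, hi={hi}")
    out = (np.clip(v.voxels.astype(np.float32), lo, hi) - lo) / (hi - lo)
    return v.with_voxels(out)


def sliding_windows(
    shape: Sequence[int],
    patch: Sequence[int],
    overlap_fraction: float = 0.0,
) -> list[Window]:
    """Deterministic z-major tiling of ``shape`` by ``patch``-sized windows.

    The stride per axis is ``ceil(patch * (1 - overlap_fraction))``; the last
    window per axis is shifted so it ends exactly at the boundary, so the
    union of windows always covers every voxel.  Patches larger than the
    volume are clamped to it.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    patch = tuple(min(int(p), int(n)) for p, n in zip(patch, shape))
    starts_per_axis = []
    for n, p in zip(shape, patch):
        stride = max(1, math.ceil(p * (1.0 - overlap_fraction)))
        starts = list(range(0, n - p + 1, stride))
        if starts[-1] != n - p:
            starts.append(n - p)
        starts_per_axis.append(starts)
    return [
        Window(start=(z, y, x), size=patch)  # type: ignore[arg-type]
        for z in starts_per_axis[0]
        for y in starts_per_axis[1]
        for x in starts_per_axis[2]
    ]
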