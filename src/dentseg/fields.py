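"""Shared dense-field containers used by the phantom generator and pipelines."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class OffsetField:
    """Per-voxel 3-vectors (voxel units, (dz, dy, dx) order) toward a target.

    ``vectors`` has shape ``(Z, Y, X, 3)``.  Vectors are meaningful only where
    ``valid`` is set (object foreground); background voxels carry zeros and
    must be ignored downstream.
    """

    vectors: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(f"vectors must be (Z, Y, X, 3), got {self.vectors.shape}")
        if self.valid.shape != self.vectors.shape[:3]:
            raise ValueError("valid mask shape mismatch")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("offset vectors must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.valid.shape  # type: ignore[return-value]
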