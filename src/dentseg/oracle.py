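"""Ground-truth oracle predictors.

Each oracle implements the same Predictor interface as a trained network but
reads its outputs straight from a phantom's GroundTruth, which makes every
non-neural stage of the pipeline (voting, clustering, cropping, assembly,
fusion) deterministically testable in isolation from training quality.

Oracles locate their patch through the ``context`` dict that
``predict_patchwise`` / the tooth branch pass along: ``window`` is the patch
window in the coordinates of the array being tiled and ``offset_origin`` the
origin of that array in full-volume coordinates.
"""

from __future__ import annotations

import numpy as np

from dentseg.io_core import Window
from dentseg.nets.model import class_from_fdi
from dentseg.phantom import (
    GroundTruth,
    derive_boundary_and_apex,
    make_offset_targets,
    occlusal_axis_for,
)


def _global_slices(patch_shape, context) -> tuple[slice, slice, slice]:
    ctx = context or {}
    w: Window | None = ctx.get("window")
    origin = np.asarray(ctx.get("offset_origin", (0, 0, 0)))
    if w is None:
        start = origin
    else:
        start = origin + np.asarray(w.start)
    return tuple(slice(int(s), int(s + d)) for s, d in zip(start, patch_shape))


class OracleRoiPredictor:
    """Binary tooth-foreground probability straight from the GT labels."""

    def __init__(self, gt: GroundTruth):
        self.fg = (gt.tooth_labels > 0).astype(np.float32)

    def predict(self, patch, context=None):
        sl = _global_slices(patch.shape[1:], context)
        return {"mask": self.fg[sl][None]}


class OracleOffsetPredictor:
    """GT offset field (centroid or skeleton mode) plus the foreground mask."""

    def __init__(self, gt: GroundTruth, mode: str):
        field = make_offset_targets(gt.tooth_labels, mode, gt)
        self.vectors = np.moveaxis(field.vectors, -1, 0).astype(np.float32)
        self.fg = field.valid.astype(np.float32)

    def predict(self, patch, context=None):
        sl = _global_slices(patch.shape[1:], context)
        return {
            "offset": self.vectors[(slice(None),) + sl],
            "mask": self.fg[sl][None],
        }


class OracleToothPredictor:
    """GT mask/boundary/apex/FDI of the tooth whose centroid is nearest the
    crop's query centroid."""

    def __init__(self, gt: GroundTruth, multitask: bool = True):
        self.gt = gt
        self.multitask = multitask
        self._codes = list(gt.centroids)
        self._cents = np.array([gt.centroids[f] for f in self._codes]) if self._codes else None

    def predict(self, patch, context=None):
        sl = _global_slices(patch.shape[1:], context)
        ctx = context or {}
        query = ctx.get("centroid")
        if query is None:  # fall back to the crop center
            query = np.array([(s.start + s.stop - 1) / 2.0 for s in sl])
        if self._cents is None:
            raise RuntimeError("oracle has no teeth to segment")
        fdi = self._codes[int(np.argmin(np.linalg.norm(self._cents - query, axis=1)))]
        mask = (self.gt.tooth_labels[sl] == fdi).astype(np.float32)
        out = {"mask": mask[None]}
        if self.multitask and mask.any():
            boundary, apex, _ = derive_boundary_and_apex(
                mask.astype(bool), occlusal_axis_for(fdi)
            )
            out["boundary"] = boundary[None]
            out["apex"] = apex[None]
        logits = np.full(32, -10.0, dtype=np.float32)
        logits[class_from_fdi(fdi)] = 10.0
        out["class_logits"] = logits
        return out


class OracleBonePredictor:
    """One-hot {background, midface, mandible} probabilities from GT."""

    def __init__(self, gt: GroundTruth):
        onehot = np.zeros((3,) + gt.bone_labels.shape, dtype=np.float32)
        for c in range(3):
            onehot[c] = gt.bone_labels == c
        self.onehot = onehot

    def predict(self, patch, context=None):
        sl = _global_slices(patch.shape[1:], context)
        return {"bones": self.onehot[(slice(None),) + sl]}


def oracle_predictors(gt: GroundTruth, multitask: bool = True) -> dict:
    """The full predictor set for oracle-mode pipeline runs."""
    return {
        "roi": OracleRoiPredictor(gt),
        "centroid": OracleOffsetPredictor(gt, "centroid"),
        "skeleton": OracleOffsetPredictor(gt, "skeleton"),
        "tooth": OracleToothPredictor(gt, multitask=multitask),
        "bone_coarse": OracleBonePredictor(gt),
        "bone_refine": OracleBonePredictor(gt),
    }
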