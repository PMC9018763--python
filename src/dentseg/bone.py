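"""Alveolar-bone branch: Haar boundary enhancement + cascaded 3-class segmentation.

The enhancement is a one-level 3D Haar wavelet decomposition whose seven
detail-subband magnitudes are summed, upsampled back to the image grid and
rescaled to [0, 1]; the response concentrates on intensity discontinuities,
i.e. bone boundaries.  The cascade feeds (original, enhanced) into a coarse
3-class network, then (original, enhanced, coarse probabilities) into a
refining network; the voxelwise argmax over {background, midface bone,
mandible bone} is the bone label map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from dentseg.io_core import Volume
from dentseg.nets.model import Predictor
from dentseg.nets.predict import predict_patchwise


@dataclass(frozen=True)
class EnhancedPair:
    """Original image and its Haar detail-magnitude map, on the same grid."""

    original: Volume
    enhanced: Volume

    def __post_init__(self):
        if self.original.shape != self.enhanced.shape:
            raise ValueError("original and enhanced shapes differ")
        if self.original.spacing != self.enhanced.spacing:
            raise ValueError("original and enhanced spacing differ")


def haar_enhance(v: Volume) -> Volume:
    """Boundary-enhancement map from a one-level 3D Haar transform.

    Odd dimensions are edge-padded to even, the seven detail subbands are
    summed in absolute value, nearest-upsampled to the original grid and
    rescaled to [0, 1] by the maximum (an all-constant input maps to zeros).
    """
    x = v.voxels.astype(np.float32)
    pad = [(0, s % 2) for s in x.shape]
    if any(p[1] for p in pad):
        x = np.pad(x, pad, mode="edge")
    coeffs = pywt.dwtn(x, "haar")
    detail = np.zeros_like(coeffs["ddd"])
    for key, sub in coeffs.items():
        if key != "aaa":
            detail += np.abs(sub)
    up = np.repeat(np.repeat(np.repeat(detail, 2, axis=0), 2, axis=1), 2, axis=2)
    up = up[: v.shape[0], : v.shape[1], : v.shape[2]]
    m = up.max()
    if m > 0:
        up = up / m
    return v.with_voxels(up.astype(np.float32))


def make_enhanced_pair(v: Volume) -> EnhancedPair:
    return EnhancedPair(original=v, enhanced=haar_enhance(v))


def segment_bones(
    pair: EnhancedPair,
    coarse_predictor: Predictor,
    refine_predictor: Predictor | None = None,
    patch: tuple[int, int, int] = (64, 64, 64),
    use_haar: bool = True,
    context: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cascaded 3-class bone segmentation.

    Returns ``(labels, probabilities)`` with labels in {0 background,
    1 midface, 2 mandible} and probabilities of shape (3, Z, Y, X).
    ``use_haar=False`` (the w/o-Haar ablation) replaces the enhanced channel
    with zeros; ``refine_predictor=None`` collapses the cascade to a single
    network.
    """
    enh = pair.enhanced.voxels if use_haar else np.zeros_like(pair.enhanced.voxels)
    extra = enh[None].astype(np.float32)
    out = predict_patchwise(coarse_predictor, pair.original, patch,
                            extra_channels=extra, context=context)
    probs = out["bones"]
    if refine_predictor is not None:
        extra2 = np.concatenate([extra, probs], axis=0)
        out2 = predict_patchwise(refine_predictor, pair.original, patch,
                                 extra_channels=extra2, context=context)
        probs = out2["bones"]
    labels = np.argmax(probs, axis=0).astype(np.uint8)
    return labels, probs
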