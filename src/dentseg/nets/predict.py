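"""Whole-volume inference by sliding-window tiling with voxelwise averaging."""

from __future__ import annotations

import numpy as np

from dentseg.io_core import Volume, sliding_windows
from dentseg.nets.model import Predictor


def predict_patchwise(
    predictor: Predictor,
    v: Volume | np.ndarray,
    patch: tuple[int, int, int],
    overlap_fraction: float = 0.25,
    extra_channels: np.ndarray | None = None,
    context: dict | None = None,
) -> dict[str, np.ndarray]:
    """Apply ``predictor`` over a tiling of the volume; overlapping window
    outputs are averaged voxelwise.  ``extra_channels`` (C-1, Z, Y, X) are
    stacked under the image to form multi-channel inputs.

    Patch sides are snapped down to the predictor's divisibility constraint
    when the volume is smaller than the requested patch.
    """
    vox = v.voxels if isinstance(v, Volume) else v
    div = 2 ** (getattr(predictor, "cfg", None).levels - 1) if hasattr(predictor, "cfg") else 1
    eff_patch = []
    for p, n in zip(patch, vox.shape):
        p = min(p, n)
        p -= p % div
        if p == 0:
            raise ValueError(f"volume shape {vox.shape} too small for level count")
        eff_patch.append(p)
    windows = sliding_windows(vox.shape, eff_patch, overlap_fraction)
    sums: dict[str, np.ndarray] = {}
    counts = np.zeros(vox.shape, dtype=np.float32)
    cls_accum = None
    for w in windows:
        sl = w.slices()
        inp = vox[sl][None].astype(np.float32)
        if extra_channels is not None:
            inp = np.concatenate([inp, extra_channels[(slice(None),) + sl]], axis=0)
        ctx = dict(context or {})
        ctx["window"] = w
        try:
            out = predictor.predict(inp, context=ctx)
        except Exception as e:
            raise RuntimeError(f"predictor failed on window {w}") from e
        for name, arr in out.items():
            if name == "class_logits":
                cls_accum = arr if cls_accum is None else cls_accum + arr
                continue
            if name not in sums:
                sums[name] = np.zeros((arr.shape[0],) + vox.shape, dtype=np.float32)
            sums[name][(slice(None),) + sl] += arr
        counts[sl] += 1.0
    out = {name: s / counts[None] for name, s in sums.items()}
    if cls_accum is not None:
        out["class_logits"] = cls_accum / len(windows)
    return out
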