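"""Loss functions for the multi-task heads, plus their logit-space gradients.

Conventions: binary cross-entropy for sigmoid mask heads, mean squared error
for linear regression heads (offset / boundary / apex maps; offset heads are
averaged over foreground voxels only), multi-class cross-entropy for softmax
heads and the FDI classifier.  The total is the weighted sum over heads.
"""

from __future__ import annotations

import numpy as np

from dentseg.nets.layers import sigmoid, softmax
from dentseg.nets.model import NetConfig

_EPS = 1e-7


def compute_losses(
    pred: dict[str, np.ndarray],
    target: dict[str, np.ndarray],
    cfg: NetConfig,
    mask: np.ndarray | None = None,
    weights: dict[str, float] | None = None,
    class_target: int | None = None,
) -> dict[str, float]:
    """Per-head losses on post-activation predictions, plus ``"total"``.

    ``mask`` (binary, spatial shape) restricts masked heads to foreground;
    an empty mask contributes zero, not NaN.
    """
    weights = weights or {}
    out: dict[str, float] = {}
    total = 0.0
    for hs in cfg.heads:
        p, t = pred[hs.name], target[hs.name]
        if p.shape != t.shape:
            raise ValueError(f"head {hs.name}: shape {p.shape} != target {t.shape}")
        if hs.activation == "sigmoid":
            pc = np.clip(p, _EPS, 1.0 - _EPS)
            loss = float(-np.mean(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)))
        elif hs.activation == "softmax":
            pc = np.clip(p, _EPS, 1.0)
            loss = float(-np.mean(np.sum(t * np.log(pc), axis=0)))
        else:  # linear -> L2
            if hs.masked:
                if mask is None or not mask.any():
                    loss = 0.0
                else:
                    diff = (p - t)[:, mask]
                    loss = float(np.mean(diff**2))
            else:
                loss = float(np.mean((p - t) ** 2))
        out[hs.name] = loss
        total += weights.get(hs.name, 1.0) * loss
    if class_target is not None and "class_logits" in pred:
        z = pred["class_logits"]
        logp = z - z.max()
        logp = logp - np.log(np.exp(logp).sum())
        loss = float(-logp[class_target])
        out["fdi"] = loss
        total += weights.get("fdi", 1.0) * loss
    out["total"] = total
    return out


def losses_and_logit_grads(
    head_raw: dict[str, np.ndarray],
    cls_logits: np.ndarray | None,
    target: dict[str, np.ndarray],
    cfg: NetConfig,
    mask: np.ndarray | None = None,
    weights: dict[str, float] | None = None,
    class_target: int | None = None,
):
    """Losses evaluated from raw logits together with d(total)/d(logits).

    Used by the training loop; numerically stable (logit-space BCE/CE).
    """
    weights = weights or {}
    losses: dict[str, float] = {}
    dhead: dict[str, np.ndarray] = {}
    total = 0.0
    for hs in cfg.heads:
        z, t = head_raw[hs.name], target[hs.name]
        w = weights.get(hs.name, 1.0)
        if hs.activation == "sigmoid":
            p = sigmoid(z)
            loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
            g = (p - t) / z.size
        elif hs.activation == "softmax":
            p = softmax(z, axis=0)
            n = z[0].size
            loss = float(-np.mean(np.sum(t * np.log(np.clip(p, _EPS, 1.0)), axis=0)))
            g = (p - t) / n
        else:
            if hs.masked:
                if mask is None or not mask.any():
                    loss, g = 0.0, np.zeros_like(z)
                else:
                    diff = np.where(mask[None], z - t, 0.0)
                    nfg = z.shape[0] * int(mask.sum())
                    loss = float(np.sum(diff**2) / nfg)
                    g = 2.0 * diff / nfg
            else:
                diff = z - t
                loss = float(np.mean(diff**2))
                g = 2.0 * diff / z.size
        losses[hs.name] = loss
        total += w * loss
        dhead[hs.name] = (w * g).astype(np.float32)
    dcls = None
    if class_target is not None and cls_logits is not None:
        w = weights.get("fdi", 1.0)
        p = softmax(cls_logits, axis=0)
        loss = float(-np.log(max(p[class_target], _EPS)))
        g = p.copy()
        g[class_target] -= 1.0
        losses["fdi"] = loss
        total += w * loss
        dcls = (w * g).astype(np.float32)
    losses["total"] = total
    return losses, dhead, dcls
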