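"""V-Net-style encoder-decoder with task heads and optional FDI classifier.

The backbone halves resolution and doubles channels per level on the way
down, with skip connections back up.  Dense task heads are 1x1x1
convolutions over the finest decoder features; the classifier branch (three
fully-connected layers over globally max-pooled bottleneck features) emits
one logit vector per input patch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np

from dentseg.nets import layers as L

FDI_CLASS_TABLE = tuple(q * 10 + p for q in (1, 2, 3, 4) for p in range(1, 9))


def fdi_from_class(index: int) -> int:
    """Fixed class->FDI bijection: quadrants 1-4 x positions 1-8, row-major."""
    return FDI_CLASS_TABLE[index]


def class_from_fdi(fdi: int) -> int:
    return FDI_CLASS_TABLE.index(fdi)


@dataclass(frozen=True)
class HeadSpec:
    """One dense output branch: ``activation`` in {sigmoid, softmax, linear};
    ``masked`` restricts the L2 loss to foreground voxels (offset heads)."""

    name: str
    channels: int
    activation: str
    masked: bool = False

    def __post_init__(self):
        if self.activation not in ("sigmoid", "softmax", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class NetConfig:
    in_channels: int
    levels: int
    base_channels: int
    patch: tuple[int, int, int]
    heads: tuple[HeadSpec, ...]
    n_classes: int | None = None  # 32 for the FDI classifier branch
    convs_per_block: int = 2  # 1 halves compute for the cheaper stages
    decoder: str = "concat"  # "concat" (U-Net style) or "add" (cheaper, additive skips)

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.convs_per_block not in (1, 2):
            raise ValueError("convs_per_block must be 1 or 2")
        if self.decoder not in ("concat", "add"):
            raise ValueError("decoder must be 'concat' or 'add'")
        div = 2 ** (self.levels - 1)
        if any(p % div for p in self.patch):
            raise ValueError(
                f"patch {self.patch} must be divisible by 2^(levels-1) = {div}"
            )
        names = [h.name for h in self.heads]
        if len(set(names)) != len(names):
            raise ValueError(f"head names must be unique, got {names}")


class Predictor(Protocol):
    """Maps a multi-channel input patch to named output maps.

    Dense outputs have the input's spatial shape; sigmoid/softmax outputs lie
    in [0, 1] and softmax outputs sum to 1 over channels.  ``context`` lets
    ground-truth oracle implementations locate the patch in the volume; real
    networks ignore it.
    """

    def predict(self, patch: np.ndarray, context: dict | None = None) -> dict[str, np.ndarray]:
        ...


class SegNet:
    """Parameter container + forward/backward for the backbone."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        c_prev = cfg.in_channels
        for lvl in range(cfg.levels):
            c = cfg.base_channels * 2**lvl
            self._add_conv(rng, f"enc{lvl}a", c_prev, c)
            if cfg.convs_per_block == 2:
                self._add_conv(rng, f"enc{lvl}b", c, c)
            c_prev = c
        for lvl in range(cfg.levels - 2, -1, -1):
            c_deep = cfg.base_channels * 2 ** (lvl + 1)
            c = cfg.base_channels * 2**lvl
            # "add": channel reduction at the coarse grid, additive skip fusion
            # "concat": upsample first, then reduce, then concatenate the skip
            self._add_conv(rng, f"up{lvl}", c_deep, c)
            self._add_conv(rng, f"dec{lvl}", 2 * c if cfg.decoder == "concat" else c, c)
        for h in cfg.heads:
            self._add_conv(rng, f"head_{h.name}", cfg.base_channels, h.channels, k=1)
        if cfg.n_classes:
            cb = cfg.base_channels * 2 ** (cfg.levels - 1)
            hid = max(32, 2 * cb)
            self._add_fc(rng, "fc1", cb, hid)
            self._add_fc(rng, "fc2", hid, hid)
            self._add_fc(rng, "fc3", hid, cfg.n_classes)

    def _add_conv(self, rng, name, cin, cout, k=3):
        fan_in = cin * k**3
        self.params[f"{name}.w"] = (
            rng.standard_normal((cout, cin, k, k, k)) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)

    def _add_fc(self, rng, name, nin, nout):
        self.params[f"{name}.w"] = (
            rng.standard_normal((nout, nin)) * np.sqrt(2.0 / nin)
        ).astype(np.float32)
        self.params[f"{name}.b"] = np.zeros(nout, dtype=np.float32)

    # -- forward ----------------------------------------------------------
    def _conv_relu(self, x, name, cache, keep):
        z, c1 = L.conv3d_forward(x, self.params[f"{name}.w"], self.params[f"{name}.b"], keep)
        a, c2 = L.relu_forward(z)
        if keep:
            cache[name] = (c1, c2)
        return a

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Raw (pre-activation) head maps and classifier logits.

        Returns (head_raw: dict, cls_logits or None, cache).
        """
        cfg = self.cfg
        cache: dict = {}
        skips = []
        h = x.astype(np.float32, copy=False)
        for lvl in range(cfg.levels):
            h = self._conv_relu(h, f"enc{lvl}a", cache, keep_cache)
            if cfg.convs_per_block == 2:
                h = self._conv_relu(h, f"enc{lvl}b", cache, keep_cache)
            if lvl < cfg.levels - 1:
                skips.append(h)
                h, pshape = L.avgpool2_forward(h)
                if keep_cache:
                    cache[f"pool{lvl}"] = pshape
        bottleneck = h
        for lvl in range(cfg.levels - 2, -1, -1):
            if cfg.decoder == "add":
                h = self._conv_relu(h, f"up{lvl}", cache, keep_cache)
                h, ushape = L.upsample2_forward(h)
                if keep_cache:
                    cache[f"upsample{lvl}"] = ushape
                h = h + skips[lvl]
            else:
                h, ushape = L.upsample2_forward(h)
                if keep_cache:
                    cache[f"upsample{lvl}"] = ushape
                h = self._conv_relu(h, f"up{lvl}", cache, keep_cache)
                h = np.concatenate([h, skips[lvl]], axis=0)
            h = self._conv_relu(h, f"dec{lvl}", cache, keep_cache)
        head_raw = {}
        for hs in cfg.heads:
            z, c1 = L.conv3d_forward(
                h, self.params[f"head_{hs.name}.w"], self.params[f"head_{hs.name}.b"], keep_cache
            )
            head_raw[hs.name] = z
            if keep_cache:
                cache[f"head_{hs.name}"] = c1
        cls_logits = None
        if cfg.n_classes:
            pooled, pc = L.globalmaxpool_forward(bottleneck)
            a1, x1 = L.linear_forward(pooled, self.params["fc1.w"], self.params["fc1.b"])
            r1, m1 = L.relu_forward(a1)
            a2, x2 = L.linear_forward(r1, self.params["fc2.w"], self.params["fc2.b"])
            r2, m2 = L.relu_forward(a2)
            cls_logits, x3 = L.linear_forward(r2, self.params["fc3.w"], self.params["fc3.b"])
            if keep_cache:
                cache["cls"] = (pc, x1, m1, x2, m2, x3)
        if keep_cache:
            cache["final"] = h
        return head_raw, cls_logits, cache

    # -- backward ---------------------------------------------------------
    def backward(self, dhead_raw, dcls, cache, grads):
        """Accumulate parameter gradients into ``grads``; inputs are
        gradients w.r.t. raw head maps / classifier logits."""
        cfg = self.cfg

        def conv_relu_back(g, name):
            c1, relu_mask = cache[name]
            g = L.relu_backward(g, relu_mask)
            dx, dw, db = L.conv3d_backward(g, c1)
            grads[f"{name}.w"] += dw
            grads[f"{name}.b"] += db
            return dx

        h = cache["final"]
        dh = np.zeros_like(h)
        for hs in cfg.heads:
            g = dhead_raw.get(hs.name)
            if g is None:
                continue
            dx, dw, db = L.conv3d_backward(g, cache[f"head_{hs.name}"])
            grads[f"head_{hs.name}.w"] += dw
            grads[f"head_{hs.name}.b"] += db
            dh += dx
        dbottleneck_extra = None
        if cfg.n_classes and dcls is not None:
            pc, x1, m1, x2, m2, x3 = cache["cls"]
            g, dw, db = L.linear_backward(dcls, x3, self.params["fc3.w"])
            grads["fc3.w"] += dw
            grads["fc3.b"] += db
            g = L.relu_backward(g, m2)
            g, dw, db = L.linear_backward(g, x2, self.params["fc2.w"])
            grads["fc2.w"] += dw
            grads["fc2.b"] += db
            g = L.relu_backward(g, m1)
            g, dw, db = L.linear_backward(g, x1, self.params["fc1.w"])
            grads["fc1.w"] += dw
            grads["fc1.b"] += db
            dbottleneck_extra = L.globalmaxpool_backward(g, pc)

        dskips = [None] * (cfg.levels - 1)
        g = dh
        for lvl in range(0, cfg.levels - 1):
            g = conv_relu_back(g, f"dec{lvl}")
            if cfg.decoder == "add":
                dskips[lvl] = g  # additive fusion passes the gradient through
                g = L.upsample2_backward(g, cache[f"upsample{lvl}"])
                g = conv_relu_back(g, f"up{lvl}")
            else:
                cup = self.params[f"up{lvl}.w"].shape[0]
                g_up, dskips[lvl] = g[:cup], g[cup:]
                g = conv_relu_back(g_up, f"up{lvl}")
                g = L.upsample2_backward(g, cache[f"upsample{lvl}"])
        if dbottleneck_extra is not None:
            g = g + dbottleneck_extra
        for lvl in range(cfg.levels - 1, -1, -1):
            if lvl < cfg.levels - 1:
                g = L.avgpool2_backward(g, cache[f"pool{lvl}"])
                g = g + dskips[lvl]
            if cfg.convs_per_block == 2:
                g = conv_relu_back(g, f"enc{lvl}b")
            g = conv_relu_back(g, f"enc{lvl}a")
        return g


def apply_activations(cfg: NetConfig, head_raw: dict, cls_logits) -> dict[str, np.ndarray]:
    out = {}
    for hs in cfg.heads:
        z = head_raw[hs.name]
        if hs.activation == "sigmoid":
            out[hs.name] = L.sigmoid(z)
        elif hs.activation == "softmax":
            out[hs.name] = L.softmax(z, axis=0)
        else:
            out[hs.name] = z
    if cls_logits is not None:
        out["class_logits"] = cls_logits
    return out


class NetPredictor:
    """Predictor backed by a (trained) SegNet."""

    def __init__(self, net: SegNet):
        self.net = net

    @property
    def cfg(self) -> NetConfig:
        return self.net.cfg

    def predict(self, patch: np.ndarray, context: dict | None = None) -> dict[str, np.ndarray]:
        if patch.ndim != 4 or patch.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected ({self.cfg.in_channels}, D, H, W) input, got {patch.shape}"
            )
        div = 2 ** (self.cfg.levels - 1)
        if any(s % div for s in patch.shape[1:]):
            raise ValueError(f"spatial shape {patch.shape[1:]} not divisible by {div}")
        head_raw, cls_logits, _ = self.net.forward(patch, keep_cache=False)
        return apply_activations(self.cfg, head_raw, cls_logits)


def build_segnet(cfg: NetConfig, seed: int = 0) -> NetPredictor:
    """Seeded construction of the encoder-decoder predictor."""
    return NetPredictor(SegNet(cfg, seed=seed))


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(predictor: NetPredictor, path: str | Path) -> None:
    cfg = predictor.cfg
    meta = {
        "in_channels": cfg.in_channels,
        "levels": cfg.levels,
        "base_channels": cfg.base_channels,
        "patch": list(cfg.patch),
        "heads": [
            {"name": h.name, "channels": h.channels, "activation": h.activation,
             "masked": h.masked}
            for h in cfg.heads
        ],
        "n_classes": cfg.n_classes,
        "convs_per_block": cfg.convs_per_block,
        "decoder": cfg.decoder,
    }
    np.savez(path, __config__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **predictor.net.params)


def load_checkpoint(path: str | Path) -> NetPredictor:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        cfg = NetConfig(
            in_channels=meta["in_channels"],
            levels=meta["levels"],
            base_channels=meta["base_channels"],
            patch=tuple(meta["patch"]),
            heads=tuple(HeadSpec(**h) for h in meta["heads"]),
            n_classes=meta["n_classes"],
            convs_per_block=meta.get("convs_per_block", 2),
            decoder=meta.get("decoder", "concat"),
        )
        net = SegNet(cfg, seed=0)
        for k in net.params:
            net.params[k] = data[k]
    return NetPredictor(net)
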