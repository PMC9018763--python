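"""Desk-scale training orchestration for the five pipeline networks.

Builds patch datasets from synthetic phantoms and trains, in order: the ROI
foreground net, the centroid- and skeleton-offset nets, the multi-task
single-tooth net (with FDI classifier), and the two-stage bone cascade
(the refiner consumes the trained coarse net's probabilities).

Supervision mirrors the pipeline's needs: offsets are L2-regressed on
foreground voxels only, masks use binary cross-entropy, bone labels use
3-class cross-entropy, and the tooth net additionally regresses boundary
and apex heatmaps unless the multi-task ablation is on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from dentseg.bone import haar_enhance
from dentseg.io_core import Volume, clip_normalize
from dentseg.nets.model import (
    HeadSpec,
    NetConfig,
    NetPredictor,
    build_segnet,
    class_from_fdi,
)
from dentseg.nets.predict import predict_patchwise
from dentseg.nets.train import TrainConfig, train_model
from dentseg.phantom import (
    GroundTruth,
    PhantomSpec,
    derive_boundary_and_apex,
    generate_phantom,
    make_offset_targets,
    occlusal_axis_for,
)
from dentseg.tooth import ToothInstance, build_tooth_input


@dataclass
class DeskTrainSettings:
    """Sizes and schedules for desk-scale (CPU) training."""

    net_patch: tuple[int, int, int] = (32, 32, 32)
    tooth_patch: tuple[int, int, int] = (24, 24, 24)
    crops_per_phantom: dict = field(default_factory=lambda: {
        "roi": 2, "centroid": 3, "skeleton": 3,
        "bone_coarse": 2, "bone_refine": 2,
    })
    teeth_per_phantom: int = 4
    base_channels: dict = field(default_factory=lambda: {
        "roi": 4, "centroid": 8, "skeleton": 8, "tooth": 6,
        "bone_coarse": 6, "bone_refine": 6,
    })
    max_epochs: dict = field(default_factory=lambda: {
        "roi": 5, "centroid": 8, "skeleton": 6, "tooth": 10,
        "bone_coarse": 7, "bone_refine": 6,
    })
    learning_rate: float = 1e-3
    patience_epochs: int = 5
    patience_tolerance: float = 1e-4


@dataclass
class PhantomData:
    """One preprocessed phantom with all dense supervision precomputed."""

    image: np.ndarray  # [0, 1]
    gt: GroundTruth
    fg: np.ndarray
    cent_off: np.ndarray  # (3, Z, Y, X)
    skel_off: np.ndarray
    haar: np.ndarray
    bones_onehot: np.ndarray  # (3, Z, Y, X)


def prepare_phantom(vol: Volume, gt: GroundTruth) -> PhantomData:
    v = clip_normalize(vol)
    fg = gt.tooth_labels > 0
    cent = make_offset_targets(gt.tooth_labels, "centroid", gt)
    skel = make_offset_targets(gt.tooth_labels, "skeleton", gt)
    onehot = np.zeros((3,) + gt.bone_labels.shape, dtype=np.float32)
    for c in range(3):
        onehot[c] = gt.bone_labels == c
    return PhantomData(
        image=v.voxels.astype(np.float32),
        gt=gt,
        fg=fg,
        cent_off=np.moveaxis(cent.vectors, -1, 0).astype(np.float32),
        skel_off=np.moveaxis(skel.vectors, -1, 0).astype(np.float32),
        haar=haar_enhance(v).voxels,
        bones_onehot=onehot,
    )


def _crop_origin(center, patch, shape, rng):
    jitter = rng.integers(-4, 5, size=3)
    lo = np.asarray(center) - np.asarray(patch) // 2 + jitter
    lo = np.clip(lo, 0, np.asarray(shape) - np.asarray(patch))
    return tuple(int(a) for a in lo)


def _crop_centers(data: PhantomData, kind: str, n: int, rng) -> list:
    src = data.fg if kind in ("roi", "centroid", "skeleton") else (
        data.fg | (data.gt.bone_labels > 0)
    )
    coords = np.argwhere(src)
    if len(coords) == 0:
        coords = np.array([[s // 2 for s in data.image.shape]])
    idx = rng.integers(0, len(coords), size=n)
    return [coords[i] for i in idx]


def dense_samples(data: PhantomData, kind: str, patch, n_crops: int, rng) -> list[dict]:
    samples = []
    for center in _crop_centers(data, kind, n_crops, rng):
        o = _crop_origin(center, patch, data.image.shape, rng)
        sl = tuple(slice(a, a + p) for a, p in zip(o, patch))
        img = data.image[sl][None]
        fg = data.fg[sl]
        if kind == "roi":
            s = {"input": img, "targets": {"mask": fg[None].astype(np.float32)}}
        elif kind in ("centroid", "skeleton"):
            off = data.cent_off if kind == "centroid" else data.skel_off
            s = {
                "input": img,
                "targets": {
                    "offset": off[(slice(None),) + sl],
                    "mask": fg[None].astype(np.float32),
                },
                "fg_mask": fg,
            }
        elif kind in ("bone_coarse", "bone_refine"):
            s = {
                "input": np.concatenate([img, data.haar[sl][None]]),
                "targets": {"bones": data.bones_onehot[(slice(None),) + sl]},
            }
        else:
            raise ValueError(kind)
        samples.append(s)
    return samples


def tooth_samples(
    data: PhantomData,
    vol_patch,
    n_teeth: int,
    rng,
    no_skeleton: bool = False,
    no_multitask: bool = False,
    sigma_centroid: float = 2.0,
) -> list[dict]:
    """Per-tooth three-channel crops supervised with GT morphology."""
    v = Volume(voxels=data.image)
    codes = data.gt.fdi_codes
    if not codes:
        return []
    chosen = rng.choice(codes, size=min(n_teeth, len(codes)), replace=False)
    samples = []
    for fdi in chosen:
        fdi = int(fdi)
        skel_map = None
        if not no_skeleton:
            # degrade the GT skeleton (voxel dropout + unit jitter) so the
            # network tolerates the vote-built skeletons seen at inference
            skel = data.gt.skeletons[fdi]
            keep = rng.random(len(skel)) > 0.2
            pts = skel[keep] if keep.any() else skel
            jitter = rng.integers(-1, 2, size=pts.shape) * (
                rng.random((len(pts), 1)) < 0.3
            )
            pts = np.clip(pts + jitter, 0, np.asarray(data.image.shape) - 1).astype(int)
            skel_map = np.zeros(data.image.shape, dtype=np.float32)
            skel_map[tuple(pts.T)] = 1.0
        inst = ToothInstance(
            instance_id=0,
            fdi=fdi,
            centroid=data.gt.centroids[fdi],
            skeleton_voxels=data.gt.skeletons[fdi],
        )
        inp, origin = build_tooth_input(v, inst, skel_map, vol_patch, sigma_centroid)
        sl = tuple(slice(a, a + p) for a, p in zip(origin, vol_patch))
        mask = (data.gt.tooth_labels[sl] == fdi)
        targets = {"mask": mask[None].astype(np.float32)}
        if not no_multitask and mask.any():
            boundary, apex, _ = derive_boundary_and_apex(mask, occlusal_axis_for(fdi))
            targets["boundary"] = boundary[None]
            targets["apex"] = apex[None]
        samples.append(
            {"input": inp, "targets": targets, "class_index": class_from_fdi(fdi)}
        )
    return samples


def net_config(kind: str, settings: DeskTrainSettings, no_multitask: bool = False) -> NetConfig:
    base = settings.base_channels[kind]
    if kind == "roi":
        # additive decoder: a bounding-box stage needs little capacity
        return NetConfig(1, 2, base, settings.net_patch, (HeadSpec("mask", 1, "sigmoid"),),
                         decoder="add")
    if kind in ("centroid", "skeleton"):
        # offsets are smooth, large-scale fields: wide but shallow blocks and
        # the cheaper additive decoder retain enough capacity for them, and
        # the vote-cluster size filter absorbs residual mask noise
        return NetConfig(
            1, 2, base, settings.net_patch,
            (HeadSpec("offset", 3, "linear", masked=True), HeadSpec("mask", 1, "sigmoid")),
            convs_per_block=1,
            decoder="add",
        )
    if kind == "tooth":
        heads = [HeadSpec("mask", 1, "sigmoid")]
        if not no_multitask:
            heads += [HeadSpec("boundary", 1, "linear"), HeadSpec("apex", 1, "linear")]
        return NetConfig(3, 2, base, settings.tooth_patch, tuple(heads), n_classes=32)
    if kind == "bone_coarse":
        return NetConfig(2, 2, base, settings.net_patch, (HeadSpec("bones", 3, "softmax"),))
    if kind == "bone_refine":
        return NetConfig(5, 2, base, settings.net_patch, (HeadSpec("bones", 3, "softmax"),))
    raise ValueError(kind)


def _degenerate_fit(predictor, val_samples) -> bool:
    """True when a dense head collapsed to background everywhere.

    Rarely, a run lands in a dead-decoder optimum: the mask (or bone) head
    emits a spatially constant sub-threshold map.  Detected on validation
    samples with nonempty targets; such fits are retrained from a shifted
    init seed.
    """
    checked = empty = 0
    for s in val_samples[:8]:
        out = predictor.predict(s["input"])
        if "mask" in out and s["targets"].get("mask") is not None:
            if s["targets"]["mask"].sum() == 0:
                continue
            checked += 1
            empty += int((out["mask"][0] >= 0.5).sum() == 0)
        elif "bones" in out and s["targets"].get("bones") is not None:
            if s["targets"]["bones"][1:].sum() == 0:
                continue
            checked += 1
            empty += int((np.argmax(out["bones"], axis=0) > 0).sum() == 0)
    return checked > 0 and empty == checked


def _train_one(kind, train_samples, val_samples, settings, seed, no_multitask=False):
    cfg = net_config(kind, settings, no_multitask)
    tc = TrainConfig(
        learning_rate=settings.learning_rate,
        patience_epochs=settings.patience_epochs,
        patience_tolerance=settings.patience_tolerance,
        max_epochs=settings.max_epochs[kind],
        loss_weights={"fdi": 0.3},
        seed=seed,
    )
    for attempt in range(3):
        predictor = build_segnet(cfg, seed=seed + 1000003 * attempt)
        predictor, history = train_model(predictor, train_samples, val_samples, tc)
        if not _degenerate_fit(predictor, val_samples):
            break
    return predictor, history


def prepare_phantoms(phantoms: list[tuple[Volume, GroundTruth]]) -> list[PhantomData]:
    return [prepare_phantom(v, g) for v, g in phantoms]


def train_desk_models(
    train_phantoms: list[tuple[Volume, GroundTruth]] | list[PhantomData],
    val_phantoms: list[tuple[Volume, GroundTruth]] | list[PhantomData],
    seed: int = 0,
    settings: DeskTrainSettings | None = None,
    no_skeleton: bool = False,
    no_multitask: bool = False,
    kinds: tuple[str, ...] = ("roi", "centroid", "skeleton", "tooth", "bone_coarse", "bone_refine"),
) -> tuple[dict, dict]:
    """Train the desk-scale predictor set; returns (predictors, histories).

    Inputs may be (Volume, GroundTruth) pairs or already-prepared
    PhantomData (so several training seeds can share one preparation).
    """
    settings = settings or DeskTrainSettings()
    rng = np.random.default_rng(seed)

    def _prep(items):
        return [x if isinstance(x, PhantomData) else prepare_phantom(*x) for x in items]

    train_data = _prep(train_phantoms)
    val_data = _prep(val_phantoms)
    predictors: dict[str, NetPredictor] = {}
    histories: dict[str, list] = {}

    def build_sets(kind):
        if kind == "tooth":
            tr = [
                s
                for d in train_data
                for s in tooth_samples(
                    d, settings.tooth_patch, settings.teeth_per_phantom, rng,
                    no_skeleton=no_skeleton, no_multitask=no_multitask,
                )
            ]
            va = [
                s
                for d in val_data
                for s in tooth_samples(
                    d, settings.tooth_patch, 2, rng,
                    no_skeleton=no_skeleton, no_multitask=no_multitask,
                )
            ]
        else:
            tr = [
                s
                for d in train_data
                for s in dense_samples(
                    d, kind, settings.net_patch, settings.crops_per_phantom[kind], rng
                )
            ]
            va = [
                s
                for d in val_data
                for s in dense_samples(d, kind, settings.net_patch, 1, rng)
            ]
        return tr, va

    for kind in kinds:
        if kind == "bone_refine":
            # refiner consumes the trained coarse net's probability maps
            if "bone_coarse" not in predictors:
                continue
            for d in train_data + val_data:
                probs = predict_patchwise(
                    predictors["bone_coarse"],
                    d.image,
                    settings.net_patch,
                    extra_channels=d.haar[None],
                )["bones"]
                d.coarse_probs = probs  # type: ignore[attr-defined]
            def refine_set(data_list, n):
                out = []
                for d in data_list:
                    for center in _crop_centers(d, "bone_refine", n, rng):
                        o = _crop_origin(center, settings.net_patch, d.image.shape, rng)
                        sl = tuple(slice(a, a + p) for a, p in zip(o, settings.net_patch))
                        inp = np.concatenate(
                            [d.image[sl][None], d.haar[sl][None],
                             d.coarse_probs[(slice(None),) + sl]]
                        )
                        out.append(
                            {"input": inp,
                             "targets": {"bones": d.bones_onehot[(slice(None),) + sl]}}
                        )
                return out

            tr = refine_set(train_data, settings.crops_per_phantom["bone_refine"])
            va = refine_set(val_data, 1)
        else:
            tr, va = build_sets(kind)
        predictors[kind], histories[kind] = _train_one(
            kind, tr, va, settings,
            seed=int(rng.integers(0, 2**31 - 1)),
            no_multitask=no_multitask,
        )
    return predictors, histories


def desk_phantom_specs(
    n: int,
    seed: int,
    grid: int = 48,
    teeth_per_arch: int = 6,
    missing_prob: float = 0.1,
    metal_count: int = 0,
) -> list[PhantomSpec]:
    """The desk-scale study conditions: 48^3 phantoms at 0.4 mm, 6 teeth per
    arch, 10% missing-tooth rate, mild misalignment jitter."""
    rng = np.random.default_rng(seed)
    return [
        PhantomSpec(
            grid_shape=(grid,) * 3,
            teeth_per_arch=teeth_per_arch,
            missing_prob=missing_prob,
            metal_count=metal_count,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for _ in range(n)
    ]
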