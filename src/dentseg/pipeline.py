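"""End-to-end orchestration: preprocess -> tooth branch -> bone branch -> fuse.

The two branches are independent (neither reads the other's output before
fusion) and everything downstream of the predictors is deterministic, so an
oracle-mode run on a phantom reproduces its ground truth exactly and a
model-mode run is reproducible bit-for-bit given the same checkpoints.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dentseg import io_core
from dentseg.bone import make_enhanced_pair, segment_bones
from dentseg.config import PipelineConfig
from dentseg.evaluate import fuse
from dentseg.fields import OffsetField
from dentseg.io_core import Volume, Window
from dentseg.nets.model import load_checkpoint
from dentseg.nets.predict import predict_patchwise
from dentseg.tooth import (
    ToothInstance,
    assemble_instances,
    assign_fdi_by_arch,
    build_tooth_input,
    cast_votes,
    cluster_votes,
    localize_roi,
    segment_single_tooth,
)


@dataclass
class ToothBranchResult:
    labels: np.ndarray
    probs: np.ndarray
    instance_ids: np.ndarray
    instances: list[ToothInstance]
    roi_window: Window
    conflicts: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class PipelineResult:
    image: Volume
    tooth: ToothBranchResult
    bone_labels: np.ndarray
    bone_probs: np.ndarray
    fused_tooth: np.ndarray
    fused_bone: np.ndarray
    timings: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)


def preprocess(v: Volume, cfg: PipelineConfig) -> Volume:
    """Resample to the isotropic working resolution and clip-normalize."""
    if any(abs(s - cfg.target_mm) > 1e-9 for s in v.spacing):
        v = io_core.resample_isotropic(v, cfg.target_mm)
    return io_core.clip_normalize(v, cfg.clip_lo, cfg.clip_hi)


def run_tooth_branch(v: Volume, predictors: dict, cfg: PipelineConfig) -> ToothBranchResult:
    """The hierarchical morphology-guided tooth branch on a preprocessed volume."""
    window, _ = localize_roi(
        v,
        predictors["roi"],
        patch=cfg.net_patch,
        threshold=cfg.roi_threshold,
        min_component_voxels=cfg.roi_min_component,
        margin=cfg.roi_margin,
    )
    sub = Volume(np.ascontiguousarray(v.voxels[window.slices()]), v.spacing, v.origin)
    ctx = {"offset_origin": window.start}

    cent = predict_patchwise(
        predictors["centroid"], sub, cfg.net_patch, cfg.overlap_fraction, context=ctx
    )
    fg = cent["mask"][0] >= cfg.mask_threshold
    off = OffsetField(
        vectors=np.moveaxis(cent["offset"], 0, -1).astype(np.float32), valid=fg
    )
    votes = cast_votes(off, fg)
    assignment, centroids = cluster_votes(
        votes,
        cfg.cluster_dc,
        cfg.cluster_min_density,
        cfg.cluster_min_sep,
        cfg.cluster_min_votes,
    )
    assign_vol = np.full(sub.shape, -1, dtype=np.int64)
    assign_vol[tuple(votes.sources.T)] = assignment

    # skeleton votes, routed to instances through the centroid clustering
    n_inst = len(centroids)
    skeletons: list[list[np.ndarray]] = [[] for _ in range(n_inst)]
    if not cfg.no_skeleton:
        skel = predict_patchwise(
            predictors["skeleton"], sub, cfg.net_patch, cfg.overlap_fraction, context=ctx
        )
        skel_fg = (skel["mask"][0] >= cfg.mask_threshold) & (assign_vol >= 0)
        skel_off = OffsetField(
            vectors=np.moveaxis(skel["offset"], 0, -1).astype(np.float32), valid=skel_fg
        )
        skel_votes = cast_votes(skel_off, skel_fg)
        targets = np.clip(
            np.round(skel_votes.points).astype(int), 0, np.asarray(sub.shape) - 1
        )
        owners = assign_vol[tuple(skel_votes.sources.T)]
        for t, o in zip(targets, owners):
            skeletons[o].append(t)

    start = np.asarray(window.start)
    instances = []
    for k, c in enumerate(centroids):
        skel_vox = (
            np.unique(np.asarray(skeletons[k]), axis=0) + start
            if skeletons[k]
            else np.zeros((0, 3), dtype=int)
        )
        instances.append(
            ToothInstance(
                instance_id=k + 1,
                fdi=None,
                centroid=np.asarray(c) + start,
                skeleton_voxels=skel_vox,
            )
        )

    heuristic_fdi = assign_fdi_by_arch([i.centroid for i in instances], v.shape)
    for inst, h_fdi in zip(instances, heuristic_fdi):
        skel_map = None
        if not cfg.no_skeleton and len(inst.skeleton_voxels):
            # thin the vote support so the channel resembles the clean
            # skeletons the single-tooth network is supervised with
            from dentseg.phantom import derive_skeleton

            support = np.zeros(v.shape, dtype=bool)
            support[tuple(inst.skeleton_voxels.T)] = True
            skel_map = np.zeros(v.shape, dtype=np.float32)
            skel_map[tuple(derive_skeleton(support).T)] = 1.0
        inp, origin = build_tooth_input(
            v, inst, skel_map, cfg.tooth_patch, cfg.sigma_centroid
        )
        mask, prob, boundary, apex, fdi_cls = segment_single_tooth(
            inp,
            predictors["tooth"],
            context={"window": Window(origin, cfg.tooth_patch), "centroid": inst.centroid},
            threshold=cfg.mask_threshold,
        )
        inst.crop_origin = origin
        inst.mask_crop = mask
        inst.prob_crop = prob
        inst.boundary_crop = boundary
        inst.apex_crop = apex
        inst.fdi = (
            fdi_cls if (cfg.fdi_source == "classifier" and fdi_cls is not None) else h_fdi
        )
    labels, probs, inst_ids, conflicts = assemble_instances(instances, v.shape)
    return ToothBranchResult(
        labels=labels,
        probs=probs,
        instance_ids=inst_ids,
        instances=instances,
        roi_window=window,
        conflicts=conflicts,
    )


def run_bone_branch(v: Volume, predictors: dict, cfg: PipelineConfig):
    pair = make_enhanced_pair(v)
    return segment_bones(
        pair,
        predictors["bone_coarse"],
        predictors.get("bone_refine"),
        patch=cfg.net_patch,
        use_haar=not cfg.no_haar,
    )


def load_predictors(cfg: PipelineConfig) -> dict:
    """Load the checkpoint set named in the config; fail fast on gaps."""
    required = ["roi", "centroid", "skeleton", "tooth", "bone_coarse"]
    missing = [k for k in required if k not in cfg.model_paths]
    if missing:
        raise ValueError(f"missing model paths for stages: {missing}")
    preds = {}
    for name, path in cfg.model_paths.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"model checkpoint for {name!r} not found: {path}")
        preds[name] = load_checkpoint(path)
    return preds


def run_pipeline(
    image: Volume | str | Path,
    cfg: PipelineConfig,
    predictors: dict | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Full two-branch segmentation of one scan.

    ``predictors`` may be trained-network predictors or ground-truth oracles;
    if omitted they are loaded from ``cfg.model_paths``.  When ``out_dir`` is
    given, label volumes, per-tooth metadata and a run log are written there.
    """
    if predictors is None:
        predictors = load_predictors(cfg)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    v = io_core.read_volume(image) if not isinstance(image, Volume) else image
    v = preprocess(v, cfg)
    timings["preprocess_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tooth = run_tooth_branch(v, predictors, cfg)
    timings["tooth_branch_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    bone_labels, bone_probs = run_bone_branch(v, predictors, cfg)
    timings["bone_branch_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fused_tooth, fused_bone = fuse(tooth.labels, tooth.probs, bone_labels, bone_probs)
    timings["fuse_s"] = time.perf_counter() - t0

    result = PipelineResult(
        image=v,
        tooth=tooth,
        bone_labels=bone_labels,
        bone_probs=bone_probs,
        fused_tooth=fused_tooth,
        fused_bone=fused_bone,
        timings=timings,
        config=cfg.to_dict(),
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    v = result.image
    io_core.write_volume(v.with_voxels(result.fused_tooth.astype(np.uint16)), out / "tooth_labels.nii.gz")
    io_core.write_volume(v.with_voxels(result.fused_bone.astype(np.uint16)), out / "bone_labels.nii.gz")
    voxel_mm3 = float(np.prod(v.spacing))
    teeth = []
    for inst in result.tooth.instances:
        n_vox = int(result.fused_tooth[result.fused_tooth == (inst.fdi or 0)].size) if inst.fdi else 0
        teeth.append(
            {
                "instance_id": inst.instance_id,
                "fdi": inst.fdi,
                "centroid_mm": [float(c * s) for c, s in zip(inst.centroid, v.spacing)],
                "volume_mm3": n_vox * voxel_mm3,
                "crop_origin": [int(o) for o in inst.crop_origin],
            }
        )
    log = {
        "config": result.config,
        "timings_s": result.timings,
        "n_instances": len(result.tooth.instances),
        "fdi_conflicts": result.tooth.conflicts,
    }
    (out / "teeth.json").write_text(json.dumps(teeth, indent=2))
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
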