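"""Hierarchical morphology-guided tooth branch.

Stages: dental ROI localization -> centroid/skeleton offset prediction ->
vote casting -> density-peaks clustering into tooth instances -> per-tooth
three-channel crop (centroid map, skeleton map, image) -> multi-task
single-tooth segmentation with FDI classification -> paste-back assembly of
the instance label volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from dentseg.fields import OffsetField
from dentseg.io_core import Volume, Window
from dentseg.nets.model import Predictor, fdi_from_class
from dentseg.nets.predict import predict_patchwise


class NoDentalRoiError(RuntimeError):
    """The foreground network found no dental region."""


class NoTeethDetectedError(RuntimeError):
    """No vote-density peak satisfied the cluster-center criteria."""


@dataclass(frozen=True)
class VoteCloud:
    """Positions voted for by foreground voxels (source + predicted offset)."""

    points: np.ndarray  # (N, 3) float voxel coords
    sources: np.ndarray  # (N, 3) int voxel indices

    def __post_init__(self):
        if len(self.points) != len(self.sources):
            raise ValueError("points and sources must have equal length")


@dataclass
class ToothInstance:
    instance_id: int
    fdi: int | None
    centroid: np.ndarray  # (z, y, x) float, volume coords
    skeleton_voxels: np.ndarray  # (K, 3) int, volume coords
    crop_origin: tuple[int, int, int] = (0, 0, 0)
    mask_crop: np.ndarray | None = None
    prob_crop: np.ndarray | None = None
    boundary_crop: np.ndarray | None = None
    apex_crop: np.ndarray | None = None


# ---------------------------------------------------------------------------
# ROI localization


def localize_roi(
    v: Volume,
    predictor: Predictor,
    patch: tuple[int, int, int] = (64, 64, 64),
    threshold: float = 0.5,
    min_component_voxels: int = 20,
    margin: int = 4,
    context: dict | None = None,
) -> tuple[Window, Volume]:
    """Bounding window of the thresholded, size-filtered tooth foreground,
    dilated by ``margin`` voxels and clamped to the volume."""
    out = predict_patchwise(predictor, v, patch, context=context)
    prob = out["mask"][0]
    mask = prob >= threshold
    lab, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_component_voxels) + 1
        mask = np.isin(lab, keep)
    if not mask.any():
        raise NoDentalRoiError("no dental ROI: empty foreground after filtering")
    coords = np.argwhere(mask)
    lo = np.maximum(coords.min(axis=0) - margin, 0)
    hi = np.minimum(coords.max(axis=0) + 1 + margin, v.shape)
    window = Window(start=tuple(int(a) for a in lo), size=tuple(int(b - a) for a, b in zip(lo, hi)))
    return window, v.with_voxels(mask)


# ---------------------------------------------------------------------------
# voting and density-peaks clustering


def cast_votes(off: OffsetField, fg: np.ndarray) -> VoteCloud:
    """One vote per foreground voxel at source + offset."""
    fg = np.asarray(fg, dtype=bool)
    if fg.shape != off.shape:
        raise ValueError(f"shape mismatch: fg {fg.shape} vs offsets {off.shape}")
    sources = np.argwhere(fg)
    points = sources + off.vectors[fg]
    return VoteCloud(points=points.astype(np.float64), sources=sources)


def _density_peaks(points: np.ndarray, dc: float, min_density: int, min_sep: float):
    """Density-peaks clustering.

    rho_i = number of other points within dc; delta_i = distance to the
    nearest point of higher density (ties broken by lexicographic
    coordinate so the result is permutation-invariant); centers satisfy
    rho >= min_density and delta >= min_sep; remaining points inherit the
    label of their nearest higher-density neighbor, in density order.

    Returns (labels, center_order_indices) with labels in center order.
    """
    n = len(points)
    tree = cKDTree(points)
    rho = tree.query_ball_point(points, dc, return_length=True) - 1
    # density order; coordinate tie-break keeps the result independent of
    # input permutation even with coincident points
    order = np.lexsort((points[:, 2], points[:, 1], points[:, 0], -rho))
    delta = np.empty(n)
    nn = np.full(n, -1, dtype=np.int64)
    block = 1024
    for b0 in range(0, n, block):
        idx = order[b0:b0 + block]
        pts = points[idx]
        best_d = np.full(len(idx), np.inf)
        best_j = np.full(len(idx), -1, dtype=np.int64)
        if b0 > 0:
            prev = order[:b0]
            d, j = cKDTree(points[prev]).query(pts)
            best_d, best_j = d, prev[j]
        # predecessors inside the block
        if len(idx) > 1:
            dmat = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            iu = np.triu_indices(len(idx))
            dmat[iu[0], iu[0]] = np.inf  # self
            dmat[np.triu_indices(len(idx), k=1)] = np.inf  # successors
            jloc = np.argmin(dmat, axis=1)
            dloc = dmat[np.arange(len(idx)), jloc]
            better = dloc < best_d
            best_d[better] = dloc[better]
            best_j[better] = idx[jloc[better]]
        delta[idx] = best_d
        nn[idx] = best_j
    # the globally densest point is always eligible as a center (a single
    # tight cluster must yield one instance regardless of its extent)
    delta[order[0]] = np.inf
    is_center = (rho >= min_density) & (delta >= min_sep)
    if not is_center.any():
        raise NoTeethDetectedError(
            "no teeth detected: no vote-density peak met the center criteria"
        )
    labels = np.full(n, -1, dtype=np.int64)
    next_label = 0
    for i in order:
        if is_center[i]:
            labels[i] = next_label
            next_label += 1
        else:
            labels[i] = labels[nn[i]]
    return labels, np.flatnonzero(is_center)


def cluster_votes(
    cloud: VoteCloud,
    dc: float = 2.0,
    peak_min_density: int = 20,
    peak_min_sep: float = 5.0,
    min_cluster_votes: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Cluster votes into tooth instances.

    Returns ``(assignment, centroids)``: per-vote instance ids (aligned with
    ``cloud.sources``; -1 for votes of discarded clusters) and per-instance
    mean vote positions.  Instances are numbered in lexicographic centroid
    order for determinism.

    ``min_cluster_votes`` discards clusters with fewer member votes: a real
    tooth is supported by hundreds of foreground voxels, while false-positive
    foreground specks yield small stray clusters.  The filter is off by
    default; the pipeline enables it at a scale-appropriate level.
    """
    if len(cloud.points) == 0:
        raise NoTeethDetectedError("no teeth detected: empty vote cloud")
    labels, _ = _density_peaks(cloud.points, dc, peak_min_density, peak_min_sep)
    sizes = np.bincount(labels)
    keep = np.flatnonzero(sizes >= min_cluster_votes)
    if len(keep) == 0:
        raise NoTeethDetectedError(
            "no teeth detected: all clusters below min_cluster_votes"
        )
    centroids = np.stack([cloud.points[labels == i].mean(axis=0) for i in keep])
    order = np.lexsort((centroids[:, 2], centroids[:, 1], centroids[:, 0]))
    remap = np.full(int(sizes.size), -1, dtype=np.int64)
    remap[keep[order]] = np.arange(len(keep))
    return remap[labels], [centroids[i] for i in order]


# ---------------------------------------------------------------------------
# provisional FDI numbering from arch geometry


def assign_fdi_by_arch(centroids: Sequence[np.ndarray], shape: tuple[int, int, int]) -> list[int]:
    """Provisional FDI codes from arch position.

    Arches are split at the largest z-gap between sorted centroids (fallback:
    the volume midplane).  Within an arch, a parabola y(x) is fitted to the
    centroids, teeth are parameterized by signed arc length from the vertex
    (the dental midline), and slot positions are inferred from the median
    angular gap so that missing teeth shift numbering correctly.
    """
    cents = np.asarray(list(centroids), dtype=float)
    n = len(cents)
    if n == 0:
        return []
    zs = np.sort(cents[:, 0])
    gaps = np.diff(zs)
    if n > 1 and gaps.max() >= max(3.0, 0.08 * shape[0]):
        z_split = (zs[np.argmax(gaps)] + zs[np.argmax(gaps) + 1]) / 2.0
    else:
        z_split = shape[0] / 2.0
    # midline: vertex of a parabola y(x) fitted to ALL centroids (both
    # arches share the dental midline, and pooling stabilizes the fit when
    # anterior teeth are missing); per-tooth geometry below uses chord
    # distances, which are local and immune to fit arc-length distortion
    if n >= 3 and np.ptp(cents[:, 2]) > 1e-6:
        coef = np.polyfit(cents[:, 2], cents[:, 1], 2)
        a, b = coef[0], coef[1]
        x_v = -b / (2.0 * a) if abs(a) > 1e-9 else cents[:, 2].mean()
        x_v = float(np.clip(x_v, cents[:, 2].min(), cents[:, 2].max()))
        y_v = float(np.polyval(coef, x_v))
    else:
        x_v = float(cents[:, 2].mean())
        y_v = float(cents[:, 1].mean())

    # typical slot spacing: chords between arch-order neighbors, pooled over
    # both arches; chords spanning a missing slot are ~2x the unit spacing,
    # so estimate the unit from the lower quartile and take the median of
    # the chords close to it
    all_chords: list[float] = []
    arch_sel = {}
    for upper in (True, False):
        sel = np.flatnonzero((cents[:, 0] < z_split) == upper)
        arch_sel[upper] = sel
        if len(sel) < 2:
            continue
        pts = cents[sel]
        d = np.hypot(pts[:, 1] - y_v, pts[:, 2] - x_v)
        order = np.argsort(np.where(pts[:, 2] < x_v, -d, d))
        all_chords += [
            float(np.hypot(*(pts[i, 1:] - pts[j, 1:])))
            for i, j in zip(order, order[1:])
        ]
    if all_chords:
        unit = float(np.percentile(all_chords, 25))
        near = [c for c in all_chords if c <= 1.45 * unit]
        step = float(np.median(near)) if near else float(np.median(all_chords))
    else:
        step = 1.0
    if not np.isfinite(step) or step < 1e-6:
        step = 1.0

    fdis = [0] * n
    for upper in (True, False):
        sel = arch_sel[upper]
        if len(sel) == 0:
            continue
        pts = cents[sel]
        d = np.hypot(pts[:, 1] - y_v, pts[:, 2] - x_v)
        side_neg = pts[:, 2] < x_v
        # innermost tooth per side anchored by its distance to the vertex
        # (slot centers sit at (k - 1/2) * step from the midline), then
        # numbering proceeds outward with chord-gap increments so missing
        # middle teeth shift subsequent numbers correctly
        for neg in (True, False):
            side = np.flatnonzero(side_neg == neg)
            if len(side) == 0:
                continue
            srt = side[np.argsort(d[side])]
            quadrant = (1 if neg else 2) if upper else (4 if neg else 3)
            prev = 0
            pos = int(round(d[srt[0]] / step + 0.5))
            for k, i in enumerate(srt):
                if k > 0:
                    gap = float(np.hypot(*(pts[i, 1:] - pts[srt[k - 1], 1:])))
                    pos = prev + max(1, int(round(gap / step)))
                pos = min(max(pos, prev + 1), 8)
                prev = pos
                fdis[sel[i]] = quadrant * 10 + pos
    return fdis


# ---------------------------------------------------------------------------
# per-tooth crops and segmentation


def _clamped_origin(center, patch, shape):
    lo = np.round(np.asarray(center) - np.asarray(patch) / 2.0).astype(int)
    lo = np.maximum(lo, 0)
    lo = np.minimum(lo, np.asarray(shape) - np.asarray(patch))
    return tuple(int(a) for a in lo)


def build_tooth_input(
    v: Volume,
    inst: ToothInstance,
    skeleton_map: np.ndarray | None,
    patch: tuple[int, int, int] = (24, 24, 24),
    sigma_centroid: float = 2.0,
    skeleton_sigma: float = 1.0,
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Three-channel patch (centroid map, skeleton map, image) centered on
    the instance centroid, shifted inward at volume borders.

    ``skeleton_map=None`` (the w/o-skeleton ablation) zeroes channel 2
    without changing shapes.
    """
    shape = v.shape
    if any(p > s for p, s in zip(patch, shape)):
        raise ValueError(f"patch {patch} larger than volume {shape}")
    origin = _clamped_origin(inst.centroid, patch, shape)
    sl = tuple(slice(o, o + p) for o, p in zip(origin, patch))
    img = v.voxels[sl].astype(np.float32)
    # unit-peak Gaussian at the centroid voxel
    cz, cy, cx = (int(round(c)) - o for c, o in zip(inst.centroid, origin))
    grid = np.indices(patch, dtype=np.float32)
    d2 = (grid[0] - cz) ** 2 + (grid[1] - cy) ** 2 + (grid[2] - cx) ** 2
    centroid_map = np.exp(-d2 / (2.0 * sigma_centroid**2))
    if skeleton_map is not None:
        skel = skeleton_map[sl].astype(np.float32)
        if skel.any():
            skel = ndimage.gaussian_filter(skel, skeleton_sigma)
            skel /= skel.max()
    else:
        skel = np.zeros(patch, dtype=np.float32)
    return np.stack([centroid_map, skel, img]), origin


def segment_single_tooth(
    input_patch: np.ndarray,
    predictor: Predictor,
    context: dict | None = None,
    threshold: float = 0.5,
):
    """Single-tooth multi-task inference.

    Returns ``(mask, prob, boundary, apex, fdi)``; the binary mask is the
    largest connected component of the thresholded sigmoid output, and fdi
    comes from the 32-class logits through the fixed class<->FDI table
    (None when the predictor has no classifier branch).
    """
    out = predictor.predict(input_patch, context=context)
    prob = out["mask"][0]
    mask = prob >= threshold
    if mask.any():
        lab, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
    boundary = out["boundary"][0] if "boundary" in out else np.zeros_like(prob)
    apex = out["apex"][0] if "apex" in out else np.zeros_like(prob)
    fdi = None
    if "class_logits" in out:
        fdi = fdi_from_class(int(np.argmax(out["class_logits"])))
    return mask, prob, boundary, apex, fdi


def assemble_instances(
    instances: Sequence[ToothInstance],
    shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Paste per-tooth crops back into FDI label / probability volumes.

    Overlapping voxels go to the higher per-voxel probability (ties to the
    lower FDI code).  Duplicate FDI codes across instances are kept as
    separate instances in the instance-id volume and reported as conflicts.
    """
    labels = np.zeros(shape, dtype=np.uint16)
    probs = np.zeros(shape, dtype=np.float32)
    inst_ids = np.zeros(shape, dtype=np.int32)
    seen_fdi: dict[int, int] = {}
    conflicts: list[tuple[int, int]] = []
    for inst in instances:
        if inst.mask_crop is None or not inst.mask_crop.any():
            continue
        stop = tuple(o + s for o, s in zip(inst.crop_origin, inst.mask_crop.shape))
        if any(o < 0 for o in inst.crop_origin) or any(t > s for t, s in zip(stop, shape)):
            raise ValueError(f"crop at {inst.crop_origin} outside volume {shape}")
        fdi = inst.fdi if inst.fdi is not None else 0
        if fdi in seen_fdi:
            conflicts.append((fdi, inst.instance_id))
        else:
            seen_fdi[fdi] = inst.instance_id
        sl = tuple(slice(o, o + s) for o, s in zip(inst.crop_origin, inst.mask_crop.shape))
        m = inst.mask_crop
        p = np.where(m, inst.prob_crop, 0.0).astype(np.float32)
        cur_p, cur_l = probs[sl], labels[sl]
        take = m & ((p > cur_p) | ((p == cur_p) & ((cur_l == 0) | (fdi < cur_l))))
        labels[sl] = np.where(take, fdi, cur_l)
        probs[sl] = np.where(take, p, cur_p)
        iid = inst_ids[sl]
        inst_ids[sl] = np.where(take, inst.instance_id, iid)
    return labels, probs, inst_ids, conflicts
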