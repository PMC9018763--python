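"""Seedable synthetic jaw phantoms with full segmentation ground truth.

A phantom emulates the structures a dental CBCT scan of the jaws contains,
on a small grid: two arch-shaped bone bands (maxilla/midface and mandible),
4-16 crown+root shaped teeth per arch placed along parabolic arch curves,
soft-tissue background, additive Gaussian noise, and the three clinically
common abnormality classes - missing teeth, misaligned (jittered) teeth, and
saturating metal inserts with radial streaks.

Intensities are rendered in raw scanner-like units so the standard
preprocessing (clip to [0, 2500], normalize to [0, 1]) applies unchanged:
soft tissue ~500, alveolar bone ~1250, dentin ~2000, metal above the clip
ceiling.

Ground truth includes, per tooth: FDI code, mask, centroid, a thinned 3D
skeleton, root apex landmarks, plus the {background, midface, mandible} bone
labeling - everything the two-branch segmentation system is supervised with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from dentseg.fields import OffsetField
from dentseg.io_core import Volume

# Raw-unit intensity levels (clip window is [0, 2500]).
SOFT_TISSUE = 500.0
BONE = 1250.0
TOOTH = 2000.0
INTENSITY_CEIL = 2500.0

FDI_QUADRANTS = (1, 2, 3, 4)
ALL_FDI = tuple(q * 10 + p for q in FDI_QUADRANTS for p in range(1, 9))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic jaw; the seed fully determines the output.

    ``misalign_jitter`` is ``(max_translation_voxels, max_tilt_degrees)``.
    ``metal_intensity`` must sit at or above the clip ceiling so inserts
    saturate after normalization, as real metal does.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 0.4
    teeth_per_arch: int = 8
    missing_prob: float = 0.1
    misalign_jitter: tuple[float, float] = (1.5, 6.0)
    metal_count: int = 0
    metal_intensity: float = 3200.0
    noise_sigma: float = 0.03
    tooth_scale: float = 1.0
    tooth_intensity_scale: float = 1.0
    age_years: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 24 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be at least (24,24,24), got {self.grid_shape}")
        if not 4 <= self.teeth_per_arch <= 16:
            raise ValueError(f"teeth_per_arch must be in [4, 16], got {self.teeth_per_arch}")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError(f"missing_prob must be in [0, 1], got {self.missing_prob}")
        if self.metal_count < 0 or self.noise_sigma < 0:
            raise ValueError("metal_count and noise_sigma must be non-negative")
        if self.age_years < 0:
            raise ValueError(f"age_years must be non-negative, got {self.age_years}")


@dataclass
class GroundTruth:
    """Complete annotation of one phantom."""

    tooth_labels: np.ndarray  # uint16, FDI codes, 0 = background
    bone_labels: np.ndarray  # uint8, {0 background, 1 midface, 2 mandible}
    centroids: dict[int, np.ndarray]  # FDI -> float (z, y, x)
    apices: dict[int, list[tuple[int, int, int]]]
    skeletons: dict[int, np.ndarray]  # FDI -> (K, 3) int voxel coords
    age_years: int = 30

    @property
    def fdi_codes(self) -> list[int]:
        return sorted(self.centroids)


# ---------------------------------------------------------------------------
# arch geometry


def _arch_slots(shape, n_teeth, rng_unused=None):
    """Even-arc-length slot centers along a parabolic arch.

    Returns (t_values, slot_xy, spacing_voxels, curve_xy) where ``slot_xy``
    are (y, x) positions and ``curve_xy`` a dense polyline of the arch.
    """
    Z, Y, X = shape
    xc, ax = X / 2.0, 0.38 * X
    y_front, ay = 0.20 * Y, 0.52 * Y
    t = np.linspace(-1.0, 1.0, 512)
    x = xc + ax * t
    y = y_front + ay * t * t
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    spacing = total / n_teeth
    fractions = (np.arange(n_teeth) + 0.5) / n_teeth
    t_slots = np.interp(fractions * total, s, t)
    slot_xy = np.stack([y_front + ay * t_slots**2, xc + ax * t_slots], axis=1)
    return t_slots, slot_xy, spacing, np.stack([y, x], axis=1)


def _fdi_for_slot(t: float, upper: bool, t_slots: np.ndarray) -> int:
    """FDI code for the slot at parameter ``t``: quadrant from side and arch,
    position counted outward from the midline."""
    side_neg = t < 0
    same_side = np.sort(np.abs(t_slots[(t_slots < 0) == side_neg]))
    position = int(np.searchsorted(same_side, abs(t) - 1e-9) + 1)
    position = min(position, 8)
    if upper:
        quadrant = 1 if side_neg else 2
    else:
        quadrant = 4 if side_neg else 3
    return quadrant * 10 + position


def _rotation(tilt_zy: float, tilt_zx: float) -> np.ndarray:
    """Small rotation of the tooth axis: tilts (radians) in the (z,y) and (z,x) planes."""
    cy, sy = math.cos(tilt_zy), math.sin(tilt_zy)
    cx, sx = math.cos(tilt_zx), math.sin(tilt_zx)
    r_zy = np.array([[cy, -sy, 0.0], [sy, cy, 0.0], [0.0, 0.0, 1.0]])
    r_zx = np.array([[cx, 0.0, -sx], [0.0, 1.0, 0.0], [sx, 0.0, cx]])
    return r_zx @ r_zy


def _rasterize_tooth(shape, crown_center, axis_root, crown_radii, root_len, root_base_radius):
    """Boolean mask of one crown+root tooth.

    The crown is an ellipsoid at ``crown_center`` with semi-axes
    ``crown_radii`` (rz, ry, rx); the root is a tapered cone of length
    ``root_len`` along the unit vector ``axis_root``.
    """
    lo = np.maximum(np.floor(crown_center - root_len - max(crown_radii) - 2), 0).astype(int)
    hi = np.minimum(
        np.ceil(crown_center + root_len + max(crown_radii) + 2) + 1,
        np.asarray(shape),
    ).astype(int)
    zz, yy, xx = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1).astype(np.float64)
    d = pts - crown_center
    # crown ellipsoid
    crown = np.sum((d / np.asarray(crown_radii)) ** 2, axis=-1) <= 1.0
    # tapered root cone
    u = d @ axis_root  # signed distance along the root axis
    radial = np.linalg.norm(d - u[..., None] * axis_root, axis=-1)
    frac = np.clip(u / root_len, 0.0, 1.0)
    taper = root_base_radius * (1.0 - frac) + 0.35
    root = (u >= 0.0) & (u <= root_len) & (radial <= taper)
    local = crown | root
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = local
    return mask


# ---------------------------------------------------------------------------
# ground-truth geometry helpers


def derive_skeleton(mask: np.ndarray) -> np.ndarray:
    """Thin, 26-connected skeleton of a binary mask via iterative 3D thinning.

    Returns an ``(K, 3)`` integer array of voxel coordinates contained in the
    mask; never empty for a nonempty mask (falls back to the innermost voxel
    of very small masks for which thinning erases everything).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    # thin on a tight crop for speed
    slc = ndimage.find_objects(mask.astype(np.uint8))[0]
    crop = mask[slc]
    skel = skeletonize(crop)
    if not skel.any():
        dist = ndimage.distance_transform_edt(crop)
        idx = np.unravel_index(int(np.argmax(dist)), crop.shape)
        skel = np.zeros_like(crop)
        skel[idx] = True
    coords = np.argwhere(skel)
    coords += np.array([s.start for s in slc])
    return coords


def find_apices(mask: np.ndarray, occlusal_axis: np.ndarray) -> list[tuple[int, int, int]]:
    """Root apex voxels: local extrema of the mask in the root direction
    (opposite the occlusal axis), one per connected extremal cluster."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no apices")
    root_dir = -np.asarray(occlusal_axis, dtype=float)
    root_dir = root_dir / np.linalg.norm(root_dir)
    coords = np.argwhere(mask)
    proj = coords @ root_dir
    cand = coords[proj >= proj.max() - 1.0]
    cand_mask = np.zeros(mask.shape, dtype=bool)
    cand_mask[tuple(cand.T)] = True
    lab, n = ndimage.label(cand_mask, structure=np.ones((3, 3, 3)))
    apices = []
    for i in range(1, n + 1):
        pts = np.argwhere(lab == i)
        p = pts @ root_dir
        best = pts[np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], -p))][0]
        apices.append(tuple(int(c) for c in best))
    return sorted(apices)


def derive_boundary_and_apex(
    mask: np.ndarray,
    occlusal_axis: np.ndarray,
    sigma: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, int]]]:
    """Regression targets for the multi-task tooth head.

    boundary map: the 1-voxel boundary shell (mask minus its erosion),
    Gaussian-smoothed and renormalized to peak 1.  apex map: sum of
    unit-peak Gaussians at the apex landmarks, clamped to [0, 1].
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    shell = mask & ~ndimage.binary_erosion(mask)
    boundary = ndimage.gaussian_filter(shell.astype(np.float32), sigma)
    boundary /= boundary.max()
    apex_points = find_apices(mask, occlusal_axis)
    apex_map = np.zeros(mask.shape, dtype=np.float32)
    grid = np.indices(mask.shape, dtype=np.float32)
    for p in apex_points:
        d2 = sum((grid[a] - p[a]) ** 2 for a in range(3))
        apex_map += np.exp(-d2 / (2.0 * sigma**2))
    np.clip(apex_map, 0.0, 1.0, out=apex_map)
    return boundary, apex_map, apex_points


def occlusal_axis_for(fdi: int) -> np.ndarray:
    """Unit vector from root toward crown: +z for maxillary teeth (Q1/Q2,
    superior at z=0), -z for mandibular teeth (Q3/Q4)."""
    return np.array([1.0, 0.0, 0.0]) if fdi < 30 else np.array([-1.0, 0.0, 0.0])


def make_offset_targets(
    labels: np.ndarray,
    target: str,
    gt: GroundTruth,
) -> OffsetField:
    """Per-voxel offsets from each foreground voxel to its tooth's centroid
    (``target='centroid'``) or nearest skeleton voxel (``target='skeleton'``)."""
    if target not in ("centroid", "skeleton"):
        raise ValueError(f"target must be 'centroid' or 'skeleton', got {target!r}")
    labels = np.asarray(labels)
    vectors = np.zeros(labels.shape + (3,), dtype=np.float32)
    valid = labels > 0
    for fdi in np.unique(labels[valid]):
        fdi = int(fdi)
        if fdi not in gt.centroids:
            raise ValueError(f"label {fdi} present in volume but absent from ground truth")
        coords = np.argwhere(labels == fdi)
        if target == "centroid":
            off = gt.centroids[fdi][None, :] - coords
        else:
            skel = gt.skeletons[fdi]
            _, idx = cKDTree(skel).query(coords)
            off = skel[idx] - coords
        vectors[tuple(coords.T)] = off.astype(np.float32)
    return OffsetField(vectors=vectors, valid=valid)


# ---------------------------------------------------------------------------
# phantom generation


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Render one synthetic jaw volume and its full ground truth."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    Z, Y, X = shape

    t_slots, slot_xy, slot_spacing, curve_xy = _arch_slots(shape, spec.teeth_per_arch)
    if slot_spacing < 4.0:
        raise ValueError(
            f"{spec.teeth_per_arch} teeth per arch exceed arch capacity at "
            f"grid {shape}: slot spacing {slot_spacing:.2f} voxels < 4"
        )

    crown_r = 0.42 * slot_spacing * spec.tooth_scale
    crown_rz = 0.55 * slot_spacing * spec.tooth_scale
    tooth_h = min(2.0 * slot_spacing * spec.tooth_scale, 0.32 * Z)
    root_len = tooth_h - crown_rz
    jit_vox, jit_deg = spec.misalign_jitter

    tooth_labels = np.zeros(shape, dtype=np.uint16)
    centroids: dict[int, np.ndarray] = {}
    apices: dict[int, list[tuple[int, int, int]]] = {}
    skeletons: dict[int, np.ndarray] = {}

    for upper in (True, False):
        # crown centers sit just off the occlusal plane; roots point away from it
        crown_z = 0.46 * Z - crown_rz if upper else 0.54 * Z + crown_rz
        root_sign = -1.0 if upper else 1.0
        for t, (sy, sx) in zip(t_slots, slot_xy):
            fdi = _fdi_for_slot(float(t), upper, t_slots)
            # one RNG draw per slot regardless of outcome keeps layouts stable
            drop = rng.random() < spec.missing_prob
            shift = rng.uniform(-jit_vox, jit_vox, size=3)
            tilts = np.deg2rad(rng.uniform(-jit_deg, jit_deg, size=2))
            if drop:
                continue
            center = np.array([crown_z, sy, sx]) + shift
            axis = _rotation(*tilts) @ np.array([root_sign, 0.0, 0.0])
            mask = _rasterize_tooth(
                shape, center, axis, (crown_rz, crown_r, crown_r), root_len, 0.7 * crown_r
            )
            mask &= tooth_labels == 0  # first-come claim on contested voxels
            if not mask.any():
                continue
            lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
            if n > 1:  # keep the largest fragment so each FDI stays connected
                sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
                mask = lab == (1 + int(np.argmax(sizes)))
            tooth_labels[mask] = fdi
            coords = np.argwhere(mask)
            centroids[fdi] = coords.mean(axis=0)
            apices[fdi] = find_apices(mask, occlusal_axis_for(fdi))
            skeletons[fdi] = derive_skeleton(mask)

    # arch-shaped bone bands around the root regions
    bone_labels = np.zeros(shape, dtype=np.uint8)
    yy, xx = np.meshgrid(np.arange(Y), np.arange(X), indexing="ij")
    grid2d = np.stack([yy.ravel(), xx.ravel()], axis=1)
    d2d, _ = cKDTree(curve_xy).query(grid2d)
    band = (d2d.reshape(Y, X) <= 0.8 * slot_spacing)
    root_top_u = 0.46 * Z - tooth_h
    root_top_l = 0.54 * Z + tooth_h
    for cls, zlo, zhi in (
        (1, max(1, int(root_top_u - 2)), int(0.46 * Z - 0.5 * tooth_h)),
        (2, int(0.54 * Z + 0.5 * tooth_h), min(Z - 1, int(root_top_l + 2))),
    ):
        slab = np.zeros(shape, dtype=bool)
        slab[zlo:zhi + 1] = band[None, :, :]
        bone_labels[slab & (bone_labels == 0)] = cls
    bone_labels[tooth_labels > 0] = 0  # tooth and bone foregrounds are disjoint

    # intensity rendering
    img = np.full(shape, SOFT_TISSUE, dtype=np.float32)
    img[bone_labels > 0] = BONE
    img[tooth_labels > 0] = TOOTH * spec.tooth_intensity_scale
    img = ndimage.gaussian_filter(img, 0.5)  # soften boundaries a little

    # metal inserts: saturated crown caps plus radial streaks
    present = sorted(centroids)
    n_metal = min(spec.metal_count, len(present))
    if n_metal > 0:
        metal_fdis = list(rng.choice(present, size=n_metal, replace=False))
        for fdi in metal_fdis:
            tooth_vox = np.argwhere(tooth_labels == fdi)
            occl = occlusal_axis_for(fdi)
            proj = tooth_vox @ occl
            cap_center = tooth_vox[int(np.argmax(proj))].astype(float)
            zz, yyv, xxv = np.indices(shape, sparse=True)
            d2 = (
                (zz - cap_center[0]) ** 2
                + (yyv - cap_center[1]) ** 2
                + (xxv - cap_center[2]) ** 2
            )
            img[d2 <= (0.8 * crown_r) ** 2] = spec.metal_intensity
            # streaks in the axial plane through the cap
            for _ in range(8):
                theta = rng.uniform(0.0, 2.0 * math.pi)
                amp = rng.choice([-1.0, 1.0]) * rng.uniform(300.0, 600.0)
                for r in np.arange(2.0, 0.45 * min(Y, X), 0.7):
                    py = int(round(cap_center[1] + r * math.sin(theta)))
                    px = int(round(cap_center[2] + r * math.cos(theta)))
                    pz = int(round(cap_center[0]))
                    if 0 <= py < Y and 0 <= px < X and 0 <= pz < Z:
                        img[pz, py, px] += amp * math.exp(-r / (0.25 * min(Y, X)))

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma * INTENSITY_CEIL, size=shape).astype(np.float32)
    np.clip(img, 0.0, None, out=img)

    vol = Volume(voxels=img, spacing=(spec.spacing_mm,) * 3)
    gt = GroundTruth(
        tooth_labels=tooth_labels,
        bone_labels=bone_labels,
        centroids=centroids,
        apices=apices,
        skeletons=skeletons,
        age_years=spec.age_years,
    )
    return vol, gt


def save_case(out_dir, case_id: str, vol: Volume, gt: GroundTruth) -> None:
    """Write a phantom as NIfTI volumes plus a JSON sidecar (centroids,
    apices, age); skeletons are recomputed on load."""
    import json
    from pathlib import Path

    from dentseg.io_core import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(vol, out / f"image_{case_id}.nii.gz")
    write_volume(
        Volume(gt.tooth_labels, vol.spacing, vol.origin), out / f"tooth_labels_{case_id}.nii.gz"
    )
    write_volume(
        Volume(gt.bone_labels, vol.spacing, vol.origin), out / f"bone_labels_{case_id}.nii.gz"
    )
    meta = {
        "age_years": gt.age_years,
        "centroids": {str(f): list(map(float, c)) for f, c in gt.centroids.items()},
        "apices": {str(f): [list(map(int, a)) for a in v] for f, v in gt.apices.items()},
    }
    (out / f"meta_{case_id}.json").write_text(json.dumps(meta, indent=2))


def load_case(data_dir, case_id: str) -> tuple[Volume, GroundTruth]:
    """Reload a saved phantom; skeletons are re-derived from the tooth masks."""
    import json
    from pathlib import Path

    from dentseg.io_core import read_volume

    d = Path(data_dir)
    vol = read_volume(d / f"image_{case_id}.nii.gz")
    tooth = read_volume(d / f"tooth_labels_{case_id}.nii.gz").voxels.astype(np.uint16)
    bone = read_volume(d / f"bone_labels_{case_id}.nii.gz").voxels.astype(np.uint8)
    meta = json.loads((d / f"meta_{case_id}.json").read_text())
    centroids = {int(f): np.asarray(c) for f, c in meta["centroids"].items()}
    apices = {int(f): [tuple(a) for a in v] for f, v in meta["apices"].items()}
    skeletons = {f: derive_skeleton(tooth == f) for f in centroids}
    gt = GroundTruth(
        tooth_labels=tooth,
        bone_labels=bone,
        centroids=centroids,
        apices=apices,
        skeletons=skeletons,
        age_years=int(meta["age_years"]),
    )
    return vol, gt


def list_cases(data_dir) -> list[str]:
    from pathlib import Path

    return sorted(
        p.name[len("image_"):-len(".nii.gz")]
        for p in Path(data_dir).glob("image_*.nii.gz")
    )


def make_cohort(
    n: int,
    seed: int = 0,
    base: PhantomSpec | None = None,
) -> list[tuple[PhantomSpec, Volume, GroundTruth]]:
    """A small age-stratified cohort for the tooth volume/density statistics.

    Ages are drawn uniformly over 0-89 years.  Tooth radii are scaled by 1.2
    for ages 20-49 (larger permanent dentition in mid-life), and tooth
    intensity rises mildly from 30 to 79 before dropping at 80+ (enamel
    densification, then wear) - the qualitative trends the statistics utility
    is meant to expose.
    """
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        age = int(rng.integers(0, 90))
        scale = 1.2 if 20 <= age <= 49 else 1.0
        if 30 <= age < 80:
            inten = 1.0 + 0.002 * (age - 30)
        elif age >= 80:
            inten = 0.95
        else:
            inten = 1.0
        spec = PhantomSpec(
            grid_shape=base.grid_shape,
            spacing_mm=base.spacing_mm,
            teeth_per_arch=base.teeth_per_arch,
            missing_prob=base.missing_prob,
            misalign_jitter=base.misalign_jitter,
            metal_count=base.metal_count,
            noise_sigma=base.noise_sigma,
            tooth_scale=scale,
            tooth_intensity_scale=inten,
            age_years=age,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, gt = generate_phantom(spec)
        out.append((spec, vol, gt))
    return out
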