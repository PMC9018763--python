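"""Branch fusion, segmentation metrics, and tooth volume/intensity statistics.

Metrics follow the standard definitions: Dice = 2|R∩G| / (|R|+|G|),
sensitivity = |R∩G| / |G|, and the average surface distance (ASD) is made
symmetric: the mean of the two directed mean surface distances, in physical
mm with anisotropy-aware coordinates.  Surface voxels are a mask minus its
one-voxel erosion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from dentseg.io_core import Volume

AGE_BINS = [f"{d}-{d + 9}" for d in range(0, 90, 10)]


@dataclass(frozen=True)
class MetricsRecord:
    label: int
    dice: float
    sensitivity: float
    asd_mm: float


@dataclass(frozen=True)
class ToothStat:
    fdi: int
    volume_mm3: float
    mean_intensity: float
    age_bin: str


def fuse(
    tooth_labels: np.ndarray,
    tooth_prob: np.ndarray,
    bone_labels: np.ndarray,
    bone_prob: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve voxels claimed by both branches toward the higher branch
    probability; exact ties go to the tooth.  Output foregrounds are disjoint.

    ``bone_prob`` may be the (3, ...) softmax stack or a single foreground
    probability map.
    """
    shapes = {tooth_labels.shape, tooth_prob.shape, bone_labels.shape}
    if len(shapes) != 1:
        raise ValueError(f"misaligned volumes: {sorted(shapes)}")
    if bone_prob.ndim == 4:
        bone_fg_prob = np.take_along_axis(
            bone_prob, bone_labels[None].astype(np.int64), axis=0
        )[0]
    else:
        bone_fg_prob = bone_prob
    both = (tooth_labels > 0) & (bone_labels > 0)
    tooth_out = tooth_labels.copy()
    bone_out = bone_labels.copy()
    tooth_wins = both & (tooth_prob >= bone_fg_prob)
    bone_wins = both & ~tooth_wins
    bone_out[tooth_wins] = 0
    tooth_out[bone_wins] = 0
    return tooth_out, bone_out


def overlap_metrics(r: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """(dice, sensitivity) of result mask ``r`` against reference ``g``.

    Both-empty masks have Dice 1 by convention (needed for missing-tooth
    evaluation); sensitivity with an empty reference is NaN and flagged by
    the caller-facing ``evaluate_case``.
    """
    r = np.asarray(r, dtype=bool)
    g = np.asarray(g, dtype=bool)
    if r.shape != g.shape:
        raise ValueError(f"mask shapes differ: {r.shape} vs {g.shape}")
    nr, ng = int(r.sum()), int(g.sum())
    inter = int((r & g).sum())
    dice = 1.0 if nr + ng == 0 else 2.0 * inter / (nr + ng)
    sensitivity = np.nan if ng == 0 else inter / ng
    return dice, sensitivity


def _surface(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def average_surface_distance(
    r: np.ndarray,
    g: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Symmetric ASD in mm between the surfaces of two nonempty masks."""
    r = np.asarray(r, dtype=bool)
    g = np.asarray(g, dtype=bool)
    if not r.any() or not g.any():
        raise ValueError("average surface distance requires two nonempty masks")
    sp = np.asarray(spacing, dtype=float)
    ps_r = np.argwhere(_surface(r)) * sp
    ps_g = np.argwhere(_surface(g)) * sp
    d_rg = cKDTree(ps_g).query(ps_r)[0].mean()
    d_gr = cKDTree(ps_r).query(ps_g)[0].mean()
    return float((d_rg + d_gr) / 2.0)


def evaluate_case(
    pred_labels: np.ndarray,
    gt_labels: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[MetricsRecord]:
    """One MetricsRecord per label present in either volume.

    Labels present in ground truth but absent from the prediction score
    dice/sensitivity 0 with ASD NaN; labels absent from both (e.g. a missing
    tooth correctly not predicted) score dice 1.
    """
    labels = sorted(set(np.unique(gt_labels)) | set(np.unique(pred_labels)))
    out = []
    for lab in labels:
        if lab == 0:
            continue
        r = pred_labels == lab
        g = gt_labels == lab
        dice, sens = overlap_metrics(r, g)
        asd = (
            average_surface_distance(r, g, spacing)
            if r.any() and g.any()
            else (0.0 if not r.any() and not g.any() else np.nan)
        )
        out.append(MetricsRecord(label=int(lab), dice=dice, sensitivity=sens, asd_mm=asd))
    return out


def records_to_frame(records: list[MetricsRecord], case: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"case": case, "label": r.label, "dice": r.dice,
             "sensitivity": r.sensitivity, "asd_mm": r.asd_mm}
            for r in records
        ]
    )


def tooth_stats(
    labels: np.ndarray,
    image: Volume | np.ndarray,
    spacing: tuple[float, float, float],
    age_years: int,
) -> list[ToothStat]:
    """Per-tooth volume (mm^3) and mean intensity, tagged with a decade bin."""
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    img = image.voxels if isinstance(image, Volume) else image
    if labels.shape != img.shape:
        raise ValueError("labels and image must be aligned")
    voxel_mm3 = float(np.prod(spacing))
    age_bin = AGE_BINS[min(age_years // 10, len(AGE_BINS) - 1)]
    out = []
    for fdi in np.unique(labels):
        if fdi == 0:
            continue
        m = labels == fdi
        out.append(
            ToothStat(
                fdi=int(fdi),
                volume_mm3=float(m.sum()) * voxel_mm3,
                mean_intensity=float(img[m].mean()),
                age_bin=age_bin,
            )
        )
    return out


def aggregate_stats(stats: list[ToothStat]) -> pd.DataFrame:
    """Mean volume and intensity per (FDI, age decade)."""
    df = pd.DataFrame([s.__dict__ for s in stats])
    if df.empty:
        return df
    return (
        df.groupby(["fdi", "age_bin"], as_index=False)
        .agg(volume_mm3=("volume_mm3", "mean"), mean_intensity=("mean_intensity", "mean"))
    )
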