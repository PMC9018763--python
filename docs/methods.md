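# Methods

## Problem and system overview

`dentseg` segments individual teeth (with FDI numbering) and alveolar bone
from dental cone-beam CT (CBCT) volumes with a fully automatic two-branch
pipeline:

1. **Tooth branch** (hierarchical, morphology-guided):
   a dental-ROI network first localizes the jaws by binary tooth-foreground
   segmentation; two offset-regression networks then predict, per foreground
   voxel, a 3D vector to the owning tooth's *centroid* and to its nearest
   *skeleton* voxel; voxels cast votes at `position + offset`, votes are
   clustered into tooth instances by density-peaks clustering; each instance
   is cropped into a three-channel patch (centroid heatmap, skeleton map,
   image) and segmented by a multi-task network that also regresses tooth
   boundary and root-apex heatmaps and classifies the 32-class FDI code.
2. **Bone branch**: a one-level 3D Haar wavelet transform produces a
   boundary-enhancement map; a coarse-to-fine cascade of two networks maps
   (image, enhanced) — and, for the refiner, the coarse class probabilities —
   to {background, midface bone, mandible bone}.

Voxels claimed by both branches are resolved toward the higher branch
probability (ties to the tooth), so the fused foregrounds are disjoint.

## Preprocessing

Input volumes are resampled to an isotropic 0.4 mm grid (trilinear for
images, nearest-neighbor for labels; output shape per axis is
`round(shape * spacing / 0.4)`) and intensities are clipped to `[0, 2500]`
raw units and rescaled linearly to `[0, 1]`.  The clip ceiling suppresses
extreme metal-artifact values.  Clipping bounds are treated as raw scanner
units, not Hounsfield units.

The internal axis convention is `(z, y, x)`, 0-based, half-open windows;
NIfTI's `(x, y, z)` storage order is transposed on read and write.

## Synthetic phantoms: what they emulate and what they do not

Real annotated CBCT data is not distributed with the package; all training
and evaluation run on a seedable phantom generator (`dentseg.phantom`).
Each phantom contains:

- two parabolic dental arches in separate axial slabs (maxilla above the
  occlusal plane, mandible below), each carrying 4–16 crown+root teeth
  (ellipsoid crown fused with a tapered root cone) placed at even arc-length
  slots; FDI codes follow quadrant (side × arch) and position from the
  midline;
- arch-shaped bone bands (class 1 = midface, 2 = mandible) surrounding the
  roots, with teeth carved out so tooth and bone ground truths are disjoint;
- soft-tissue background; mean intensities are ordered
  soft tissue (≈500) < bone (≈1250) < teeth (≈2000) on the raw scale, with a
  0.5-voxel Gaussian blur of the piecewise-constant scene and additive
  Gaussian noise (σ expressed as a fraction of the 2500-unit window,
  default 0.03);
- the three clinically common abnormality classes: tooth slots dropped with
  probability `missing_prob` (default 0.1), per-tooth pose jitter
  (translation up to 1.5 voxels, tilt up to 6°), and `metal_count` saturated
  crown inserts (intensity 3200 > clip ceiling) with radial intensity
  streaks in the axial plane.

Ground truth includes per-tooth masks, centroids, root-apex landmarks
(extremal voxels in the root direction), and skeletons obtained by
iterative 3D thinning (`skimage.morphology.skeletonize`), plus the 3-class
bone labeling.  Supervision targets derived from these are: exact
centroid/skeleton offset fields, and unit-peak Gaussian boundary/apex
heatmaps (boundary shell = mask minus its 1-voxel erosion; σ = 1.5 voxels).

Phantoms deliberately do **not** model CT physics (beam hardening, scatter,
reconstruction artifacts beyond stylized streaks), anatomically realistic
tooth/root shapes (no multi-rooted molars), deciduous dentition, or
contact between adjacent crowns under normal bite.  Passing tests therefore
demonstrate that the pipeline machinery — voting, clustering, numbering,
multi-task segmentation, Haar enhancement, fusion, metrics — is correct and
learnable at desk scale, not that the trained weights transfer to clinical
scans.

### Desk-scale study conditions

All trained experiments use 48³-voxel phantoms at 0.4 mm with 6 teeth per
arch (the same physical tooth size as an 8-per-arch dentition on a 64³
grid), `missing_prob=0.1`, jitter (1.5 voxels, 6°), no metal during
training; metal and high missing rates are exercised in the oracle
end-to-end checks.  Training uses 30 phantoms, validation 3, testing 10.

## Networks, losses, training

No deep-learning framework is used: the volumetric encoder–decoder, its
heads, losses, Adam optimizer, and backpropagation are implemented in NumPy
with numba-jitted 3×3×3 convolution kernels (a pure-NumPy BLAS fallback is
retained).  The backbone is V-Net-style: per level one or two 3×3×3
conv+ReLU blocks, channel count doubling per level, 2× average-pool
downsampling, and a decoder that reduces channels at the coarse grid,
nearest-upsamples, and fuses skips additively before a final conv per
level.  Dense heads are 1×1×1 convolutions (sigmoid, softmax, or linear);
the FDI classifier applies global max-pooling to the bottleneck followed by
three fully-connected layers (exact layer recipes of the original V-Net are
a non-goal).

Losses: binary cross-entropy for sigmoid mask heads; mean squared error for
offset/boundary/apex regression, with offset L2 averaged over ground-truth
foreground voxels only (the paired mask head exists to filter background
votes at inference); multi-class cross-entropy for the 3-class bone heads
and the 32-class FDI classifier (weight 0.3).  Training uses Adam at
learning rate 0.001 with batch size 1.  Early stopping: training stops when
the best validation loss has not improved by more than a tolerance
(default 1e-4) for 5 consecutive epochs; the best-validation snapshot is
returned.

Two decoder variants exist: `concat` (upsample, reduce channels,
concatenate the skip — the U-Net wiring) and `add` (reduce channels at the
coarse grid, upsample, add the skip — cheaper).  Dense 3-class softmax
heads measurably need the concat wiring; smooth offset fields do not.

Desk-scale network sizes and schedules (all levels=2, 32³ training crops;
per-tooth crops 24³):

| network        | base channels | convs/block | decoder | epochs | crops or teeth per phantom |
|----------------|--------------|-------------|---------|--------|-----------------------------|
| ROI            | 4            | 2           | add     | 5      | 2 crops |
| centroid offsets | 8          | 1           | add     | 8      | 3 crops |
| skeleton offsets | 8          | 1           | add     | 6      | 3 crops |
| single tooth   | 6            | 2           | concat  | 8      | 4 teeth |
| bone coarse    | 6            | 2           | concat  | 5      | 2 crops |
| bone refine    | 6            | 2           | concat  | 5      | 2 crops |

Two training-robustness measures matter at this scale.  First, the
single-tooth network's skeleton channel is supervised with *degraded*
ground-truth skeletons (20% voxel dropout, unit jitter on 30% of voxels),
and at inference the skeleton channel built from vote targets is re-thinned
before smoothing — both shrink the gap between the clean skeletons seen in
training and the noisy vote-built skeletons seen in deployment.  Second, a
small fraction of training runs lands in a dead-decoder optimum where a
dense head emits a spatially constant background map; this is detected on
validation samples (nonempty target, empty thresholded prediction) and the
run is restarted from a shifted initialization seed (at most twice).

These sizes were chosen to fit a single-CPU budget while keeping the
offset-regression capacity that instance detection needs; `paper`-preset
constants (256³ patches, 96³ tooth crops) are retained as named
configuration but are GPU-class jobs outside the test surface.  All
randomness (init, data order, crop sampling) is driven by one run seed.

## Instance detection details

Votes are clustered with density-peaks clustering: ρ_i = number of other
votes within `dc` (default 2 voxels at 0.4 mm, roughly half a phantom tooth
radius); δ_i = distance to the nearest vote of higher ρ (coordinate-
lexicographic tie-breaks make the result permutation-invariant); cluster
centers require ρ ≥ 20 and δ ≥ 5 voxels (the globally densest vote is
always center-eligible, so a single tight cluster yields one instance);
remaining votes inherit the label of their nearest denser vote, in density
order.  The pipeline additionally
discards clusters supported by fewer than `cluster_min_votes` (default 100)
votes: a real tooth projects hundreds of foreground voxels, while
false-positive foreground specks form small stray clusters; the filter is
off by default in the library function so the bare clustering rule stays
testable against its literal definition.

**FDI numbering.** The final code per instance defaults to an
arch-geometry heuristic rather than the classifier head.  Arches are split
at the largest z-gap between instance centroids; a parabola `y(x)` fitted
to *all* centroids places the dental midline (its vertex — pooling both
arches stabilizes the fit when anterior teeth are missing); left/right
quadrant follows the side of the vertex.  Positions use chord geometry,
which is local and immune to arc-length distortion of the fit: the unit
slot spacing is the lower-quartile-calibrated median of neighbor chords
pooled over both arches (chords spanning a missing slot are ~2 units and
are excluded); each side's innermost tooth is anchored by its vertex
distance (slot centers sit at `(k - 1/2) * step` from the midline), and
numbering proceeds outward with `max(1, round(gap/step))` increments so
missing middle teeth shift subsequent numbers correctly.  Rationale:
phantom teeth share essentially one shape, so a centered 24³ crop carries
no arch-position information and a crop-level 32-class classifier is
ill-posed in this synthetic setting; on real anatomy, where tooth shape
encodes position, `fdi_source="classifier"` switches the pipeline to the
classifier head.  The classifier branch is still trained and exposed.

Paste-back: each instance's thresholded (0.5), largest-connected-component
mask is written at its crop origin with its FDI code; overlapping voxels go
to the higher per-voxel probability, ties to the lower code; duplicate FDI
codes are kept as distinct instances in a parallel instance-id volume and
reported as conflicts.

## Bone branch details

"Haar enhancement" is the sum of absolute values of the seven detail
subbands of a one-level 3D Haar decomposition (edge-padded to even
dimensions), nearest-upsampled to the image grid and rescaled to [0, 1] by
its maximum; a constant volume maps to zeros.  A coefficient-magnitude map
was chosen over a filtered reconstruction because it directly measures
local intensity discontinuity and is resolution-preserving up to the
2-voxel block grid.  The cascade's refiner consumes
(image, enhanced, coarse softmax) and its argmax is the bone labeling;
setting `no_haar` zeroes the enhanced channel without changing shapes.

## Evaluation metrics

Dice = 2|R∩G|/(|R|+|G|); sensitivity = |R∩G|/|G| (deliberately asymmetric);
ASD is symmetric — the mean of the two directed mean surface distances
between surface voxel sets (mask minus 1-voxel erosion), computed on
physical coordinates so anisotropic grids evaluate correctly.  Conventions
for degenerate cases: both-empty masks score Dice 1 (a correctly absent
missing tooth), empty-reference sensitivity is NaN, ASD requires two
nonempty masks.  Per-case evaluation emits one record per label present in
either volume; a GT label absent from the prediction scores Dice 0 rather
than crashing.

The statistics utility aggregates per-tooth volume (voxel count × voxel
volume) and mean image intensity by FDI code and age decade (bins 0–9 …
80–89).  The phantom cohort generator scales tooth radii ×1.2 for ages
20–49 and applies a mild intensity rise over ages 30–79 with a drop at 80+,
so the aggregated curves reproduce the qualitative mid-life volume peak and
late-life density decline that such trajectory analyses target.

## Numerical and design choices

- Sigmoid-mask threshold 0.5 everywhere; largest-connected-component
  post-filter per tooth.
- Overlapping sliding-window outputs are averaged voxelwise; windows tile
  with stride `ceil(patch · (1−overlap))` and the last window per axis is
  shifted to end at the boundary.  Inference may use a larger window than
  the training crop (the networks are fully convolutional).
- Resampling output shape uses `round()` to minimize physical-extent error.
- The tooth crop must cover a whole tooth: 24³ suffices for 48³ desk
  phantoms; 64³ phantoms need 32³ crops (the 96³ paper-scale crop has the
  same role for ~25 mm real teeth).
- Tooth/bone branches run sequentially; neither reads the other's output
  before fusion.
- Class↔FDI table is the fixed row-major bijection over quadrants 1–4 ×
  positions 1–8 (class 0 ↔ FDI 11, class 31 ↔ FDI 48), stable across
  checkpoint save/load.

## Known limitations

- Phantom realism limits (see above); reported desk-scale Dice values
  characterize the pipeline on phantoms only.
- The arch heuristic assumes at most two arches roughly orthogonal to z and
  parabola-like in (x, y); extreme malocclusion or supernumerary teeth
  would need the classifier path plus shape priors.
- Offsets are regressed in voxel units at the 0.4 mm working resolution;
  other working resolutions rescale `dc`/`min_sep` implicitly.
- The NumPy/numba training stack is single-threaded and desk-scale by
  design; it is not a general-purpose deep-learning framework.
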