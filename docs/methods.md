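# Methods

This note documents the models, the numerical choices and the limits of
what the synthetic test bed can show. It is written for someone extending
or auditing the package, not for end users.

## Problem setting

Two acquisitions of the same neck/bust region are taken at different times
with different devices: an infrared video sweep (≈180°, the subject seated
on a swivel chair) and a contrast CT. The goal is one unified 3D model in
the DICOM coordinate system: the CT-derived outer surface carrying the
projected skin-temperature texture, with segmented inner structures
(thyroid, trachea, vessels) inside it. The quantitative output is the
displacement error of labeled markers between the thermal model and the
CT model.

## Thermal ingestion and intensification

Frames arrive as per-pixel °C CSV files. Conversion to 8-bit gray is a
linear map over a configurable range (per-frame min/max by default; the
pipeline fixes one global range across the sequence for photometric
consistency). Intensification is a percentile contrast stretch
(p_low=2, p_high=98), an optional gamma, and optional tile-based adaptive
equalization (8×8 tiles). Skin thermograms are inherently low-contrast;
intensification exists to give the feature detector texture to work with.
The adaptive-equalization step is on by default for `intensify()` itself,
but the pipeline's feature-detection path disables it: equalization
amplifies the camera noise of the uniform background into spurious,
view-unstable keypoints.

## Structure from motion

The driver follows the classical incremental recipe, with several
hardenings that matter on this data. The imaged surface is *quasi-planar*
(the visible side of a bust spans ~100 mm of depth at ~900 mm range), which
makes the textbook 8-point essential matrix unstable: its consensus drifts
toward degenerate near-zero-baseline models, and the plane-induced
two-fold decomposition ambiguity cannot be resolved from a single pair.

* **Features.** DoG detection with orientation-histogram descriptors
  (scikit-image's SIFT), rootSIFT normalization, and a DoG contrast
  threshold (5e-4) far below the photographic convention — intensified
  thermograms carry genuinely weak texture. Matching is mutual
  nearest-neighbor with Lowe's ratio (0.9).
* **Pairwise relative pose.** Motion hypotheses are pooled from three
  homography-RANSAC runs (full iteration budget — an adaptive early exit
  would lock onto the first local planar patch) and two essential-matrix
  RANSAC runs (with a cheirality/parallax plausibility gate inside the
  consensus loop). Each surviving hypothesis is polished by a two-view
  bundle adjustment. Up to three refined hypotheses are kept per pair.
* **Branch selection.** The hypothesis per pair is chosen globally by
  rotation cycle consistency: iterated conditional modes on the mean
  triplet cycle error, with a small support-count tiebreak. A subsequent
  cleaning pass drops pairs whose median cycle error stays above 0.15 rad,
  never disconnecting the view graph. Distant frame pairs (|Δindex| > 3)
  additionally need an unusually clean consensus (inlier ratio ≥ 0.45),
  since a video sweep gives them little genuine overlap.
* **Tracks.** Pairwise matches merge into multi-view tracks by
  conflict-avoiding greedy union (components merge only when their view
  sets are disjoint): one wrong match must not poison or destroy
  otherwise-consistent tracks.
* **Incremental registration.** PnP (DLT + RANSAC + nonlinear refinement)
  where 2D–3D support exists; otherwise chain registration from a refined
  pairwise pose, with the baseline scale voted by common 3D points
  (median, rejected if the vote spread exceeds 25%).
* **Bundle adjustment.** Trust-region least squares (scipy) with an
  analytic sparsity pattern, first camera fixed (gauge), soft-L1 loss
  (f_scale 2 px) during reconstruction and a final plain pass; gross
  observations are pruned per observation, not per track. Epipolar-guided
  retriangulation rounds with an annealed band (6 → 4 → 3 px) rebuild the
  tracks as the poses improve.
* **Restarts.** RANSAC luck occasionally steers the whole solve into a
  self-consistent but warped optimum. The pipeline therefore runs up to
  three independent solves (shifted RNG streams, rotated initialization
  pair) and keeps the one minimizing the registration score below.

Thresholds (2.5 px RANSAC, 3 px epipolar band and PnP, 4 px pruning) match
the measured localization precision of features on this texture (~0.9 px
median, ~1.8 px at the 90th percentile).

## CT volume processing

Threshold segmentation with interactive-editing equivalents: per-slice
brush add/remove, shape-based inter-slice interpolation (per-slice signed
distance transforms linearly interpolated along the slice axis and
thresholded at zero), largest-connected-component keep plus morphological
closing. Surfaces come from marching cubes at level 0.5 on the binary
grid after a light Gaussian pre-smoothing (σ = 0.8 voxels): the raw
staircase isosurface overestimates area by ~9%, the smoothed one is
accurate to ~1–3% (the raw grid is used when smoothing would erase a tiny
structure). Smoothing is Taubin's two-pass Laplacian (λ = 0.5, μ = −0.53,
10 iterations; volume drift ≤ 5%). World convention: voxel (slice i, row j,
col k) ↦ origin + (k·dx, j·dy, i·dz) mm; meshes and DICOM share this frame.
HU windows per structure are configuration values, not constants.

## Registration and evaluation

Landmark similarity fit (Umeyama) → affine fit (linear least squares,
the full 12-parameter model) → trimmed, landmark-anchored point-to-surface
ICP. The ICP details:

* correspondences by exact point-triangle distance on KD-tree-preselected
  candidate faces;
* the worst 30% of correspondences are trimmed each iteration, and points
  beyond 5× the median initial distance are gated out once (spurious
  reconstruction points);
* the seven landmark correspondences are added to every update with total
  weight equal to the surface term (a weighted points-and-surfaces
  registration). The bust surface is smooth and nearly left-right
  symmetric; pure surface ICP has sliding modes along it, and residual
  non-affine reconstruction warp would otherwise drag the transform off
  the landmark fit;
* a step that increases the mean trimmed distance is rejected and the
  iteration stops, so the recorded distance sequence is non-increasing.

Evaluation markers on the thermal model are obtained the way an operator
would click them: each marker's per-frame pixel position (in views where
it is visible) is triangulated with the *recovered* poses, using a trimmed
triangulation that rejects observations disagreeing grossly with the
consensus point. The displacement report uses the population standard
deviation (n divisor).

**Restart selection.** Among the reconstruction restarts the pipeline keeps
the one minimizing (affine landmark-fit RMS) + (landmark/surface
consistency: the mean distance the anchored ICP pulls the landmarks away
from their own fit). Both terms are computed purely from registration
inputs — the marker sets and the CT surface — and are the automated analog
of the operator's visual check that a manual alignment "looks right",
redoing it when it does not.

## The synthetic scene

All shapes are signed-distance-field primitives; meshes are extracted by
marching cubes (3 mm pitch) and the CT-like volume (1.5 mm voxels) is
voxelized from the same SDFs, so mesh/volume consistency holds by
construction. Defaults are the study conditions: head width 148 mm, neck
width 106 mm (average adult female dimensions), 12 views over 180° at
900 mm range, 320×240 frames at 500 px focal length, skin baseline 33 °C,
thyroid hotspot +1.5 °C (Gaussian falloff, σ = 25 mm), band-limited
high-frequency texture ±0.2 °C (wavelengths 10–30 mm, comfortably above
the mesh pitch so the vertex field represents them faithfully from every
viewpoint), ambient background 22 °C, per-pixel camera noise 0.05 °C
(typical detector NETD). The scene ("SfM") frame maps into the DICOM frame
by a fixed similarity (15° axial rotation + translation, scale 1), and the
seven markers are bust-mesh vertices nearest to anatomical anchors
(forehead, nose, chin, throat, left/right neck, sternum). All randomness
flows from one spec seed.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: physically based emission/reflection (no
emissivity or reflected-temperature effects), breathing or posture motion
between frames, lens distortion in the rendered frames (the projection
model supports Brown–Conrady distortion, the renderer defaults to zero),
CT artifacts beyond Gaussian noise, and anatomically accurate organ
shapes. Real thermal video also provides hundreds of frames where the
fixture provides 12; the sparse-view setting is the harder one for SfM.

## Numerical conventions and degenerate inputs

Camera frame x-right / y-down / z-forward; poses store world→camera.
Undistortion by 10 fixed-point iterations. Triangulation flags parallel
rays via the second-smallest singular value of the DLT system. The z-buffer
rasterizer interpolates 1/z linearly (perspective-correct); texture
sampling restricts the bilinear stencil to surface (finite-depth) texels
so silhouette samples never blend in the ambient background, with a 1 mm
depth tolerance against the buffer. Constant images pass through
intensification unchanged with a warning; empty masks, mixed DICOM series,
coplanar affine fits and collinear similarity fits raise typed errors.

## Problem sizes

The shipped configuration runs end to end in roughly 8 minutes on one CPU:
12 views at 320×240, ~300–450 features per frame, clouds of 600–900 points,
a ~250×300×190-voxel volume at 1.5 mm, and CT meshes of ~50k faces. All of
these scale with the `SceneSpec` parameters.

## Known limitations

* Reconstruction accuracy is bounded by feature localization on weak
  thermal texture; the residual cloud warp after bundle adjustment is a
  few millimetres at bust scale, part of which is non-affine and therefore
  survives registration.
* The affine model can absorb global warp modes but not bending; no
  non-rigid registration is attempted (out of scope by design).
* End-of-arc views are the least constrained (single-sided connectivity)
  and dominate the marker-error tail.
* The CLI's `run-all` orchestrates the synthetic study; applying the
  pipeline to real FLIR exports requires only the CSV dialect and a
  calibrated intrinsics JSON, but has, by the nature of this package,
  never been exercised on clinical data.
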