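# Methods

This note records the model behind `myofield`, the main numerical choices, and
the reasoning behind the design decisions that are not obvious from the code.
Parameter defaults live in `myofield/config.py`; every dataclass there can be
overridden from the YAML pipeline configuration.

## 1. Problem setting

The package reconstructs the three-dimensional fibre architecture of smooth
muscle from a stack of serial histological sections. Each section is a
stained colour image in which smooth-muscle nuclei appear as elongated dark
ellipses; the long axis of a nucleus tracks the local fibre direction. The
pipeline proceeds in stages:

1. **Nucleus extraction** (`nuclei`) — local colour thresholding and
   moment-based ellipse fitting.
2. **Regional classification** (`regions`) — aggregation into square regions
   labelled planar (in-plane fibres, with a median orientation), vertical
   (out-of-plane fibres), or empty.
3. **Rigid and elastic registration** (`rigid_reg`, `elastic_reg`) — stack
   alignment from edge images, then tile-wise warp refinement.
4. **Stack assembly** (`stack_assembly`) — grouping registered slides into
   isotropic voxel ranges and building one representative slide per range.
5. **3D direction assignment** (`direction3d`) — line-probe walks that lift
   the per-region 2D observations to headless 3D unit vectors.
6. **Voxel weights** (`weights`) — stereological density correction and a
   local homogeneity score.
7. **Segmentation** (`segmentation`) — anisotropy-guided watershed merging
   into fibre pools, in 2D per slide and in 3D on the assembled volume.
8. **Masks** (`masks`) — exclusion of vessels (red-blood-cell-rich voxels)
   and decidual/placental tissue (nucleus-dense voxels).
9. **Metrics** (`metrics`) — final smoothing, bundle-width sampling in 2D and
   3D, and equivalence statistics between width distributions.

Synthetic data generation (`fixtures`) is a first-class module: every stage
is validated against phantoms with exact ground truth.

## 2. Nucleus extraction

Nuclei are segmented by a local colour rule evaluated on 32 px windows: a
pixel is nuclear if its red value falls below 5/6 of the window mean red and
its blue value below the window mean blue. Connected components between 40
and 600 px are fitted with image-moment ellipses. Components are classified
by fitted area: smooth-muscle nuclei between 10 and 60 µm², small objects
below 14 µm² counted separately as likely red blood cells. The two bands
overlap deliberately (10–14 µm² objects contribute to both counts); the
small-object count is only used as a fraction for vessel masking, so the
overlap is harmless and avoids a hard boundary in a noisy size estimate.

## 3. Regional classification

Regions are 128 px squares (0.371 µm/px, so a region pitch of 47.488 µm).
Nuclei with aspect ratio above 2.0 vote planar; below 1.6 vote vertical;
the band in between votes for both. A region is vertical when the vertical
fraction exceeds 5/9, planar otherwise, and empty below a minimum count.
Planar regions carry the circular median of nuclear orientations (axial,
modulo 180°); if the orientation inter-quartile range exceeds 45° the region
is reclassified vertical, since an isotropic orientation distribution in the
section plane is the signature of fibres crossing it. Regions are placed on
a fixed padded frame so that all slides share coordinates.

## 4. Rigid registration

Registration works on Canny edge images (Gaussian σ = 3, hysteresis 50/30)
of the region-count image scaled by 20. A seven-step coarse-to-fine search
alternates an FFT-based translation vote with a rotation search over a grid
of candidate centres (pitch 50·step px; from step 2 onward centres stay
within 200 px of the step-1 optimum) and shrinking angular bounds (±180°,
±10°, ±5°, ±2.5°, ±1.25°, ±1°, ±1°). The objective is the number of moving
edge pixels falling within 1 px of a reference edge pixel. The 1 px
tolerance makes the score flat on a one-pixel plateau around the true
optimum; ties are broken toward the smaller translation, so recovered
translations are exact only up to one pixel, which is below the region pitch
and therefore immaterial downstream. Slides whose best alignment stays poor
are flagged `rigid_unregistered` and excluded.

## 5. Elastic registration

Each registered slide is divided into 16-region tiles. For each tile a
match energy e = 1 − matched/N is computed between moving and reference
regions; tiles with e ≤ 0.2 are left untouched. Poorly matching tiles are
first expanded along content (heterogeneity-bounded growth capped at a
(45°)² orientation variance), then a Hough search over rotations |θ| ≤ 30°
(1° classes) and translations |t| ≤ 16·e px selects the transform gathering
the most compatible region pairs, refined on a 3×3 neighbourhood. Nuclei are
warped by inverse-square-distance blending of the four surrounding tile
transforms, which keeps the warp continuous across tile boundaries.

## 6. Stack assembly

Voxels are isotropic at the region pitch. With a physical slide spacing of
9.5 slide-numbers per voxel, slide s belongs to range z when
z·9.5 ≤ s < (z+1)·9.5. Singleton ranges borrow the nearest slide outside the
range (ties toward the lower number); empty ranges borrow the nearest slides
below the maximum and above the minimum of their neighbours. Counts in the
representative slide are averaged with the borrow divisor so that borrowed
slides do not inflate density. The representative orientation is the value
minimising the median absolute axial deviation from the contributing slides.
Assembly optionally crops to the content bounding box.

## 7. 3D direction assignment

For every non-empty voxel p and candidate direction v, L(p, v) is the length
of the longest probe through p along v that stays inside compatible tissue.
The probe is a simultaneous two-arm walk with a shared stopping index, which
enforces the headless symmetry L(v) = L(−v) exactly. A step stops the walk
when it leaves the frame, enters an empty voxel, or fails a 30° continuity
test; the test compares the encountered voxel with the *running* bundle
direction (updated voxel to voxel), not with the fixed probe direction, so
probes may bend with curving bundles. For unassigned planar voxels only the
in-plane angle is compared — their elevation is unknown at walk time — and
for unassigned vertical voxels the probe must be steep (|φ| > 30°).

Planar voxels keep their measured θ and receive an elevation φ as the
length-weighted average over an elevation grid; vertical voxels search a
(θ, φ) grid with φ ∈ [30°, 90°]. Because the average pools inclined probes
whose lengths are comparable to the best one, assigned elevations
concentrate around, not exactly on, the true value; phantoms show interior
errors within 15° for slabs and within 30° (median ≤ 15°) for vertical
cylinders. Probes cap at l_max = 40 voxels. Voxels where no probe exceeds
the minimum length fall back to the category default and are marked
non-confident.

## 8. Voxel weights

The planar nucleus count underestimates true density when fibres leave the
plane: a fibre at elevation φ intersects the section less often in
proportion to its in-plane path. The corrected count is
N = min(n/(0.3·dz), n/0.1) with dz = |sin φ|, i.e. the correction saturates
at a factor 10. A trapezoidal density weight w_d ramps from 0 at N = 10 to 1
at N = 160. The homogeneity weight is the squared resultant length
w_h = |Σ v|²/n² of the doubled-angle direction vectors
v = (sin φc·cos 2θ, sin φc·sin 2θ, cos φc) over a neighbourhood, with φc the
colatitude; it is 1 for perfectly aligned neighbourhoods and ~1/n for
isotropic ones. The voxel weight is the product.

## 9. Segmentation

Segmentation is a watershed on a greyscale anisotropy index computed in
closed form. With a separable Gaussian kernel K (zero-padded) and weighted
headless directions, the index at voxel p is
Iw(p) = Σ_jk K(p−j)K(p−k) w_j w_k (2(v_j·v_k)² − 1), which is evaluated with
a handful of Gaussian smoothings of doubled-angle component maps rather than
the quadratic double sum. Pool merging uses the mean squared scalar product
between the Gaussian-weighted direction distributions of two pools,
f = E[(v_j·v_k)²] normalised so that coplanar fields give
f = (2cos 2Δ + 1 + 1)/4; pools merge when f exceeds 0.54 (2D) or 0.5 (3D).
Crossing fibre sheets at 60° stay separate (cos²60° < 0.5) while 30°
crossings merge, matching the anatomical expectation that gradual rotation
belongs to one sheet. The kernel scale adapts per slide by minimising
1.22σ² + ε² over σ ∈ [0.4, 4.0] in steps of 0.1, trading smoothing radius
against residual noise ε.

All closed forms are tested against brute-force double-sum oracles to 1e−9.

## 10. Masks

Vessels: voxels whose smoothed small-object (red-blood-cell) fraction
exceeds 0.5, grouped by 26-connectivity, kept at ≥ 9 voxels, then dilated by
one voxel. Placenta/decidua: nucleus density above 4500/mm² smoothed with a
Gaussian of σ = 4 on the binary map and hysteresis-thresholded at 0.3/0.6;
clusters below 10000 voxels are dropped. With σ = 4 the smoothed peak of a
compact seed only exceeds the 0.6 upper threshold when the seed extends
roughly 20 voxels per axis, so the mask responds to tissue-scale structures
rather than local density spikes.

## 11. Widths and equivalence

Bundle widths are sampled at random voxels along random directions
perpendicular to the local fibre direction; each arm steps in half-voxel
increments until the containing voxel leaves the pool, giving a chord length
in voxels converted to µm by the region pitch. 2D widths are measured on
per-slide planar maps, 3D widths on the assembled volume over a coarse grid
of sampling regions. Stepping overshoots by at most one step per arm, so a
width-10 phantom yields samples in [9, 12] voxels with the median on target.

Two width distributions are compared on log widths: a 95% confidence
interval for the mean log difference must fall within ±log(1.1) (mean
equivalence), and the two-sample Kolmogorov–Smirnov statistic's 90% upper
confidence bound must fall below the 95th percentile of the null KS
distribution (shape equivalence). Samples above 2000 are subsampled without
replacement to bound the test's sensitivity. The verdict is `equivalent`
only when both criteria hold, `not_equivalent` when the mean interval
excludes equality.

## 12. Synthetic data

`fixtures` generates every input the pipeline consumes:

- `render_slide` draws stained-image tiles with elliptical nuclei at
  controlled density, orientation field, and noise, for the extraction
  tests.
- `synth_regional_slide` produces regional slides directly from an
  orientation field (planar) and an elevation field (vertical regions).
- `blob_mask` and `patch_field` build organ-like cross-sections and
  piecewise-constant orientation mosaics.
- `distort_stack` applies known rigid transforms plus a smooth random
  elastic warp (band-limited displacement field normalised to a requested
  amplitude) and returns the exact ground truth for closure tests.
- `phantom_volume` builds labelled 3D geometries (slab, inclined slab,
  vertical cylinder, two orthogonal layers) with exact direction fields and
  known widths.
- `stereology_sample` Monte-Carlo-samples plane crossings of fibres at a
  given elevation, providing an independent oracle for the density
  correction.

All generators are deterministic given a seed; fixture sizes stay small
because everything is generated programmatically at test time.

## 13. Numerical and design decisions

- **Headless directions.** Fibre orientations have no polarity; all angular
  arithmetic is axial (modulo 180° in-plane, v ≡ −v in 3D). Sign alignment
  before averaging (`metrics.final_smooth`) prevents antiparallel
  cancellation.
- **Numba for the walks.** The line-probe assignment is the only hot loop
  not expressible with array operations; it is compiled with `numba.njit`.
  Everything else uses NumPy/SciPy/scikit-image primitives.
- **Zero-padded smoothing.** All Gaussian smoothings use zero padding
  (constant mode), which the closed-form identities require; weights absorb
  the boundary mass deficit where it matters via explicit renormalisation.
- **Determinism.** Every stochastic step takes an explicit seed or
  `numpy.random.Generator`; the pipeline derives all stage seeds from the
  single configuration seed, so identical configurations produce
  byte-identical artifacts (verified in the test suite).
- **Plateau tolerance in rigid search.** The 1 px coincidence tolerance is
  kept (rather than a sub-pixel objective) because it makes the score robust
  to rasterisation of edges; the resulting ±1 px ambiguity is two orders of
  magnitude below the region pitch.
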