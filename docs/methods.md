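# Methods

This note documents the model behind `nuclei3d`, the parameters that matter,
the numerical choices made where the design was genuinely open, what the
synthetic specimens do and do not emulate, and the known limitations.

## Imaging model and assumptions

The pipeline assumes fluorescence z-stacks of DAPI-stained nuclei of
adherent cells: bright, compact, roughly ellipsoidal objects over a dim
background, possibly touching in clusters, with intensity fading gradually
with scanning depth and a background noise level that may trend across the
field. Stacks are shallow relative to their lateral extent (tens of optical
sections versus >1000 px laterally) and voxels are anisotropic (~2× coarser
along Z). All grids are indexed `(z, y, x)`, matching page-major TIFF
storage; when a file carries no spacing metadata the loader assumes
250 nm × 120 nm × 120 nm.

The method is threshold-based at heart, so its one hard premise is that
background stays below ~10 % of the stack's maximum intensity. Where that
fails (see *Limitations*) no global threshold exists and the output degrades.

## Threshold estimation

* `n_level = 0.05` — width of the scanned noise band, as a fraction of
  I_Max. The noise-band estimator assumes background noise occupies a narrow
  intensity band; it counts voxels in the open band
  ((Th − n_level)·I_Max, Th·I_Max) for Th ∈ {0.05, 0.10, 0.15, 0.20} and
  returns the fullest band's upper fraction. Ties go to the smallest
  candidate (least aggressive removal). Both bounds are strict.
* The triangle threshold is computed on the full histogram (256 bins for
  8-bit input, 4096 otherwise, native quantisation) in raw (bin, count)
  coordinates: the threshold bin maximises the perpendicular distance to the
  line from the histogram peak to the far end of its longer tail. Note that
  triangle thresholds are not invariant to axis scaling; this implementation
  deliberately uses the unnormalised geometry and its test oracle does the
  same exhaustive search.
* `th_int1 = min(max(noise_band, triangle), th_int2)`: the final first-pass
  fraction honours whichever estimator is higher but never exceeds the
  second-pass fraction `th_int2 = 0.10`, past which thresholding starts to
  eat nuclear structure. The cap also guarantees the documented invariant
  `th_int1 ≤ th_int2` when the band scan elects 0.15 or 0.20.

## Block grid and volume units

The stack is halved in X/Y (nearest neighbour, floor) and averaged over
non-overlapping 3×3×3 blocks; edge blocks are padded by edge replication so
the grid shape is `ceil(shape/3)` per axis. Classification is strict
(`mean > I_Max·th`), making foreground monotone non-increasing in the
threshold.

Structures are measured on the block grid, but the volume bounds of the
single-nucleus test are defined on the *reduced-stack* voxel count
(`vol_min = 5·10⁻⁶·|Im|`, `vol_max = 2·10⁻²·|Im|`); block-grid voxel counts
are converted by ×27 before comparison. Sphericity and solidity are
scale-free, so only the volume bound needs the unit bookkeeping.

## Morphometry

* Volume = voxel count; solidity = voxel count / rasterised convex-hull
  voxel count. The hull is rasterised from the voxel centres
  (`offset_coordinates=False`); the half-voxel outward padding of the
  scikit-image default would push a digital ball's solidity down to ~0.91
  and make the 0.95 gate unreachable for genuinely convex nuclei.
* Surface area comes from a triangulated isosurface of the binary mask at
  level 0.5 (marching cubes). Face counting would overestimate a sphere's
  area ~1.5×; the mesh's residual bias is much smaller but real and worth
  stating plainly: the staircase of a binary isosurface inflates a digital
  ball's area by a scale-free ~7–8 % (sphericity ≈ 0.92–0.93 at radii
  6–24), and the mesh bevels sharp edges by half a voxel, deflating an
  axis-aligned cube's area by ≈ 0.59/a (sphericity 0.839 instead of the
  analytic 0.806 at a = 15). Smoothing-based estimators (smoothed-field or
  signed-distance meshes, Crofton counts, gradient/coarea integrals,
  Minkowski dilate–erode differences) remove the sphere bias but necessarily
  misread sharp edges over at least a one-voxel band and fare worse on flat
  geometry; since the 0.85 sphericity gate only needs consistency, not
  unbiasedness, the plain mesh is used and the gate values were tuned for it.
* Tiny structures (a few voxels) have no meaningful mesh; their sphericity
  can exceed 1. They fall below `vol_min` and are removed by the debris
  filter, so the pathology is harmless in the pipeline.

## Cluster splitting

The splitting map is `dist23 = dist2 + 2·dist3`, with `dist2` the slice-wise
2D Euclidean distance transform and `dist3` the full 3D one, unit metric.
A plain 3D EDT in a shallow stack is dominated by the short Z extent and
stops reflecting in-plane nucleus size; the slice-wise term (with double
weight on the 3D term) restores a usable size signal. Everything outside the
array counts as background — a structure touching the stack border is cut
there, which is also the physically correct reading.

Seeds grow over a descending threshold schedule from `dist_MaxTh` (map
maximum over the cluster) to `dist_MinTh = 0.5·dist_MaxTh` in steps of 0.2
distance units (typical clusters take ~10–25 iterations). At each level the
connected components of the super-level set are matched against the live
seeds:

* a component containing an existing seed's anchor (its birth peak voxel) is
  that seed's grown region;
* a component containing none is compared to every seed by the
  centroid-distance rule — it is *new* iff its centroid is at least the two
  regions' combined extents away from every seed, where a region's extent at
  level t is its peak value minus t (a super-level component around a peak
  of height v reaches roughly v − t from its centre). Otherwise it is
  absorbed by the nearest seed.

Two numerical guards deal with discretisation noise on the blocky maps:
components smaller than 2 voxels are ignored, and a newborn seed stays
*provisional* until it has persisted alone over ≥ 1.0 dist23-units of
descent (about half a 3D-EDT voxel). A provisional seed whose region merges
with a stronger one before confirmation was a plateau ripple and is
discarded; confirmed seeds are never destroyed — when two confirmed regions
meet (a genuine saddle between nuclei), both survive. Without these guards,
plateaus in the quantised map register twin seeds and single nuclei get
split.

The final seeds initialise a marker-controlled watershed on `−dist23`
(26-connectivity) restricted to the cluster. The split is then verified
against the cluster's own size range: `dist_MinTh` is by construction the
smallest distance-transform size of a nucleus in the cluster, so every
watershed part must itself reach it (its own modified-distance peak ≥
`dist_MinTh`). Parts that stay below are slivers carved off by spurious
seeds; their seeds are dropped and the watershed re-run with the survivors.

## Pipeline control flow

Per 26-connected structure of the first-pass grid: a structure passing the
shape test is accepted; a group is seeded and, with ≥ 2 seeds, split into
sub-nuclei that are all accepted; with one seed it is accepted if not
oversized, and otherwise re-thresholded locally at `th_int2·I_Max` (global
I_Max, local region) — the shrunken components re-enter the same routine
once. Whatever still resists division is accepted unsplit. Termination is
structural: two threshold levels, and each split strictly shrinks
components. Voxels of a re-thresholded group between the two thresholds
return to background; border refinement at full resolution recovers part of
that rim. Debris below `vol_min` is removed after both passes, then labels
are renumbered 1..K.

A threshold that removes almost nothing (> 90 % of blocks foreground at both
passes) means there is no bright structure over background at all — an empty
or noise-only field. The pipeline then returns an empty result with a
warning rather than one field-sized "nucleus". Relative to its own maximum,
a pure-noise volume survives any capped threshold, so no histogram rule can
produce the empty answer by itself.

The segmentation path contains no randomness; identical input and
configuration give bitwise-identical labels.

## Border refinement

Upsampling is two-stage nearest neighbour (×3 on all axes to the reduced
grid, then ×2 in X/Y), leaving a surface contour ~3 voxels thick. The shell
is defined as labelled voxels within 3 erosion steps (26-connectivity) of
*background* — voxels facing a neighbouring nucleus are interior for this
purpose and are never reassigned. Per nucleus, `NC_MeanInt` is the mean
original-resolution intensity over the interior; a shell voxel survives iff
its intensity exceeds `i_th·NC_MeanInt` with `i_th = 0.3` (higher values eat
real nucleus volume; lower ones change little). The mask can only shrink.
If trimming disconnects a nucleus, the largest 26-connected piece is kept.
A nucleus with no interior (thinner than twice the shell) is left
unrefined. On the synthetic study the refinement lifts the mean Jaccard
from ≈ 0.59 to ≈ 0.89.

## Evaluation protocol

Expert nuclei are processed in descending area. A nucleus is TP when a
single algorithm label covers > 50 % of its area (coverage measured relative
to the expert mask); each label is claimable once, and a label that has
claimed a nucleus is not re-checked against others — further nuclei under it
are under-segmentation FNs. All unclaimed labels on the evaluated layer are
FPs, which makes FP = (labels) − TP and reproduces the published count
arithmetic. The mean Jaccard averages over matched pairs only; with no
matches the ratio metrics are NaN, not zero. The matcher is
dimension-agnostic: the same code scores the 2D expert layer and full-3D
synthetic ground truth.

## Synthetic specimens

Defaults describe the desk-scale study conditions used by the tests and the
acceptance script: 30×256×256 voxels, 20 nuclei at low confluency, semi-axes
5–8 (Z) and 14–20 (X/Y) voxels, 12-bit intensities 1200–3600, multiplicative
Z-attenuation 0.985 per section, Gaussian blur σ = (0.5, 1, 1) voxels, and
uniform noise at 5 % of the reference intensity. These mirror the target
data qualitatively: at the real scale a nucleus spans ~40 blocks across;
here it spans ~5–7, which makes the desk problem *harder* per nucleus (all
discretisation guards above were designed against this). Confluency controls
the minimum centre spacing in units of summed semi-axes (low 1.10,
moderate 0.80, high 0.55); placement retries are bounded and an overcrowded
spec raises rather than silently degrading.

Orientation is free in the imaging plane with only a small (±0.15 rad)
out-of-plane tilt: nuclei of slide-grown cells are oblate with the short
axis along the optical axis. Unconstrained 3D rotation would produce
edge-on ellipsoids that no monolayer specimen contains. Overlap voxels are
assigned to the nearer centre in ellipsoid-normalised metric, so the labels
partition the rendered foreground exactly. The directional noise model adds
a linear ramp along a chosen axis (default Z, the documented trend
direction) on top of the uniform term.

Not emulated: chromatin texture, a physically accurate confocal PSF,
spherical aberration, or inter-cell intensity bleed. Passing tests therefore
demonstrate the pipeline's geometry and control flow, not photometric
realism.

## Problem sizes

The test suite and acceptance script run on 30×256×256 stacks (20 nuclei,
5 seeds), fused-ball clusters up to 10 balls of radius 8 (≈ 40×40×130
voxel boxes), and oracle volumes of 14³–32³. These sizes keep every stage's
behaviour observable — multiple blocks per nucleus, genuine cluster fusion,
non-trivial histograms — while a full suite run takes well under a minute.

## Limitations

* An in-plane background ramp that pushes background beyond 10 % of I_Max
  defeats any global threshold; the band estimator then picks a compromise
  and residual background survives to the local passes. The Z-trend case is
  handled (the band estimator raises the threshold to the cap), the steep
  X/Y-trend case is not.
* Deep multi-nucleus clusters at high confluency under-split when their
  interior distance map fuses (detection recall degrades to ~0.6–0.8 at
  the desk scale's small relative nucleus size, while precision stays
  ≈ 1.0).
* The second pass accepts its shrunken shapes; rim voxels between the two
  thresholds are only partially recovered by refinement.
* Sphericity carries the mesh estimator's documented discretisation bias;
  the 0.85 gate is calibrated for that estimator and should be retuned if
  the surface measure is swapped.
* Evaluation against 2D expert layers (the published protocol) only samples
  delineation at one optical section; the synthetic path also scores full
  3D overlap, real data usually cannot.
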