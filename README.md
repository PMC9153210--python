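# nuclei3d

Fully automatic 3D segmentation of cell nuclei in confocal z-stacks, built
for high-content screening (HCS) workflows where fluorescence per cell must
be quantified across whole 3D specimens. The package targets DAPI-stained
nuclei imaged as multi-page TIFF stacks (typically ~1576×1576 px × 35–50
optical sections, anisotropic voxels of about 120×120×250 nm) and is robust
to the usual nuisances of such data: variable cell confluency, drug-induced
shape changes, fluorescence fading with scanning depth, and background noise
that trends across the field or along Z.

## The algorithm

The pipeline runs entirely in 3D, at three scales:

1. **Background elimination (global, reduced scale).** The stack is halved
   in X/Y (nearest neighbour) and partitioned into 3×3×3-voxel blocks whose
   mean intensities form a working grid. Two automatic estimators set the
   global threshold: a *noise-band* scan that, for candidate fractions
   Th ∈ {0.05, 0.10, 0.15, 0.20} of the maximum intensity I_Max, counts
   voxels inside the open band ((Th − 0.05)·I_Max, Th·I_Max) and picks the
   fullest band, and the classical *triangle* method on the intensity
   histogram. The first-pass threshold is Th_Int1 = max of the two, capped
   at Th_Int2 = 0.10·I_Max, beyond which thresholding starts to destroy
   nuclear structure. A block is foreground iff its mean exceeds
   Th_Int1·I_Max.

2. **Single-vs-group classification and splitting (local).** Each
   26-connected structure is measured: volume V, surface S, sphericity
   Ψ = (36π V²)^(1/3) / S, and solidity V / V_convex. A structure is a
   single nucleus (NC_S) iff solidity ≥ 0.95, Ψ ≥ 0.85 and
   5·10⁻⁶·|Im| ≤ V < 2·10⁻²·|Im| (|Im| = voxel count of the reduced
   stack). Everything else is a group (NC_G) and is split on a modified
   distance map `dist23 = dist2 + 2·dist3` (per-slice 2D EDT plus twice the
   3D EDT, compensating the Z-compression of shallow stacks). Seeds are
   grown by scanning thresholds from dist_MaxTh down to
   dist_MinTh = 0.5·dist_MaxTh in steps of 0.2, tracking each emerging peak's
   identity between iterations; the final seeds drive a marker-controlled 3D
   watershed. Groups that refuse to split yet exceed the volume ceiling are
   re-thresholded locally at Th_Int2·I_Max and re-enter the same loop.

3. **Border refinement (original scale).** Labels are upsampled back to the
   original grid (nearest neighbour), which leaves a blocky surface shell;
   each shell voxel is kept only if its intensity exceeds
   I_Th · NC_MeanInt = 0.3 × the nucleus' interior mean. The shell can only
   shrink — refinement never claims new voxels.

Accuracy is scored the way HCS practitioners do: an expert nucleus counts as
detected (TP) when one algorithm mask covers more than 50 % of its area; a
label that has claimed one nucleus is not re-checked against others.
Precision, recall, F1 and the mean per-nucleus Jaccard index (JI) follow
from the matching.

Because the original Zenodo image set is not required, the package ships a
synthetic specimen generator (`nuclei3d.synthetic`) that renders oblate
ellipsoidal nuclei with exact per-voxel ground truth, depth attenuation,
confocal-like blur and uniform or directionally trending noise — every stage
and the whole pipeline are testable at desk scale.

## Worked example

```python
from nuclei3d import (SpecimenSpec, generate_specimen, segment,
                      match_labels, compute_metrics)

spec = SpecimenSpec(seed=1)                       # 30x256x256, 20 nuclei
volume, truth, gt_layer = generate_specimen(spec)

result = segment(volume)
print(f"thresholds: Th_Int1={result.thresholds.th_int1:.3f} "
      f"Th_Int2={result.thresholds.th_int2:.3f} I_Max={result.thresholds.i_max}")
print(f"nuclei detected: {result.n_nuclei} (true: {truth.n_labels})")

report = compute_metrics(match_labels(result.labels.labels, truth.labels))
print(f"precision={report.precision:.3f} recall={report.recall:.3f} "
      f"F1={report.f1:.3f} JI_avg={report.ji_avg:.3f}")
```

prints

```
thresholds: Th_Int1=0.050 Th_Int2=0.100 I_Max=3652
nuclei detected: 20 (true: 20)
precision=1.000 recall=1.000 F1=1.000 JI_avg=0.888
```

Both estimators settle on the 5 % floor for this clean specimen, all 20
nuclei are recovered one-to-one, and the refined masks overlap the ground
truth at a mean Jaccard of 0.89 (without border refinement it drops to
about 0.59 — the blocky upsampled masks overshoot the true surfaces).

The same is available from a shell:

```sh
nuclei3d synth --out-prefix demo --shape 24 192 192 --n-nuclei 12 --seed 3
nuclei3d segment --input demo_intensity.tif --output demo_labels.tif
nuclei3d eval --labels demo_labels.tif --gt demo_gt.png --layer 12 \
              --report report.json --overlay overlay.png
```

`segment` accepts a YAML config with every pipeline parameter
(see `nuclei3d.pipeline.PipelineConfig`) and a `--no-refine` switch that
trades a little delineation accuracy for speed.

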