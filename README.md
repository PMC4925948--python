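# angio3d

Patient-specific 3D coronary-vessel surface models from **two monoplane X-ray
angiogram projections**.

Given a pair of grayscale angiograms with their C-arm acquisition geometry
(SID, pixel size, gantry angles) and user-selected start/end points per vessel
segment, the pipeline runs four stages:

1. **Centreline extraction** (`angio3d.enhance`, `angio3d.centerline`) —
   multiscale Hessian-eigenvalue vesselness, hysteresis thresholding,
   skeletonization with bifurcation/end-point detection, shortest-path segment
   extraction between the (snapped) user points, and sub-pixel spline
   smoothing that excludes bifurcation pixels.
2. **Wall delineation** (`angio3d.walls`) — dynamic programming over candidate
   nodes on normals to the centreline (10 per side by default), maximizing a
   merit that combines gradient-magnitude reward, a first/second-derivative
   ratio consistency term and squared edge-direction changes, traded off by a
   `beta` hyperparameter (default 0.75).
3. **3D reconstruction** (`angio3d.recon`) — epipolar correspondence between
   the two projected centrelines with monotone matching and bifurcation
   anchors, midpoint triangulation, iterative re-matching to remove
   foreshortening, and radius estimation from the back-projected wall curves
   (circular cross-section assumption).
4. **Surface generation** (`angio3d.recon`) — discrete Frenet frames (with a
   parallel-transport fallback on straight runs), per-point curvature and
   torsion, circular-ring tube meshing, and STL/OBJ export.

`angio3d.validate` implements the evaluation machinery (Hausdorff curve
distance and EM fusion of multiple annotators' binary edge labels with
per-annotator confusion matrices / ROC points), and `angio3d.phantom`
generates synthetic vessels (line / arc / helix / branched, optional stenosis)
with rendered cone-beam projection pairs and full ground truth, so the whole
pipeline is testable without clinical data.

## CLI

```sh
# render a synthetic projection pair with ground truth
angio3d phantom --kind helix --stenosis-severity 0.5 --out-prefix ph

# inspect enhancement / pick points
angio3d enhance ph_A.png --out skeleton.png
angio3d centreline ph_A.png --start 60 50 --end 200 180 --out cl.csv
angio3d walls ph_A.png --centreline-csv cl.csv --out walls

# full four-stage run from a YAML config
angio3d run --config run.yaml --seed 0

# multi-annotator label fusion
angio3d validate --annotations labels.csv --out report.json
```

A run config lists the two images, per-view geometry
(`sid_mm`, `pixel_size_mm`, `primary_angle_deg`, `secondary_angle_deg`,
`image_shape`, optional `sod_mm` / `translation_mm`) and one or more segments
with per-view start/end pixel coordinates; outputs are an STL/OBJ mesh and a
CSV of centreline coordinates, radius, curvature and torsion per segment,
plus a JSON manifest of all parameters.

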