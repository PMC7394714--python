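# leafct

Random-forest segmentation and 3D anatomical trait quantification for X-ray
microCT scans of plant leaves.

## The problem

Synchrotron microCT resolves the full 3D internal anatomy of a leaf — the two
epidermes, the mesophyll cells and their interconnected airspace, and the
veins with their bundle sheaths — but grayscale alone can only separate
water-filled tissue from air. Every tissue beyond cell/air historically had
to be hand-drawn slice by slice, taking up to a day per scan and limiting
studies to a handful of leaves. `leafct` replaces that bottleneck with a
per-scan trainable pixel classifier: label a handful of slices by hand
(typically six out of ~2000), train a random forest on them, and let it
segment the rest of the stack, then extract the anatomical traits
physiologists actually need.

## Method

For a scan the package expects two co-registered 8-bit reconstructions of the
same leaf: a *gridrec* (absorption) volume with sharp cell interfaces and a
*phase-contrast* (Paganin) volume with strong cell/air contrast, plus sparse
hand-labeled slices. The pipeline:

1. **Binarize and combine** — each modality is thresholded (intensity ≥ t is
   cell, below is air) and the two cell masks are combined (union by default).
2. **Local thickness** — from the binary stack, each voxel gets the diameter
   (in voxels) of the largest sphere inscribed in its phase that covers it
   (Hildebrand–Rüegsegger, computed exactly via squared Euclidean distance
   transforms). This encodes 3D structure size, e.g. veins vs cell walls.
3. **Feature layers** — per slice: multi-scale Gaussian blurs and square-window
   variance filters of the two raw images, of their Sobel gradient magnitudes
   and of a top/bottom edge-distance map, plus the raw intensities and the
   local-thickness slice.
4. **Random forest** — a fresh 50-tree forest (scikit-learn) is fitted per scan
   on the labeled pixels of the selected training slices, then predicts every
   remaining slice, streaming slice by slice so a whole scan fits in ordinary
   workstation memory. The estimator (`LeafSegmenter`) follows the sklearn
   fit/predict API and composes with sklearn tooling.
5. **Anatomy-aware corrections** — only the two largest similar-volume
   epidermis components are real (assigned adaxial/abaxial by position;
   speckles become mesophyll cell); vein/bundle-sheath components below
   27 voxels are noise and are removed. If the epidermes come out merged the
   stack is flagged and side-specific traits are withheld.
6. **Traits** — thickness of the leaf, mesophyll and each epidermis measured
   over every (z, x) voxel column (mean ± SD, µm); per-tissue volumes by voxel
   count (µm³); mesophyll surface area exposed to the airspace by marching
   cubes with anisotropic voxel spacing (µm²); porosity = airspace fraction of
   the mesophyll region.

An evaluation module reproduces the standard validation design: train on
n = 1…12 randomly chosen labeled slices, repeat 30×, predict the held-out
labeled slices, and tabulate per-class precision/recall from confusion
matrices (recall_k = M_kk/Σ_j M_kj, precision_k = M_kk/Σ_i M_ik), plus trait
stability across full-stack predictions.

Because real scans are large external downloads, the package ships a
synthetic leaf **phantom**: a slab with two epidermis layers, spherical-void
airspace carved to a target porosity, z-running veins wrapped in bundle-sheath
rings, gentle lamina undulation, rendered into both noisy modalities with a
voxel-exact truth stack and closed-form trait expectations. Every stage of
the pipeline is tested against it and against brute-force oracles.

## Worked example

```python
from leafct import (PhantomSpec, generate, hand_label_sim, binarize_and_combine,
                    local_thickness, FeatureConfig, assemble_training_table, train,
                    predict_stack, apply_corrections, compile_report)

spec = PhantomSpec(shape=(24, 64, 64), epidermis_thickness=4, mesophyll_thickness=40,
                   vein_count=2, vein_radius=4, sheath_thickness=2,
                   void_radius_range=(2, 5), undulation_amplitude=(3, 2), seed=11)
bundle = generate(spec)                                  # two modalities + truth
labels = hand_label_sim(bundle.truth, 8)                 # 8 "hand-labeled" slices
binary = binarize_and_combine(bundle.gridrec, bundle.phase, t_grid=72, t_phase=90)
lt = local_thickness(binary, "cell")
cfg = FeatureConfig(gaussian_sigmas=(1, 2, 4), variance_windows=(3, 5))
idx = labels.labeled_slice_indices[:4]
table = assemble_training_table(bundle.gridrec, bundle.phase, lt, labels, idx, cfg)
model = train(table, bundle.truth.class_map, cfg, seed=7, slice_indices=idx)
pred = predict_stack(model, bundle.gridrec, bundle.phase, lt)
report = compile_report(apply_corrections(pred))
```

which prints, formatted:

```
leaf thickness:  15.66 +/- 0.16 um  (truth 15.60 um)
porosity:        0.357  (truth 0.355)
mesophyll area:  661 um2
vein volume:     40.0 um3  (truth 40.4)
flags:           none
```

The segmentation recovers the phantom's leaf thickness within 0.4%, porosity
within 0.002, and vein volume within 1% from four training slices.

## Command line

The same workflow is scriptable from a shell (`leafct --help`):

```bash
leafct phantom --spec spec.yml --out phantom/         # synthetic test scan
leafct segment --config run.yml                       # train + predict + correct
leafct traits --labels out/corrected.tif --spacing 0.1625 0.325 0.325 --out traits.csv
leafct evaluate --config run.yml --n-max 12 --reps 30 # precision/recall study
```

`run.yml` carries paths, thresholds, feature scales, training settings and one
base seed; every run writes a `provenance.json` sufficient to reproduce it.

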