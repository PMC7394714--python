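# Methods

This note documents the models, conventions and numerical choices behind
`leafct`, and what its synthetic tests do and do not demonstrate.

## Geometry and conventions

All volumes are `(z, y, x)` arrays: `z` is the slice index, `y` the image row
(the adaxial–abaxial axis for an upright-mounted leaf), `x` the column.
Indices are 0-based, ranges half-open. Voxel spacing is per axis in µm; the
default `(0.1625, 0.325, 0.325)` corresponds to a 40× synchrotron scan whose
x/y dimensions were halved for tractability (block-mean for grayscale,
block-mode with ties to the smallest code for labels) while keeping full z
resolution. Tissue classes are `background=0, epidermis_adaxial=1,
epidermis_abaxial=2, mesophyll_cell=3, airspace=4, vein=5, bundle_sheath=6`;
sparse hand-labeled stacks mark unlabeled voxels with the sentinel
`max(code)+1`, which never enters training or prediction.

## Binarization

A voxel is *cell* in one modality iff intensity ≥ threshold; ties go to cell.
The two cell masks are combined by `union` (default), `intersection`, or
`mean_rethreshold` (mean image against mean threshold). The rule is a
parameter rather than a constant because practice varies between labs;
thresholds are user inputs chosen by eye, not automated.

## Local thickness

Definition (Hildebrand–Rüegsegger): the thickness at voxel v is the diameter
of the largest sphere fully inside the phase that covers v. Spheres are
rasterized with integer radius r as `{u : ||u−c||² ≤ r²}` and the diameter is
reported as `2r+1` voxels, so an isolated voxel has thickness 1 and an
n-voxel slab has thickness n through its interior. The phase ends at the
volume border.

Algorithm: squared EDT of the phase gives each candidate center its largest
inscribed radius `r(c) = ⌊√(sedt(c)−1)⌋`; radii are then visited in
descending order, and all voxels within distance r of a radius-r center
(found with one complementary EDT per distinct radius) receive `2r+1` unless
already assigned. Because radii descend, the first assignment is the
maximum; the test suite verifies voxel-exact agreement with a brute-force
enumeration oracle on dozens of random ≤16³ volumes. Voxels are treated as
isotropic even under anisotropic spacing — values are in voxel units and are
used as a relative size feature, not a physical length; traits that need µm
apply spacing explicitly.

## Feature layers

Per slice, base images = {gridrec, phase, Sobel magnitude of each, and the
edge-distance map `min(row, H−1−row)`}; each is filtered with Gaussian blurs
(default σ ∈ {2,4,8,16,32,64} px) and square variance windows (default
{3,9,17} px); raw gridrec, raw phase and the local-thickness slice are
appended. Borders are reflected; values are float32 and never rescaled (tree
ensembles are scale-invariant). The default scale ladder spans cell-wall to
vein scale at 0.325 µm/px and is fully overridable; `FeatureConfig.fast()`
(σ ∈ {2,4,8,16}, windows {3,9}) is used for volumes ≲256 px across, where
the largest default scales exceed the image. The edge-distance map is kept
in raw pixels (not normalized by height); features are strictly 2D per slice
apart from the 3D-derived local-thickness layer.

## Classifier

`LeafSegmenter` wraps a scikit-learn `RandomForestClassifier` (50 estimators
by default, optional out-of-bag scoring and warm-start growth, library
defaults for per-node feature subsampling, all recorded in model metadata).
Training uses every labeled pixel of the selected slices — no subsampling —
and no class reweighting by default, so the natural class imbalance of leaf
anatomy (rare, thin tissues are harder) is reflected in the results;
balanced weights are available behind a flag. Prediction streams slice by
slice (peak memory ≈ one slice × layers) and ties between class votes
resolve to the lowest class code, making runs bit-reproducible given the
seed. Models are deliberately per-scan: transfer between scans is out of
scope.

## Post-prediction corrections

*Epidermis rule*: all epidermis-labeled voxels are pooled; if the two largest
connected components (26-connectivity by default, tolerant of slice-to-slice
jitter from 2D prediction) have volume ratio ≤ 5 they are kept and assigned
adaxial = lower mean row (flag-flippable), everything else becomes mesophyll
cell. Otherwise — merged or wildly unequal epidermes, the typical one-or-two
training-slice failure — the stack is flagged `epidermes_connected`, left
untouched, and side-specific thickness traits are withheld as NaN.
*Small-volume rule*: vein/bundle-sheath components with fewer than 27 voxels
(a 3³ cube) are reassigned to mesophyll cell; exactly-27 survives ("below").
Reassignment to mesophyll cell (rather than deletion) conserves the voxel
count; both rules are idempotent.

## Traits

Thickness is counted along y per (z, x) voxel column × spacing_y; columns
without the tissue are excluded from the mean/SD (computed over columns).
There is no surface-normal correction, so a bowed lamina biases thickness
slightly upward — accepted, and buffered by averaging millions of columns.
Volumes are voxel counts × voxel volume; their sum over all classes equals
the stack volume exactly. Mesophyll surface area: the binary cell mask is
smoothed with a σ = 0.8 voxel Gaussian (removing the voxelization staircase
that otherwise inflates a digital sphere's area by ~8%; residual error on a
radius-20 sphere is ~0.05%), triangulated by marching cubes at level 0.5
with the anisotropic spacing, and only faces whose centroid voxel touches an
airspace voxel within its 26-neighborhood are summed — interfaces with
epidermis, veins, sheaths or background contribute nothing. Porosity =
airspace / (airspace + cells + veins + sheaths), i.e. the mesophyll region
(leaf minus epidermes). Projected leaf area counts (z, x) columns containing
any leaf tissue.

## Evaluation design

`cross_validate(n_range, reps, base_seed)` draws, for each cell (n, rep), n
training slices uniformly without replacement from the labeled set using a
child seed spawned as `SeedSequence(base_seed, spawn_key=(n, rep))` — any
cell is re-runnable in isolation. The model predicts all held-out labeled
slices; per-class precision/recall come from the confusion matrix over
labeled pixels, with zero denominators reported as missing (NaN) and
excluded from medians rather than coerced to 0. Raw predictions are
evaluated — corrections are deliberately not applied here. Rows are emitted
for each split class and for merged `epidermis` and `vein_bundle_sheath`
classes, the merged views being the ones usually reported (the two epidermis
sides are rendered identically and are later assigned by position anyway).
`trait_stability` runs full-stack predictions per (n, rep), applies the
corrections, and tabulates the trait report against n.

## The phantom

The generator emulates a laminar leaf in air: two epidermis slabs around a
mesophyll, airspace carved by random spherical voids until measured porosity
is within ±0.02 of the target, z-running veins wrapped by bundle-sheath
rings, all rendered twice (absorption-like and phase-like optics, the latter
with larger cell/air contrast) as class mean intensity + Gaussian noise +
blur. Three realism choices matter:

- **Undulation**: the lamina's vertical position varies sinusoidally along z
  and x (integer per-column offsets, default amplitudes 8 and 4 voxels).
  Real laminas are never flat, and this is what makes a single training
  slice unrepresentative of the stack — without it, any one slice predicts
  all others perfectly and the training-slice-count experiment is vacuous.
  Integer offsets shift whole columns, so the closed-form thickness
  (2·epidermis + mesophyll) × spacing_y stays exact.
- **Void gradient**: void density ramps linearly toward the abaxial side
  (spongy mesophyll below, denser palisade-like tissue above), as in real
  dicot leaves; the resulting context asymmetry is the only cue separating
  the two identically rendered epidermis layers, as in real scans.
- **Presets**: the default ("easy") intensities are well separated —
  appropriate for end-to-end parameter-recovery tests. The "hard" preset
  gives all water-filled tissues nearly identical intensities (gaps of ~4–5
  gray levels at noise SD 10), as in real scans where epidermis, mesophyll
  and vasculature are the same material; classification must then rely on
  structural context, which reproduces the qualitative behavior of real
  validation: background/cell/air recall high from 1–2 slices, epidermis
  needing several slices, vasculature hardest.

Background and internal airspace share one intensity (they are the same air);
the edge-distance and local-thickness features disambiguate them. The
phantom does not simulate reconstruction physics (ring artifacts, phase
fringes), real cell-wall geometry, or stomata — so passing tests demonstrate
the pipeline's correctness and its qualitative training-slice behavior, not
segmentation accuracy on any particular real scan.

Simulated hand labeling takes n evenly spaced slices of the truth stack
(mirroring the practice of labeling ~24 slices spread evenly over ~1900).

## Problem sizes used by the test suite and acceptance script

End-to-end parameter recovery runs on the full default phantom
(200×256×256, 6 labeled slices, `FeatureConfig.fast()`, 50 trees): recovered
leaf thickness within 2%, per-class volumes within 5%, porosity within 0.03,
and background/cell/air held-out recall ≥ 0.90 from 3 training slices. The
training-slice scaling study runs on a 64×128×128 hard-preset phantom with
12 labeled slices, n ∈ {1,3,5}, 5 repetitions (and n ∈ {1,4} for trait
stability) — large enough to exhibit the epidermis-recall increase and the
shrinking trait spread, small enough for a single CPU in minutes. Unit tests
use ≤24³–64³ volumes and brute-force oracles.

## Known limitations

- 2D per-slice prediction causes slice-to-slice inconsistencies on inherently
  3D structures (veins vanishing between slices); the corrections mitigate
  but do not fix this, and no 3D smoothing is attempted.
- Thickness is measured along the mount axis, not the local surface normal.
- Local thickness ignores voxel anisotropy (voxel units by design).
- Airspace tortuosity / diffusive path-length analyses are out of scope.
- Models never transfer between scans; each scan needs its own labels.
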