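# Methods

This note documents the models, defaults and numerical choices behind
`ricecanopy`, and what the synthetic-data-based tests do and do not
establish about real canopies.

## Geometry

**Leaf blade.** The blade is parameterised by arc position z along the
midrib, z ∈ [0, L]. Width follows `w(z) = w_max·[1 − (2(z/L − 0.5))²]`
(zero at base and tip, maximum at mid-length) and droop displaces each
station by `y(z) = −k·z²/L` in the plane of the inclination rotation. The
droop is a *displacement* of sample stations, not an arc-length
re-parameterisation: for k > 0 the meshed surface is slightly longer than
L along its surface. We keep it this way because the droop model is defined
as a displacement field; for the mild defaults the discrepancy is below 1%.

The local frame starts with the midrib along +Z, width along X, droop along
−Y. Inclination is a rotation about X (so the straight-midrib tip lands
exactly θ from vertical — a property tested to 1e−6 degrees), azimuth a
rotation about Z. The strip triangulation splits every quad along the same
diagonal with outward winding, so output files are byte-deterministic.

* `curvature_k` default **0.05 cm⁻¹**: the droop factor is not a routinely
  measured trait; this value gives a visually plausible sag of ~5% of leaf
  length at the tip. It is exposed on `LeafSpec` and in scene configs.
* `resolution` default **20 stations** per leaf: error from the chord
  approximation is far below the centimetre measurement scale.

**Culm.** A tapered open cylinder: ring i of `n_radial` vertices at height
`i·h/n_sections`, radius linearly interpolated base→top. Defaults
`n_sections=8, n_radial=12, base_radius=0.4 cm, top_radius=0.25 cm` —
culm radii are not part of the measured trait set, so these are plausible
tunables, not data.

**Plant.** Each leaf's insertion point is `position_ratio · stem_height`
on the culm surface, in the direction the blade extends. Position ratios
are normalised by *stem* height (not plant height): this guarantees leaves
attach on the culm for ratios up to 1. Leaves alternate azimuth by 180°
(distichous phyllotaxy) when built from structural records.

**Hill.** Plants occupy concentric rings of capacities 1, 6, 12, 18, …
(centre first, hexagonal-style growth chosen for uniform clump density —
the field observation is only "concentric circles with varying counts"),
ring i at radius `i·ring_spacing`, equal angular spacing within a ring.
Three seeded perturbations: positional jitter (uniform per coordinate,
default ±0.5 cm), rotation about the stem (uniform in [0°, `rotation_jitter`),
default 360°), and stem tilt about the plant base (uniform magnitude in
[0, `tilt_max`], default 8°, uniformly oriented horizontal axis). Tilt is
applied about the base point *before* translation, so the tilt bound equals
the stem-axis angle from vertical exactly. Per-hill seeds in a scene are
derived as `scene.seed + hill_index`: scenes are reproducible while hills
differ.

Within a hill, stems keep per-plant groups while leaf layers are merged
across plants (all L2 blades → one `L2` group). This matches the downstream
need: optical properties are assigned per layer, not per tiller.

**Scene.** Hills on a rows × hills-per-row grid (defaults 3 × 6, row
spacing 30 cm, plant spacing 15 cm, 1 m × 1 m extent — a standard paddy
configuration), centred over a soil quad at z = 0. Group naming in the
merged mesh: `soil`, `hill{h}_plant{p}_stem`, `hill{h}_L{layer}`.

Layer indexing is top-down throughout (layer 1 = flag leaf), matching the
sensitivity analysis's framing; field protocols often record positions
bottom-up, so ingest code converting external tables must re-index.

## Traits

Leaf area uses the rice allometry `LA = a·b·0.7746`. Pigments use the
classical ethanol-extract equations; results are returned in raw formula
units (mg/L of extract) with a units tag, because the conversion to
µg·cm⁻² requires extract volume and sample mass, which are protocol
constants outside this model. `Cw = (FW−DW)/LA`, `Cm = DW/LA`.

The leaf-inclination-angle function is linear in leaf position,
`LIA = 85.64 − 4.12·LP` by default (an erectophile fit), evaluated with a
clamp to [0°, 90°] (with a warning) because the line leaves the physical
range for large LP and the geometry layer requires a valid angle.
`fit_leaf_inclination_function` refits the line by OLS and reports R² and
RMSE; on noiseless samples of any line it recovers the coefficients to
1e−9 (tested).

## Rapid-mode estimation

Inputs: transplant day, PH, AGB, LAI. Targets: leaf count (multi-class
classification over the observed integer counts), plant/tiller count and
stem height (regression), and leaf length / width / position ratio
(regression on leaf-exploded rows with leaf position as a fifth feature).
The split is stratified 70/30 on leaf count; 5-fold CV scores are recorded
at training time. Features are centred/scaled inside each pipeline, so
normalisation statistics structurally cannot leak from the test split.

Hyperparameters (none are dictated by the source data, all exposed):
RF 500 trees, unlimited depth; XGBoost 300 rounds, learning rate 0.1,
max depth 4, L2 regularisation 1.0; SVM RBF kernel, C = 10. Predicted
plant counts are rounded to the nearest integer ≥ 1; all predictions are
clipped into the measured parameter ranges, with clip events logged.

Metrics: accuracy and one-vs-rest precision/recall per class
(macro-averaged summary), R² = 1 − RSS/TSS and RMSE per regression target.
A normalised-RMSE variant (RMSE divided by the measured mean) is available
behind the `normalized_rmse` flag. Zero-variance truth yields an undefined
R², reported as missing with a warning.

## Synthetic data generator

The generator emulates the *study conditions*: marginal ranges fixed to the
measured field statistics (PH 27.4–113 cm, LAI 1.20–8.03, AGB 1.45–81.18 g,
leaf count 2–6, stem height 11.6–75.4 cm, plant count 7–40, leaf length
16.2–57.4 cm, leaf width 0.70–2.00 cm, position ratio 0.2984–1.0), and a
correlation structure driven by a single latent growth stage g ~ U(0, 1):
transplant day and PH linear in g; stem height ∝ g^1.1 and AGB ∝ g^1.6
(monotone power laws, so the strong mutual correlations arise by
construction); LAI weakly coupled (affine in g with triple noise); leaf
count a monotone step of g; plant count independent uniform (tiller number
per hill is set at transplanting and is observed to be nearly uncorrelated
with growth). Transplant day spans 10–90 days, covering tillering through
booting. Vertical profiles: length peaks at mid-canopy positions, width
increases toward the top, position ratio decreases from the flag leaf
downward, inclination from the LIA line.

Noise is multiplicative, relative, default σ = 0.05 (a realistic
measurement-scale jitter), followed by truncation into the measured range.
All sampling flows from one `numpy` generator, so datasets are bit
deterministic per seed.

**What the generator does not emulate:** nitrogen-treatment effects,
variety differences, within-hill tiller heterogeneity, panicles, and any
real residual structure beyond the single latent driver. Rapid-mode
recovery results on this data (R² ≈ 1 at σ = 0) therefore demonstrate that
the pipeline is *correct and leak-free*, not that field accuracy of that
magnitude is attainable; on measured data the attainable accuracy is set
by biology, not by this code path.

## Sensitivity analysis

An ensemble of structures (1000 by default in the CLI; tests use 200,
chosen as the smallest size at which importance rankings are stable across
seeds) is converted to spectra by a pluggable provider and regressed by
random forests. The built-in `toy_reflectance` provider is a synthetic
stand-in with the right monotonicities, not a radiative-transfer solver:
soil is seen through a Beer–Lambert gap `exp(−0.5·LAI_eff)` with LAI_eff
from summed per-leaf allometric areas × plant count over the ground area
(default the 40 × 40 cm single-hill plot), and the vegetated fraction is an
area-weighted mixture of per-layer spectra with exponential depth
extinction (coefficient 0.5 per layer). Production use replaces it with an
engine such as LESS run on the exported scenes; the pipeline only requires
one reflectance row per structure on a shared wavelength grid.

Importances: one forest per wavelength band (default grid 400–1000 nm at
10 nm; 200 trees per band), per-band impurity importances averaged across
the grid and normalised to sum to 1. Averaging per-band importances was
chosen over a single multi-output forest so each band's response surface
is modelled independently; permutation importance is available behind the
`method="permutation"` flag. Excluding plant count drops the column before
fitting, so remaining importances renormalise among themselves.
Aggregations sum importances by layer (`L{n}_*`; canopy-level features pool
into `canopy`) or by parameter type; both partition the total exactly.

Feature encoding: plant count, plant height, and per-layer
length/width/inclination/position-ratio up to 6 layers, absent layers as 0
with a presence flag. Because the generator assigns inclination
deterministically from the LIA line, inclination columns are constant
within a layer and receive ~0 importance on generated ensembles; ensembles
with measured (varying) inclinations exercise that axis.

Vegetation indices are nearest-band NDVI ((R800−R670)/(R800+R670)) and
CIrededge (R800/R720 − 1).

## Degenerate inputs and tie-breaks

Zero leaf area → the provider returns the soil spectrum exactly. Constant
feature columns are kept but flagged. OBJ faces with quads are
fan-triangulated from the first vertex; face index 0 (illegal in OBJ) and
out-of-range indices are format errors with line numbers. Group ranges in
every mesh are contiguous, disjoint and covering — enforced at
construction, so a malformed partition cannot propagate.

## Problem sizes

Default test/acceptance runs use 120–300 hills for estimation and 200
structures for sensitivity, sizes at which the recovery and dominance
properties are already stable; the CLI defaults to the full 1000-structure
ensemble for analysis runs.

## Known limitations

No panicle geometry, leaf twist, sheath geometry or collision avoidance;
no row/ridge micro-topography; the LIA line is a single-variety,
mixed-stage fit and extrapolates poorly beyond leaf position ~6; the toy
reflectance provider ignores multiple scattering and view/sun geometry
entirely; rapid-mode accuracy on real data depends on upstream UAV
retrieval errors of PH/AGB/LAI, which this package does not model.
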