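# ricecanopy

Parametric 3D rice canopy construction for radiative-transfer work, with
machine-learned estimation of vertical leaf structure from canopy-level
remote-sensing observables.

3D radiative-transfer engines (LESS, DART) can simulate rice canopy
reflectance far more faithfully than turbid-medium models such as PROSAIL,
but only if they are fed a realistic 3D scene — and measuring every leaf's
length, width, inclination and insertion height by hand does not scale.
`ricecanopy` addresses both halves of that bottleneck for researchers in
crop remote sensing and phenotyping:

* **Precision mode** — given fully measured per-leaf structural parameters,
  procedurally build triangle meshes for leaves, culms, single plants,
  hills (transplanted clumps) and whole field scenes, and export them as
  Wavefront OBJ with named per-component face groups plus a JSON manifest
  binding each group to reflectance/transmittance spectra for any external
  radiative-transfer engine.
* **Rapid mode** — given only four canopy observables that UAV platforms
  retrieve routinely (days since transplanting, plant height PH, above-ground
  biomass AGB, and LAI), estimate the vertical leaf structure with
  SVM / random-forest / XGBoost models and build the same scenes.

## The model

A leaf blade is a strip of edge-vertex pairs sampled along the midrib
z ∈ [0, L]. Its half-width follows an inverted parabola and its sag a
quadratic droop:

```
w(z) = w_max · [1 − (2(z/L − 0.5))²],        y(z) = −k z² / L,
```

after which the blade is rotated by its inclination angle θ (degrees from
the vertical culm axis, applied in the droop plane) and its azimuth about
the culm. The culm is a linearly tapered cylinder meshed from polar-coordinate
vertex rings. Plants attach each leaf at `position_ratio · stem_height`;
hills place plants on concentric rings (capacities 1, 6, 12, …) with seeded
jitter of position, orientation and stem tilt; scenes lay hills on a
row-spacing × plant-spacing grid over a soil quad.

Rice is erectophile, and the canopy's leaf inclination angle is modelled as
a linear function of leaf position LP (counted from the top, 1 = flag leaf):

```
LIA(LP) = 85.64 − 4.12 · LP        (degrees from vertical)
```

available as `ricecanopy.RICE_LIA` and refittable from (LP, mean angle)
data with `fit_leaf_inclination_function`.

Supporting trait formulas: leaf area `LA = a·b·0.7746`; chlorophyll a/b and
carotenoids from ethanol-extract absorbances (A470/A649/A665); equivalent
water thickness `Cw = (FW − DW)/LA` and dry matter content `Cm = DW/LA`.

A synthetic-data module generates structural datasets whose ranges match
field statistics and whose correlation structure follows a single latent
growth-stage driver (transplant day, PH, stem height and AGB strongly
coupled; LAI weakly; tiller count independent), and a sensitivity harness
ranks structural parameters by random-forest importance for canopy
reflectance, aggregated by leaf layer and by parameter type, with and
without the dominant plant-count variable.

## Worked example

```python
import ricecanopy as rc

# Precision mode: one 18-tiller hill centred in a 40 x 40 cm plot
leaves = tuple(
    rc.LeafSpec(length=30, max_width=1.2, inclination=rc.RICE_LIA(p),
                azimuth=(p - 1) * 180.0, position_ratio=1.0 - 0.12 * (p - 1),
                layer_index=p)
    for p in range(1, 5)
)
plant = rc.PlantSpec(stem=rc.StemSpec(height=45.0), leaves=leaves, plant_height=70.0)
hill = rc.HillSpec(plant_count=18, plant_template=plant, seed=42)
scene = rc.build_scene(rc.SceneSpec(rows=1, hills_per_row=1, extent=(40, 40)), hill)
print("scene:", scene.mesh.n_vertices, "vertices,", scene.mesh.n_faces, "faces")
rc.write_obj(scene, "scene.obj")

# Rapid mode: recover vertical structure from the four canopy inputs
records = rc.generate_structural_dataset(rc.GeneratorConfig(n=300, seed=1, noise_sd=0.0))
results = rc.RapidStructureModel(records, algorithm="rf").fit(seed=1)
print(results.summary())
```

prints

```
scene: 4828 vertices, 6194 faces
Rapid-mode structure estimation (rf, 210 train / 90 test hills, 5-fold CV)
...
--- test ---
Leaf-count classification (n = 90)
  accuracy          0.9889
  macro precision   0.9882
  macro recall      0.9882
Regression targets           R2        RMSE
  plant_count              -0.7022     11.8908
  stem_height               0.9999      0.1955
  leaf_length               0.9983      0.3450
  leaf_width                0.9997      0.0040
  position_ratio            0.9987      0.0083
```

The scene mesh carries groups `soil`, `hill0_plant{p}_stem` and `hill0_L{l}`
(leaf layers merged across tillers), ready for per-component optical
assignment. In the rapid-mode summary, stem height, leaf length, width and
position ratio are recovered almost perfectly because this dataset was
generated noise-free; plant count is uncorrelated with the four inputs by
construction (in a transplanted paddy the tiller count per hill is set at
transplanting), so its R² hovers around zero — exactly the behaviour the
generator encodes.

A `ricecanopy` CLI wraps the same functionality:
`ricecanopy synth`, `ricecanopy precision`, `ricecanopy rapid train|predict`,
`ricecanopy sensitivity`.

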