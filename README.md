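# mitoqc

Quantification of mitophagic flux and mitochondrial morphology from
dual-reporter (tandem mCherry–GFP) fluorescence micrographs of cultured
neurons — for cell biologists studying mitochondrial quality control under
stressors such as oxygen–glucose deprivation/reoxygenation.

## The measurement

Mitochondria carrying the tandem reporter fluoresce in both the GFP and
mCherry channels. When a mitochondrion is delivered to an acidic lysosome,
the pH-sensitive GFP is quenched while mCherry persists, so **mCherry-only
("red-only") puncta mark mitochondria undergoing mitophagy**. The pipeline:

1. **Pre-processing** per channel: rolling-ball background subtraction
   (radius 10 px), normalized unsharp mask (σ = 1 px, weight 0.6), CLAHE
   (block 127, 256 bins, max slope 3.0), disc-median filter (radius 2 px).
2. **Pixel segmentation**: a trainable random-forest pixel classifier over a
   10-feature-per-channel bank separates *mitophagy* (red-only), *healthy*
   mitochondria and *background*; its "mitophagy" probability map is
   thresholded at ≥ 0.31 and 8-connected components are counted (no size
   filter) and normalized to the number of cells (nuclei) analyzed:

   puncta per cell = N(red-only particles) / N(cells).

3. **Morphometry**: every segmented object gets 32 shape descriptors (area,
   perimeter, circularity = 4πA/P², Feret/MinFeret by rotating calipers,
   best-fit-ellipse aspect ratio, solidity, convexity, extent, hexagonal
   shape factors, ...), with a 0.3 µm² minimum area for the mitochondria
   channel (scale 9.7 px/µm).
4. **Morphology classification**: a random forest (500 trees, mtry = 2,
   tuned over 25 bootstrap iterations, stratified 80/20 split) assigns each
   object one of four classes — *network*, *unbranched*, *swollen*,
   *punctate*.
5. **Endpoints**: puncta and LAMP1 particles per cell, Pearson and Mander's
   (M1/M2, Otsu-thresholded) colocalization, per-class object and area
   fractions, and the per-class mitophagy fraction
   red-only\_c / (red-only\_c + GFP-positive\_c).

Because no public reference imaging dataset exists for this assay, the
package ships a seeded synthetic-scene generator (`mitoqc.synthetic`) that renders
the four morphology archetypes, GFP-quenched red-only puncta co-located
with ~1.2 µm lysosomes, nuclei, a Gaussian PSF and a Poisson–Gaussian
camera model — giving every pipeline stage a ground truth to be tested
against.

## Worked example

```python
import dataclasses
from mitoqc import synthetic, quantify, classifier
from mitoqc.io_config import RunConfig

cfg = RunConfig()                       # all reference-protocol defaults
scene = synthetic.generate_scene(
    synthetic.SceneConfig(size_px=384, n_cells=3, n_objects=40, seed=11).noise_free()
)
train_scene = synthetic.generate_scene(
    synthetic.SceneConfig(size_px=384, n_cells=3, n_objects=40, seed=99).noise_free()
)
models = quantify.train_models_from_scene(train_scene, cfg, seed=5)
labels = synthetic.generate_labeled_feature_table(600, seed=7)
models["morphology_model"] = classifier.train_morphology_model(
    labels, dataclasses.replace(cfg, rf_tune_iters=2), seed=3
)
record, objects = quantify.run_field_pipeline(
    scene.field, models, cfg, cell_count=scene.cell_count
)
print(record["puncta_count"], record["puncta_per_cell"])
print({c: record[f"red_frac_{c}"] for c in classifier.MORPHOLOGY_CLASSES})
```

prints

```
11 3.6666666666666665
{'network': 0.0, 'unbranched': 0.0, 'swollen': 0.09090909090909091,
 'punctate': 0.9090909090909091}
```

— the scene programmed 11 mitophagy events and the pipeline counted exactly
11 red-only puncta (3.67 per cell over 3 cells); classifying those red-only
objects shows the punctate morphology dominating, the expected signature
when mitophagy preferentially clears small mitochondria.

A CLI mirrors the stages (`mitoqc simulate | segment | features | train |
classify | mitophagy | coloc | report`); every run writes a `manifest.json`
that pins config, inputs and seed.

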