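# ishquant

Cell-type-specific quantification of RNA in situ hybridization (RNA-ISH)
images. `ishquant` measures how much marker RNA each individual carcinoma,
immune or stromal cell carries in chromogenic brightfield images (brown DAB
dots on a blue hematoxylin counterstain, e.g. RNAScope), and turns those
per-cell measurements into per-spot and per-patient statistics: average
expression, a mean-independent expression-variability factor, nested
variance decomposition, and survival grouping. It is aimed at tissue
microarray (TMA) and whole-slide studies where hundreds of samples make
visual scoring impractical.

## What it computes

Chromogenic images superimpose the counterstain and the marker on a single
RGB raster. Under the Beer–Lambert law, absorbances mix linearly:

    OD_c = -ln(I_c / I0_c) = C_H h_c + C_D d_c,   c ∈ {R, G, B}

with unit stain vectors *h* (hematoxylin) and *d* (DAB). Per-pixel inversion
of this 3×3 system separates a nuclear channel C_H from a marker channel
C_D; Rényi entropy thresholding suppresses marker background. Where dense
chromogen has destroyed the counterstain, the nuclear channel is restored by
harmonic inpainting before segmentation (adaptive Otsu + shape-based
watershed declumping, object diameter 25–170 px). Each nucleus is classified
by a quadratic Gaussian (QDA) classifier on four morphology features (area,
mean nuclear stain intensity, eccentricity, perimeter-to-area ratio), with
class posteriors low-pass filtered in log space over a 100 px disk to
exploit the spatial co-localization of cell types. Segments are expanded
into the cytoplasm (20/5/5 px for cancer/immune/stromal, ties to the
nearest segment) and the marker signal is summed per cell after masking
saturated nonspecific regions.

Per spot or patient, with cell areas as weights:

    m = Σᵢ Intensityᵢ / Σᵢ Areaᵢ
    v = Σᵢ (Areaᵢ / ΣArea) · (Intensityᵢ/Areaᵢ − m)²

Because v is naturally coupled to m, expression variability is reported as
the **variability factor**: the residual of an OLS fit of log₁₀ v on log₁₀ m
across samples — a generalized Fano factor with a fitted power law
v = c·mᵝ. Survival analysis supports median splits and an optimized
three-way grouping (≤ 20 candidate threshold pairs, Benjamini–Hochberg
adjusted to control for the optimization).

A first-class synthetic generator (`ishquant.synthetic`) renders chromogenic
spots with full ground truth — cell masks, classes, per-cell dot counts and
signal, Beer–Lambert mixing, counterstain occlusion under dense chromogen,
and multi-spot-per-patient cohorts with survival linked to injected mean or
variability — so every stage is testable without cohort data.

## Worked example

```python
import numpy as np
from ishquant import pipeline, stats, synthetic as syn

# render a synthetic TMA spot (200 cells) and train the classifier
cfg = pipeline.PipelineConfig()
train = [
    dict(zip(("image", "truth"), syn.render_spot(syn.SyntheticSpotSpec(seed=s))[:2]))
    for s in (100, 101)
]
model = pipeline.train_from_spots(cfg, train)

spec = syn.SyntheticSpotSpec(seed=7)
image, truth, table, extras = syn.render_spot(spec)
res = pipeline.run_spot(cfg, image, model, spot_id="demo")

cells = res["cells"]
cancer = cells[cells["cell_class"] == "cancer"]
m = stats.weighted_mean(cancer)
v = stats.weighted_variance(cancer, m)
print(f"cells detected: {len(cells)} (true: {len(truth.classes)})")
print(f"cancer cells:   {len(cancer)}")
print(f"weighted mean expression m = {m:.5f}")
print(f"weighted expression variance v = {v:.3e}")
```

prints

```
cells detected: 199 (true: 200)
cancer cells:   112
weighted mean expression m = 0.00607
weighted expression variance v = 2.477e-05
```

199 of the 200 rendered cells are recovered; the cancer-cell weighted mean
of 0.006 intensity units sits in the 0.001–0.01 band typical of real
chromogenic material (1 = a cell fully saturated with chromogen, so typical
dot coverage gives small values). The variance feeds the variability-factor
fit across patients.

## Command line

```
ishquant generate --out-dir cohort --patients 20 --spots-per-patient 3 \
    --seed 0 --survival-link variability
ishquant train-classifier --cohort-dir cohort
ishquant run-cohort --cohort-dir cohort --out-dir results
ishquant crop-spots --slide slide.png --out-dir spots --min-diameter 800
ishquant stats --cells results/cells.csv --out summaries.csv
ishquant survival --summary summaries.csv --clinical cohort/clinical.csv \
    --on varfactor --out groups.csv
```

`run-cohort` writes `cells.csv`, `spot_summary.csv`, `patient_summary.csv`
(m, v, variability factor per patient), `qc.csv` and
`survival_splits.csv`, plus a manifest keyed by the configuration hash so a
completed run is not recomputed.

## Limitations

- Touching TMA cores are not split (no grid-model dearraying).
- Proprietary scanner formats (e.g. MRXS pyramids) are out of scope; inputs
  are stitched rasters (PNG/TIFF).
- The classifier's spatial smoothing assumes co-localized cell types;
  disable it (`spatial_smoothing=False`) for highly intermixed tissue.
- Expression is reported in relative intensity units, not absolute
  transcript counts.
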