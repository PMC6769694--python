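# mucinquant

Quantification of histochemical mucin staining (PAS, alcian blue) in
brightfield microscopy fields. Two independent segmentation backends report
the stained area fraction **A%**:

- **filter-hsv** — threshold segmentation in HSV color space;
  `A% = reaction pixels / tissue pixels × 100`, with tissue defined as all
  non-background (non-glass) pixels.
- **smart-seg** — seeded three-class pixel classification (reaction /
  tissue-without-reaction / background) by a Gaussian quadratic discriminant;
  `A% = class-1 / (class-1 + class-2) × 100`.

These are complemented by the semi-quantitative immunoreactive score
(IRS = PP × SI, 0–12), field-to-slide aggregation, a nonparametric
statistics harness (Cronbach's alpha, Spearman, paired Wilcoxon,
Mann–Whitney, Kaplan–Meier / log-rank on above/below-mean expression
groups), and a synthetic-data module that generates stained-tissue-like
fields with exact ground-truth masks and patient cohorts with configurable
effect structure.

The HSV threshold presets are calibration choices for typical magenta (PAS)
and blue (AB) reaction products, not published values; every bound is
overridable via YAML config, and each run logs its fully resolved
configuration.

## CLI

```sh
# simulate a slide of synthetic fields with known truth
mucinquant simulate field --target 0.25 --stain pas --n-fields 10 --out-dir fields/

# segment with the HSV threshold backend (per-field and per-slide CSVs)
mucinquant segment --backend filter-hsv --stain pas \
    --manifest slides.yaml --out fields.csv --slide-out slides.csv

# segment with the seeded classifier (seeds.yaml: per-class [x, y] coords)
mucinquant segment --backend smart-seg --seeds seeds.yaml --out fields.csv IMG...

# synthetic cohort and the full report-table set
mucinquant simulate cohort --n 33 --seed 1 --out cohort.csv
mucinquant stats --cohort cohort.csv --out report/

# Cronbach's alpha of a ratings matrix (rows = slides, columns = methods)
mucinquant agree --matrix matrix.csv
```

`slides.yaml` maps `slide_id` to a list of field image paths. PNG and TIFF
are the supported 8-bit RGB formats; JPEG is accepted with a warning about
compression artifacts.

`seeds.yaml` example:

```yaml
image: field.png          # optional; defaults to the first input image
classes:
  1: [[10, 12], [11, 13]] # reaction seed pixels as [x, y]
  2: [[40, 40]]           # tissue
  3: [[2, 2]]             # background
```

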