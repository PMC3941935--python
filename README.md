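# vbmorph

Vascular-bundle morphometry of leaflet cross sections and cultivar
classification with a from-scratch multilayer perceptron.

The pipeline extracts nine descriptors from fluorescence cross-section
images of palm leaflets and classifies cultivars with a small neural
network:

1. **imageprep** — blue-channel extraction, thresholding (Otsu or fixed),
   small-particle removal, outer-contour tracing on the pixel grid, and
   periodic cubic B-spline smoothing that suppresses hair-like spikes.
2. **vbfeatures** — four minor-bundle (MnVB) distribution features measured
   against the baseline joining the two major-bundle (MjVB) centres
   (count, perpendicular-distance ratio, midpoint-distance ratio, and a
   travelling-salesman tour ratio, exact via Held–Karp up to 13 points),
   plus five MjVB shape features (form factor, aspect ratio,
   rectangularity, eccentricity and the residual of a direct least-squares
   ellipse fit).
3. **mlp** — a 9 → 10 → K multilayer perceptron (tanh hidden layer, softmax
   output, cross-entropy loss) trained by full-batch gradient descent with
   a backtracking line search so every accepted iteration strictly reduces
   the loss; repeated random-split cross-validation and permutation
   variable importance.
4. **synthgen** — a seed-deterministic generator of synthetic cross-section
   scenes (images + ground-truth annotations) with five well-separated
   default classes, so the whole pipeline is testable without real
   samples.

## CLI

All stages are subcommands of `vbmorph` (see `vbmorph --help`):

```sh
# synthetic cohort: images, truth annotations, features
vbmorph simulate --counts 14,22,17,20,12 --seed 1 --out-dir cohort/

# contour of the brightest object in one image
vbmorph preprocess --image cohort/class_a_000.png --out contour.csv

# nine features per annotated scene (contours named <scene>_mjvb{0,1}.csv)
vbmorph extract --annotations cohort/annotations.csv \
    --contours-dir contours/ --out features.csv

# classifier training, prediction, cross-validation, importance
vbmorph train --features features.csv --hidden 10 --seed 1 --out model.json
vbmorph predict --model model.json --features features.csv
vbmorph crossval --features features.csv --runs 10 --train-prob 0.7 \
    --report cv_report.csv
vbmorph importance --model model.json --features features.csv \
    --permutations 200 --out importance.csv

# everything end to end, with a JSON run manifest
vbmorph run --counts 14,22,17,20,12 --runs 10 --seed 1 --out-dir run/
```

## File formats

- Annotation CSV: `scene_id, role {mjvb_rect|mnvb_oval}, cx, cy, width,
  height, angle_deg, label` (one row per shape).
- Feature CSV: `scene_id`, the nine features in canonical order, `label`.
- Contour CSV: `point_index, x, y` (pixel units, origin top-left).
- Models are stored as JSON (layer sizes, weights, biases, class names,
  standardization statistics, seed).
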