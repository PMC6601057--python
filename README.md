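# wsgrade

Computer-vision grading of **white striping (WS)** severity in broiler
breast fillets. White striping is a myopathy of the pectoralis major
that appears as white striations parallel to the muscle fibers; fillets
are graded **NORM** (no striping), **MOD** (lines < 1 mm thick, easily
visible) or **SEV** (lines generally > 1 mm, very visible). Visual
grading on processing lines is subjective; `wsgrade` grades photographs
of fillets on a blue background automatically.

The package is aimed at meat-science and food-engineering groups who
want a reproducible WS grading baseline, and it ships a seeded synthetic
scene generator so the whole pipeline is testable without a camera.

## Pipeline

1. **Segmentation** — Otsu's threshold on the HSV hue channel splits
   meat from the blue backdrop; pixels whose R, G, B all exceed the
   region means and whose gray level exceeds 240 (specular spots,
   rulers) are removed; small components are dropped by 8-connectivity.
2. **Illumination normalization** — overlay blend of the image with its
   inverted Gaussian-blurred HSL lightness M:
   `E = (I/255) · (I + 2·(M/255)·(255 − I))`,
   darkening dark regions and lightening light ones, which flattens
   heterogeneous incident light.
3. **Hole filling** — removed bright pixels inside the meat are set to
   the mean of nonzero neighbors in a 25×25 window.
4. **Contrast enhancement** — CLAHE with 64×64 tiles and clip limit
   0.07, making the striations stand out.
5. **Features** — a 25-value descriptor: FFT spectrum energy/entropy/
   homogeneity/inertia (1–4), intensity-histogram statistics and
   run-structure (5–17), gray-level co-occurrence matrix entropy/
   homogeneity/inertia/correlation/energy (18–22), image entropy, global
   contrast factor and the EME enhancement measure (23–25).
6. **Selection** — information gain `IG = H(class) − H(class | feature)`
   with MDL-stop entropy discretization; features with IG = 0 are pruned.
7. **Models** — random forest, RBF SVM, MLP and an Ishibuchi-style
   weighted fuzzy rule-based classifier (fuzzy-W), evaluated by a
   repeated stratified 70/30 holdout (50 repetitions) with accuracy,
   error, macro precision/recall/F-score and a per-image accumulated
   error map.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from wsgrade import (generate_dataset, preprocess_pipeline, extract_all,
                     rank_features)

images, manifest = generate_dataset(n_per_class=2, seed=7)
enhanced = preprocess_pipeline(images[0].pixels)
fv = extract_all(enhanced)
print(f"image {images[0].image_id} ({images[0].degree}): "
      f"meat_area={enhanced.mask.meat_area}")
print(f"  GLCM energy (f22)={fv[22]:.5f}  "
      f"image entropy (f23)={fv[23]:.3f} bits  EME (f25)={fv[25]:.2f}")
```

prints

```
image 1 (NORM): meat_area=23653
  GLCM energy (f22)=0.00199  image entropy (f23)=7.539 bits  EME (f25)=6.67
```

`meat_area` is the segmented fillet size in pixels. GLCM energy is the
squared sum of co-occurrence probabilities — high for the homogeneous
NORM surface, lower once striations spread intensity pairs. Image
entropy (bits) measures tonal randomness, and EME the blockwise
max/min log-contrast after enhancement.

The same flow from a shell, end to end:

```sh
wsgrade run --simulate --n-per-class 20 --reps 50 --seed 7 --out results/
wsgrade classify --image fillet.png --bundle model.joblib
```

The `run` subcommand writes `features.csv`, `ranking.json`, per-algorithm
metric and error-map CSVs, and `report.json` (carrying the config hash);
`simulate`, `preprocess`, `extract`, `rank`, `evaluate`, `train` and
`classify` expose the stages individually.

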