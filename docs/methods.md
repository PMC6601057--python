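# Methods

## Problem

White striping (WS) is a myopathy of the broiler pectoralis major that
shows as white fat/connective-tissue striations running parallel to the
muscle fibers. Carcasses are graded visually into three severity degrees:
**NORM** (no striping), **MOD** (lines thinner than 1 mm but easily
visible), **SEV** (lines generally thicker than 1 mm and very visible).
Manual grading is subjective; `wsgrade` implements an image-analysis
pipeline that grades photographs of fillets on a blue background
automatically, and a synthetic scene generator that stands in for such
photographs so the pipeline can be validated end to end without a
proprietary image set.

## Synthetic scenes

`wsgrade.synthetic` renders the structural elements of the photographs:
a mottled pale-pink elliptical meat region on a blue backdrop, a white
ruler-like bar, specular highlight spots, a multiplicative illumination
ramp, additive Gaussian noise, and — for MOD/SEV — bright curvilinear
bands with a Gaussian cross-profile aligned to a fiber axis. Severity is
encoded exactly where the grading rule puts it: stripe width. A
configurable scale (default 4 px/mm) translates the physical rule; MOD
widths draw below 4 px, SEV above, with SEV also drawing more stripes
and higher contrast. Striations blend toward a matte fat-white
(228, 222, 216) and never reach the specular range, while the ruler and
highlight spots are drawn near-saturated — this mirrors real scenes,
where rulers and surface reflections are the "extremely bright" pixels
that segmentation removes but striations are not.

Default scene size is 256×256 px with a 20-samples-per-degree, two
captures-per-sample design (120 images), the scale of the original
study; the second capture re-renders the sample with a perturbed seed.
Two stripe-parameter profiles exist: `strong` (disjoint MOD/SEV width
and contrast draws; the default study condition) and `overlapping`
(width distributions adjacent at the 1 mm boundary, for probing
confusion structure). Per-stripe amplitude jitter is U(0.75, 1), keeping
every rendered line individually visible as the degree definitions
require.

What the generator does **not** emulate: real muscle-surface texture
(folds, wet sheen, connective tissue), camera optics and sensor noise,
color variation between birds, and the tactile firmness cue that
distinguishes borderline MOD/SEV in practice (not a visual property).
Passing tests therefore show that the pipeline recovers striation
structure of this idealized kind; they do not certify accuracy on
photographs.

## Segmentation and enhancement

1. **Background split** — Otsu's threshold on the HSV hue histogram,
   keeping the side whose mean hue is circularly farther from backdrop
   blue. The hue circle is rotated a half turn before histogramming
   because meat hues straddle the 0/1 wrap. The Otsu cut is defined as
   `{bins < t} / {bins >= t}` with ties toward the lower cut.
2. **Bright-pixel removal** — a pixel leaves the mask when all three
   channels exceed their mask-region means *and* its gray level exceeds
   a floor (default 240). The bare above-the-mean rule alone would
   delete roughly half of any region; the floor restricts removal to
   specular/ruler pixels.
3. **Connectivity cleanup** — 8-connected components below 0.5 % of the
   image area are dropped (largest kept if all are small). The final
   meat region closes the specular holes morphologically.
4. **Illumination normalization** — Gaussian blur (sigma = min dim / 20),
   invert, take HSL lightness L = (max+min)/2, and overlay-blend against
   the original per channel: `E = (I/255)(I + 2(M/255)(255−I))`, clamped.
   This form has fixed points 0→0 and 255→255 and leaves mid gray
   unchanged at M = 127.5; dark regions darken and light regions lighten
   with M, which flattens light spots driven by the inverted blurred
   lightness.
5. **Hole filling** — zero pixels inside the region become the mean of
   nonzero pixels in a 25×25 window, repeated (≤ 100 passes) until no
   hole remains.
6. **CLAHE** — 64×64 tiles, clip limit 0.07, applied to the full raster
   and re-masked. Grayscale uses BT.601 luma.

## The 25-feature descriptor

Computed on the post-CLAHE image over mask-interior pixels only
(exterior forced to 0, so histogram bin 0 is excluded from run-structure
logic):

* **FFT (1–4)** — energy Σq², entropy −Σq log₂q, homogeneity
  Σq/(1+d), inertia Σd²q of the DC-excluded normalized power spectrum,
  d the centered radial frequency distance.
* **Histogram (5–17)** — maximal runs of occupied bins ("non-zero
  groups": count, peaks and lengths of largest/smallest, ties by run
  mass then lower start); pixel-intensity mean/median/SD/variance/
  skewness/excess kurtosis (0 on degenerate distributions); occupied-bin
  count; modal intensity.
* **GLCM (18–22)** — 64 gray levels, distance 1, four angles
  accumulated symmetrically, mask-interior pairs only; entropy,
  homogeneity, inertia (contrast), correlation (0 when either marginal
  variance vanishes), energy (angular second moment).
* **Contrast/quality (23–25)** — Shannon entropy of the intensity
  distribution (bits); the multi-resolution global contrast factor
  (gamma-2.2 perceptual lightness, mean absolute 4-neighbor difference,
  nine 2×2-halved resolutions combined with the published weight
  polynomial); the measure of enhancement EME over an 8×8 block grid,
  averaged over mask-intersecting blocks with both block extremes
  floored at 1.

All logarithms are base 2. Every feature has a brute-force loop oracle
in the test suite that must agree to 1e-9 relative tolerance.

## Feature selection

Information gain requires discrete attributes; continuous features are
discretized by recursive entropy-minimizing binary splits with the
minimum-description-length stopping rule (Fayyad–Irani). This choice is
load-bearing: a feature with no MDL-admissible cut gets *exactly* zero
gain and is pruned, which is how an uninformative feature drops out of
the retained set. IG is computed once on the full table (the ranking is
a dataset property, not a per-split one); retained features (IG > 0,
descending, ties by feature number) are what the models consume.

## Classifiers and protocol

Four families: random forest, RBF-kernel SVM, one-hidden-layer MLP, and
a weighted fuzzy rule-based classifier (fuzzy-W) in the Ishibuchi style.
RF/SVM/MLP are scikit-learn estimators; fuzzy-W is implemented here:
per-feature triangular Ruspini partitions on min-max-scaled [0, 1]
features, one candidate rule per occupied antecedent cell (each training
example's maximum-membership cell), product t-norm, consequent by
maximum confidence, certainty weight = confidence margin over the best
competing class, single-winner inference with ties by larger weight then
lower class index. Inference floors each feature membership at 1e-6 so
that rule ranking degrades gracefully (fewest mismatched features, then
the product over the rest) instead of collapsing to a majority fallback
when products are exactly zero — common with example-generated rules
over ~20 antecedent conditions. The min t-norm was evaluated and was
uniformly worse; the product form stands.

Hyper-parameters are grid-searched with 3-fold cross-validation on the
training split only: RF trees {100, 500} × per-split features
{√p, p/3}; SVM cost {0.1, 1, 10, 100} with the median-heuristic kernel
width; MLP hidden units {5, 10, 20}, ≤ 500 epochs; fuzzy partitions
{3, 5}. SVM/MLP standardize features inside the pipeline.

Evaluation repeats a stratified 70/30 holdout (default 50 repetitions),
deterministic in (seed, repetition); per repetition it records accuracy,
error = 1 − accuracy, and unweighted macro precision/recall/F-score, and
accumulates a per-image error map (misclassifications / test-set
appearances; an image never tested is reported as not evaluated rather
than 0). Splits operate on images, not samples, so the two captures of
one fillet can land on opposite sides of a split — a deliberate mirror
of the protocol, noted here as a potential optimistic bias ("leakage")
caveat for the absolute accuracy numbers.

## Numerical and design choices

* Scene size 256×256 px keeps a 120-image run (generation through a
  50-repetition evaluation of all four algorithms) in a few CPU-minutes;
  all pixel-geometry defaults scale with image size.
* Segmentation flags "no foreground found" when the hue histogram is
  near-degenerate (occupied span < 4 bins) or one Otsu side is empty.
* CLAHE output has interior zeros lifted to 1 so mask-interior pixels
  remain distinguishable from holes/background.
* The EME average is over mask-intersecting blocks only; dividing by
  the full grid would penalize images by their background area.
* Degenerate statistics are pinned: skewness/kurtosis 0 at zero
  variance, GLCM correlation 0 at zero marginal variance, FFT features
  all 0 when the DC-excluded spectrum is identically zero.
* Known limitation: with ~20 retained features the fuzzy-W grid-rule
  classifier trails RF/SVM by a few accuracy points (full-length
  antecedents degrade with dimensionality; with the 13 strongest
  features it is at parity). This is a property of the method family,
  reproduced faithfully rather than patched.
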