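"""The 25-feature descriptor of the enhanced fillet image.

Four families describe the white-striping texture:

* FFT spectrum features (1-4): energy, entropy, homogeneity and inertia of
  the DC-excluded normalized power spectrum — striations are a periodic
  pattern and concentrate spectral mass at their spatial frequency.
* Intensity-histogram features (5-17): distribution statistics plus
  run-structure of the histogram ("non-zero groups" are maximal runs of
  consecutive occupied bins).
* Gray-level co-occurrence matrix features (18-22): Haralick-style
  entropy, homogeneity, inertia (contrast), correlation and energy
  (angular second moment) — repetition of thin bright bands over a
  homogeneous surface shows up here.
* Contrast / quality features (23-25): image entropy, the multi-resolution
  global contrast factor (GCF), and the blockwise measure of enhancement
  (EME).

All statistics are computed over mask-interior pixels only; the mask
exterior is forced to 0, and bin 0 is therefore excluded from the
histogram-group logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from .preprocess import EnhancedImage

FEATURE_NAMES = {
    1: "fft_energy",
    2: "fft_entropy",
    3: "fft_homogeneity",
    4: "fft_inertia",
    5: "hist_n_groups",
    6: "hist_kurtosis",
    7: "hist_largest_group_peak",
    8: "hist_smallest_group_peak",
    9: "hist_skewness",
    10: "hist_largest_group_length",
    11: "hist_smallest_group_length",
    12: "hist_mean",
    13: "hist_median",
    14: "hist_sd",
    15: "hist_variance",
    16: "hist_n_nonzero_bins",
    17: "hist_peak_bin",
    18: "glcm_entropy",
    19: "glcm_homogeneity",
    20: "glcm_inertia",
    21: "glcm_correlation",
    22: "glcm_energy",
    23: "image_entropy",
    24: "global_contrast_factor",
    25: "eme",
}

GLCM_LEVELS = 64
GLCM_DISTANCE = 1
EME_BLOCKS = (8, 8)
GCF_RESOLUTIONS = 9


@dataclass
class IntensityHistogram:
    """256-bin intensity histogram over mask-interior pixels."""

    counts: np.ndarray
    n_pixels: int


@dataclass
class CooccurrenceMatrix:
    """Symmetric, normalized gray-level co-occurrence matrix."""

    probabilities: np.ndarray
    levels: int
    offsets: tuple


@dataclass
class FeatureVector:
    """Ordered 25-value descriptor keyed by feature numbers 1-25."""

    values: np.ndarray
    image_id: int = 0
    sample_id: int = 0
    degree: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (25,):
            raise ValueError("feature vector must have exactly 25 values")
        if not np.isfinite(self.values).all():
            raise ValueError("feature vector must be finite")

    def __getitem__(self, number: int) -> float:
        return float(self.values[number - 1])


def intensity_histogram(enhanced: EnhancedImage) -> IntensityHistogram:
    """Tally intensities of mask-interior pixels into 256 bins."""
    m = enhanced.mask.mask
    if not m.any():
        raise ValueError("empty mask")
    vals = enhanced.gray[m]
    counts = np.bincount(vals.ravel(), minlength=256)
    return IntensityHistogram(counts=counts, n_pixels=int(vals.size))


def _weighted_moments(counts: np.ndarray):
    n = counts.sum()
    bins = np.arange(counts.size, dtype=np.float64)
    mean = float(np.sum(counts * bins) / n)
    var = float(np.sum(counts * (bins - mean) ** 2) / n)
    return n, bins, mean, var


def histogram_statistics(hist: IntensityHistogram) -> dict[int, float]:
    """Distribution statistics: features 6, 9, 12-17.

    Mean/median/SD/variance/skewness/kurtosis of the pixel-intensity
    distribution (kurtosis is the excess form); feature 16 counts occupied
    bins, feature 17 is the modal intensity.
    """
    counts = np.asarray(hist.counts, dtype=np.float64)
    if hist.n_pixels <= 0:
        raise ValueError("histogram has no pixels")
    n, bins, mean, var = _weighted_moments(counts)
    sd = np.sqrt(var)
    if sd > 0:
        m3 = np.sum(counts * (bins - mean) ** 3) / n
        m4 = np.sum(counts * (bins - mean) ** 4) / n
        skew = float(m3 / sd**3)
        kurt = float(m4 / var**2 - 3.0)
    else:
        skew = kurt = 0.0
    cum = np.cumsum(counts)
    half = n / 2.0
    lo = int(np.searchsorted(cum, half, side="left"))
    hi = int(np.searchsorted(cum, half + 0.5, side="left"))
    median = (lo + hi) / 2.0 if n % 2 == 0 else float(hi)
    return {
        6: kurt,
        9: skew,
        12: mean,
        13: float(median),
        14: float(sd),
        15: float(var),
        16: float(np.count_nonzero(counts)),
        17: float(np.argmax(counts)),
    }


def histogram_groups(hist: IntensityHistogram) -> dict[int, float]:
    """Run-structure features 5, 7, 8, 10, 11.

    Groups are maximal runs of consecutive nonzero bins over bins 1..255
    (bin 0 is the background convention and excluded).  Largest/smallest
    are by run length; ties break by total run mass, then lower start bin.
    Returns group count (5), peak of largest (7), peak of smallest (8),
    length of largest (10), length of smallest (11).
    """
    counts = np.asarray(hist.counts)
    occupied = counts[1:] > 0
    if not occupied.any():
        raise ValueError("no nonzero bin among bins 1..255")
    padded = np.concatenate([[False], occupied, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1   # bin indices (1-based bins)
    ends = np.flatnonzero(diff == -1) + 1    # exclusive
    groups = []
    for s, e in zip(starts, ends):
        run = counts[s:e]
        groups.append((e - s, int(run.sum()), s, int(run.max())))
    # sort key: (length, mass, -start) — pick max for "largest"
    largest = max(groups, key=lambda g: (g[0], g[1], -g[2]))
    smallest = min(groups, key=lambda g: (g[0], g[1], g[2]))
    return {
        5: float(len(groups)),
        7: float(largest[3]),
        8: float(smallest[3]),
        10: float(largest[0]),
        11: float(smallest[0]),
    }


def glcm(
    enhanced: EnhancedImage,
    levels: int = GLCM_LEVELS,
    distance: int = GLCM_DISTANCE,
) -> CooccurrenceMatrix:
    """Symmetric co-occurrence matrix over mask-interior pixel pairs.

    Intensities are quantized to ``levels``; co-occurrences accumulate over
    the four standard angles {0, 45, 90, 135 degrees} at ``distance``, in
    both directions, counting only pairs with both ends inside the mask.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    m = enhanced.mask.mask
    gray = enhanced.gray
    q = (gray.astype(np.int64) * levels) // 256
    # reserve level `levels` as the outside-mask sentinel so skimage counts
    # pairs with a masked end into rows/cols we can discard
    q = np.where(m, q, levels)
    angles = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    P = graycomatrix(
        q.astype(np.uint8), distances=[distance], angles=list(angles),
        levels=levels + 1, symmetric=True, normed=False,
    )
    counts = P[:levels, :levels, 0, :].sum(axis=-1).astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("mask contains no valid pixel pair")
    return CooccurrenceMatrix(
        probabilities=counts / total, levels=levels,
        offsets=tuple((distance, a) for a in angles),
    )


def glcm_features(P: CooccurrenceMatrix) -> dict[int, float]:
    """Haralick-style scalars 18-22 of a normalized co-occurrence matrix."""
    p = P.probabilities
    i, j = np.indices(p.shape)
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    inertia = float(((i - j) ** 2 * p).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    if var_i > 0 and var_j > 0:
        corr = float((((i - mu_i) * (j - mu_j) * p).sum())
                     / np.sqrt(var_i * var_j))
    else:
        corr = 0.0  # degenerate: a single occupied gray level
    energy = float((p**2).sum())
    return {18: entropy, 19: homogeneity, 20: inertia, 21: corr, 22: energy}


def fft_features(enhanced: EnhancedImage) -> dict[int, float]:
    """Spectrum features 1-4 from the DC-excluded normalized power spectrum.

    The 2-D DFT power spectrum of the masked gray raster is centered,
    its DC term removed, and the rest normalized to a distribution q(u, v);
    energy, entropy, homogeneity and inertia are then computed with the
    centered radial frequency distance d(u, v) playing the role the
    gray-level difference plays for co-occurrence features.
    """
    gray = np.asarray(enhanced.gray, dtype=np.float64)
    if not (gray > 0).any():
        raise ValueError("all-zero raster")
    F = np.fft.fftshift(np.fft.fft2(gray))
    power = np.abs(F) ** 2
    h, w = power.shape
    cy, cx = h // 2, w // 2
    power[cy, cx] = 0.0  # exclude DC
    total = power.sum()
    if total <= 0:
        return {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
    q = power / total
    yy, xx = np.indices(power.shape)
    d = np.hypot(yy - cy, xx - cx)
    nz = q > 0
    energy = float((q**2).sum())
    entropy = float(-(q[nz] * np.log2(q[nz])).sum())
    homogeneity = float((q / (1.0 + d)).sum())
    inertia = float((d**2 * q).sum())
    return {1: energy, 2: entropy, 3: homogeneity, 4: inertia}


def image_entropy(hist: IntensityHistogram) -> float:
    """Feature 23: Shannon entropy (bits) of the intensity distribution."""
    if hist.n_pixels <= 0:
        raise ValueError("histogram has no pixels")
    p = hist.counts / hist.n_pixels
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def _gcf_weights(n: int = GCF_RESOLUTIONS) -> np.ndarray:
    # resolution-weighting polynomial of the GCF method
    i = np.arange(1, n + 1) / n
    return (-0.406385 * i + 0.334573) * i + 0.0877526


def global_contrast_factor(enhanced: EnhancedImage) -> float:
    """Feature 24: multi-resolution global contrast factor.

    Pixel values are gamma-linearized (gamma 2.2) and mapped to perceptual
    lightness L = 100*sqrt(l); local contrast is the mean absolute
    4-neighbor lightness difference, averaged per resolution; resolutions
    halve nine times and combine with the published weight polynomial.
    Resolutions coarser than the image are truncated.
    """
    gray = np.asarray(enhanced.gray, dtype=np.float64)
    weights = _gcf_weights()
    gcf = 0.0
    img = gray
    for w_i in weights:
        h, w = img.shape
        if h < 2 or w < 2:
            break  # image smaller than this resolution: truncate
        lin = (img / 255.0) ** 2.2
        L = 100.0 * np.sqrt(lin)
        diffs = np.zeros_like(L)
        cnt = np.zeros_like(L)
        for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            rolled = np.roll(L, shift, axis=axis)
            d = np.abs(L - rolled)
            # exclude wrap-around pairs
            sl = [slice(None), slice(None)]
            sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            d[tuple(sl)] = 0.0
            valid = np.ones_like(L)
            valid[tuple(sl)] = 0.0
            diffs += d
            cnt += valid
        local = diffs / np.maximum(cnt, 1.0)
        gcf += w_i * float(local.mean())
        # superpixel halving: average 2x2 blocks
        h2, w2 = h // 2, w // 2
        if h2 < 1 or w2 < 1:
            break
        img = img[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))
    return gcf


def eme(enhanced: EnhancedImage, blocks: tuple[int, int] = EME_BLOCKS) -> float:
    """Feature 25: blockwise measure of enhancement.

    The raster is divided into a ``blocks`` grid; each block intersecting
    the mask contributes 20*log10(Imax/Imin) over its mask-interior pixels
    with both extremes floored at 1; the average is over contributing
    blocks.
    """
    k1, k2 = blocks
    if k1 < 1 or k2 < 1:
        raise ValueError("block grid must be at least 1x1")
    gray = np.asarray(enhanced.gray, dtype=np.float64)
    m = enhanced.mask.mask
    h, w = gray.shape
    rows = np.linspace(0, h, k1 + 1).astype(int)
    cols = np.linspace(0, w, k2 + 1).astype(int)
    terms = []
    for r0, r1 in zip(rows[:-1], rows[1:]):
        for c0, c1 in zip(cols[:-1], cols[1:]):
            bm = m[r0:r1, c0:c1]
            if not bm.any():
                continue
            vals = gray[r0:r1, c0:c1][bm]
            imax = max(vals.max(), 1.0)
            imin = max(vals.min(), 1.0)
            terms.append(20.0 * np.log10(imax / imin))
    if not terms:
        raise ValueError("no block intersects the mask")
    return float(np.mean(terms))


def extract_all(enhanced: EnhancedImage) -> FeatureVector:
    """Compute the full ordered 25-feature descriptor."""
    feats: dict[int, float] = {}
    hist = intensity_histogram(enhanced)
    try:
        feats.update(fft_features(enhanced))
        feats.update(histogram_groups(hist))
        feats.update(histogram_statistics(hist))
        feats.update(glcm_features(glcm(enhanced)))
        feats[23] = image_entropy(hist)
        feats[24] = global_contrast_factor(enhanced)
        feats[25] = eme(enhanced)
    except ValueError as exc:
        missing = sorted(set(FEATURE_NAMES) - set(feats))
        raise ValueError(f"feature {missing[0]}: {exc}") from exc
    values = np.array([feats[k] for k in range(1, 26)])
    return FeatureVector(values=values)
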