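"""Meat-region segmentation and image enhancement.

The enhancement chain mirrors the grading system's front end: segment the
fillet away from the blue background (Otsu on the HSV hue channel), knock
out specular/ruler pixels brighter than the per-channel means, drop small
stray components, flatten heterogeneous illumination with an overlay blend
against the inverted blurred lightness, fill the knocked-out holes from
their neighborhoods, and finish with contrast-limited adaptive histogram
equalization (CLAHE) to make the striations stand out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, measure
from skimage.color import rgb2hsv

PIPELINE_STAGES = ("segment", "normalize_illumination", "fill", "clahe")

#: BT.601 luma weights for grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])

#: hue of the blue backdrop on the [0, 1) hue circle (~240 degrees)
_BACKGROUND_HUE = 2.0 / 3.0


class SegmentationError(RuntimeError):
    """No meat foreground could be separated from the background."""


class UnfillableRegionError(RuntimeError):
    """A hole inside the meat mask could not be filled by neighborhood means."""


@dataclass
class MeatMask:
    """Binary raster marking the meat region (True = meat)."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def meat_area(self) -> int:
        return int(self.mask.sum())


@dataclass
class EnhancedImage:
    """Masked, enhanced grayscale image that feature extraction consumes."""

    gray: np.ndarray  # uint8, zero outside mask
    mask: MeatMask
    provenance: list[str] = field(default_factory=list)


@dataclass
class PreprocessConfig:
    """Tunable knobs of the enhancement chain (defaults follow the method)."""

    blur_sigma: float | None = None  # None -> min(H, W) / 20
    bright_floor: int = 240
    min_area_fraction: float = 0.005
    fill_window: int = 25
    clahe_tile: int = 64
    clahe_clip: float = 0.07


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold for a 256-bin intensity histogram.

    Returns the cut t maximizing the between-class variance of the split
    {bins < t} / {bins >= t}; ties break toward the lower cut.  A histogram
    whose mass sits in a single bin returns that bin's index.
    """
    counts = np.asarray(histogram, dtype=np.float64)
    if counts.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if counts.sum() <= 0:
        raise ValueError("histogram is empty")
    nonzero = np.flatnonzero(counts)
    if nonzero.size == 1:
        return int(nonzero[0])
    p = counts / counts.sum()
    bins = np.arange(256)
    w0 = np.cumsum(p)[:-1]          # mass of {bins < t} for t = 1..255
    mu = np.cumsum(p * bins)[:-1]   # first moment of {bins < t}
    mu_t = float(np.sum(p * bins))
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (mu_t * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    var_between = np.nan_to_num(var_between, nan=-1.0)
    return int(np.argmax(var_between)) + 1  # first (lowest) maximizing cut


def segment_background(image: np.ndarray) -> MeatMask:
    """Split meat from the blue backdrop by Otsu on the HSV hue channel.

    The hue histogram is thresholded and the side whose mean hue lies
    farther from the backdrop blue is kept as foreground.  The hue circle
    is rotated a half turn first so the meat's reddish hues (which straddle
    the 0/1 wrap) form one compact mode that a linear Otsu cut can split
    from the blue mode.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    hsv = rgb2hsv(image)
    hue = (hsv[..., 0] + 0.5) % 1.0
    hue_bins = np.clip((hue * 255.0).astype(np.int64), 0, 255)
    hist = np.bincount(hue_bins.ravel(), minlength=256)
    nonzero = np.flatnonzero(hist)
    if nonzero.size and (nonzero[-1] - nonzero[0]) < 4:
        raise SegmentationError("no foreground found: near-uniform hue")
    t = otsu_threshold(hist)
    low = hue_bins < t
    high = ~low
    if low.sum() == 0 or high.sum() == 0:
        raise SegmentationError("no foreground found: degenerate hue split")

    background_hue = (_BACKGROUND_HUE + 0.5) % 1.0  # in rotated coordinates

    def hue_dist(side):
        mean_h = hue[side].mean()
        d = abs(mean_h - background_hue)
        return min(d, 1.0 - d)  # circular distance

    mask = low if hue_dist(low) > hue_dist(high) else high
    return MeatMask(mask)


def remove_bright_pixels(
    image: np.ndarray, mask: MeatMask, bright_floor: int = 240
) -> MeatMask:
    """Remove specular/ruler pixels from the mask.

    A pixel leaves the mask when its R, G and B each exceed that channel's
    mean over the current mask region and its gray level exceeds
    ``bright_floor``; removed pixels become holes to be filled later.
    """
    image = np.asarray(image, dtype=np.float64)
    m = mask.mask
    if not m.any():
        raise ValueError("empty mask")
    means = image[m].mean(axis=0)
    above = (image > means).all(axis=-1)
    gray = image @ _LUMA
    bright = above & (gray > bright_floor) & m
    return MeatMask(m & ~bright)


def clean_mask(mask: MeatMask, min_area_fraction: float = 0.005) -> MeatMask:
    """Drop small 8-connected components; keep the largest if all are small."""
    m = mask.mask
    if not m.any():
        raise ValueError("empty mask")
    labels = measure.label(m, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    threshold = min_area_fraction * m.size
    keep = np.flatnonzero(areas >= threshold)
    if keep.size == 0:
        keep = np.array([int(np.argmax(areas))])
    return MeatMask(np.isin(labels, keep))


def overlay_blend(base: np.ndarray, lightness: np.ndarray) -> np.ndarray:
    """Overlay-blend an image against a lightness layer, both in [0, 255].

    E = (I/255) * (I + 2*(M/255)*(255 - I)), clamped to [0, 255].  Dark
    pixels darken and bright pixels brighten as the lightness M grows;
    0 and 255 are fixed points and M = 127.5 leaves mid gray unchanged.
    """
    I = np.asarray(base, dtype=np.float64)
    M = np.asarray(lightness, dtype=np.float64)
    if (I < 0).any() or (I > 255).any() or (M < 0).any() or (M > 255).any():
        raise ValueError("inputs must lie in [0, 255]")
    E = (I / 255.0) * (I + 2.0 * (M / 255.0) * (255.0 - I))
    return np.clip(E, 0.0, 255.0)


def normalize_illumination(
    image: np.ndarray, blur_sigma: float | None = None
) -> np.ndarray:
    """Flatten uneven lighting via overlay blend with inverted blurred lightness.

    A Gaussian-blurred copy spreads the light spots; its negative is taken
    and reduced to HSL lightness L = (max + min)/2, which drives the
    overlay blend per channel: bright spots get attenuated, homogeneously
    lit regions change little.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    if blur_sigma is None:
        blur_sigma = min(image.shape[:2]) / 20.0
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    blurred = np.stack(
        [ndimage.gaussian_filter(image[..., c], blur_sigma) for c in range(3)],
        axis=-1,
    )
    inverted = 255.0 - blurred
    lightness = (inverted.max(axis=-1) + inverted.min(axis=-1)) / 2.0
    return overlay_blend(image, lightness[..., None] * np.ones(3))


def fill_bright_holes(
    gray: np.ndarray, mask: MeatMask, window: int = 25, max_passes: int = 100
) -> np.ndarray:
    """Fill zero pixels inside the meat region with local nonzero means.

    Each zero-valued pixel inside the mask becomes the mean of the nonzero
    pixels in its centered ``window`` x ``window`` neighborhood; passes
    repeat until no zero pixel remains inside the mask.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    out = np.asarray(gray, dtype=np.float64).copy()
    m = mask.mask
    for _ in range(max_passes):
        holes = (out == 0) & m
        if not holes.any():
            return np.clip(np.rint(out), 0, 255).astype(np.uint8)
        nonzero = out > 0
        sums = ndimage.uniform_filter(out, size=window, mode="constant") * window**2
        cnts = ndimage.uniform_filter(nonzero.astype(np.float64), size=window,
                                      mode="constant") * window**2
        cnts = np.rint(cnts)
        fillable = holes & (cnts > 0.5)
        if not fillable.any():
            raise UnfillableRegionError("unfillable region inside meat mask")
        vals = np.rint(sums[fillable] / cnts[fillable])
        out[fillable] = np.clip(vals, 1, 255)  # filled pixels must be nonzero
    raise UnfillableRegionError("unfillable region: pass limit reached")


def clahe(
    gray: np.ndarray, mask: MeatMask, tile: int = 64, clip_limit: float = 0.07
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, re-masked after.

    Runs on the full rectangular raster with a ``tile`` x ``tile`` grid and
    normalized clip limit, then zeroes everything outside the mask.
    """
    if not 0 < clip_limit <= 1:
        raise ValueError("clip_limit must be in (0, 1]")
    gray = np.asarray(gray)
    eq = exposure.equalize_adapthist(
        gray, kernel_size=(tile, tile), clip_limit=clip_limit
    )
    out = np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)
    out[out == 0] = 1  # keep mask-interior pixels distinguishable from holes
    out[~mask.mask] = 0
    return out


def to_gray(image: np.ndarray) -> np.ndarray:
    """BT.601 luma grayscale of an RGB raster (float, same scale)."""
    return np.asarray(image, dtype=np.float64) @ _LUMA


def preprocess_pipeline(
    image: np.ndarray, config: PreprocessConfig | None = None
) -> EnhancedImage:
    """Run the full enhancement chain on one RGB image.

    Order: segment_background -> remove_bright_pixels -> clean_mask ->
    normalize_illumination -> grayscale -> fill_bright_holes -> clahe.
    The returned mask is the cleaned meat region with its specular holes
    closed, and the gray raster is zero outside it.
    """
    cfg = config or PreprocessConfig()
    stage = "segment"
    try:
        mask = segment_background(image)
        mask = remove_bright_pixels(image, mask, cfg.bright_floor)
        mask = clean_mask(mask, cfg.min_area_fraction)
        # the meat region proper: cleaned mask with specular holes closed
        region = MeatMask(ndimage.binary_fill_holes(mask.mask))
        stage = "normalize_illumination"
        normalized = normalize_illumination(image, cfg.blur_sigma)
        gray = to_gray(normalized)
        gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
        np.maximum(gray, 1, out=gray, where=mask.mask)  # nonzero where meat kept
        gray[~mask.mask] = 0  # holes and background are zero
        stage = "fill"
        filled = fill_bright_holes(gray, region, cfg.fill_window)
        stage = "clahe"
        enhanced = clahe(filled, region, cfg.clahe_tile, cfg.clahe_clip)
    except (SegmentationError, UnfillableRegionError, ValueError) as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    return EnhancedImage(gray=enhanced, mask=region,
                         provenance=list(PIPELINE_STAGES))
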