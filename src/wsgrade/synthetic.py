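"""Seeded synthetic fillet scenes with controllable striation severity.

The study images are photographs of broiler breast fillets on a blue
background: a roughly elliptical meat region, bright specular reflections,
white ruler-like objects near the meat, heterogeneous room illumination,
and — for affected samples — white striations running parallel to the
muscle-fiber axis.  Severity is graded by stripe thickness: NORM shows no
striping, MOD shows easily visible lines thinner than 1 mm, SEV shows very
visible lines generally thicker than 1 mm.

This module renders that scene structure procedurally so the whole grading
pipeline can be exercised and validated without the original photographs.
The physical <1 mm / >1 mm rule is translated to pixels through a
configurable scale (default 4 px/mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

DEGREES = ("NORM", "MOD", "SEV")

#: pixels per millimetre used to translate the physical stripe-width rule
DEFAULT_PX_PER_MM = 4.0

#: strong-separation stripe-width draws (px), per degree profile
_WIDTH_RANGES = {
    "strong": {"MOD": (1.5, 3.5), "SEV": (5.0, 9.0)},
    # MOD/SEV width distributions adjacent at the 1 mm boundary: grading
    # near the boundary becomes genuinely ambiguous between the two.
    "overlapping": {"MOD": (2.0, 4.0), "SEV": (4.0, 7.0)},
}
_COUNT_RANGES = {
    "strong": {"MOD": (6, 12), "SEV": (12, 18)},
    "overlapping": {"MOD": (8, 14), "SEV": (10, 16)},
}
_CONTRAST_RANGES = {
    # MOD striations are "easily visible", SEV "very visible": the draws
    # are disjoint so rendered contrast honors the degree definitions
    "strong": {"MOD": (55.0, 75.0), "SEV": (80.0, 100.0)},
    "overlapping": {"MOD": (55.0, 75.0), "SEV": (60.0, 80.0)},
}

_BACKGROUND_BLUE = (40, 70, 160)
_MEAT_BASE = (205.0, 145.0, 150.0)  # pale pink: high R, moderate G/B
# matte fat-white of the striations: bright but below the specular range,
# unlike the mirror-like highlight spots
_STRIPE_COLOR = (228.0, 222.0, 216.0)


class UnknownDegreeError(ValueError):
    """Raised when a white-striping degree label is not NORM/MOD/SEV."""


@dataclass(frozen=True)
class SceneParams:
    """Full parameterization of one rendered fillet scene.

    All linear quantities are in pixels; ``stripe_contrast``, ``mottle_amp``
    and ``noise_sd`` are 8-bit intensity units.
    """

    image_size: tuple[int, int] = (256, 256)
    meat_axes: tuple[float, float] = (100.0, 72.0)
    fiber_angle: float = 30.0
    stripe_count: int = 0
    stripe_width_px: float = 2.0
    stripe_contrast: float = 60.0
    n_specular_spots: int = 3
    illumination_gradient: float = 0.15
    noise_sd: float = 3.0
    mottle_amp: float = 6.0
    background_color: tuple[int, int, int] = _BACKGROUND_BLUE
    seed: int = 0
    degree: str = "NORM"

    def __post_init__(self):
        h, w = self.image_size
        margin = 0.05 * min(h, w)
        a, b = self.meat_axes
        if a <= 0 or b <= 0:
            raise ValueError("degenerate ellipse: semi-axes must be positive")
        if a > w / 2 - margin or b > h / 2 - margin:
            raise ValueError(
                "meat ellipse must fit inside the image with a 5% margin"
            )
        if self.degree not in DEGREES:
            raise UnknownDegreeError(f"unknown degree {self.degree!r}")
        if (self.stripe_count == 0) != (self.degree == "NORM"):
            raise ValueError("stripe_count must be 0 iff degree is NORM")
        if self.stripe_width_px <= 0:
            raise ValueError("stripe_width_px must be positive")


@dataclass
class LabeledImage:
    """An 8-bit RGB raster with its severity label and identifiers."""

    pixels: np.ndarray  # (H, W, 3) uint8
    degree: str
    sample_id: int
    image_id: int
    params: SceneParams | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.degree not in DEGREES:
            raise UnknownDegreeError(f"unknown degree {self.degree!r}")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) raster")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit per channel")


def degree_to_params(
    degree: str,
    seed: int,
    *,
    px_per_mm: float = DEFAULT_PX_PER_MM,
    profile: str = "strong",
    image_size: tuple[int, int] = (256, 256),
) -> SceneParams:
    """Draw jittered scene parameters consistent with a severity degree.

    NORM gets no stripes; MOD stripe widths fall below ``px_per_mm`` (the
    1 mm boundary expressed in pixels), SEV widths above it, with SEV also
    drawing at least as many stripes.  All continuous jitter comes from a
    generator seeded with ``seed`` so identical calls return identical
    parameters.
    """
    if degree not in DEGREES:
        raise UnknownDegreeError(f"unknown degree {degree!r}")
    if profile not in _WIDTH_RANGES:
        raise ValueError(f"unknown profile {profile!r}")
    rng = np.random.default_rng(seed)
    h, w = image_size
    scale = min(h, w) / 256.0
    axes = (
        rng.uniform(88, 108) * scale,
        rng.uniform(62, 80) * scale,
    )
    common = dict(
        image_size=image_size,
        meat_axes=axes,
        fiber_angle=float(rng.uniform(0.0, 180.0)),
        n_specular_spots=int(rng.integers(2, 6)),
        illumination_gradient=float(rng.uniform(0.05, 0.15)),
        noise_sd=float(rng.uniform(2.0, 4.0)),
        mottle_amp=float(rng.uniform(4.0, 8.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
        degree=degree,
    )
    if degree == "NORM":
        return SceneParams(stripe_count=0, stripe_width_px=1.0,
                           stripe_contrast=0.0, **common)
    lo, hi = _WIDTH_RANGES[profile][degree]
    # width draws scale with px/mm so the <1 mm / >1 mm rule holds at any scale
    width = float(rng.uniform(lo, hi)) * px_per_mm / DEFAULT_PX_PER_MM
    clo, chi = _COUNT_RANGES[profile][degree]
    count = int(rng.integers(clo, chi + 1))
    glo, ghi = _CONTRAST_RANGES[profile][degree]
    contrast = float(rng.uniform(glo, ghi))
    return SceneParams(stripe_count=count, stripe_width_px=width,
                       stripe_contrast=contrast, **common)


def ellipse_mask(params: SceneParams) -> np.ndarray:
    """Ground-truth boolean mask of the meat ellipse (True = meat)."""
    h, w = params.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    theta = np.deg2rad(params.fiber_angle)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    a, b = params.meat_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_scene(params: SceneParams) -> LabeledImage:
    """Render the scene described by ``params`` into an 8-bit RGB raster.

    Composition order: blue background, mottled pale-pink meat ellipse,
    bright striation bands aligned to the fiber axis (Gaussian
    cross-profile, mild sinusoidal meander), a white ruler-like bar near
    the border, multiplicative illumination ramp, near-saturated specular
    blobs, additive Gaussian noise, clip to [0, 255].
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(params.background_color, dtype=np.float64)

    inside = ellipse_mask(params)
    cy, cx = h / 2.0, w / 2.0
    theta = np.deg2rad(params.fiber_angle)
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)   # along fibers
    v = -dx * np.sin(theta) + dy * np.cos(theta)  # across fibers

    meat = np.empty((h, w, 3))
    meat[:] = np.asarray(_MEAT_BASE)
    if params.mottle_amp > 0:
        # low-frequency mottling so the meat is not flat even for NORM
        for c, gain in enumerate((1.0, 0.8, 0.8)):
            field_ = gaussian_filter(rng.normal(0.0, 1.0, (h, w)),
                                     sigma=0.08 * min(h, w))
            sd = field_.std()
            if sd > 0:
                meat[..., c] += params.mottle_amp * gain * field_ / sd

    a, b = params.meat_axes
    if params.stripe_count > 0:
        sigma = params.stripe_width_px / 2.355  # FWHM = stripe width
        offsets = rng.uniform(-0.85 * b, 0.85 * b, params.stripe_count)
        # every striation stays individually visible (degree definitions
        # describe visible lines), with mild amplitude variation
        amps = rng.uniform(0.75, 1.0, params.stripe_count)
        meander_amp = rng.uniform(0.5, 2.0, params.stripe_count)
        meander_freq = rng.uniform(0.02, 0.05, params.stripe_count)
        phase = rng.uniform(0, 2 * np.pi, params.stripe_count)
        band = np.zeros((h, w))
        for k in range(params.stripe_count):
            center = offsets[k] + meander_amp[k] * np.sin(
                meander_freq[k] * u + phase[k])
            d = v - center
            band += amps[k] * np.exp(-0.5 * (d / sigma) ** 2)
        # blend toward matte fat-white: striation brightness never reaches
        # the specular range, so bright-pixel removal leaves stripes intact
        t = np.clip(band, 0.0, 1.0) * min(params.stripe_contrast / 100.0, 1.0)
        for c in range(3):
            meat[..., c] = meat[..., c] * (1.0 - t) + _STRIPE_COLOR[c] * t

    img[inside] = meat[inside]

    # multiplicative illumination ramp across a random direction
    phi = rng.uniform(0, 2 * np.pi)
    ramp = (dx * np.cos(phi) + dy * np.sin(phi)) / max(h, w)
    img *= (1.0 + params.illumination_gradient * ramp)[..., None]

    # ruler-like white bar outside the meat, near an image edge; rulers
    # photograph near-saturated, i.e. inside the "extremely bright" range
    bar_h = max(3, h // 32)
    bar_row = rng.integers(2, max(3, h // 10))
    bar = np.zeros((h, w), dtype=bool)
    bar[bar_row:bar_row + bar_h, w // 8: 7 * w // 8] = True
    bar &= ~inside
    img[bar] = 250.0

    # specular highlights: saturated cores with Gaussian shoulders
    for _ in range(params.n_specular_spots):
        r = rng.uniform(0.2, 0.75)
        ang = rng.uniform(0, 2 * np.pi)
        # place in ellipse coordinates to guarantee the spot is on the meat
        su = r * a * np.cos(ang)
        sv = r * b * np.sin(ang)
        px = cx + su * np.cos(theta) - sv * np.sin(theta)
        py = cy + su * np.sin(theta) + sv * np.cos(theta)
        rad = rng.uniform(2.5, 5.0)
        d2 = (xx - px) ** 2 + (yy - py) ** 2
        blob = 255.0 * np.exp(-0.5 * d2 / rad**2)
        core = d2 <= (0.9 * rad) ** 2
        img = np.maximum(img, blob[..., None])
        img[core] = 255.0

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, img.shape)

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabeledImage(pixels=pixels, degree=params.degree,
                        sample_id=0, image_id=0, params=params)


def generate_dataset(
    n_per_class: int,
    seed: int,
    *,
    profile: str = "strong",
    image_size: tuple[int, int] = (256, 256),
    px_per_mm: float = DEFAULT_PX_PER_MM,
) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Generate a balanced labeled image set with two captures per sample.

    Mirrors the study design: ``n_per_class`` fillet samples per severity
    degree, photographed twice (the second capture re-renders the same
    sample with a perturbed seed), so the returned list holds
    ``6 * n_per_class`` images.  The manifest has one row per image with
    columns (image_id, sample_id, degree, seed).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    images: list[LabeledImage] = []
    rows = []
    sample_id = 0
    image_id = 0
    for degree in DEGREES:
        for _ in range(n_per_class):
            sample_id += 1
            base = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
            for capture in range(2):
                image_id += 1
                sub = base + capture  # second photograph: perturbed seed
                params = degree_to_params(
                    degree, sub, px_per_mm=px_per_mm,
                    profile=profile, image_size=image_size)
                im = render_scene(params)
                im.sample_id = sample_id
                im.image_id = image_id
                images.append(im)
                rows.append({"image_id": image_id, "sample_id": sample_id,
                             "degree": degree, "seed": sub})
    manifest = pd.DataFrame(rows)
    return images, manifest


def params_to_dict(params: SceneParams) -> dict:
    """JSON-serializable view of scene parameters."""
    d = asdict(params)
    d["image_size"] = list(d["image_size"])
    d["meat_axes"] = list(d["meat_axes"])
    d["background_color"] = list(d["background_color"])
    return d
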