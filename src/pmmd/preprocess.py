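"""Image preprocessing: median filtering, Otsu binarization, dilation,
and the stochastic augmentation schedule.

The canonical order is grayscale -> 3x3 median filter -> Otsu -> optional
dilation.  Noise removal always precedes dilation so that salt-and-pepper
speckle is not grown into fake strokes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import yaml
from scipy import ndimage
from skimage.transform import AffineTransform, warp

from .raster import ImageContractError, RasterImage

__all__ = [
    "AugmentConfig",
    "DegenerateHistogramError",
    "median_filter_3x3",
    "otsu_threshold",
    "otsu_binarize",
    "dilate",
    "augment",
    "preprocess",
]


class DegenerateHistogramError(ValueError):
    """Otsu thresholding is undefined on a single-valued image."""


# --------------------------------------------------------------------------
# median filter
# --------------------------------------------------------------------------

def median_filter_3x3(img: RasterImage) -> RasterImage:
    """3x3 median filter with edge replication at the borders.

    Border pixels see a full 9-sample window whose out-of-frame entries
    replicate the nearest edge pixel, so corners are filtered with the
    same window size as interior pixels.
    """
    out = ndimage.median_filter(img.pixels, size=3, mode="nearest")
    return img.with_pixels(out, "median_filter_3x3")


# --------------------------------------------------------------------------
# Otsu
# --------------------------------------------------------------------------

def otsu_threshold(pixels: np.ndarray) -> int:
    """Threshold maximizing between-class variance over the 256-bin histogram.

    Pixels with intensity ``<= t`` form the low class, ``> t`` the high
    class.  Among maximizing candidates the lowest threshold is returned.
    Raises :class:`DegenerateHistogramError` on single-valued input.
    """
    hist = np.bincount(np.asarray(pixels, dtype=np.uint8).ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("image has fewer than 2 distinct intensities")
    total = hist.sum()
    levels = np.arange(256, dtype=float)
    # cumulative class 0 (<= t) statistics for every candidate t
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * levels)
    mean_total = m0[-1] / total
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # exclude t = 255 (empty high class); argmax returns the lowest maximizer
    return int(np.argmax(between[:255]))


def otsu_binarize(img: RasterImage) -> tuple[RasterImage, int]:
    """Binarize with the Otsu threshold.

    Pixels above the threshold map to 255 (background), the rest to 0, so
    dark ink becomes the foreground value 0.  The convention is recorded
    in metadata as ``foreground="low"``.
    """
    t = otsu_threshold(img.pixels)
    binary = np.where(img.pixels > t, 255, 0).astype(np.uint8)
    out = img.with_pixels(binary, "otsu_binarize")
    out.metadata["otsu_threshold"] = t
    out.metadata["foreground"] = "low"
    return out, t


# --------------------------------------------------------------------------
# dilation
# --------------------------------------------------------------------------

def dilate(binary: RasterImage, kernel_size: int = 3, iterations: int = 1) -> RasterImage:
    """Morphological dilation of the ink foreground with a square element.

    The foreground (ink = 0 in the light-background convention) never
    shrinks; ``iterations`` applications compose.
    """
    if not binary.is_binary:
        raise ImageContractError("dilate requires a binary {0, 255} image")
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ImageContractError("kernel_size must be an odd integer >= 1")
    if iterations < 0:
        raise ImageContractError("iterations must be >= 0")
    fg = binary.pixels == 0
    if iterations > 0 and kernel_size > 1:
        structure = np.ones((kernel_size, kernel_size), dtype=bool)
        fg = ndimage.binary_dilation(fg, structure=structure, iterations=iterations)
    out = np.where(fg, 0, 255).astype(np.uint8)
    return binary.with_pixels(out, f"dilate(k={kernel_size},n={iterations})")


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Stochastic augmentation schedule.

    The defaults are the study schedule: both flips enabled, 10% shifts,
    brightness multipliers in (0.5, 1.5), full 360-degree rotation and 20%
    zoom.  Shift/zoom fractions are relative to the image dimensions.
    """

    horizontal_flip: bool = True
    vertical_flip: bool = True
    width_shift_range: float = 0.1
    height_shift_range: float = 0.1
    brightness_range: tuple[float, float] = (0.5, 1.5)
    rotation_range: float = 360.0
    zoom_range: float = 0.2
    copies_per_image: int = 1
    fill_value: int = 255
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.width_shift_range <= 1 and 0 <= self.height_shift_range <= 1):
            raise ValueError("shift fractions must lie in [0, 1]")
        lo, hi = self.brightness_range
        if lo > hi:
            raise ValueError("brightness_range must be (low, high) with low <= high")
        if not (0 <= self.rotation_range <= 360):
            raise ValueError("rotation_range must lie in [0, 360]")
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "AugmentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "brightness_range" in raw:
            raw["brightness_range"] = tuple(raw["brightness_range"])
        return cls(**raw)

    def with_seed(self, seed: int) -> "AugmentConfig":
        return replace(self, seed=seed)


def _augment_one(px: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    h, w = px.shape
    out = px.astype(float)

    flip_h = cfg.horizontal_flip and rng.random() < 0.5
    flip_v = cfg.vertical_flip and rng.random() < 0.5
    dx = rng.uniform(-cfg.width_shift_range, cfg.width_shift_range) * w
    dy = rng.uniform(-cfg.height_shift_range, cfg.height_shift_range) * h
    brightness = rng.uniform(*cfg.brightness_range)
    angle = np.deg2rad(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
    zoom = 1.0 + rng.uniform(-cfg.zoom_range, cfg.zoom_range)

    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]

    geometric = (dx, dy) != (0.0, 0.0) or angle != 0.0 or zoom != 1.0
    if geometric:
        centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        t = (
            AffineTransform(translation=-centre)
            + AffineTransform(rotation=angle, scale=zoom)
            + AffineTransform(translation=centre + np.array([dx, dy]))
        )
        out = warp(
            out,
            t.inverse,
            order=1,
            cval=float(cfg.fill_value),
            mode="constant",
            preserve_range=True,
        )
    out = out * brightness
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment(img: RasterImage, config: AugmentConfig) -> list[RasterImage]:
    """Emit ``copies_per_image`` randomized variants of ``img``.

    Sampling (flips, shift, brightness, rotation, zoom) is driven entirely
    by ``config.seed``, so a fixed config reproduces the same sequence.
    Out-of-frame regions are filled with ``fill_value`` (background white
    by default, so no fake ink appears at the borders).
    """
    rng = np.random.default_rng(config.seed)
    out: list[RasterImage] = []
    for i in range(config.copies_per_image):
        px = _augment_one(img.pixels, rng, config)
        aug = img.with_pixels(px, f"augment[{i}]")
        out.append(aug)
    return out


# --------------------------------------------------------------------------
# standard pipeline
# --------------------------------------------------------------------------

def preprocess(
    img: RasterImage,
    apply_dilation: bool = False,
    kernel_size: int = 3,
    iterations: int = 1,
) -> tuple[RasterImage, RasterImage]:
    """Run the standard chain and return ``(filtered, binary)``.

    ``filtered`` is the median-filtered grayscale page (used by features
    that need pre-binarization intensities, e.g. pen-pressure analysis);
    ``binary`` is its Otsu binarization, optionally dilated.
    """
    filtered = median_filter_3x3(img)
    binary, _ = otsu_binarize(filtered)
    if apply_dilation:
        binary = dilate(binary, kernel_size=kernel_size, iterations=iterations)
    return filtered, binary
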