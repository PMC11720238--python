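"""Handcrafted micrographia features from handwriting page images.

Four scalar features summarize the graphomotor properties of a scanned
page:

    PPI  pen-pressure irregularity: mean intensity SD over ink patches
    SI   slant irregularity: SD of detected stroke-segment angles
    HLI  handwritten-line irregularity: RMS baseline deviation per line
    WS   word spacing: mean horizontal gap between consecutive words

PPI reads the grayscale (pre-binarization) page; SI, HLI and WS read the
binarized page.  Angles use an x-right / y-up convention (image rows are
negated) and are folded to (-90, 90] degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import skeletonize
from skimage.transform import probabilistic_hough_line

from .preprocess import DegenerateHistogramError, otsu_threshold
from .raster import ImageContractError, RasterImage, ink_mask

__all__ = [
    "HandwritingFeatures",
    "NoInkError",
    "InsufficientWordsError",
    "pen_pressure_irregularity",
    "slant_irregularity",
    "line_irregularity",
    "word_spacing",
    "extract_handwriting_features",
]


class NoInkError(ValueError):
    """Raised when a page holds no usable ink."""


class InsufficientWordsError(ValueError):
    """Raised when no text line holds two or more words."""


@dataclass
class HandwritingFeatures:
    """The four handcrafted page features plus their per-item detail."""

    ppi: float
    si: float
    hli: float
    ws: float
    per_line_angles: list[float]
    word_gaps: list[float]

    def as_array(self) -> np.ndarray:
        return np.array([self.ppi, self.si, self.hli, self.ws])

    names = ("ppi", "si", "hli", "ws")


# --------------------------------------------------------------------------
# PPI
# --------------------------------------------------------------------------

def pen_pressure_irregularity(
    img: RasterImage, patch_size: int = 16, ink_fraction: float = 0.10
) -> tuple[float, list[float]]:
    """Mean within-patch intensity SD over ink-containing patches.

    The page is tiled with non-overlapping ``patch_size`` squares; a patch
    counts as ink when at least ``ink_fraction`` of its pixels fall at or
    below the page's Otsu threshold (the binarization ink class).  Per patch, the mean is ``sum(X) / N`` and
    the SD uses divisor ``N - 1``; PPI is the mean of the patch SDs.
    """
    if patch_size < 2:
        raise ValueError("patch_size must be >= 2")
    px = img.pixels
    try:
        t = otsu_threshold(px)
    except DegenerateHistogramError as exc:
        raise NoInkError("constant page has no ink") from exc
    sds: list[float] = []
    h, w = px.shape
    for r0 in range(0, h - patch_size + 1, patch_size):
        for c0 in range(0, w - patch_size + 1, patch_size):
            patch = px[r0:r0 + patch_size, c0:c0 + patch_size].astype(float)
            if (patch <= t).mean() >= ink_fraction:
                sds.append(float(np.std(patch, ddof=1)))
    if not sds:
        raise NoInkError("no ink patches found")
    return float(np.mean(sds)), sds


# --------------------------------------------------------------------------
# SI
# --------------------------------------------------------------------------

def segment_angle_deg(x1: float, y1: float, x2: float, y2: float) -> float:
    """Angle of a segment in degrees, x-right / y-up, folded to (-90, 90]."""
    ang = np.rad2deg(np.arctan2(y2 - y1, x2 - x1))
    while ang > 90:
        ang -= 180
    while ang <= -90:
        ang += 180
    return float(ang)


def slant_irregularity(
    img: RasterImage,
    line_length: int = 30,
    line_gap: int = 3,
    hough_threshold: int = 10,
) -> tuple[float, list[float]]:
    """SD of stroke-segment angles detected on the page.

    Straight segments are found with a probabilistic Hough transform on
    the skeleton of the ink mask (seeded, so detection is deterministic).
    Segment endpoints are image ``(col, row)`` pairs; rows are negated to
    obtain y-up angles, folded to (-90, 90].  Returns ``si = 0`` with a
    warning when no segment is found.
    """
    if not img.is_binary:
        raise ImageContractError("slant_irregularity expects a binarized page")
    mask = ink_mask(img)
    if not mask.any():
        warnings.warn("no ink on page; SI set to 0", stacklevel=2)
        return 0.0, []
    skel = skeletonize(mask)
    segments = probabilistic_hough_line(
        skel, threshold=hough_threshold, line_length=line_length,
        line_gap=line_gap, rng=np.random.default_rng(0),
    )
    angles = [
        segment_angle_deg(p0[0], -p0[1], p1[0], -p1[1]) for p0, p1 in segments
    ]
    if not angles:
        warnings.warn("no straight segments detected; SI set to 0", stacklevel=2)
        return 0.0, []
    ddof = 1 if len(angles) > 1 else 0
    return float(np.std(angles, ddof=ddof)), angles


# --------------------------------------------------------------------------
# line segmentation helpers
# --------------------------------------------------------------------------

def _line_bands(mask: np.ndarray) -> list[tuple[int, int]]:
    """Text-line row bands from horizontal-projection valleys."""
    profile = mask.sum(axis=1)
    rows_with_ink = profile > 0
    bands: list[tuple[int, int]] = []
    start = None
    for r, has in enumerate(rows_with_ink):
        if has and start is None:
            start = r
        elif not has and start is not None:
            bands.append((start, r))
            start = None
    if start is not None:
        bands.append((start, len(rows_with_ink)))
    return bands


# --------------------------------------------------------------------------
# HLI
# --------------------------------------------------------------------------

def line_irregularity(img: RasterImage) -> tuple[float, list[np.ndarray]]:
    """Mean RMS deviation of each line's lower contour from its baseline.

    Lines are segmented by projection valleys; per line, the bottom-most
    ink row of each ink-bearing column is collected, a least-squares
    straight baseline is fitted through those points, and the line's score
    is the RMS vertical residual.  HLI is the mean over lines.
    """
    if not img.is_binary:
        raise ImageContractError("line_irregularity expects a binarized page")
    mask = ink_mask(img)
    bands = _line_bands(mask)
    if not bands:
        raise NoInkError("no text lines found")
    rms_values: list[float] = []
    baselines: list[np.ndarray] = []
    for r0, r1 in bands:
        band = mask[r0:r1]
        cols = np.flatnonzero(band.any(axis=0))
        if len(cols) < 3:
            continue
        # bottom-most ink row per ink column
        bottoms = r0 + (band.shape[0] - 1 - np.argmax(band[::-1][:, cols], axis=0))
        coef = np.polyfit(cols, bottoms.astype(float), 1)
        fitted = np.polyval(coef, cols)
        resid = bottoms - fitted
        rms_values.append(float(np.sqrt(np.mean(resid**2))))
        baselines.append(np.column_stack([cols, fitted]))
    if not rms_values:
        raise NoInkError("no usable text lines found")
    return float(np.mean(rms_values)), baselines


# --------------------------------------------------------------------------
# WS
# --------------------------------------------------------------------------

def _merge_word_gaps(gaps: list[float]) -> list[float]:
    """Drop intra-word gaps using an Otsu split of the gap distribution.

    Character-level splits inside a word produce a cluster of small gaps
    well below the inter-word cluster.  The Otsu threshold over the
    pooled gap lengths separates the two, but it only activates under a
    bimodality guard — the split must explain >= 85% of the gap variance
    and the lower cluster's mean must be under half the upper cluster's —
    so a unimodal spread of genuine inter-word gaps is never split.
    """
    arr = np.asarray(gaps, dtype=float)
    if len(arr) < 3 or arr.max() < 2 * arr.min() or arr.var() == 0:
        return list(gaps)
    scaled = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    try:
        t = otsu_threshold(scaled)
    except DegenerateHistogramError:
        return list(gaps)
    low, high = arr[arr <= t], arr[arr > t]
    if len(low) == 0 or len(high) == 0:
        return list(gaps)
    w0 = len(low) / len(arr)
    between = w0 * (1 - w0) * (low.mean() - high.mean()) ** 2
    if between / arr.var() < 0.85 or low.mean() >= 0.5 * high.mean():
        return list(gaps)
    return high.tolist()


def word_spacing(img: RasterImage, min_component_area: int = 12
                 ) -> tuple[float, list[float]]:
    """Mean horizontal gap between consecutive words, per text line.

    Words are connected components assigned to projection-valley line
    bands by centroid row; per line, components are ordered by column and
    the gap between consecutive bounding boxes is the count of empty
    columns between them.  Gaps below the intra-word threshold (Otsu on
    the pooled gap distribution, with a bimodality guard) are treated as
    within-word splits and discarded.
    """
    if not img.is_binary:
        raise ImageContractError("word_spacing expects a binarized page")
    mask = ink_mask(img)
    bands = _line_bands(mask)
    if not bands:
        raise NoInkError("no text lines found")
    labels = cc_label(mask, connectivity=2)
    props = [p for p in regionprops(labels) if p.area >= min_component_area]
    if not props:
        raise NoInkError("no word components found")

    band_centres = np.array([(r0 + r1) / 2.0 for r0, r1 in bands])
    per_band: dict[int, list] = {i: [] for i in range(len(bands))}
    for p in props:
        bi = int(np.argmin(np.abs(band_centres - p.centroid[0])))
        per_band[bi].append(p)

    raw_gaps: list[float] = []
    any_two_words = False
    for comps in per_band.values():
        if len(comps) < 2:
            continue
        any_two_words = True
        comps = sorted(comps, key=lambda p: p.bbox[1])
        for a, b in zip(comps, comps[1:]):
            gap = b.bbox[1] - a.bbox[3]  # empty columns between boxes
            raw_gaps.append(float(max(gap, 0)))
    if not any_two_words:
        raise InsufficientWordsError("fewer than 2 words on every line")
    gaps = _merge_word_gaps(raw_gaps)
    return float(np.mean(gaps)), gaps


# --------------------------------------------------------------------------
# combined
# --------------------------------------------------------------------------

def extract_handwriting_features(
    gray: RasterImage, binary: RasterImage, patch_size: int = 16
) -> HandwritingFeatures:
    """Compute PPI (on the grayscale page) and SI/HLI/WS (on the binary page)."""
    ppi, _ = pen_pressure_irregularity(gray, patch_size=patch_size)
    si, angles = slant_irregularity(binary)
    hli, _ = line_irregularity(binary)
    ws, gaps = word_spacing(binary)
    return HandwritingFeatures(ppi, si, hli, ws, angles, gaps)
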