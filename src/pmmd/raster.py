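"""Grayscale raster images with provenance metadata.

Every image operation in the package consumes and produces a
:class:`RasterImage`: a 2-D grid of 8-bit intensities plus a free-form
metadata map that records where the image came from and which operations
have been applied to it.  Colour inputs are reduced to luminance with the
Rec. 601 weights before any analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np

__all__ = ["RasterImage", "ImageContractError", "rgb_to_gray", "ink_mask"]

#: Rec. 601 luma weights used to collapse RGB scans to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


class ImageContractError(ValueError):
    """Raised when an image violates an operation's input contract."""


def rgb_to_gray(pixels: np.ndarray) -> np.ndarray:
    """Collapse an ``(H, W, 3)`` or ``(H, W, 4)`` array to 8-bit luminance."""
    rgb = np.asarray(pixels, dtype=float)[..., :3]
    gray = rgb @ _LUMA
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


@dataclass
class RasterImage:
    """A 2-D grayscale image with intensities in ``[0, 255]``.

    Parameters
    ----------
    pixels:
        2-D ``uint8`` array (rows, columns).  RGB(A) input is converted
        to luminance on construction.
    metadata:
        Provenance map.  Generators store ground-truth parameters here
        (spiral centre and polylines, handwriting line angles, ...);
        image operations append their names under ``"applied_ops"``.
    """

    pixels: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3:
            px = rgb_to_gray(px)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageContractError(f"expected a non-empty 2-D image, got shape {px.shape}")
        if px.dtype != np.uint8:
            arr = np.asarray(px, dtype=float)
            if arr.min() < 0 or arr.max() > 255:
                raise ImageContractError("intensities must lie in [0, 255]")
            px = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def is_binary(self) -> bool:
        """True when the image contains only the values {0, 255}."""
        return bool(np.isin(np.unique(self.pixels), (0, 255)).all())

    def with_pixels(self, pixels: np.ndarray, op: str | None = None) -> "RasterImage":
        """Return a new image carrying this image's metadata, optionally
        recording ``op`` in the applied-operations trail."""
        meta = dict(self.metadata)
        if op is not None:
            meta["applied_ops"] = list(meta.get("applied_ops", [])) + [op]
        return RasterImage(pixels, meta)

    def copy(self) -> "RasterImage":
        return RasterImage(self.pixels.copy(), dict(self.metadata))

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        iio.imwrite(Path(path), self.pixels)

    @classmethod
    def load(cls, path: str | Path) -> "RasterImage":
        px = iio.imread(Path(path))
        return cls(px, {"source_path": str(path)})

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, RasterImage):
            return NotImplemented
        return self.pixels.shape == other.pixels.shape and bool(
            (self.pixels == other.pixels).all()
        )


def ink_mask(img: RasterImage, threshold: int | None = None) -> np.ndarray:
    """Boolean mask of ink (stroke) pixels.

    Pages are dark-ink-on-light-background, so ink is the *low* intensity
    class.  For binary images ink is exactly the 0 level; otherwise pixels
    strictly below ``threshold`` (which must then be given) are ink.
    """
    if img.is_binary:
        return img.pixels == 0
    if threshold is None:
        raise ImageContractError("non-binary image requires an explicit ink threshold")
    return img.pixels < threshold


def asdict_meta(img: RasterImage) -> dict[str, Any]:  # pragma: no cover - helper
    return dataclasses.asdict(img)
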