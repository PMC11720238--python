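"""Pluggable image-embedding backbones.

Deep page embeddings complement the four handcrafted handwriting features.
A backbone is anything satisfying the ``image -> fixed-length vector``
contract; backbones register themselves in a module-level registry and
are addressed by id.  The packaged default is a compact two-stage
convolutional network with fixed, seeded He-initialized filters: random
convolutional features are deterministic, training-free, and well suited
to offline pipelines, while remaining swappable for any heavier network
that honours the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from skimage.transform import resize

from .raster import RasterImage

__all__ = ["EmbeddingVector", "Backbone", "SmallConvNet", "register_backbone",
           "get_backbone", "deep_embedding"]


@dataclass
class EmbeddingVector:
    """A fixed-length embedding with its provenance."""

    values: np.ndarray
    backbone_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("embedding contains non-finite values")

    @property
    def dimension(self) -> int:
        return int(self.values.size)


class Backbone(Protocol):
    """The contract an embedding backbone must satisfy."""

    backbone_id: str
    dim: int

    def embed(self, pixels: np.ndarray) -> np.ndarray:  # pragma: no cover
        ...


def _conv_valid(x: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Valid-mode 2-D correlation of ``x`` (H, W, Cin) with filters
    (Cout, kh, kw, Cin), via a sliding-window einsum."""
    kh, kw = filters.shape[1], filters.shape[2]
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(0, 1))
    # windows: (H-kh+1, W-kw+1, Cin, kh, kw)
    return np.einsum("ijcab,oabc->ijo", windows, filters)


class SmallConvNet:
    """Two seeded random-filter conv stages with pooling statistics.

    Input pages are resized to ``input_size`` squared, mapped to ink
    saliency in [0, 1] (dark ink -> high activation), passed through
    conv(3x3) -> ReLU -> 2x2 average pool -> conv(3x3) -> ReLU, and
    reduced to per-channel mean and max activations.  The filters are
    fixed at construction from ``weight_seed``, so the embedding is a
    pure deterministic function of the image.
    """

    def __init__(self, backbone_id: str = "smallcnn32", input_size: int = 64,
                 c1: int = 8, c2: int = 16, weight_seed: int = 1234) -> None:
        rng = np.random.default_rng(weight_seed)
        self.backbone_id = backbone_id
        self.input_size = input_size
        # He-style init keeps activation scale stable through the stages
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / 9.0), (c1, 3, 3, 1))
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / (9.0 * c1)), (c2, 3, 3, c1))
        self.dim = 2 * c2

    def embed(self, pixels: np.ndarray) -> np.ndarray:
        x = np.asarray(pixels, dtype=float)
        x = resize(x, (self.input_size, self.input_size), order=1,
                   preserve_range=True, anti_aliasing=True)
        x = 1.0 - x / 255.0  # ink saliency
        x = x[..., None]
        h = np.maximum(_conv_valid(x, self.w1), 0.0)
        # 2x2 average pooling
        hh, ww = (h.shape[0] // 2) * 2, (h.shape[1] // 2) * 2
        h = h[:hh, :ww].reshape(hh // 2, 2, ww // 2, 2, -1).mean(axis=(1, 3))
        h = np.maximum(_conv_valid(h, self.w2), 0.0)
        return np.concatenate([h.mean(axis=(0, 1)), h.max(axis=(0, 1))])


_REGISTRY: dict[str, Callable[[], Backbone]] = {}
_INSTANCES: dict[str, Backbone] = {}


def register_backbone(backbone_id: str, factory: Callable[[], Backbone]) -> None:
    _REGISTRY[backbone_id] = factory


def get_backbone(backbone_id: str) -> Backbone:
    if backbone_id not in _REGISTRY:
        raise KeyError(
            f"unknown backbone {backbone_id!r}; registered: {sorted(_REGISTRY)}"
        )
    if backbone_id not in _INSTANCES:
        _INSTANCES[backbone_id] = _REGISTRY[backbone_id]()
    return _INSTANCES[backbone_id]


register_backbone("smallcnn32", lambda: SmallConvNet("smallcnn32"))
register_backbone("smallcnn16", lambda: SmallConvNet("smallcnn16", c1=4, c2=8))


def deep_embedding(img: RasterImage, backbone_id: str = "smallcnn32") -> EmbeddingVector:
    """Embed a page with a registered backbone.

    Deterministic for fixed backbone weights; raises ``KeyError`` for an
    unregistered id.
    """
    backbone = get_backbone(backbone_id)
    values = backbone.embed(img.pixels)
    vec = EmbeddingVector(values, backbone_id)
    if vec.dimension != backbone.dim:
        raise RuntimeError("backbone returned a vector of undeclared length")
    return vec
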