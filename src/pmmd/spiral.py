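"""Spiral tremor statistics from matched template/trace radius series.

A subject traces a printed spiral template; tremor shows up as radial
deviation of the drawn trace (HT) from the template (ET).  Radii are
sampled at matched angular positions along the spiral winding by casting
rays from the shared centre, and five scalar statistics summarize the
per-position radius differences:

    x1  RMS of the differences
    x2  maximum absolute difference
    x3  minimum absolute difference
    x4  population SD of the signed differences
    x5  mean relative tremor (MRT): mean absolute lag-l radius increment

The MRT lag and the series it reads (trace vs template radii) are
configurable; the default reads the trace, where tremor lives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .raster import ImageContractError, RasterImage, ink_mask

__all__ = [
    "SpiralSamplingConfig",
    "RadiusSeries",
    "SpiralFeatures",
    "NoCurveError",
    "sample_radii",
    "spiral_statistics",
    "extract_spiral_features",
]


class NoCurveError(ValueError):
    """Raised when an image holds no usable spiral foreground."""


class InsufficientPairsError(ValueError):
    """Raised when too few matched radius pairs survive sampling."""


@dataclass
class SpiralSamplingConfig:
    """How radii are sampled and summarized.

    ``n_samples`` matched positions are taken along the full winding;
    ``mrt_lag`` is the increment lag l of the MRT statistic (1 <= l <
    n_samples); ``max_missing_fraction`` bounds the tolerated fraction of
    rays with no usable crossing.
    """

    n_samples: int = 360
    centre_mode: str = "metadata"          # metadata | centroid | user
    centre: tuple[float, float] | None = None
    mrt_lag: int = 4
    mrt_series: str = "trace"              # trace | template
    angular_start: float = 0.0
    radial_step: float = 0.5
    max_missing_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not (1 <= self.mrt_lag < self.n_samples):
            raise ValueError("mrt_lag must satisfy 1 <= lag < n_samples")
        if self.centre_mode not in ("metadata", "centroid", "user"):
            raise ValueError(f"unknown centre_mode {self.centre_mode!r}")
        if self.mrt_series not in ("trace", "template"):
            raise ValueError(f"unknown mrt_series {self.mrt_series!r}")


@dataclass
class RadiusSeries:
    """Matched centre-to-curve distances on template and trace.

    Missing samples (rays without a usable crossing) are NaN in both
    arrays and excluded pairwise by :func:`spiral_statistics`.
    """

    radii_template: np.ndarray
    radii_trace: np.ndarray
    centre: tuple[float, float]
    angles: np.ndarray
    n_missing: int = 0

    def __post_init__(self) -> None:
        self.radii_template = np.asarray(self.radii_template, dtype=float)
        self.radii_trace = np.asarray(self.radii_trace, dtype=float)
        if self.radii_template.shape != self.radii_trace.shape:
            raise ValueError("template and trace radius series must have equal length")
        for arr in (self.radii_template, self.radii_trace):
            if np.nanmin(arr, initial=0.0) < 0:
                raise ValueError("radii must be >= 0")

    @property
    def usable(self) -> np.ndarray:
        return ~(np.isnan(self.radii_template) | np.isnan(self.radii_trace))


@dataclass
class SpiralFeatures:
    """The five spiral statistics, all in pixels."""

    x1_rms: float
    x2_max_diff: float
    x3_min_diff: float
    x4_std_diff: float
    x5_mrt: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x1_rms, self.x2_max_diff, self.x3_min_diff,
                         self.x4_std_diff, self.x5_mrt])

    names = ("x1_rms", "x2_max_diff", "x3_min_diff", "x4_std_diff", "x5_mrt")


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def _resolve_centre(template: RasterImage, mask: np.ndarray,
                    config: SpiralSamplingConfig) -> tuple[float, float]:
    if config.centre_mode == "user":
        if config.centre is None:
            raise ValueError("centre_mode='user' requires config.centre")
        return tuple(map(float, config.centre))
    if config.centre_mode == "metadata" and "centre" in template.metadata:
        return tuple(map(float, template.metadata["centre"]))
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def _ray_crossings(mask: np.ndarray, centre: tuple[float, float], phi: float,
                   radial_step: float) -> np.ndarray:
    """Radii of foreground runs along one ray (run centres, ascending)."""
    h, w = mask.shape
    r_max = float(np.hypot(h, w))
    radii = np.arange(0.0, r_max, radial_step)
    rows = np.rint(centre[0] - radii * np.sin(phi)).astype(int)
    cols = np.rint(centre[1] + radii * np.cos(phi)).astype(int)
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    hit = np.zeros(radii.shape, dtype=bool)
    hit[inside] = mask[rows[inside], cols[inside]]
    if not hit.any():
        return np.empty(0)
    # run-length encode: crossings are centres of contiguous hit runs
    d = np.diff(hit.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if hit[0]:
        starts = np.r_[0, starts]
    if hit[-1]:
        ends = np.r_[ends, hit.size]
    return (radii[starts] + radii[ends - 1]) / 2.0


def sample_radii(template: RasterImage, trace: RasterImage,
                 config: SpiralSamplingConfig | None = None) -> RadiusSeries:
    """Sample matched radii along the spiral winding of a template/trace pair.

    ``n_samples`` positions are spread over the full winding (``turns``
    revolutions, from metadata, default 3).  At sample i with cumulative
    angle theta_i, the ray at ``theta_i mod 2pi`` crosses each spiral arm
    once; the template radius is the crossing belonging to turn
    ``floor(theta_i / 2pi)`` (crossings sorted ascending), and the trace
    radius is the trace crossing closest to that template radius —
    tremor perturbations are small against the turn pitch, so proximity
    to the template arm resolves the arm ambiguity.
    """
    config = config or SpiralSamplingConfig()
    mask_t = ink_mask(template) if template.is_binary else None
    mask_d = ink_mask(trace) if trace.is_binary else None
    if mask_t is None or mask_d is None:
        raise ImageContractError("sample_radii expects binarized images")
    if not mask_t.any() or not mask_d.any():
        raise NoCurveError("empty foreground")

    centre = _resolve_centre(template, mask_t, config)
    turns = int(template.metadata.get("turns", 3))
    theta0 = float(template.metadata.get("angular_start", config.angular_start))
    n = config.n_samples
    # stop just short of the endpoint so the final arm is always present
    total = 2 * np.pi * turns
    thetas = theta0 + (np.arange(n) + 0.5) * total / (n + 1)

    r_et = np.full(n, np.nan)
    r_ht = np.full(n, np.nan)
    for i, th in enumerate(thetas):
        phi = th % (2 * np.pi)
        k = int((th - theta0) // (2 * np.pi))
        ct = _ray_crossings(mask_t, centre, phi, config.radial_step)
        if len(ct) <= k:
            continue
        r_template = ct[k]
        cd = _ray_crossings(mask_d, centre, phi, config.radial_step)
        if len(cd) == 0:
            continue
        r_et[i] = r_template
        r_ht[i] = cd[np.argmin(np.abs(cd - r_template))]

    n_missing = int(np.isnan(r_et).sum() + np.isnan(r_ht[~np.isnan(r_et)]).sum())
    series = RadiusSeries(r_et, r_ht, centre, thetas, n_missing=n_missing)
    dropped = 1.0 - series.usable.mean()
    if dropped > config.max_missing_fraction:
        raise NoCurveError(
            f"{dropped:.0%} of rays had no usable crossing (limit "
            f"{config.max_missing_fraction:.0%})"
        )
    if dropped > 0:
        warnings.warn(f"dropped {dropped:.1%} of radius samples", stacklevel=2)
    return series


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def spiral_statistics(series: RadiusSeries,
                      config: SpiralSamplingConfig | None = None) -> SpiralFeatures:
    """Compute the five spiral statistics from a matched radius series.

    Differences are trace minus template.  x1 is the RMS, x2/x3 the
    max/min absolute difference, x4 the population SD (divisor n) of the
    signed differences, and x5 the mean absolute lag-l increment of the
    selected radius series (trace by default).
    """
    config = config or SpiralSamplingConfig(
        n_samples=max(2, len(series.radii_template)),
        mrt_lag=min(4, max(1, len(series.radii_template) - 1)),
    )
    ok = series.usable
    if ok.sum() < 2:
        raise InsufficientPairsError("need at least 2 usable radius pairs")
    et = series.radii_template[ok]
    ht = series.radii_trace[ok]
    d = ht - et
    x1 = float(np.sqrt(np.mean(d**2)))
    x2 = float(np.max(np.abs(d)))
    x3 = float(np.min(np.abs(d)))
    x4 = float(np.std(d))
    mrt_src = ht if config.mrt_series == "trace" else et
    lag = config.mrt_lag
    if len(mrt_src) <= lag:
        raise InsufficientPairsError("series shorter than the MRT lag")
    x5 = float(np.mean(np.abs(mrt_src[lag:] - mrt_src[:-lag])))
    return SpiralFeatures(x1, x2, x3, x4, x5)


def extract_spiral_features(template: RasterImage, trace: RasterImage,
                            config: SpiralSamplingConfig | None = None) -> SpiralFeatures:
    """Sample radii and reduce to the five statistics in one call."""
    config = config or SpiralSamplingConfig()
    return spiral_statistics(sample_radii(template, trace, config), config)
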