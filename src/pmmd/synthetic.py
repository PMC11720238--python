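"""Seeded synthetic multimodal cohorts.

The study's clinical dataset is private, so every downstream stage is
exercised on generated data: Archimedean spiral template/trace pairs with
a sinusoidal tremor perturbation, handwriting pages whose strokes carry
controllable pressure jitter, slant jitter, baseline wobble and word
spacing (the micrographia axis), and clinical tables whose symptom
prevalences differ between classes by a configurable effect.

Every generator stores its ground-truth parameters in image metadata (or
the returned table) so feature extractors can be tested for parameter
recovery, and all randomness flows from a single cohort seed through
per-subject child seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .raster import RasterImage

__all__ = [
    "CohortConfig",
    "SyntheticSubject",
    "SYMPTOM_COLUMNS",
    "CLINICAL_COLUMNS",
    "generate_spiral_pair",
    "generate_handwriting_page",
    "generate_clinical_table",
    "generate_cohort",
    "write_cohort",
]

PD, HC = "PD", "HC"

#: The seven binary symptom indicators of the clinical schema.
SYMPTOM_COLUMNS = [
    "postural_instability",
    "fatigue_somnolence",
    "olfactory_loss",
    "constipation",
    "sleep_disorders",
    "speech_changes",
    "lift_heavy_difficulty",
]

CLINICAL_COLUMNS = ["age", "gender", "education_level", *SYMPTOM_COLUMNS]

_INK = 60  # nominal stroke intensity
_BG = 245  # page background intensity


class ConfigurationError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    The defaults describe a balanced 150-subject cohort with moderate
    graphomotor and clinical class effects; set the PD parameters equal to
    the HC ones (and ``clinical_effect`` to zeros) for a null cohort.
    """

    n_pd: int = 75
    n_hc: int = 75
    # --- spiral drawing ---
    image_size: int = 256
    spiral_turns: int = 3
    stroke_width: int = 3
    tremor_amplitude: float = 1.5      # radial perturbation (px) for PD traces
    tremor_frequency: float = 8.0      # oscillations per revolution
    trace_noise: float = 0.8           # smooth radial jitter SD (px), both classes
    # --- handwriting page ---
    page_height: int = 256
    page_width: int = 384
    n_lines: int = 5
    words_per_line: int = 4
    pressure_jitter_pd: float = 12.0   # intra-stroke intensity SD
    pressure_jitter_hc: float = 4.0
    slant_jitter_pd: float = 3.0       # per-line angle SD (degrees)
    slant_jitter_hc: float = 1.0
    baseline_wobble_pd: float = 3.0    # vertical deviation SD (px)
    baseline_wobble_hc: float = 1.0
    word_gap_mean_pd: float = 12.0     # mean inter-word gap (px); micrographia
    word_gap_mean_hc: float = 24.0
    word_gap_sd: float = 0.0
    # --- per-subject heterogeneity ---
    severity_spread: float = 0.3       # lognormal sigma scaling each subject's effects
    # --- clinical table ---
    clinical_effect: tuple[float, ...] = (0.4,) * 7
    symptom_base_prev: float = 0.15
    missing_fraction: float = 0.0
    outlier_fraction: float = 0.0
    # --- corruption / seed ---
    noise_salt_pepper: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_hc < 0:
            raise ConfigurationError("subject counts must be >= 0")
        if self.image_size < 64:
            raise ConfigurationError("image_size must be >= 64 px")
        if self.n_lines < 2 or self.words_per_line < 3:
            raise ConfigurationError("need >= 2 lines and >= 3 words per line")
        for name in (
            "tremor_amplitude", "trace_noise", "pressure_jitter_pd", "pressure_jitter_hc",
            "slant_jitter_pd", "slant_jitter_hc", "baseline_wobble_pd", "baseline_wobble_hc",
            "word_gap_sd", "severity_spread",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0")
        for name in ("missing_fraction", "outlier_fraction", "noise_salt_pepper",
                     "symptom_base_prev"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        self.clinical_effect = tuple(float(e) for e in self.clinical_effect)
        if len(self.clinical_effect) != len(SYMPTOM_COLUMNS):
            raise ConfigurationError(
                f"clinical_effect must have {len(SYMPTOM_COLUMNS)} entries"
            )
        if self._min_page_width() > self.page_width or self._min_page_height() > self.page_height:
            raise ConfigurationError("page too small for the requested line/word layout")

    def _min_page_width(self) -> int:
        gap = max(self.word_gap_mean_pd, self.word_gap_mean_hc)
        return int(24 + self.words_per_line * 45 + (self.words_per_line - 1) * gap)

    def _min_page_height(self) -> int:
        return int(2 * 24 + (self.n_lines - 1) * 40 + 16)

    # ------------------------------------------------------------------
    def null(self) -> "CohortConfig":
        """A copy with every class effect removed (chance-level cohort)."""
        return dataclasses.replace(
            self,
            tremor_amplitude=0.0,
            pressure_jitter_pd=self.pressure_jitter_hc,
            slant_jitter_pd=self.slant_jitter_hc,
            baseline_wobble_pd=self.baseline_wobble_hc,
            word_gap_mean_pd=self.word_gap_mean_hc,
            clinical_effect=(0.0,) * len(SYMPTOM_COLUMNS),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clinical_effect"] = list(d["clinical_effect"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "clinical_effect" in raw:
            raw["clinical_effect"] = tuple(raw["clinical_effect"])
        return cls(**raw)


@dataclass
class SyntheticSubject:
    """One generated subject: matched spiral pair, page, and clinical row."""

    subject_id: str
    label: str
    spiral_template: RasterImage
    spiral_trace: RasterImage
    handwriting_page: RasterImage
    clinical_row: dict


# --------------------------------------------------------------------------
# spiral pair
# --------------------------------------------------------------------------

def _render_polyline(size: int, rows: np.ndarray, cols: np.ndarray,
                     stroke_width: int) -> np.ndarray:
    """Stamp a polyline onto a light page as a dark stroke of given width."""
    mask = np.zeros((size, size), dtype=bool)
    r = np.clip(np.rint(rows).astype(int), 0, size - 1)
    c = np.clip(np.rint(cols).astype(int), 0, size - 1)
    mask[r, c] = True
    radius = max(0, (stroke_width - 1) // 2)
    if radius > 0:
        yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
        disk = yy**2 + xx**2 <= radius**2
        mask = ndimage.binary_dilation(mask, structure=disk)
    page = np.full((size, size), _BG, dtype=np.uint8)
    page[mask] = _INK
    return page


def _salt_pepper(px: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    if fraction <= 0:
        return px
    out = px.copy()
    n = int(round(fraction * px.size))
    if n == 0:
        return out
    idx = rng.choice(px.size, size=n, replace=False)
    values = np.where(rng.random(n) < 0.5, 0, 255).astype(np.uint8)
    out.ravel()[idx] = values
    return out


def generate_spiral_pair(
    config: CohortConfig, label: str, seed: int
) -> tuple[RasterImage, RasterImage]:
    """Generate a clean spiral template and a perturbed drawn trace.

    The template is an Archimedean spiral ``r = a + b*theta`` over
    ``spiral_turns`` full turns.  The trace perturbs the radius with
    ``A*sin(f*theta)`` (A = ``tremor_amplitude`` for PD, 0 for HC) plus a
    smooth Gaussian jitter of SD ``trace_noise`` for both classes.  The
    underlying polylines, centre and spiral coefficients are stored in
    metadata.
    """
    rng = np.random.default_rng(seed)
    severity = _severity(rng, config)
    size = config.image_size
    centre = ((size - 1) / 2.0, (size - 1) / 2.0)  # (row, col)
    a = 6.0
    turns = config.spiral_turns
    margin = 12.0 + config.tremor_amplitude + 3 * config.trace_noise
    b = (size / 2.0 - margin - a) / (2 * np.pi * turns)
    if b <= 0:
        raise ConfigurationError("image too small for the requested spiral")

    n_pts = max(2000, int(40 * turns * size / 64))
    theta = np.linspace(0.0, 2 * np.pi * turns, n_pts)
    r_template = a + b * theta

    amp = config.tremor_amplitude * severity if label == PD else 0.0
    noise_sd = config.trace_noise * _severity(rng, config)
    eps = rng.normal(0.0, noise_sd, n_pts) if noise_sd > 0 else np.zeros(n_pts)
    if noise_sd > 0:
        # smooth the jitter so the trace stays a plausible pen path
        eps = ndimage.gaussian_filter1d(eps, sigma=10.0, mode="nearest")
        eps *= noise_sd / max(eps.std(), 1e-12)
    r_trace = r_template + amp * np.sin(config.tremor_frequency * theta) + eps
    r_trace = np.clip(r_trace, 0.0, None)

    def to_image(radii: np.ndarray) -> np.ndarray:
        rows = centre[0] - radii * np.sin(theta)
        cols = centre[1] + radii * np.cos(theta)
        return _render_polyline(size, rows, cols, config.stroke_width)

    meta_common = {
        "centre": centre,
        "spiral_a": a,
        "spiral_b": b,
        "turns": turns,
        "angular_start": 0.0,
        "label": label,
    }
    template = RasterImage(
        _salt_pepper(to_image(r_template), config.noise_salt_pepper, rng),
        {**meta_common, "kind": "spiral_template",
         "polyline_theta": theta, "polyline_r": r_template},
    )
    trace = RasterImage(
        _salt_pepper(to_image(r_trace), config.noise_salt_pepper, rng),
        {**meta_common, "kind": "spiral_trace",
         "polyline_theta": theta, "polyline_r": r_trace,
         "tremor_amplitude": amp, "tremor_frequency": config.tremor_frequency},
    )
    return template, trace


# --------------------------------------------------------------------------
# handwriting page
# --------------------------------------------------------------------------

def _severity(rng: np.random.Generator, config: CohortConfig) -> float:
    """Per-subject multiplicative severity factor (lognormal, median 1).

    Real cohorts are heterogeneous: symptom expression varies across
    subjects, so each subject scales the class-level effect parameters by
    a lognormal draw.  ``severity_spread = 0`` disables the heterogeneity
    (every subject expresses the class-level parameter exactly).
    """
    if config.severity_spread <= 0:
        return 1.0
    return float(rng.lognormal(0.0, config.severity_spread))


def _class_params(config: CohortConfig, label: str, rng: np.random.Generator) -> dict:
    sev = _severity(rng, config)
    if label == PD:
        base = dict(
            pressure_jitter=config.pressure_jitter_pd,
            slant_jitter=config.slant_jitter_pd,
            baseline_wobble=config.baseline_wobble_pd,
            word_gap_mean=config.word_gap_mean_pd,
        )
        # micrographia worsens (gap shrinks) with severity
        gap_scale = 1.0 / sev
    else:
        base = dict(
            pressure_jitter=config.pressure_jitter_hc,
            slant_jitter=config.slant_jitter_hc,
            baseline_wobble=config.baseline_wobble_hc,
            word_gap_mean=config.word_gap_mean_hc,
        )
        gap_scale = _severity(rng, config)
    return dict(
        pressure_jitter=base["pressure_jitter"] * sev,
        slant_jitter=base["slant_jitter"] * sev,
        baseline_wobble=base["baseline_wobble"] * sev,
        word_gap_mean=base["word_gap_mean"] * gap_scale,
    )


def generate_handwriting_page(config: CohortConfig, label: str, seed: int) -> RasterImage:
    """Render a synthetic handwriting page of slanted word strokes.

    Words are filled stroke bars (parallelograms), not glyphs: the four
    downstream features depend only on intensity dispersion, stroke
    angles, baseline straightness and inter-word gaps, not on script
    identity.  Per-line angles, the wobble waveform parameters, the exact
    gap placements and the pressure jitter SD are stored in metadata.
    """
    rng = np.random.default_rng(seed)
    p = _class_params(config, label, rng)
    H, W = config.page_height, config.page_width
    page = np.full((H, W), float(_BG))

    stroke_h = 14
    top_margin = 24
    spacing = (H - 2 * top_margin - stroke_h) / max(config.n_lines - 1, 1)
    spacing = min(spacing, 48.0)

    line_angles: list[float] = []
    all_gaps: list[float] = []
    amp = np.sqrt(2.0) * p["baseline_wobble"]

    for li in range(config.n_lines):
        y_base = top_margin + stroke_h + li * spacing
        angle = rng.normal(0.0, p["slant_jitter"]) if p["slant_jitter"] > 0 else 0.0
        line_angles.append(angle)
        slope = np.tan(np.deg2rad(angle))
        phase = rng.uniform(0, 2 * np.pi)
        # half-page wavelength: >1 full period per line, so a straight-line
        # fit cannot absorb the wobble and its RMS is recoverable
        wavelength = W / 2.0

        x = 16 + int(rng.integers(0, 6))
        x_line_start = x
        for wi in range(config.words_per_line):
            width = int(rng.integers(45, 70))
            x_end = min(x + width, W - 4)
            if x_end - x < 8:
                break
            for cx in range(x, x_end):
                wobble = amp * np.sin(2 * np.pi * cx / wavelength + phase) if amp > 0 else 0.0
                # y-up slant: row decreases as x advances for positive angles
                bottom = y_base - (cx - x_line_start) * slope + wobble
                r1 = int(round(bottom))
                r0 = r1 - stroke_h
                r0, r1 = max(r0, 0), min(r1, H - 1)
                if r1 > r0:
                    ink = _INK + (
                        rng.normal(0.0, p["pressure_jitter"], r1 - r0)
                        if p["pressure_jitter"] > 0 else 0.0
                    )
                    page[r0:r1, cx] = np.clip(ink, 5, 180)
            gap = int(round(max(4.0, rng.normal(p["word_gap_mean"], config.word_gap_sd)))) \
                if config.word_gap_sd > 0 else int(round(p["word_gap_mean"]))
            if wi < config.words_per_line - 1 and x_end + gap + 8 < W - 4:
                all_gaps.append(gap)
            x = x_end + gap

    px = np.clip(np.rint(page), 0, 255).astype(np.uint8)
    px = _salt_pepper(px, config.noise_salt_pepper, rng)
    meta = {
        "kind": "handwriting_page",
        "label": label,
        "line_angles_deg": line_angles,
        "slant_jitter": p["slant_jitter"],
        "baseline_wobble": p["baseline_wobble"],
        "pressure_jitter": p["pressure_jitter"],
        "word_gap_mean": p["word_gap_mean"],
        "word_gaps": all_gaps,
        "stroke_height": stroke_h,
    }
    return RasterImage(px, meta)


# --------------------------------------------------------------------------
# clinical table
# --------------------------------------------------------------------------

def generate_clinical_table(
    config: CohortConfig,
    labels: Sequence[str],
    seed: int,
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One clinical row per subject following the ten-variable schema.

    Age, gender and education are drawn from class-independent
    distributions; the seven binary symptoms have base prevalence
    ``symptom_base_prev`` for controls and base + effect for PD.  Optional
    missing cells and gross age outliers are injected for testing the
    clinical preprocessing; their positions are recorded in ``df.attrs``.
    """
    if len(labels) == 0:
        raise ConfigurationError("labels must be nonempty")
    rng = np.random.default_rng(seed)
    n = len(labels)
    is_pd = np.array([lab == PD for lab in labels])

    df = pd.DataFrame({
        "subject_id": subject_ids if subject_ids is not None
        else [f"S{i:04d}" for i in range(n)],
        "age": np.round(rng.normal(64.0, 9.0, n)).clip(35, 90),
        "gender": rng.choice(["M", "F"], size=n),
        "education_level": rng.integers(0, 5, n),
    })
    for col, effect in zip(SYMPTOM_COLUMNS, config.clinical_effect):
        prev = np.where(is_pd, np.clip(config.symptom_base_prev + effect, 0, 1),
                        config.symptom_base_prev)
        df[col] = (rng.random(n) < prev).astype(int)
    df["label"] = list(labels)

    outlier_idx: list[int] = []
    if config.outlier_fraction > 0:
        k = int(round(config.outlier_fraction * n))
        outlier_idx = sorted(rng.choice(n, size=k, replace=False).tolist())
        df.loc[outlier_idx, "age"] = np.round(rng.uniform(250, 450, k))
    missing_cells: list[tuple[int, str]] = []
    if config.missing_fraction > 0:
        cols = ["age", "education_level", *SYMPTOM_COLUMNS]
        total = n * len(cols)
        k = int(round(config.missing_fraction * total))
        flat = rng.choice(total, size=k, replace=False)
        for f in flat:
            i, j = divmod(int(f), len(cols))
            df.loc[i, cols[j]] = np.nan
            missing_cells.append((i, cols[j]))
    df.attrs["outlier_rows"] = outlier_idx
    df.attrs["missing_cells"] = missing_cells
    return df


# --------------------------------------------------------------------------
# cohort composition
# --------------------------------------------------------------------------

def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-subject seeds derived from the cohort seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def generate_cohort(config: CohortConfig) -> list[SyntheticSubject]:
    """Compose the three generators into a full cohort.

    Labels are ``n_pd`` PD subjects followed by ``n_hc`` controls;
    per-subject child seeds derive deterministically from ``config.seed``
    so subjects are independent yet the cohort is byte-reproducible.
    """
    n = config.n_pd + config.n_hc
    if n < 2:
        raise ConfigurationError("need at least 2 subjects")
    labels = [PD] * config.n_pd + [HC] * config.n_hc
    seeds = _child_seeds(config.seed, 2 * n + 1)
    ids = [f"S{i:04d}" for i in range(n)]
    clinical = generate_clinical_table(config, labels, seeds[-1], subject_ids=ids)

    subjects: list[SyntheticSubject] = []
    for i, (sid, lab) in enumerate(zip(ids, labels)):
        template, trace = generate_spiral_pair(config, lab, seeds[2 * i])
        page = generate_handwriting_page(config, lab, seeds[2 * i + 1])
        row = clinical.iloc[i].to_dict()
        subjects.append(SyntheticSubject(sid, lab, template, trace, page, row))
    return subjects


def write_cohort(subjects: list[SyntheticSubject], config: CohortConfig,
                 root: str | Path) -> Path:
    """Write the on-disk dataset layout.

    ``<root>/images/<id>_{spiral_template,spiral_trace,handwriting}.png``,
    ``clinical.csv``, ``labels.csv`` and ``ground_truth.json`` holding the
    generator parameters.
    """
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    gt: dict[str, dict] = {"config": config.to_dict(), "subjects": {}}
    for s in subjects:
        s.spiral_template.save(root / "images" / f"{s.subject_id}_spiral_template.png")
        s.spiral_trace.save(root / "images" / f"{s.subject_id}_spiral_trace.png")
        s.handwriting_page.save(root / "images" / f"{s.subject_id}_handwriting.png")
        rows.append(s.clinical_row)
        gt["subjects"][s.subject_id] = {
            "label": s.label,
            "tremor_amplitude": s.spiral_trace.metadata.get("tremor_amplitude"),
            "line_angles_deg": s.handwriting_page.metadata["line_angles_deg"],
            "baseline_wobble": s.handwriting_page.metadata["baseline_wobble"],
            "word_gap_mean": s.handwriting_page.metadata["word_gap_mean"],
            "pressure_jitter": s.handwriting_page.metadata["pressure_jitter"],
        }
    clinical = pd.DataFrame(rows)
    clinical.drop(columns=["label"]).to_csv(root / "clinical.csv", index=False)
    pd.DataFrame(
        {"subject_id": [s.subject_id for s in subjects],
         "label": [s.label for s in subjects]}
    ).to_csv(root / "labels.csv", index=False)
    with open(root / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1, default=float)
    return root
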