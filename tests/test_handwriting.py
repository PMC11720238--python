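"""Handcrafted handwriting features and the embedding backbone."""

import dataclasses

import numpy as np
import pytest

from pmmd.backbones import deep_embedding, get_backbone
from pmmd.handwriting import (InsufficientWordsError, NoInkError,
                              line_irregularity, pen_pressure_irregularity,
                              segment_angle_deg, slant_irregularity,
                              word_spacing)
from pmmd.preprocess import preprocess
from pmmd.raster import RasterImage
from pmmd.synthetic import CohortConfig, generate_handwriting_page


def page_image(mask_value=60, bg=245, shape=(64, 96)):
    return np.full(shape, bg, dtype=np.uint8)


def binarize(px):
    from pmmd.preprocess import otsu_binarize
    binary, _ = otsu_binarize(RasterImage(px))
    return binary


# ---------------------------------------------------------------------- PPI

def brute_force_ppi(px, patch_size, threshold, ink_fraction=0.10):
    """Double-loop implementation of the patch mean/SD definition."""
    h, w = px.shape
    sds = []
    for r0 in range(0, h - patch_size + 1, patch_size):
        for c0 in range(0, w - patch_size + 1, patch_size):
            vals = []
            ink = 0
            for i in range(patch_size):
                for j in range(patch_size):
                    v = float(px[r0 + i, c0 + j])
                    vals.append(v)
                    if v <= threshold:
                        ink += 1
            n = len(vals)
            if ink / n >= ink_fraction:
                mean = sum(vals) / n
                sd = (sum((v - mean) ** 2 for v in vals) / (n - 1)) ** 0.5
                sds.append(sd)
    return sum(sds) / len(sds), sds


class TestPPI:
    def test_hand_computed_patch(self):
        px = np.array([[10, 10], [20, 20]], dtype=np.uint8)
        ppi, sds = pen_pressure_irregularity(RasterImage(px), patch_size=2)
        assert len(sds) == 1
        assert ppi == pytest.approx(np.sqrt(100 / 3))  # ~5.7735

    def test_uniform_stroke_zero_sd(self):
        px = page_image()
        px[16:48, 16:80] = 90  # solid uniform block
        _, sds = pen_pressure_irregularity(RasterImage(px), patch_size=16)
        inner = [s for s in sds if s == 0.0]
        assert inner  # patches fully inside the stroke have zero SD

    def test_matches_double_loop_oracle(self, rng):
        from pmmd.preprocess import otsu_threshold
        px = rng.integers(0, 256, (48, 48)).astype(np.uint8)
        t = otsu_threshold(px)
        ppi, sds = pen_pressure_irregularity(RasterImage(px), patch_size=8)
        exp_ppi, exp_sds = brute_force_ppi(px, 8, t)
        assert np.allclose(sds, exp_sds, atol=1e-9)
        assert ppi == pytest.approx(exp_ppi, abs=1e-9)

    def test_translation_by_patch_multiple_invariant(self):
        px = page_image(shape=(64, 96))
        px[10:24, 10:40] = 80
        shifted = np.roll(px, 16, axis=1)
        a, _ = pen_pressure_irregularity(RasterImage(px), patch_size=16)
        b, _ = pen_pressure_irregularity(RasterImage(shifted), patch_size=16)
        assert a == pytest.approx(b)

    def test_blank_page_raises(self):
        with pytest.raises(NoInkError):
            pen_pressure_irregularity(RasterImage(page_image()), patch_size=16)


# ----------------------------------------------------------------------- SI

class TestSlant:
    def test_angle_conventions(self):
        assert segment_angle_deg(0, 0, 10, 0) == 0.0
        assert segment_angle_deg(0, 0, 1, 1) == pytest.approx(45.0)
        # fold: a segment pointing "down-left" equals its 180-rotation
        assert segment_angle_deg(0, 0, -1, -1) == pytest.approx(45.0)

    def test_single_horizontal_line_exact_zero(self):
        px = page_image(shape=(20, 80))
        px[10, 5:75] = 0  # ideal 1-px horizontal stroke
        si, angles = slant_irregularity(binarize(px))
        assert si == 0.0
        assert all(a == 0.0 for a in angles)

    def test_horizontal_bars_near_zero_si(self, clean_page):
        _, binary = preprocess(clean_page)
        si, angles = slant_irregularity(binary)
        assert angles, "expected detected segments"
        # skeleton end-spurs set a small rasterization noise floor
        assert si == pytest.approx(0.0, abs=1.0)
        assert np.max(np.abs(angles)) <= 2.5

    def test_empty_page_warns_zero(self):
        blank = RasterImage(page_image() * 0 + 255)
        with pytest.warns(UserWarning):
            si, angles = slant_irregularity(blank)
        assert si == 0.0 and angles == []

    def test_recovers_generator_slant_sd(self):
        """Mean measured SI over pages tracks the drawn angle dispersion."""
        cfg = CohortConfig(slant_jitter_pd=5.0, baseline_wobble_pd=0.0,
                           pressure_jitter_pd=0.0, severity_spread=0.0)
        measured, truth = [], []
        for seed in range(20):
            page = generate_handwriting_page(cfg, "PD", seed=seed)
            _, binary = preprocess(page)
            si, _ = slant_irregularity(binary)
            measured.append(si)
            truth.append(np.std(page.metadata["line_angles_deg"], ddof=1))
        assert abs(np.mean(measured) - np.mean(truth)) < 1.5


# ---------------------------------------------------------------------- HLI

class TestLineIrregularity:
    def test_straight_baselines_near_zero(self, clean_page):
        _, binary = preprocess(clean_page)
        hli, baselines = line_irregularity(binary)
        assert hli <= 1.0
        assert len(baselines) == 5

    def test_recovers_generator_wobble(self):
        cfg = CohortConfig(slant_jitter_pd=0.0, baseline_wobble_pd=4.0,
                           pressure_jitter_pd=0.0, severity_spread=0.0)
        vals = []
        for seed in range(5):
            page = generate_handwriting_page(cfg, "PD", seed=seed)
            _, binary = preprocess(page)
            vals.append(line_irregularity(binary)[0])
        assert abs(np.mean(vals) - 4.0) < 1.5

    def test_single_line_equals_its_rms(self):
        px = page_image(shape=(40, 96))
        # one bar with a known 2-px step in its bottom contour
        px[10:24, 10:50] = 60
        px[10:26, 50:90] = 60
        binary = binarize(px)
        hli, baselines = line_irregularity(binary)
        assert len(baselines) == 1
        cols = baselines[0][:, 0].astype(int)
        mask = binary.pixels == 0
        bottoms = np.array([np.max(np.nonzero(mask[:, c])[0]) for c in cols])
        fitted = np.polyval(np.polyfit(cols, bottoms.astype(float), 1), cols)
        expected = float(np.sqrt(np.mean((bottoms - fitted) ** 2)))
        assert hli == pytest.approx(expected)

    def test_blank_page_raises(self):
        with pytest.raises(NoInkError):
            line_irregularity(RasterImage(page_image() * 0 + 255))


# ----------------------------------------------------------------------- WS

class TestWordSpacing:
    def test_two_blobs_constructed_gap(self):
        px = page_image(shape=(40, 120))
        px[10:24, 10:40] = 60
        px[10:24, 70:100] = 60  # gap of 30 empty columns
        ws, gaps = word_spacing(binarize(px))
        assert gaps == [30.0]
        assert ws == pytest.approx(30.0, abs=1.0)

    def test_arithmetic_mean_of_gaps(self):
        px = page_image(shape=(40, 200))
        x = 5
        widths_gaps = [(20, 10), (20, 20), (20, 30), (20, None)]
        for wdt, gap in widths_gaps:
            px[10:24, x:x + wdt] = 60
            x += wdt + (gap or 0)
        ws, gaps = word_spacing(binarize(px))
        assert sorted(gaps) == [10.0, 20.0, 30.0]
        assert ws == pytest.approx(20.0)

    def test_intra_word_splits_merged_out(self):
        px = page_image(shape=(40, 220))
        # two "words", each split into fragments by 2-px character gaps
        x = 5
        for start in (5, 120):
            x = start
            for _ in range(3):
                px[10:24, x:x + 25] = 60
                x += 27  # 2-px intra-word gap
        ws, gaps = word_spacing(binarize(px))
        assert ws == pytest.approx(120 - (5 + 3 * 27 - 2), abs=1.0)

    def test_recovers_generator_gap_mean(self):
        cfg = CohortConfig(word_gap_mean_pd=18.0, word_gap_sd=0.0,
                           severity_spread=0.0, slant_jitter_pd=0.0,
                           baseline_wobble_pd=0.0, pressure_jitter_pd=0.0)
        for seed in range(5):
            page = generate_handwriting_page(cfg, "PD", seed=seed)
            _, binary = preprocess(page)
            ws, _ = word_spacing(binary)
            assert abs(ws - 18.0) <= 1.0

    def test_single_word_lines_raise(self):
        px = page_image(shape=(64, 96))
        px[10:24, 20:70] = 60
        px[40:54, 20:70] = 60
        with pytest.raises(InsufficientWordsError):
            word_spacing(binarize(px))


# ---------------------------------------------------------------- embedding

class TestEmbedding:
    def test_deterministic_and_declared_dimension(self, clean_page):
        a = deep_embedding(clean_page, "smallcnn32")
        b = deep_embedding(clean_page, "smallcnn32")
        assert a.dimension == get_backbone("smallcnn32").dim == 32
        assert np.array_equal(a.values, b.values)

    def test_distinct_pages_distinct_vectors(self, small_config):
        p1 = generate_handwriting_page(small_config, "PD", seed=1)
        p2 = generate_handwriting_page(small_config, "HC", seed=2)
        v1 = deep_embedding(p1, "smallcnn32").values
        v2 = deep_embedding(p2, "smallcnn32").values
        assert not np.allclose(v1, v2)

    def test_unknown_backbone_rejected(self, clean_page):
        with pytest.raises(KeyError):
            deep_embedding(clean_page, "resnet-nonexistent")


# ------------------------------------------------- filtering improves quality

class TestNoiseFiltering:
    def test_filtered_features_closer_to_clean(self):
        """Median filtering pulls noisy-page features back toward the
        clean-page values (the preprocessing rationale)."""
        base = CohortConfig(severity_spread=0.0)
        noisy_cfg = dataclasses.replace(base, noise_salt_pepper=0.02)

        def features(img, filtered):
            gray, binary = (preprocess(img) if filtered
                            else (img, binarize(img.pixels)))
            ppi, _ = pen_pressure_irregularity(gray)
            ws, _ = word_spacing(binary)
            return np.array([ppi, ws])

        wins = 0
        for seed in (0, 1, 2):
            clean = generate_handwriting_page(base, "HC", seed=seed)
            noisy = generate_handwriting_page(noisy_cfg, "HC", seed=seed)
            ref = features(clean, filtered=False)
            err_noisy = np.linalg.norm(features(noisy, filtered=False) - ref)
            err_filtered = np.linalg.norm(features(noisy, filtered=True) - ref)
            wins += err_filtered < err_noisy
        assert wins >= 2
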