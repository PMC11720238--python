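# Methods

`pmmd` implements a multimodal pipeline for detecting Parkinson's disease
(PD) from offline graphomotor samples — a traced spiral drawing and a
handwriting page — together with a small clinical questionnaire.  The
clinical cohorts such pipelines are developed on are private, so the
package ships a seeded synthetic cohort generator that plays the role of
the data source; every stage is specified, tested and benchmarked against
that generator's ground truth.

## Pipeline overview

1. **Image preprocessing** — grayscale (Rec. 601 luma) → 3×3 median
   filter → Otsu binarization → optional square-kernel dilation.  A
   stochastic augmentation schedule (flips, ±10% shifts, brightness
   0.5–1.5×, full rotation, ±20% zoom) is available for dataset
   enrichment.
2. **Spiral (drawing) features** — five radius-difference statistics
   between the traced curve (HT) and its template (ET).
3. **Handwriting features** — four handcrafted micrographia features
   (PPI, SI, HLI, WS) plus a deep embedding from a pluggable backbone.
4. **Clinical preparation** — robust outlier flagging, median/mode
   imputation, z-scoring and categorical encoding, all fitted on training
   rows only.
5. **Attention fusion** — per-modality multi-head self-attention plus
   pairwise two-path cross-attention, pooled and concatenated; a dense
   softmax head trains the attention parameters end-to-end.
6. **Classification and ablation** — an RBF-kernel SVM on the fused
   vectors; the ablation harness evaluates all seven modality subsets
   over five random initializations.

## Spiral statistics

Radii are sampled at matched angular positions along the spiral winding.
With differences d_i = r_HT,i − r_ET,i over n usable pairs:

- x1 = RMS(d) = sqrt(Σ d_i² / n)
- x2 = max |d_i|,  x3 = min |d_i|
- x4 = population SD of the signed d_i (divisor n)
- x5 = mean relative tremor, MRT = Σ_{i≥ℓ} |r_i − r_{i−ℓ}| / (n − ℓ)

The printed MRT formula in the source literature is ambiguous about which
radius series it reads, whether increments are absolute, and the exact
lag; the package exposes the lag ℓ (`mrt_lag`, default 4) and the series
(`mrt_series`, default `"trace"` — tremor lives on the traced curve; the
template variant is available).  x4's defining formula is likewise absent
from its source table; the verbal description ("standard deviation of the
differences") is implemented literally.

Sampling casts `n_samples` (default 360) rays from the shared centre.  A
three-turn spiral crosses each ray three times; the template crossing is
resolved by turn index, and the trace crossing nearest the template's
radius at that position resolves the trace's arm ambiguity (tremor
amplitudes are small against the ~37 px turn pitch).  Rays without a
usable crossing are dropped pairwise; more than 20% dropped raises.  The
centre comes from generator metadata when present, otherwise the template
foreground centroid.

## Handwriting features

- **PPI** (pen-pressure irregularity): the page is tiled with
  `patch_size` (default 16 px) squares; a patch is "ink" when ≥ 10% of
  its pixels fall in the Otsu ink class.  Per patch the mean is Σ X(i,j)/N
  and the SD uses divisor N−1 (as printed in its source equation, even
  though a population SD would be equally defensible); PPI is the mean
  patch SD.  Note the patch SD on a real page mixes ink-background
  contrast with intra-stroke intensity dispersion, so PPI is a noisy
  discriminator on its own.
- **SI** (slant irregularity): probabilistic Hough segments on the
  skeleton of the ink mask (seeded, hence deterministic); segment angles
  use `arctan2` in an x-right/y-up frame (image rows negated), folded to
  (−90°, 90°]; SI is the sample SD of the angles.  Skeleton end-spurs set
  a ≈ 0.8° noise floor on rasterized strokes.
- **HLI** (line irregularity): text lines are separated at
  horizontal-projection valleys; per line the bottom-most ink row of each
  ink column is fitted with a least-squares straight baseline, and the
  line's score is the RMS residual; HLI is the mean over lines.  No
  closed formula exists for this feature in the source description
  ("variation in alignment … and curvature"); the RMS-from-fitted-baseline
  operationalization is this package's definition.
- **WS** (word spacing): connected components are assigned to projection
  line bands by centroid; per line, the gap is the count of empty columns
  between consecutive bounding boxes.  Intra-word splits are removed with
  an Otsu threshold over the pooled gap distribution, guarded so it only
  activates on convincing bimodality (split explains ≥ 85% of gap
  variance and the lower cluster's mean is under half the upper's) — a
  unimodal set of genuine inter-word gaps is never split.

**Embedding backbone.**  Any object with an `image -> fixed-length
vector` contract can register as a backbone.  The packaged default
(`smallcnn32`) is a two-stage random-filter convolutional network in
numpy: resize to 64², ink saliency in [0,1], conv(3×3, 8) → ReLU → 2×2
average pool → conv(3×3, 16) → ReLU → per-channel mean and max (32
values).  Filters are He-initialized from a fixed seed and never trained,
so embeddings are pure deterministic functions of the image; random
convolutional features are a standard lightweight choice when a heavier
pretrained network is not warranted, and the registry accepts one
whenever it is.

## Attention fusion

Each modality's feature vector is chunked into `n_tokens` (default 4)
groups, zero-padded, and linearly embedded into `model_dim` (default 16)
dimensional tokens.  Self-attention per modality:

    Q = Wq x,  K = Wk x,  V = Wv x,   x' = softmax(QKᵀ / s) V

computed per head (default 2) and concatenated, followed by an output
projection.  The printed scale in the source equations is the bare model
width d; the default here is the standard sqrt of the per-head width
(`scale_mode="sqrt_d"`), with the literal `"d"` selectable.

Cross-attention runs both directions over every unordered pair of present
modalities: path 1 takes queries and values from modality a and keys from
modality b, path 2 reverses the roles.  Because values come from the
query modality while the attention weights run over the other modality's
keys, the construction requires equal token counts on both sides — the
shared `n_tokens` guarantees this (the formulation originates from a
one-vector-per-modality setting, where it is trivially satisfied).

The fused vector concatenates, in fixed order: each modality's pooled
self-attention output, then both pooled cross paths of every pair.  With
all three modalities that is (3 + 6)·model_dim = 144 values.  A single
dense softmax layer on the fused vector provides the training signal:
all parameters are learned end-to-end with mini-batch Adam (default lr
0.01, batch 32, 150 epochs) on the cross-entropy, with initialization,
shuffling and dropout all derived from one seed; the head is
zero-initialized so the untrained model sits exactly at chance.
Gradients are hand-derived and verified against finite differences in
the test suite.  No positional encoding is used (feature tokens carry no
order), and no residual/normalization stack — single attention blocks
only.

After training, fused vectors are re-extracted in evaluation mode and
classified by an RBF-kernel SVM (C = 1, gamma = "scale"); the dense head
remains available for a head-only prediction path.  The literature this
design follows is ambiguous about whether the dense head or an SVM
produces final predictions; the default pipeline trains attention with
the head and predicts with the SVM.

## Evaluation

ACC = (TP+TN)/total, PR = TP/(TP+FP), SN = TP/(TP+FN),
F1 = 2·PR·SN/(PR+SN); zero denominators yield 0 with a flag.  The
ablation harness evaluates 7 combinations (3 unimodal, 3 two-modality,
1 three-modality) × 5 seeds.  Per replicate: a stratified 70/30 split,
clinical transform and per-modality standardizers fitted on the training
rows only, fusion trained, SVM fitted on the training fused vectors, and
metrics computed on the held-out test set (reported as test metrics, not
cross-validation).  One seed per replicate drives the split, fusion
initialization and SVM; the manifest records every seed so any report is
exactly reproducible.

## The synthetic cohort

The generator emulates a balanced 150-subject cohort (75 PD / 75
controls), matching the cohort scale such studies report.  Defaults (the
study conditions):

| parameter | PD | HC | unit |
|---|---|---|---|
| tremor amplitude (radial, 8 cycles/rev) | 1.5 | 0 | px |
| smooth radial trace noise | 0.8 | 0.8 | px |
| pressure jitter (intra-stroke SD) | 12 | 4 | intensity |
| slant jitter (per-line SD) | 3 | 1 | deg |
| baseline wobble (vertical SD) | 3 | 1 | px |
| word gap mean (micrographia) | 12 | 24 | px |
| symptom prevalence | 0.55 | 0.15 | prob. |

Spirals are Archimedean (r = a + bθ, 3 turns, 1–3 px stroke) on 256²
canvases; PD traces add A·sin(8θ) radial tremor, both classes add smooth
Gaussian radial jitter.  Handwriting pages (256×384, 5 lines × 4 words)
render words as filled slanted stroke bars, not glyphs — the four
features depend only on intensity, angle, baseline and gap structure,
not script identity.  Baseline wobble is a sinusoid with half-page
wavelength so a straight-line fit cannot absorb it (making the wobble SD
recoverable), with RMS equal to the configured SD.  Each subject draws a
lognormal severity factor (σ = 0.3) scaling its class-effect parameters:
real cohorts are heterogeneous, and without overlap every modality
separates perfectly, which makes an ablation uninformative.  Age, gender
and education are class-independent; the seven binary symptoms carry the
clinical effect.  Per-subject seeds derive deterministically from the
cohort seed, so identical configurations give byte-identical datasets.

What the generator does **not** emulate: real scripts and character
shapes, scanner artifacts beyond salt-and-pepper noise, correlated
symptom structure, age effects, or disease progression.  Passing
recovery and ordering tests therefore demonstrates that the estimators
measure what they claim under controlled conditions — not clinical
performance on real cohorts.

On these conditions (n = 150, 5 seeds) the harness lands in a realistic
regime — roughly 78–89% unimodal, 86–91% two-modality, ~94% for the
full fusion, and chance on the null (all-effects-zero) cohort — with the
three-modality model dominating every unimodal one.

## Parameter-recovery test design

Recovery tests isolate the parameter being measured (e.g. slant pages
with zero wobble): the perturbations interact — wobble adds local stroke
slope that biases Hough angles, strong slant merges projection bands —
so joint recovery is not well-posed, while each estimator is unbiased in
its own regime.

## Numerical choices and degenerate inputs

- Otsu: exhaustive 256-bin search, lowest maximizing threshold;
  single-valued images raise (callers may skip binarization).
- Median filter: edge replication, so border pixels see full 9-sample
  windows.
- Augmentation fills out-of-frame regions with background white, never
  fake ink; identity schedules bypass interpolation entirely.
- Outlier rule: robust z (0.6745·(x−median)/MAD) > 3.5 flags the cell as
  missing (the row survives); MAD = 0 columns are skipped.
- Imputation: median (continuous) / mode with ties to the smallest value.
- One-hot is full (not k−1): downstream models are attention blocks and
  kernel SVMs, not linear regressions with intercept collinearity.
- Unseen categories at transform time map to an explicit "unknown"
  indicator with a warning.
- PR/SN/F1 zero-denominator convention: 0 with a `zero_division` flag.
- All derived seeds stay below 2³¹.

## Known limitations

- The drawing pipeline is strictly offline (scanned images); no
  time-resolved kinematics.
- PPI mixes stroke-edge contrast with pressure dispersion (see above).
- The backbone is untrained by design; swapping in a pretrained residual
  network is supported through the registry but not shipped.
- Features x6–x9 of the spiral family referenced in the source
  literature are undefined there and are not implemented.
- The ablation harness reproduces the experiment's structure and ordering
  properties on synthetic data; it does not reproduce any clinical
  accuracy figure.
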