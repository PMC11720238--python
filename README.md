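# pmmd — multimodal graphomotor + clinical Parkinson's detection

Early Parkinson's disease (PD) leaves measurable traces in fine-motor
output long before diagnosis: tremor shows up as radial oscillation when
a patient traces a printed spiral, and micrographia — cramped, small
handwriting with shrunken word spacing — is one of the earliest motor
signs.  `pmmd` is a research pipeline for detecting PD from three
modalities: a spiral **drawing**, a **handwriting** page, and a short
**clinical** questionnaire (age, gender, education, seven symptom
indicators).

The pipeline: images are median-filtered and Otsu-binarized; the drawing
modality yields five radius-difference statistics between the traced
spiral (HT) and its template (ET) —

    x1 = RMS(d),  x2 = max|d|,  x3 = min|d|,  x4 = SD(d),
    x5 = MRT = mean lag-ℓ |radius increment|,     d_i = r_HT,i − r_ET,i

— the handwriting modality yields pen-pressure irregularity (PPI), slant
irregularity (SI), line irregularity (HLI) and word spacing (WS) plus a
deep embedding from a pluggable backbone; the clinical table is
outlier-flagged, imputed and encoded.  Modalities are fused at the
feature level with multi-head self-attention per modality,

    Q = Wq x,  K = Wk x,  V = Wv x,   x' = softmax(QKᵀ/√d_h) V,

plus two-path cross-attention for every modality pair (queries/values
from one modality, keys from the other, and the reverse), trained
end-to-end with a dense softmax head; fused vectors are classified by an
RBF-kernel SVM and scored with ACC / PR / SN / F1.  A modality-ablation
harness evaluates all seven modality subsets over five random
initializations.

Clinical graphomotor datasets are private, so the package includes a
seeded synthetic cohort generator (spiral pairs with sinusoidal tremor,
handwriting pages with controllable pressure jitter / slant / baseline
wobble / word gaps, clinical tables with configurable symptom effect
sizes) whose ground truth drives the test suite.  See
[docs/methods.md](docs/methods.md) for the full model description.

## Worked example

```sh
# generate a 150-subject synthetic cohort (75 PD / 75 HC)
pmmd simulate --out cohort/ --seed 0

# run the full seven-combination ablation, 5 seeds each
pmmd evaluate --seed 0 --seeds 5 --report out/report.csv
```

The report (also printed) is the per-combination mean ± SD over seeds:

```
                       combo  n_modalities  acc_mean   acc_sd
                    clinical             1  0.817391 0.066295
                     drawing             1  0.839130 0.050047
                 handwriting             1  0.926087 0.032969
            drawing+clinical             2  0.908696 0.035721
        handwriting+clinical             2  0.952174 0.049573
         handwriting+drawing             2  0.943478 0.024786
handwriting+drawing+clinical             3  0.960870 0.054130
```

Reading it: on this cohort handwriting is the strongest single modality
(92.6% held-out accuracy), the drawing and clinical modalities are
weaker alone (~82–84%), and fusing all three through the attention model
is best (96.1%), beating every unimodal model — the ordering the
multimodal design is meant to produce.  `out/report.manifest.json`
records every seed and configuration; re-running with the same manifest
reproduces each number exactly.  Per-subject feature extraction is also
available piecewise (`pmmd extract-spiral`, `pmmd extract-handwriting`,
`pmmd preprocess-clinical`, `pmmd fuse-train`).

Library use mirrors the CLI:

```python
from pmmd import CohortConfig, generate_cohort, extract_cohort_features, \
    run_ablation, summarize_ablation

feats = extract_cohort_features(generate_cohort(CohortConfig(seed=0)))
detail, manifest = run_ablation(feats, n_seeds=5, base_seed=0)
print(summarize_ablation(detail))
```

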