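"""End-to-end evaluation: feature extraction, RBF-SVM classification,
confusion-matrix metrics, and the modality-ablation harness.

The ablation harness reproduces the structure of the multimodal study:
three unimodal models, three two-modality fusions and the full
three-modality fusion, each evaluated over five random initializations
(one seed drives the train/test split, the fusion initialization and the
classifier), reporting accuracy, precision, sensitivity and F1 per
combination as mean +/- SD over seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .backbones import deep_embedding
from .clinical import fit_clinical_transform
from .fusion import AttentionConfig, encode_labels, train_fusion
from .handwriting import extract_handwriting_features
from .preprocess import preprocess
from .spiral import SpiralSamplingConfig, extract_spiral_features
from .synthetic import SyntheticSubject

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CohortFeatures",
    "ALL_COMBOS",
    "compute_metrics",
    "confusion_from_predictions",
    "train_svm",
    "extract_cohort_features",
    "run_ablation",
]

#: The seven modality combinations of the ablation study.
ALL_COMBOS: list[tuple[str, ...]] = [
    ("handwriting",),
    ("drawing",),
    ("clinical",),
    ("handwriting", "drawing"),
    ("handwriting", "clinical"),
    ("drawing", "clinical"),
    ("handwriting", "drawing", "clinical"),
]


class EmptyEvaluationError(ValueError):
    """Metrics are undefined on an empty confusion table."""


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts; PD is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Accuracy, precision, sensitivity and F1, all in [0, 1]."""

    acc: float
    pr: float
    sn: float
    f1: float
    zero_division: bool = False
    modality_combo: str = ""


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Closed-form metrics from confusion counts.

    ACC = (TP+TN)/total, PR = TP/(TP+FP), SN = TP/(TP+FN),
    F1 = 2*PR*SN/(PR+SN).  Zero denominators yield 0 with the
    ``zero_division`` flag set.
    """
    if counts.total == 0:
        raise EmptyEvaluationError("no evaluated subjects")
    flag = False
    acc = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp > 0:
        pr = counts.tp / (counts.tp + counts.fp)
    else:
        pr, flag = 0.0, True
    if counts.tp + counts.fn > 0:
        sn = counts.tp / (counts.tp + counts.fn)
    else:
        sn, flag = 0.0, True
    if pr + sn > 0:
        f1 = 2 * pr * sn / (pr + sn)
    else:
        f1, flag = 0.0, True
    return MetricsReport(acc, pr, sn, f1, zero_division=flag)


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    yt = encode_labels(y_true)
    yp = encode_labels(y_pred)
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


# --------------------------------------------------------------------------
# SVM
# --------------------------------------------------------------------------

def train_svm(vectors: np.ndarray, labels, gamma="scale", C: float = 1.0,
              seed: int = 0) -> SVC:
    """Fit the RBF-kernel SVM on fused vectors.

    Raises on single-class labels; the decision function is deterministic
    given the fitted model.
    """
    y = encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    x = np.asarray(vectors, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("training vectors contain non-finite values")
    clf = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
    clf.fit(x, y)
    return clf


# --------------------------------------------------------------------------
# per-cohort feature extraction
# --------------------------------------------------------------------------

@dataclass
class CohortFeatures:
    """Raw per-subject feature blocks for every modality.

    ``handwriting`` concatenates the four handcrafted features with the
    backbone embedding; ``drawing`` holds the five spiral statistics;
    ``clinical_raw`` is the untransformed table (its encoding is fitted
    per split inside the harness).
    """

    subject_ids: list[str]
    labels: np.ndarray
    handwriting: np.ndarray
    drawing: np.ndarray
    clinical_raw: pd.DataFrame


def extract_cohort_features(
    subjects: list[SyntheticSubject],
    backbone_id: str = "smallcnn32",
    sampling: SpiralSamplingConfig | None = None,
    apply_dilation: bool = False,
) -> CohortFeatures:
    """Run preprocessing and all feature extractors over a cohort.

    Handwriting pages and spiral images go through the standard
    median-filter + Otsu chain; failures of individual extractors (e.g. a
    page with no detectable segments) degrade to zeros with a warning
    rather than dropping the subject.
    """
    sampling = sampling or SpiralSamplingConfig()
    hw_rows, dr_rows, clin_rows, ids, labels = [], [], [], [], []
    for s in subjects:
        gray, binary = preprocess(s.handwriting_page, apply_dilation=apply_dilation)
        try:
            hf = extract_handwriting_features(gray, binary)
            hand = hf.as_array()
        except ValueError as exc:
            warnings.warn(f"{s.subject_id}: handwriting features failed ({exc})",
                          stacklevel=2)
            hand = np.zeros(4)
        emb = deep_embedding(gray, backbone_id)
        hw_rows.append(np.concatenate([hand, emb.values]))

        _, tmpl_bin = preprocess(s.spiral_template)
        _, trace_bin = preprocess(s.spiral_trace)
        try:
            sf = extract_spiral_features(tmpl_bin, trace_bin, sampling)
            dr_rows.append(sf.as_array())
        except ValueError as exc:
            warnings.warn(f"{s.subject_id}: spiral features failed ({exc})",
                          stacklevel=2)
            dr_rows.append(np.zeros(5))

        clin_rows.append(s.clinical_row)
        ids.append(s.subject_id)
        labels.append(s.label)
    clinical = pd.DataFrame(clin_rows).drop(columns=["label"], errors="ignore")
    return CohortFeatures(
        subject_ids=ids,
        labels=encode_labels(labels),
        handwriting=np.vstack(hw_rows),
        drawing=np.vstack(dr_rows),
        clinical_raw=clinical.reset_index(drop=True),
    )


# --------------------------------------------------------------------------
# ablation harness
# --------------------------------------------------------------------------

def _combo_name(combo: tuple[str, ...]) -> str:
    return "+".join(combo)


def _evaluate_once(
    feats: CohortFeatures,
    combo: tuple[str, ...],
    seed: int,
    split_fraction: float,
    attention: AttentionConfig,
    svm_c: float,
    z_threshold: float,
) -> MetricsReport:
    """One replicate: split, fit transforms on train, fuse, classify."""
    import dataclasses as _dc

    y = feats.labels
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=1.0 - split_fraction, stratify=y, random_state=seed)

    blocks: dict[str, np.ndarray] = {}
    if "handwriting" in combo:
        blocks["handwriting"] = feats.handwriting
    if "drawing" in combo:
        blocks["drawing"] = feats.drawing
    if "clinical" in combo:
        transform = fit_clinical_transform(
            feats.clinical_raw.iloc[train_idx], z_threshold=z_threshold)
        blocks["clinical"] = transform.apply(feats.clinical_raw).to_numpy()

    scaled: dict[str, np.ndarray] = {}
    for m, x in blocks.items():
        scaler = StandardScaler().fit(x[train_idx])
        scaled[m] = scaler.transform(x)

    cfg = _dc.replace(attention, seed=seed)
    model = train_fusion({m: scaled[m][train_idx] for m in scaled},
                         y[train_idx], cfg)
    fused = model.fuse(scaled)
    clf = train_svm(fused[train_idx], y[train_idx], C=svm_c, seed=seed)
    pred = clf.predict(fused[test_idx])
    report = compute_metrics(confusion_from_predictions(y[test_idx], pred))
    report.modality_combo = _combo_name(combo)
    return report


def run_ablation(
    cohort: list[SyntheticSubject] | CohortFeatures,
    combos: list[tuple[str, ...]] | None = None,
    n_seeds: int = 5,
    split_fraction: float = 0.7,
    attention: AttentionConfig | None = None,
    svm_c: float = 1.0,
    z_threshold: float = 3.5,
    base_seed: int = 0,
    backbone_id: str = "smallcnn32",
) -> tuple[pd.DataFrame, dict]:
    """Run the full modality-ablation experiment.

    Returns a per-combo/per-seed tidy table plus a run manifest (seeds,
    configuration) sufficient to reproduce every number exactly.  The
    default combo list is the seven-row unimodal / two-modality /
    three-modality structure; metrics are averaged over ``n_seeds``
    random initializations.
    """
    combos = combos if combos is not None else ALL_COMBOS
    attention = attention or AttentionConfig()
    feats = (cohort if isinstance(cohort, CohortFeatures)
             else extract_cohort_features(cohort, backbone_id=backbone_id))

    seeds = [int(s) for s in
             np.random.SeedSequence(base_seed).generate_state(n_seeds) % (2**31)]
    rows = []
    for combo in combos:
        for seed in seeds:
            rep = _evaluate_once(feats, combo, seed, split_fraction,
                                 attention, svm_c, z_threshold)
            rows.append({
                "combo": rep.modality_combo,
                "n_modalities": len(combo),
                "seed": seed,
                "acc": rep.acc, "pr": rep.pr, "sn": rep.sn, "f1": rep.f1,
            })
    detail = pd.DataFrame(rows)
    manifest = {
        "base_seed": base_seed,
        "seeds": seeds,
        "n_subjects": len(feats.labels),
        "split_fraction": split_fraction,
        "svm_C": svm_c,
        "z_threshold": z_threshold,
        "backbone_id": backbone_id,
        "attention": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in attention.__dict__.items()},
        "combos": [list(c) for c in combos],
    }
    return detail, manifest


def summarize_ablation(detail: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per combination, in the seven-row report shape."""
    g = detail.groupby(["combo", "n_modalities"], sort=False)
    out = g.agg(acc_mean=("acc", "mean"), acc_sd=("acc", "std"),
                pr_mean=("pr", "mean"), pr_sd=("pr", "std"),
                sn_mean=("sn", "mean"), sn_sd=("sn", "std"),
                f1_mean=("f1", "mean"), f1_sd=("f1", "std"),
                n_seeds=("seed", "count")).reset_index()
    return out.sort_values(["n_modalities", "combo"]).reset_index(drop=True)
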