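"""Evaluation of predicted GA segmentations against registered FAF truth.

Per-B-scan probability maps are aggregated into an en-face projection
(column mean along height, B-scans stacked over depth, bilinearly resized
to 512 x 512), binarized with the better of a 2-class or 3-class Otsu
threshold (chosen by Dice against the registered ground truth, the
protocol's optimistic selection step), and scored with four pixelwise
confusion-matrix metrics:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    overlap     = TP / (TP + FP + FN)        (Jaccard reading)

``overlap`` is reported as the Jaccard index; the raw fraction TP/total is
also emitted as a supplementary field since the two readings differ.
Cross-validation partitions cases (not B-scans) into k near-equal folds,
trains on k-1 folds and evaluates held-out cases through the full
pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_multiotsu, threshold_otsu

from .label_transform import resize_bilinear
from . import segnet

ENFACE_SIZE = 512


# ----------------------------------------------------------------------
# aggregation and binarization
# ----------------------------------------------------------------------

def aggregate_enface(prob_bscans, out_size: int = ENFACE_SIZE) -> np.ndarray:
    """Collapse per-B-scan probability maps to a square en-face map.

    Each (height x width) map is averaged along height giving one width-
    length profile per B-scan; profiles are stacked over depth into a
    (width, depth) map, then bilinearly resized to out_size x out_size.
    """
    maps = list(prob_bscans)
    if len(maps) == 0:
        raise ValueError("no probability maps to aggregate")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("probability maps must share one shape")
    enface = np.stack([np.asarray(m, dtype=float).mean(axis=0) for m in maps],
                      axis=1)
    return np.clip(resize_bilinear(enface, (out_size, out_size)), 0.0, 1.0)


def otsu_thresholds(values: np.ndarray, n_classes: int = 2, nbins: int = 256):
    """Otsu threshold(s) maximizing between-class variance over a 256-bin
    histogram; one threshold for 2 classes, two (increasing) for 3."""
    values = np.asarray(values, dtype=float)
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    if np.ptp(values) == 0:
        raise ValueError("degenerate map: constant values cannot be "
                         "Otsu-thresholded")
    try:
        if n_classes == 2:
            return [float(threshold_otsu(values, nbins=nbins))]
        return [float(t) for t in
                threshold_multiotsu(values, classes=3, nbins=nbins)]
    except ValueError as e:
        raise ValueError(f"degenerate map for {n_classes}-class Otsu: {e}") from e


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """Dice on binary masks, no smoothing; empty vs empty defined as 1."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def select_binarization(enface: np.ndarray, truth: np.ndarray):
    """Binarize via the better of 2-class Otsu and the upper 3-class Otsu
    threshold, judged by Dice against the registered truth; ties (and a
    failed 3-class split) go to the 2-class threshold.

    Returns ``(mask, mode)`` with mode in {"otsu2", "otsu3"}.
    """
    truth = np.asarray(truth).astype(bool)
    if enface.shape != truth.shape:
        raise ValueError("en-face map and truth shapes differ")
    t2 = otsu_thresholds(enface, 2)[0]
    mask2 = enface > t2
    try:
        t3 = otsu_thresholds(enface, 3)[1]
    except ValueError:
        return mask2, "otsu2"
    mask3 = enface > t3
    if dice_score(mask3, truth) > dice_score(mask2, truth):
        return mask3, "otsu3"
    return mask2, "otsu2"


# ----------------------------------------------------------------------
# confusion matrix and metrics
# ----------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts of a binary prediction against binary
    truth."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    tp = int(np.logical_and(pred, truth).sum())
    fp = int(np.logical_and(pred, ~truth).sum())
    fn = int(np.logical_and(~pred, truth).sum())
    tn = int(pred.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class MetricsReport:
    """The four segmentation metrics; ratios with zero denominators are
    NaN (missing), never coerced to 0 or 1. ``tp_fraction`` is the literal
    TP/total fraction, kept as a supplementary reading of "overlap"."""

    accuracy: float
    sensitivity: float
    specificity: float
    overlap: float
    tp_fraction: float

    def as_dict(self):
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "overlap": self.overlap,
                "tp_fraction": self.tp_fraction}


def _ratio(num, den):
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    if c.total <= 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        overlap=_ratio(c.tp, c.tp + c.fp + c.fn),
        tp_fraction=_ratio(c.tp, c.total),
    )


# ----------------------------------------------------------------------
# cross-validation over prepared cases
# ----------------------------------------------------------------------

@dataclass
class PreparedCase:
    """Everything one case contributes to training and evaluation:
    per-B-scan inputs and truth masks (at the network's input resolution)
    plus the registered en-face truth at evaluation resolution."""

    case_id: str
    bscans: list                  # D arrays (h, w) float
    truth_masks: list             # D arrays (h, w) bool
    enface_truth: np.ndarray      # (512, 512) bool
    meta: dict = field(default_factory=dict)


@dataclass
class FoldResult:
    fold_id: int
    case_ids: list
    report: MetricsReport         # mean over the fold's held-out cases
    per_case: list = field(default_factory=list)  # (case_id, MetricsReport, mode)


def evaluate_case(model, case: PreparedCase):
    """Full evaluation pipeline for one case: predict every B-scan,
    aggregate en-face, Otsu-binarize (best of 2/3 classes by Dice), score.
    Returns (MetricsReport, chosen mode, en-face map, mask).

    A constant probability map carries no threshold information and cannot
    be Otsu-split; it binarizes to the empty prediction."""
    probs = segnet.predict_batch(model, case.bscans)
    enface = aggregate_enface(probs)
    if np.ptp(enface) == 0:
        mask, mode = np.zeros(enface.shape, dtype=bool), "degenerate"
    else:
        mask, mode = select_binarization(enface, case.enface_truth)
    report = compute_metrics(confusion(mask, case.enface_truth))
    return report, mode, enface, mask


def _mean_report(reports) -> MetricsReport:
    """NaN-aware mean of metric reports."""
    fields = ["accuracy", "sensitivity", "specificity", "overlap",
              "tp_fraction"]
    vals = {}
    for f in fields:
        col = [getattr(r, f) for r in reports]
        finite = [v for v in col if not math.isnan(v)]
        vals[f] = float(np.mean(finite)) if finite else math.nan
    return MetricsReport(**vals)


def make_folds(n_cases: int, k: int, seed: int):
    """Seeded case-level partition into k near-equal folds (sizes differ by
    at most 1)."""
    if k > n_cases:
        raise ValueError(f"cannot make {k} folds from {n_cases} cases")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                        0xF01D]))
    order = rng.permutation(n_cases)
    return [sorted(part.tolist()) for part in np.array_split(order, k)]


@dataclass
class CrossValResult:
    fold_results: list
    combined: MetricsReport
    per_case_rows: list
    folds: list          # list of case-index lists, one per fold
    models: list         # trained network per fold
    histories: list      # training history per fold


def crossvalidate(cases, cfg: segnet.UNetConfig, k: int = 8,
                  seed: int = 0, progress: bool = False) -> CrossValResult:
    """k-fold cross-validation at case level.

    For every fold: train a fresh network (seeded from ``cfg.seed`` and the
    fold id) on the B-scans of the other folds, then run the evaluation
    pipeline on each held-out case. The combined report is the mean over
    all held-out case metrics (primary aggregate); each fold also carries
    its own mean.
    """
    cases = list(cases)
    folds = make_folds(len(cases), k, seed)
    fold_results, all_reports, rows = [], [], []
    models, histories = [], []
    for fold_id, test_idx in enumerate(folds):
        train_idx = [i for i in range(len(cases)) if i not in test_idx]
        samples = []
        for i in train_idx:
            samples.extend(zip(cases[i].bscans, cases[i].truth_masks))
        fold_cfg = segnet.UNetConfig(
            **{**cfg.__dict__, "seed": (cfg.seed * 1009 + fold_id) % (2 ** 31)})
        model = segnet.build_unet(fold_cfg)
        hist = segnet.train(model, samples, fold_cfg)
        models.append(model)
        histories.append(hist)
        per_case = []
        for i in test_idx:
            report, mode, _, _ = evaluate_case(model, cases[i])
            per_case.append((cases[i].case_id, report, mode))
            all_reports.append(report)
            rows.append({"fold": fold_id, "case_id": cases[i].case_id,
                         "otsu_mode": mode, **report.as_dict()})
        fr = FoldResult(fold_id=fold_id, case_ids=[cases[i].case_id
                                                   for i in test_idx],
                        report=_mean_report([r for _, r, _ in per_case]),
                        per_case=per_case)
        fold_results.append(fr)
        if progress:
            print(f"fold {fold_id}: " +
                  ", ".join(f"{k_}={v:.3f}" for k_, v in
                            fr.report.as_dict().items()))
    combined = _mean_report(all_reports)
    return CrossValResult(fold_results=fold_results, combined=combined,
                          per_case_rows=rows, folds=folds, models=models,
                          histories=histories)


def metrics_table(fold_results, combined) -> "pandas.DataFrame":
    """Fold-by-fold metrics plus a combined row (mean over held-out cases),
    mirroring the cross-validation summary layout."""
    import pandas as pd

    rows = []
    for fr in fold_results:
        rows.append({"fold": str(fr.fold_id), **fr.report.as_dict()})
    rows.append({"fold": "combined", **combined.as_dict()})
    mean_of_folds = _mean_report([fr.report for fr in fold_results])
    rows.append({"fold": "mean_of_folds", **mean_of_folds.as_dict()})
    return pd.DataFrame(rows)
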