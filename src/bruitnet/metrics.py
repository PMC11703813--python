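"""Evaluation suite: confusion metrics, ROC/AUROC, PSNR/SSIM contrast.

Confusion-based metrics follow the standard definitions

    Precision = TP/(TP+FP)      Recall = TP/(TP+FN)
    F1 = 2PR/(P+R)              Accuracy = (TP+TN)/N

with "positive" = abnormal.  Degenerate denominators (e.g. no predicted
positives) yield NaN rather than a silently optimistic 0.

PSNR and SSIM quantify how different two equally-shaped normalized feature
images are: PSNR = 10 log10(MAX^2/MSE) in dB, and SSIM uses global image
statistics (single window) with C1 = (0.01 MAX)^2, C2 = (0.03 MAX)^2.
Lower PSNR/SSIM between the classes means the feature separates them more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from . import features as feat
from .audio_io import AudioRecording


@dataclass
class EvalReport:
    """Confusion counts plus derived proportions (NaN where undefined)."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    auroc: float = float("nan")
    threshold: float = 0.5

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "accuracy": self.accuracy,
            "auroc": self.auroc, "threshold": self.threshold,
        }

    def to_json_dict(self) -> dict:
        """As ``to_dict`` but with undefined (NaN) metrics as null."""
        import math

        return {
            k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in self.to_dict().items()
        }


@dataclass
class SpectralDiffReport:
    """Mean PSNR (dB) and SSIM over compared image pairs."""

    psnr: float
    ssim: float
    n_pairs: int


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_and_metrics(
    labels: np.ndarray, predictions: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Counts and metrics from 0/1 labels and 0/1 predictions (1=abnormal)."""
    y = np.asarray(labels).ravel().astype(int)
    p = np.asarray(predictions).ravel().astype(int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if len(y) == 0:
        raise ValueError("empty evaluation")
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = (tp + tn) / len(y)
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, precision=precision,
                      recall=recall, f1=f1, accuracy=accuracy, threshold=threshold)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC (Mann-Whitney equivalent, ties averaged) and the ROC curve.

    Returns (auroc, fpr, tpr).  Raises on single-class labels.
    """
    y = np.asarray(labels).ravel().astype(int)
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError("length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined with a single class")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auc, fpr, tpr


def evaluate(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Full report: threshold the scores, count, and add AUROC."""
    y = np.asarray(labels).ravel().astype(int)
    s = np.asarray(scores, dtype=np.float64).ravel()
    report = confusion_and_metrics(y, (s >= threshold).astype(int), threshold)
    if len(np.unique(y)) == 2:
        report.auroc = roc_auc(y, s)[0]
    return report


def psnr(a: np.ndarray, b: np.ndarray, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are equal."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_value**2 / mse))


def ssim(a: np.ndarray, b: np.ndarray, max_value: float = 1.0) -> float:
    """Global-statistics structural similarity index in [-1, 1].

    SSIM = (2 mu_x mu_y + C1)(2 sigma_xy + C2) /
           ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))
    with population moments over the whole image.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    c1 = (0.01 * max_value) ** 2
    c2 = (0.03 * max_value) ** 2
    mu_x, mu_y = a.mean(), b.mean()
    var_x, var_y = a.var(), b.var()
    cov = float(np.mean((a - mu_x) * (b - mu_y)))
    return float(
        (2 * mu_x * mu_y + c1) * (2 * cov + c2)
        / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    )


_FEATURE_IMAGES = {
    "Mel": lambda rec: feat.normalize_columns(feat.compute_mel_spectrogram(rec)),
    "MFCC": lambda rec: feat.normalize_columns(feat.compute_mfcc(rec)),
    "Fused": lambda rec: feat.featurize(rec).values[:, :, 0].T,
}


def compare_feature_types(
    normal_recs: list[AudioRecording],
    abnormal_recs: list[AudioRecording],
    n_samples: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Between-class PSNR/SSIM for Mel, MFCC, and fused feature images.

    Draws ``n_samples`` seeded (normal, abnormal) pairs, computes each
    feature image for both members (pre-emphasized, normalized, MAX = 1),
    and reports the mean PSNR and SSIM per feature type.  Lower values mean
    the feature exposes a larger between-class difference.
    """
    if not normal_recs or not abnormal_recs:
        raise ValueError("both classes required")
    n_possible = len(normal_recs) * len(abnormal_recs)
    if n_samples > n_possible:
        raise ValueError(f"n_samples={n_samples} exceeds {n_possible} available pairs")
    rng = np.random.default_rng(seed)
    pairs = [
        (normal_recs[rng.integers(len(normal_recs))], abnormal_recs[rng.integers(len(abnormal_recs))])
        for _ in range(n_samples)
    ]
    rows = []
    for name, image_of in _FEATURE_IMAGES.items():
        psnrs, ssims = [], []
        for rec_n, rec_a in pairs:
            img_n = image_of(feat.pre_emphasize(rec_n)) if name != "Fused" else image_of(rec_n)
            img_a = image_of(feat.pre_emphasize(rec_a)) if name != "Fused" else image_of(rec_a)
            psnrs.append(psnr(img_n, img_a, max_value=1.0))
            ssims.append(ssim(img_n, img_a, max_value=1.0))
        rows.append({"feature": name, "psnr": float(np.mean(psnrs)),
                     "ssim": float(np.mean(ssims)), "n_pairs": n_samples})
    return pd.DataFrame(rows)
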