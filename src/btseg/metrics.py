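"""Image-quality and segmentation-quality measures.

MSE / PSNR quantify denoising; TPR / TNR / FPR / FNR and their mean
quantify a binary tumour mask against ground truth.  The accuracy
convention here is the balanced one, accuracy = (TPR + TNR) / 2, which
is the arithmetic that segmentation benchmark tables in this literature
actually satisfy row by row.  Note it is *not* symmetric in (pred,
truth): the rates condition on the truth classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionRates",
    "mse",
    "psnr",
    "confusion_rates",
    "accuracy_from_rates",
    "dice",
]


@dataclass(frozen=True)
class ConfusionRates:
    """Pixel-level rates of a binary mask vs truth, as percentages.

    Invariants: tpr + fnr == 100 and tnr + fpr == 100 (exactly, by
    construction); accuracy == (tpr + tnr) / 2.  Rates conditioned on an
    absent truth class are NaN.
    """

    tpr: float
    tnr: float
    fpr: float
    fnr: float
    accuracy: float


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared per-pixel difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    err = mse(a, b)
    if err == 0:
        return math.inf
    return 10.0 * math.log10(peak**2 / err)


def accuracy_from_rates(tpr: float, tnr: float) -> float:
    """Balanced accuracy (percent) from the two class rates (percent)."""
    return (tpr + tnr) / 2.0


def confusion_rates(pred: np.ndarray, truth: np.ndarray) -> ConfusionRates:
    """Pixel-level TPR/TNR/FPR/FNR (+ balanced accuracy) in percent.

    ``pred`` and ``truth`` are boolean (or 0/1) masks of equal shape.
    If the truth lacks positives (or negatives), the rates conditioned
    on that class — and hence the accuracy — are NaN.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = np.count_nonzero(pred & truth)
    fn = np.count_nonzero(~pred & truth)
    tn = np.count_nonzero(~pred & ~truth)
    fp = np.count_nonzero(pred & ~truth)
    tpr = 100.0 * tp / (tp + fn) if tp + fn > 0 else math.nan
    tnr = 100.0 * tn / (tn + fp) if tn + fp > 0 else math.nan
    fnr = 100.0 - tpr if not math.isnan(tpr) else math.nan
    fpr = 100.0 - tnr if not math.isnan(tnr) else math.nan
    acc = accuracy_from_rates(tpr, tnr)
    return ConfusionRates(tpr=tpr, tnr=tnr, fpr=fpr, fnr=fnr, accuracy=acc)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.count_nonzero(a & b) / denom)
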