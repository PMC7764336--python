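"""Evaluation metrics for trajectory forecasts and gait-phase classification.

Trajectory metrics pool all predicted frames (and windows) of a channel:
signed mean error, MAE, RMSE, Pearson correlation R and a signal-to-noise
ratio ``SNR = 10 log10(Var(y) / MSE(y, y_hat))`` in decibels.  SNR = 0 dB
means the prediction error is as large as the signal variance; positive
values indicate a high-quality reconstruction.

Phase metrics are overall accuracy over all (window, frame) cells, the
5x5 confusion matrix (rows = true, columns = predicted) and per-phase
recall.  Standard deviations and covariances use the population
convention (divide by n), matching the normalizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedCorrelationError, ValidationError
from .phase_labeling import N_PHASES, PHASES

#: Display cap used for an infinite SNR in text reports.
SNR_DISPLAY_CAP_DB = 99.0


@dataclass
class TrajectoryMetrics:
    err: float
    mae: float
    rmse: float
    r: float
    snr_db: float
    snr_is_infinite: bool = False

    def to_dict(self) -> dict:
        return {
            "err": self.err,
            "mae": self.mae,
            "rmse": self.rmse,
            "r": self.r,
            "snr_db": SNR_DISPLAY_CAP_DB if self.snr_is_infinite else self.snr_db,
            "snr_is_infinite": self.snr_is_infinite,
        }


@dataclass
class PhaseMetrics:
    accuracy: float
    recall: list[float]
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": list(self.recall),
            "confusion": self.confusion.tolist(),
        }


def _check_shapes(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValidationError("empty input")
    return y_true, y_pred


def accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Fraction of (window, frame) cells whose predicted label matches."""
    y_true, y_pred = _check_shapes(y_true, y_pred)
    return float((y_true == y_pred).mean())


def mean_error(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Signed mean error ``mean(y - y_hat)``; zero means no systematic bias."""
    y_true, y_pred = _check_shapes(y_true, y_pred)
    return float((y_true.astype(float) - y_pred).mean())


def mae(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true, y_pred = _check_shapes(y_true, y_pred)
    return float(np.abs(y_true.astype(float) - y_pred).mean())


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true, y_pred = _check_shapes(y_true, y_pred)
    return float(np.sqrt(((y_true.astype(float) - y_pred) ** 2).mean()))


def pearson_r(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson correlation ``cov(y, y_hat) / (sd_y sd_y_hat)``."""
    y, y_hat = _check_shapes(np.ravel(y), np.ravel(y_hat))
    sy = y.std()
    sy_hat = y_hat.std()
    if sy == 0 or sy_hat == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    cov = ((y - y.mean()) * (y_hat - y_hat.mean())).mean()
    return float(cov / (sy * sy_hat))


def snr_db(y: np.ndarray, y_hat: np.ndarray) -> float:
    """``10 log10(Var(y) / MSE)`` in dB; +inf when the prediction is exact."""
    y, y_hat = _check_shapes(np.ravel(y).astype(float), np.ravel(y_hat).astype(float))
    var = y.var()
    if var == 0:
        raise ValidationError("SNR undefined for a constant true signal")
    mse = ((y - y_hat) ** 2).mean()
    if mse == 0:
        return math.inf
    return float(10.0 * np.log10(var / mse))


def confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = N_PHASES) -> np.ndarray:
    """Count matrix with true phases on rows, predicted on columns."""
    y_true, y_pred = _check_shapes(np.ravel(y_true), np.ravel(y_pred))
    for arr, name in ((y_true, "true"), (y_pred, "predicted")):
        if ((arr < 0) | (arr >= n_classes)).any():
            raise ValidationError(f"{name} labels outside 0..{n_classes - 1}")
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (y_true, y_pred), 1)
    return mat


def evaluate_phase(y_true: np.ndarray, y_pred: np.ndarray) -> PhaseMetrics:
    """Accuracy, per-phase recall and confusion counts in one report."""
    mat = confusion(y_true, y_pred)
    total = mat.sum()
    acc = float(np.trace(mat) / total)
    row_sums = mat.sum(axis=1)
    recall = [
        float(mat[i, i] / row_sums[i]) if row_sums[i] > 0 else float("nan")
        for i in range(N_PHASES)
    ]
    return PhaseMetrics(accuracy=acc, recall=recall, confusion=mat)


def evaluate_trajectory(y_true: np.ndarray, y_pred: np.ndarray) -> TrajectoryMetrics:
    """All five trajectory metrics for one channel, frames pooled."""
    s = snr_db(y_true, y_pred)
    return TrajectoryMetrics(
        err=mean_error(y_true, y_pred),
        mae=mae(y_true, y_pred),
        rmse=rmse(y_true, y_pred),
        r=pearson_r(y_true, y_pred),
        snr_db=s,
        snr_is_infinite=math.isinf(s),
    )


def per_frame_mae(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """MAE per future frame, averaged over windows and channels.

    Averaging this vector over frames recovers the pooled MAE.
    """
    y_true, y_pred = _check_shapes(y_true, y_pred)
    if y_true.ndim != 3:
        raise ValidationError("expected (n, f, D) arrays")
    return np.abs(y_true.astype(float) - y_pred).mean(axis=(0, 2))


def per_phase_error_stats(errors: np.ndarray, labels: np.ndarray) -> dict[str, dict]:
    """Boxplot-style summaries of signed errors, grouped by true phase.

    Quartiles use linear interpolation (the inclusive convention);
    whiskers extend to the most extreme points within 1.5 x IQR of the
    quartiles.  Phases with no samples are omitted.
    """
    errors = np.ravel(np.asarray(errors, dtype=float))
    labels = np.ravel(np.asarray(labels))
    if errors.shape != labels.shape:
        raise ValidationError("errors and labels must align")
    out: dict[str, dict] = {}
    for code, name in enumerate(PHASES):
        vals = errors[labels == code]
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        out[name] = {
            "n": int(vals.size),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(inside.min()),
            "whisker_high": float(inside.max()),
            "n_outliers": int(vals.size - inside.size),
        }
    return out
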