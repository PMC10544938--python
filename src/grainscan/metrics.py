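"""Evaluation metrics: R^2, MAPE, RMSE, PSNR, SSIM, and detection AP/mAP.

Trait agreement between a predicted and a true vector is scored with

* ``R^2 = 1 - sum (yhat_i - y_i)^2 / sum (y_i - ybar)^2``,
* ``MAPE = (1/n) sum |yhat_i - y_i| / y_i * 100%``,
* ``RMSE = sqrt((1/n) sum (yhat_i - y_i)^2)``.

Image fidelity between a reference X and candidate Y (8-bit, MAX_I = 255):

* ``PSNR = 10 log10(MAX_I^2 / MSE)`` in dB (+inf sentinel for identical
  images);
* ``SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2) /
  ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))`` computed from
  global (whole-image) statistics by default, with
  ``c1 = (k1 MAX_I)^2, c2 = (k2 MAX_I)^2`` and the standard
  ``k1 = 0.01, k2 = 0.03``; a mean-of-sliding-windows mode is available
  behind a flag for comparability with windowed implementations.

Detection quality is the area under the all-points-interpolated
precision-recall curve (AP) with greedy score-ordered 1-to-1 matching at a
given IoU threshold, and mAP its mean over thresholds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from grainscan.scan_io import BoundingBox

MAX_I = 255.0


def _paired(predicted, true) -> tuple[np.ndarray, np.ndarray]:
    yhat = np.asarray(predicted, dtype=np.float64).ravel()
    y = np.asarray(true, dtype=np.float64).ravel()
    if yhat.shape != y.shape or y.size < 1:
        raise ValueError("predicted and true must be equal-length, non-empty")
    return yhat, y


def r_squared(predicted: Sequence[float], true: Sequence[float]) -> float:
    """Coefficient of determination of predicted vs true values (<= 1)."""
    yhat, y = _paired(predicted, true)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("true values are all identical: R^2 undefined")
    ss_res = float(((yhat - y) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def mape(predicted: Sequence[float], true: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent (>= 0)."""
    yhat, y = _paired(predicted, true)
    if np.any(y == 0):
        raise ValueError("MAPE undefined for zero true values")
    return float(np.mean(np.abs(yhat - y) / np.abs(y))) * 100.0


def rmse(predicted: Sequence[float], true: Sequence[float]) -> float:
    """Root mean square error (>= 0)."""
    yhat, y = _paired(predicted, true)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def _image_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(x, dtype=np.float64)
    Y = np.asarray(y, dtype=np.float64)
    if X.shape != Y.shape:
        raise ValueError(f"image shapes differ: {X.shape} vs {Y.shape}")
    if X.size == 0:
        raise ValueError("empty images")
    return X, Y


def psnr(reference: np.ndarray, candidate: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images.

    For RGB inputs the MSE is computed per channel and averaged.
    """
    X, Y = _image_pair(reference, candidate)
    mse = float(np.mean((X - Y) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(MAX_I**2 / mse)


def ssim(
    reference: np.ndarray,
    candidate: np.ndarray,
    k1: float = 0.01,
    k2: float = 0.03,
    windowed: bool = False,
    window: int = 7,
) -> float:
    """Structural similarity between two equal-shape 8-bit images.

    Default is the single-window (global-statistics) form; ``windowed=True``
    averages the same formula over sliding ``window`` x ``window`` patches
    instead. RGB inputs are scored per channel and averaged.
    """
    X, Y = _image_pair(reference, candidate)
    if X.ndim == 3:
        return float(
            np.mean(
                [ssim(X[..., c], Y[..., c], k1, k2, windowed, window)
                 for c in range(X.shape[2])]
            )
        )
    c1 = (k1 * MAX_I) ** 2
    c2 = (k2 * MAX_I) ** 2
    if not windowed:
        mx, my = X.mean(), Y.mean()
        vx, vy = X.var(), Y.var()
        cxy = float(((X - mx) * (Y - my)).mean())
        return float(
            (2 * mx * my + c1) * (2 * cxy + c2)
            / ((mx**2 + my**2 + c1) * (vx + vy + c2))
        )
    from numpy.lib.stride_tricks import sliding_window_view

    if min(X.shape) < window:
        raise ValueError("image smaller than the SSIM window")
    wx = sliding_window_view(X, (window, window))
    wy = sliding_window_view(Y, (window, window))
    mx = wx.mean(axis=(-1, -2))
    my = wy.mean(axis=(-1, -2))
    vx = wx.var(axis=(-1, -2))
    vy = wy.var(axis=(-1, -2))
    cxy = (wx * wy).mean(axis=(-1, -2)) - mx * my
    s = (2 * mx * my + c1) * (2 * cxy + c2) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )
    return float(s.mean())


# ---------------------------------------------------------------------------
# Detection AP
# ---------------------------------------------------------------------------

def _match_greedy(
    pred: Sequence[BoundingBox], truth: Sequence[BoundingBox], iou_thr: float
) -> list[bool]:
    """Score-ordered greedy 1-to-1 matching; True per prediction if TP."""
    order = sorted(range(len(pred)), key=lambda i: (-pred[i].score, i))
    matched = [False] * len(truth)
    tp = [False] * len(pred)
    for i in order:
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truth):
            if matched[j]:
                continue
            iou = pred[i].iou(t)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_thr:
            matched[best_j] = True
            tp[i] = True
    return [tp[i] for i in order]


def average_precision(
    pred: Sequence[BoundingBox], truth: Sequence[BoundingBox], iou_thr: float
) -> float:
    """AP at one IoU threshold (all-points interpolation).

    Predictions are matched greedily in descending score order, each truth
    box used at most once; AP is the area under the interpolated
    precision-recall curve.  Conventions: no truth and no predictions
    -> 1.0 (nothing to find, nothing claimed); no truth with predictions
    -> 0.0; no predictions -> 0.0.
    """
    if not truth:
        return 1.0 if not pred else 0.0
    if not pred:
        return 0.0
    tp = np.array(_match_greedy(pred, truth, iou_thr), dtype=np.float64)
    fp = 1.0 - tp
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(fp)
    recall = tp_cum / len(truth)
    precision = tp_cum / (tp_cum + fp_cum)
    # all-points interpolation: envelope the precision, integrate over recall
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.where(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def mean_ap(
    pred: Sequence[BoundingBox],
    truth: Sequence[BoundingBox],
    iou_thresholds: Sequence[float] = (0.50, 0.75, 0.95),
) -> dict:
    """AP per IoU threshold plus their mean."""
    ap = {float(t): average_precision(pred, truth, t) for t in iou_thresholds}
    return {"ap": ap, "map": float(np.mean(list(ap.values())))}


@dataclass
class EvalReport:
    """Bundle of agreement metrics for a predicted-vs-true comparison."""

    r2: float | None = None
    mape_pct: float | None = None
    rmse: float | None = None
    psnr_db: float | None = None
    ssim: float | None = None
    ap: dict = field(default_factory=dict)
    map: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "r2": self.r2,
            "mape_pct": self.mape_pct,
            "rmse": self.rmse,
            "psnr_db": self.psnr_db,
            "ssim": self.ssim,
            "ap": {str(k): v for k, v in self.ap.items()},
            "map": self.map,
        }
        d.update(self.extras)
        return d

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if o == math.inf:
                return "inf"
            raise TypeError(type(o))

        s = json.dumps(self.to_dict(), indent=1, default=default)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(s, encoding="utf-8")
        return s

    @staticmethod
    def from_vectors(predicted, true) -> "EvalReport":
        return EvalReport(
            r2=r_squared(predicted, true),
            mape_pct=mape(predicted, true),
            rmse=rmse(predicted, true),
        )
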