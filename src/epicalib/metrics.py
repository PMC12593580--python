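"""Accuracy measures for comparing a fitted incidence series to ground truth.

All measures treat ``y`` as the observed (ground-truth) daily incidence and
``f`` as the model-predicted series of the same length:

* ``sse``   — sum of squared errors, the Nelder-Mead cost function.
* ``mae``   — mean absolute error, scale-dependent.
* ``mase``  — mean absolute scaled error: MAE divided by the in-sample MAE of
  the one-step naive forecast; values below 1 beat the naive forecast.
* ``rrmse`` — root mean squared error divided by the mean of the observed
  series.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "sse",
    "mae",
    "mase",
    "rrmse",
    "mean_metric_over_samples",
    "DegenerateSeriesError",
]


class DegenerateSeriesError(ValueError):
    """The observed series does not admit the requested metric.

    Raised for a constant series (MASE's naive-forecast denominator is zero)
    or a nonpositive-mean series (RRMSE's normalizer).
    """


def _as_pair(y, f) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.ndim != 1 or f.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if y.shape != f.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {f.shape[0]}")
    if y.size == 0:
        raise ValueError("empty series")
    return y, f


def sse(y, f) -> float:
    """Sum of squared differences between observed and predicted series."""
    y, f = _as_pair(y, f)
    return float(np.sum((y - f) ** 2))


def mae(y, f) -> float:
    """Mean absolute error."""
    y, f = _as_pair(y, f)
    return float(np.mean(np.abs(y - f)))


def mase(y, f) -> float:
    """Mean absolute scaled error.

    The numerator is the MAE over all ``n`` points; the denominator is the
    in-sample one-step naive forecast error ``sum(|y_t - y_{t-1}|)/(n-1)``.
    """
    y, f = _as_pair(y, f)
    if y.size < 2:
        raise ValueError("MASE needs at least 2 points")
    denom = float(np.mean(np.abs(np.diff(y))))
    if denom <= 0.0:
        raise DegenerateSeriesError("constant observed series: MASE undefined")
    return mae(y, f) / denom


def rrmse(y, f) -> float:
    """Root mean squared error relative to the mean of the observed series."""
    y, f = _as_pair(y, f)
    ybar = float(np.mean(y))
    if ybar <= 0.0:
        raise DegenerateSeriesError("nonpositive observed mean: RRMSE undefined")
    return float(np.sqrt(np.mean((y - f) ** 2))) / ybar


def mean_metric_over_samples(
    y: Sequence[float],
    samples: Iterable[tuple[float, float]],
    predict: Callable[[float, float], np.ndarray],
    metric: Callable[[np.ndarray, np.ndarray], float] = mase,
) -> float:
    """Average a metric over a set of (beta, gamma) parameter draws.

    For each draw the predicted incidence is computed with ``predict`` and
    scored against ``y``; the arithmetic mean over draws is returned. Draws
    whose metric is undefined (degenerate series, non-finite prediction) are
    excluded with a warning rather than propagating infinities.
    """
    y = np.asarray(y, dtype=float)
    values = []
    n_bad = 0
    for beta, gamma in samples:
        try:
            v = metric(y, predict(beta, gamma))
        except (DegenerateSeriesError, FloatingPointError, ValueError):
            n_bad += 1
            continue
        if not np.isfinite(v):
            n_bad += 1
            continue
        values.append(v)
    if n_bad:
        warnings.warn(f"excluded {n_bad} invalid samples from metric average")
    if not values:
        raise ValueError("all samples invalid: metric average undefined")
    return float(np.mean(values))
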