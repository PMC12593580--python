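"""Quantile summaries and MASE-weighted median ensembles.

Each calibrated ground truth yields a distribution of parameter draws,
summarized at seven quantile levels (2.5, 5, 25, 50, 75, 95, 97.5 percent).
Across the replicate ground truths of a scenario the per-level values are
combined by a weighted median, with weights inversely proportional to each
ground truth's mean MASE so that better-fitting replicates count more. A
median (rather than mean) ensemble is robust to the occasional pathological
replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: The seven summary levels, in percent.
QUANTILE_LEVELS: tuple[float, ...] = (2.5, 5.0, 25.0, 50.0, 75.0, 95.0, 97.5)

__all__ = [
    "QUANTILE_LEVELS",
    "QuantileSummary",
    "quantiles",
    "mase_weights",
    "weighted_median",
    "weighted_median_ensemble",
]


@dataclass(frozen=True)
class QuantileSummary:
    """Empirical quantiles of one parameter distribution."""

    levels: tuple[float, ...]  # in percent
    values: tuple[float, ...]
    parameter: str = ""

    def __post_init__(self):
        if len(self.levels) != len(self.values):
            raise ValueError("levels/values length mismatch")

    def as_dict(self) -> dict[float, float]:
        return dict(zip(self.levels, self.values))

    @property
    def median(self) -> float:
        return self.as_dict()[50.0]


def quantiles(
    draws: Sequence[float],
    levels: Sequence[float] = QUANTILE_LEVELS,
    parameter: str = "",
) -> QuantileSummary:
    """Empirical quantiles with linear interpolation between order statistics."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draws")
    vals = np.quantile(draws, np.asarray(levels) / 100.0, method="linear")
    return QuantileSummary(tuple(levels), tuple(float(v) for v in vals), parameter)


def mase_weights(mase_values: Sequence[float]) -> np.ndarray:
    """Ensemble weights: inverse of the normalized mean MASE, summing to 1.

    ``w_i`` is proportional to ``1/m_i``; a replicate with half the MASE of
    another gets twice its weight.
    """
    m = np.asarray(mase_values, dtype=float)
    if m.size == 0:
        raise ValueError("empty MASE list")
    if np.any(m <= 0) or not np.all(np.isfinite(m)):
        raise ValueError("MASE values must be positive and finite")
    w = (1.0 / (m / m.sum()))
    return w / w.sum()


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted median: the first sorted value whose cumulative weight reaches
    half the total weight (lower value on an exact tie, for determinism)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.size == 0:
        raise ValueError("values/weights must be equal-length and nonempty")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum, 0.5 * w.sum(), side="left"))
    return float(v[order][min(idx, v.size - 1)])


def weighted_median_ensemble(
    summaries: Sequence[QuantileSummary],
    weights: Sequence[float] | None = None,
    parameter: str | None = None,
) -> QuantileSummary:
    """Per-level weighted median across one summary per ground truth.

    With equal (or omitted) weights this reduces to the ordinary per-level
    median. Per-level medians can in pathological cases break monotonicity
    across levels; this is detected and logged, never silently re-sorted.
    """
    if not summaries:
        raise ValueError("no summaries")
    levels = summaries[0].levels
    for s in summaries[1:]:
        if s.levels != levels:
            raise ValueError("quantile level mismatch across summaries")
    if weights is None:
        weights = np.full(len(summaries), 1.0 / len(summaries))
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(summaries):
        raise ValueError("one weight per summary required")
    out = tuple(
        weighted_median([s.values[k] for s in summaries], weights)
        for k in range(len(levels))
    )
    if any(b < a for a, b in zip(out, out[1:])):
        logger.warning("ensemble quantiles not monotone across levels: %s", out)
    return QuantileSummary(levels, out, parameter or summaries[0].parameter)
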