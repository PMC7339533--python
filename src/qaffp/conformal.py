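"""Cross-conformal prediction intervals for regression.

The calibration scores are the absolute out-of-fold residuals |y − ŷ| from
cross-validation, kept per fold.  For a fold with n scores and confidence
level 1−ε, the fold's half-width is the k-th smallest score with
k = ceil((1−ε)(n+1)) — the finite-sample-valid quantile rank; when k exceeds n
the fold cannot certify the requested confidence and is undefined.  The
cross-conformal interval aggregates the defined per-fold half-widths (median
by default); if every fold is undefined the interval is infinite.

Because the nonconformity score is the raw (unnormalized) residual, the
half-width at a given confidence is a property of the calibration alone and
does not vary with the point prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

AGGREGATIONS = ("median", "pooled", "max")


@dataclass(frozen=True)
class PredictionWithInterval:
    point: float
    half_width: float  # may be math.inf
    confidence: float

    @property
    def lower(self) -> float:
        return self.point - self.half_width

    @property
    def upper(self) -> float:
        return self.point + self.half_width

    def covers(self, observed: float) -> bool:
        return self.lower <= observed <= self.upper


@dataclass
class ConformalCalibration:
    """Per-fold nonconformity scores (absolute residuals, pIC50 units)."""

    fold_scores: list[np.ndarray]
    confidence: float = 0.90
    aggregation: str = "median"

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        self.fold_scores = [np.sort(np.asarray(s, dtype=float)) for s in self.fold_scores]
        for s in self.fold_scores:
            if s.size == 0:
                raise ValueError("empty calibration fold")
            if (s < 0).any():
                raise ValueError("nonconformity scores must be >= 0")

    @property
    def n_folds(self) -> int:
        return len(self.fold_scores)

    def to_jsonable(self) -> dict:
        return {
            "confidence": self.confidence,
            "aggregation": self.aggregation,
            "fold_scores": [s.tolist() for s in self.fold_scores],
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "ConformalCalibration":
        return cls(
            [np.asarray(s) for s in obj["fold_scores"]],
            confidence=obj.get("confidence", 0.90),
            aggregation=obj.get("aggregation", "median"),
        )


def calibrate(
    oof_pairs: Sequence[tuple[Sequence[float], Sequence[float]]],
    confidence: float = 0.90,
    aggregation: str = "median",
) -> ConformalCalibration:
    """Build a calibration from per-fold (observed, predicted) lists."""
    scores = []
    for obs, pred in oof_pairs:
        obs = np.asarray(obs, dtype=float)
        pred = np.asarray(pred, dtype=float)
        if obs.size == 0:
            raise ValueError("empty calibration fold")
        scores.append(np.abs(obs - pred))
    return ConformalCalibration(scores, confidence=confidence, aggregation=aggregation)


def _fold_half_width(sorted_scores: np.ndarray, confidence: float) -> float | None:
    n = sorted_scores.size
    k = math.ceil(confidence * (n + 1))
    if k > n:
        return None
    return float(sorted_scores[k - 1])


def half_width(calibration: ConformalCalibration, confidence: float | None = None) -> float:
    """Aggregate interval half-width at the given confidence (inf if undefined)."""
    conf = calibration.confidence if confidence is None else confidence
    if not 0 < conf < 1:
        raise ValueError("confidence must be in (0, 1)")
    if calibration.aggregation == "pooled":
        pooled = np.sort(np.concatenate(calibration.fold_scores))
        hw = _fold_half_width(pooled, conf)
        return math.inf if hw is None else hw
    widths = [
        hw
        for s in calibration.fold_scores
        if (hw := _fold_half_width(s, conf)) is not None
    ]
    if not widths:
        return math.inf
    if calibration.aggregation == "max":
        return max(widths)
    return float(np.median(widths))


def interval(
    calibration: ConformalCalibration, point: float, confidence: float | None = None
) -> PredictionWithInterval:
    """Prediction interval around a point prediction."""
    conf = calibration.confidence if confidence is None else confidence
    return PredictionWithInterval(float(point), half_width(calibration, conf), conf)


def coverage_check(
    calibration: ConformalCalibration,
    points: Iterable[float],
    observed: Iterable[float],
    confidence: float | None = None,
) -> float:
    """Fraction of observations falling inside their prediction intervals."""
    points = np.asarray(list(points), dtype=float)
    observed = np.asarray(list(observed), dtype=float)
    if observed.size == 0:
        raise ValueError("empty test set")
    if points.shape != observed.shape:
        raise ValueError("points and observations differ in length")
    hw = half_width(calibration, confidence)
    if math.isinf(hw):
        return 1.0
    return float(np.mean(np.abs(observed - points) <= hw))
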