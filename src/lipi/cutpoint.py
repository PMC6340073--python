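"""Empirical ROC curves and dichotomization-cutoff selection.

Cutoffs are chosen by the closest-to-corner criterion: the threshold
minimizing (1 - sensitivity)^2 + (1 - specificity)^2, i.e. the point on the
empirical ROC curve nearest the perfect-classification corner.  Candidate
thresholds sit at midpoints between consecutive distinct observed values
(plus infinite sentinels), so a selected rule reads as a strict inequality
such as "> 8" or "< 60.5" on the risk side.  Youden's J is available for
comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, ValidationError


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sens: float
    spec: float


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: one (sens, spec) pair per candidate threshold."""

    points: tuple[RocPoint, ...]
    direction: str  # "greater-is-risk" | "less-is-risk"
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffResult:
    feature: str
    threshold: float
    direction: str
    sens: float
    spec: float
    criterion: float


def _predict_positive(values: np.ndarray, threshold: float, direction: str):
    if direction == "greater-is-risk":
        return values > threshold
    return values < threshold


def roc_points(values, labels, direction: str | None = None,
               feature: str = "") -> RocCurve:
    """Empirical ROC curve over midpoint thresholds.

    ``labels`` are 1 for cases, 0 for controls.  When ``direction`` is not
    given it is auto-detected as the side with higher event rate (cases
    tending larger -> "greater-is-risk").  Sensitivity and specificity use
    strict inequalities on the risk side.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite feature values")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("both classes required for an ROC curve")

    if direction is None:
        # Mann-Whitney direction check: cases larger on average -> greater.
        cases, controls = values[labels], values[~labels]
        gt = np.sum(cases[:, None] > controls[None, :])
        lt = np.sum(cases[:, None] < controls[None, :])
        direction = "greater-is-risk" if gt >= lt else "less-is-risk"
    elif direction not in ("greater-is-risk", "less-is-risk"):
        raise ValueError(f"unknown direction {direction!r}")

    distinct = np.unique(values)
    thresholds = np.concatenate([
        [-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]])
    pts = []
    for t in thresholds:
        pred = _predict_positive(values, t, direction)
        sens = float(pred[labels].mean())
        spec = float((~pred[~labels]).mean())
        pts.append(RocPoint(threshold=float(t), sens=sens, spec=spec))
    return RocCurve(points=tuple(pts), direction=direction,
                    n_pos=n_pos, n_neg=n_neg)


def closest_corner_cutoff(curve: RocCurve, feature: str = "") -> CutoffResult:
    """Threshold minimizing (1-sens)^2 + (1-spec)^2 over the curve.

    Ties break toward higher specificity (rule-in performance), then toward
    the more extreme threshold (fewer test-positives).
    """
    extreme_sign = 1.0 if curve.direction == "greater-is-risk" else -1.0
    best = min(
        curve.points,
        key=lambda p: ((1 - p.sens) ** 2 + (1 - p.spec) ** 2,
                       -p.spec,
                       -extreme_sign * p.threshold),
    )
    return CutoffResult(feature=feature, threshold=best.threshold,
                        direction=curve.direction, sens=best.sens,
                        spec=best.spec,
                        criterion=(1 - best.sens) ** 2 + (1 - best.spec) ** 2)


def youden_cutoff(curve: RocCurve, feature: str = "") -> CutoffResult:
    """Threshold maximizing Youden's J = sens + spec - 1 (comparison only)."""
    extreme_sign = 1.0 if curve.direction == "greater-is-risk" else -1.0
    best = max(
        curve.points,
        key=lambda p: (p.sens + p.spec - 1, p.spec, extreme_sign * p.threshold),
    )
    return CutoffResult(feature=feature, threshold=best.threshold,
                        direction=curve.direction, sens=best.sens,
                        spec=best.spec,
                        criterion=(1 - best.sens) ** 2 + (1 - best.spec) ** 2)
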