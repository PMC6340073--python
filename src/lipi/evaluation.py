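"""Diagnostic-performance evaluation of indices and single variables.

Sensitivity and specificity carry exact (Clopper-Pearson) binomial 95%
confidence intervals; likelihood ratios follow LR+ = sens/(1-spec) and
LR- = (1-sens)/spec; the AUC is the tie-adjusted pairwise-comparison
probability with a DeLong confidence interval by default (an untruncated
normal-approximation variant is kept for comparability with reports whose
intervals exceed 1, and such bounds are flagged).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta, norm

from .cohort import Cohort
from .errors import DegenerateDataError, EvaluationError, ValidationError
from .index import IndexDefinition, lipi_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.tp + self.fn < 1 or self.fp + self.tn < 1:
            raise ValidationError("need at least one case and one control")


@dataclass
class PerformanceReport:
    """Table-style performance row; sens/spec in percent, AUC as a fraction."""

    model: str
    dataset: str
    cutoff: float
    sens: float
    sens_ci: tuple[float, float]
    spec: float
    spec_ci: tuple[float, float]
    lr_pos: float          # math.inf when spec = 100%
    lr_neg: float          # math.nan when spec = 0%
    auc: float = math.nan
    auc_ci: tuple[float, float] = (math.nan, math.nan)
    p: float = math.nan
    auc_ci_untruncated: bool = False


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI from beta quantiles; bounds as fractions in [0, 1]."""
    if not (0 <= x <= n) or n < 1:
        raise ValidationError(f"invalid binomial counts x={x}, n={n}")
    lo = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def diagnostic_metrics(counts: ConfusionCounts, alpha: float = 0.05,
                       model: str = "", dataset: str = "baseline",
                       cutoff: float = math.nan,
                       continuity: bool = False) -> PerformanceReport:
    """Sensitivity, specificity (percent, exact CIs) and likelihood ratios.

    With ``continuity=True``, 0.5 is added to every cell before computing
    likelihood ratios (only), so zero-cell LRs become finite.
    """
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.tn + counts.fp)
    sens_ci = clopper_pearson(counts.tp, counts.tp + counts.fn, alpha)
    spec_ci = clopper_pearson(counts.tn, counts.tn + counts.fp, alpha)

    if continuity:
        s = (counts.tp + 0.5) / (counts.tp + counts.fn + 1)
        c = (counts.tn + 0.5) / (counts.tn + counts.fp + 1)
        lr_pos = s / (1 - c)
        lr_neg = (1 - s) / c
    else:
        lr_pos = math.inf if spec == 1.0 else sens / (1 - spec)
        lr_neg = math.nan if spec == 0.0 else (1 - sens) / spec
    return PerformanceReport(
        model=model, dataset=dataset, cutoff=cutoff,
        sens=100 * sens, sens_ci=(100 * sens_ci[0], 100 * sens_ci[1]),
        spec=100 * spec, spec_ci=(100 * spec_ci[0], 100 * spec_ci[1]),
        lr_pos=float(lr_pos), lr_neg=float(lr_neg))


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values: per-case and per-control components."""
    cases = scores[labels]
    controls = scores[~labels]
    cmp_matrix = (cases[:, None] > controls[None, :]).astype(float)
    cmp_matrix += 0.5 * (cases[:, None] == controls[None, :])
    v10 = cmp_matrix.mean(axis=1)   # one per case
    v01 = cmp_matrix.mean(axis=0)   # one per control
    return v10, v01


def auc_with_ci(scores, labels, method: str = "delong",
                alpha: float = 0.05) -> dict:
    """AUC by tie-adjusted pair counting, with a 95% CI.

    ``method="delong"`` (default) uses the DeLong structural-component
    variance; ``"normal-approx"`` uses the Hanley-McNeil standard error with
    an untruncated normal interval (bounds may leave [0, 1]; flagged).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateDataError("both classes required for AUC")
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    z = norm.ppf(1 - alpha / 2)
    if method == "delong":
        var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + \
              (np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0)
        se = math.sqrt(var)
        lo, hi = auc - z * se, auc + z * se
        return {"auc": auc, "ci": (max(0.0, lo), min(1.0, hi)), "se": se,
                "untruncated": False}
    if method == "normal-approx":
        q1 = auc / (2 - auc)
        q2 = 2 * auc ** 2 / (1 + auc)
        var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
               + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
        se = math.sqrt(max(var, 0.0))
        lo, hi = auc - z * se, auc + z * se
        return {"auc": auc, "ci": (lo, hi), "se": se,
                "untruncated": lo < 0 or hi > 1}
    raise ValueError(f"unknown method {method!r}")


def compare_auc(scores_a, scores_b, labels, labels_b=None) -> dict:
    """DeLong test for a difference between two AUCs.

    With one ``labels`` vector the comparison is paired (both scores on the
    same subjects, covariance of placements subtracted); with ``labels_b``
    the two samples are independent.  Returns the AUC difference and a
    two-sided p-value.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    la = np.asarray(labels, dtype=bool)
    if labels_b is None:
        if scores_a.shape != scores_b.shape:
            raise ValidationError("paired comparison requires equal-length scores")
        v10a, v01a = _placements(scores_a, la)
        v10b, v01b = _placements(scores_b, la)
        n1, n0 = len(v10a), len(v01a)
        delta = float(v10a.mean() - v10b.mean())
        var = 0.0
        if n1 > 1:
            var += (np.var(v10a, ddof=1) + np.var(v10b, ddof=1)
                    - 2 * np.cov(v10a, v10b, ddof=1)[0, 1]) / n1
        if n0 > 1:
            var += (np.var(v01a, ddof=1) + np.var(v01b, ddof=1)
                    - 2 * np.cov(v01a, v01b, ddof=1)[0, 1]) / n0
    else:
        lb = np.asarray(labels_b, dtype=bool)
        ra = auc_with_ci(scores_a, la)
        rb = auc_with_ci(scores_b, lb)
        delta = ra["auc"] - rb["auc"]
        var = ra["se"] ** 2 + rb["se"] ** 2
    if var <= 0:
        return {"delta": delta, "p": 1.0 if delta == 0 else 0.0, "z": math.nan}
    zstat = delta / math.sqrt(var)
    return {"delta": delta, "p": float(2 * norm.sf(abs(zstat))), "z": float(zstat)}


def _dataset_frame(cohort: Cohort, dataset: str, binary: tuple[str, ...]):
    from .association import _analysis_frame
    return _analysis_frame(cohort, dataset, binary_drugs=binary)


def evaluate_models(cohort: Cohort, models: list[IndexDefinition],
                    datasets: tuple[str, ...] = ("baseline", "nested"),
                    alpha: float = 0.05) -> list[PerformanceReport]:
    """Performance of each index on each dataset; one report row per pair.

    The row's AUC uses the integer score as the marker; the p-value tests
    AUC = 0.5 by the DeLong standard error.  Row failures are non-fatal and
    warned; if every row fails an :class:`EvaluationError` aggregates the
    causes.
    """
    reports: list[PerformanceReport] = []
    failures: list[str] = []
    for dataset in datasets:
        for model in models:
            try:
                binary = tuple(r.feature for r in model.rules
                               if r.kind == "binary-exposure")
                frame, y = _dataset_frame(cohort, dataset, binary)
                labels = y.astype(bool)
                if labels.all() or not labels.any():
                    raise DegenerateDataError("outcome has a single class")
                scores = np.array([
                    lipi_score(row.to_dict(), model)["score"]
                    for _, row in frame.iterrows()
                ], dtype=float)
                predicted = scores > model.threshold
                counts = ConfusionCounts(
                    tp=int((predicted & labels).sum()),
                    fn=int((~predicted & labels).sum()),
                    fp=int((predicted & ~labels).sum()),
                    tn=int((~predicted & ~labels).sum()))
                report = diagnostic_metrics(counts, alpha=alpha,
                                            model=model.name, dataset=dataset,
                                            cutoff=model.threshold)
                res = auc_with_ci(scores, labels, alpha=alpha)
                report.auc = res["auc"]
                report.auc_ci = res["ci"]
                report.auc_ci_untruncated = res["untruncated"]
                if res["se"] > 0:
                    report.p = float(2 * norm.sf(abs(res["auc"] - 0.5) / res["se"]))
                reports.append(report)
            except Exception as exc:  # noqa: BLE001 - rows are independent
                failures.append(f"{model.name}/{dataset}: {exc}")
                warnings.warn(f"evaluation row failed — {model.name}/{dataset}: {exc}",
                              stacklevel=2)
    if not reports and failures:
        raise EvaluationError("all evaluation rows failed:\n" + "\n".join(failures))
    return reports


def reports_to_frame(reports: list[PerformanceReport]) -> pd.DataFrame:
    """Report rows as a table in the published column order."""
    return pd.DataFrame([{
        "model": r.model, "dataset": r.dataset, "cutoff": r.cutoff,
        "lr_pos": r.lr_pos, "lr_neg": r.lr_neg,
        "auc": r.auc, "auc_ci_low": r.auc_ci[0], "auc_ci_high": r.auc_ci[1],
        "sens": r.sens, "sens_ci_low": r.sens_ci[0], "sens_ci_high": r.sens_ci[1],
        "spec": r.spec, "spec_ci_low": r.spec_ci[0], "spec_ci_high": r.spec_ci[1],
        "p": r.p,
    } for r in reports])
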