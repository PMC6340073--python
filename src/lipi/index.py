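"""Integer-point infection-predictive index: construction and scoring.

The index dichotomizes each selected variable (binary drug exposure, or a
continuous measurement against its ROC-derived cutoff) and assigns integer
points by risk-ratio magnitude rank: the strongest effect earns 3 points,
the second 2, and every remaining variable 1.  A patient's score is the sum
of points over satisfied rules; a score strictly above the compound
threshold predicts infection within the follow-up year.

The published rule set — cyclophosphamide use +3, Th17 > 8 x10^6/L +2,
B cells < 60.5 x10^6/L +1, monocyte TLR2 MFI < 1,364 +1, threshold 1.5 —
ships as a packaged definition (``published_lipi``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources

import pandas as pd

from .association import RiskEstimate, rr_from_2x2, univariate_screen
from .cohort import Cohort
from .cutpoint import closest_corner_cutoff, roc_points
from .errors import ScoringError, TieError, ValidationError


@dataclass(frozen=True)
class ScoreRule:
    """One dichotomized variable: cutoff, risk direction, and points."""

    feature: str
    kind: str          # "binary-exposure" | "dichotomized-continuous"
    direction: str     # "greater" | "less" | "present"
    points: int
    cutoff: float | None = None

    def __post_init__(self):
        if self.points < 1:
            raise ValidationError("points must be >= 1")
        if self.kind == "dichotomized-continuous" and (
                self.cutoff is None or not (-float("inf") < self.cutoff < float("inf"))):
            raise ValidationError(f"{self.feature}: continuous rule needs a finite cutoff")
        if self.direction not in ("greater", "less", "present"):
            raise ValidationError(f"unknown direction {self.direction!r}")

    def satisfied(self, value) -> bool:
        """Strict-inequality rule check on the risk side."""
        if self.direction == "present":
            return bool(value)
        if self.direction == "greater":
            return float(value) > self.cutoff
        return float(value) < self.cutoff


@dataclass
class IndexDefinition:
    """A named rule set with a compound prediction threshold."""

    name: str
    threshold: float
    rules: list[ScoreRule]

    def __post_init__(self):
        if self.threshold >= self.max_score:
            raise ValidationError("threshold must be below the maximum score")

    @property
    def max_score(self) -> int:
        return sum(r.points for r in self.rules)

    @property
    def features(self) -> list[str]:
        return [r.feature for r in self.rules]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "threshold": self.threshold,
                       "rules": [asdict(r) for r in self.rules]}, fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "IndexDefinition":
        return cls(name=d["name"], threshold=d["threshold"],
                   rules=[ScoreRule(**r) for r in d["rules"]])

    @classmethod
    def from_json(cls, path) -> "IndexDefinition":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def published_lipi() -> IndexDefinition:
    """The packaged published index definition (lipi_v1)."""
    text = resources.files("lipi.data").joinpath("lipi_v1.json").read_text()
    return IndexDefinition.from_dict(json.loads(text))


def assign_points(estimates: list[RiskEstimate],
                  override: dict[str, int] | None = None) -> dict[str, int]:
    """Integer points per feature by risk-ratio magnitude rank.

    Features are ranked by m = max(RR, 1/RR) descending, so protective
    effects (RR < 1) compete on equal footing; the top rank earns 3 points,
    the second 2, and all remaining features 1.  A magnitude tie across the
    3/2 or 2/1 rank boundary is ambiguous and raises :class:`TieError`
    unless ``override`` supplies explicit points for the tied features.
    """
    if not estimates:
        raise ValidationError("need at least one estimate")
    if any(e.rr <= 0 for e in estimates):
        raise ValidationError("risk ratios must be positive")
    if override:
        missing = [e.feature for e in estimates if e.feature not in override]
        if missing:
            raise ValidationError(f"override missing features: {missing}")
        return {e.feature: int(override[e.feature]) for e in estimates}

    ranked = sorted(estimates, key=lambda e: -e.magnitude)
    mags = [e.magnitude for e in ranked]
    for boundary in (0, 1):
        if len(mags) > boundary + 1 and mags[boundary] == mags[boundary + 1]:
            tied = [e.feature for e in ranked
                    if e.magnitude == mags[boundary]]
            raise TieError(
                f"magnitude tie at the {3 - boundary}/{2 - boundary} point "
                f"boundary between {tied}; pass an explicit override")
    points = {}
    for rank, est in enumerate(ranked):
        points[est.feature] = 3 if rank == 0 else 2 if rank == 1 else 1
    return points


def build_index(cohort: Cohort, features, dataset: str = "baseline",
                binary_features: tuple[str, ...] = ("cyclophosphamide",),
                threshold: float | None = None, name: str = "derived-index",
                points_override: dict[str, int] | None = None,
                ) -> IndexDefinition:
    """Derive an index from a cohort: screen, cut, and assign points.

    Continuous features get an ROC closest-to-corner cutoff and a risk
    direction; binary exposures enter as present/absent rules with a 2x2
    risk ratio.  The compound threshold defaults to the second-ranked
    rule's points minus 0.5 (which yields the published "> 1.5" when the
    point set is 3/2/1/1); pass ``threshold`` to override.
    """
    from .association import _analysis_frame

    continuous = [f for f in features if f not in binary_features]
    binaries = [f for f in features if f in binary_features]

    frame, y = _analysis_frame(cohort, dataset,
                               binary_drugs=tuple(binary_features))
    estimates: list[RiskEstimate] = []
    if continuous:
        estimates.extend(univariate_screen(cohort, continuous, dataset=dataset))
    for drug in binaries:
        exposed_mask = frame[drug].astype(bool).to_numpy()
        a = int(y[exposed_mask].sum())
        c = int(y[~exposed_mask].sum())
        estimates.append(rr_from_2x2(
            (a, int(exposed_mask.sum())), (c, int((~exposed_mask).sum())),
            feature=drug, dataset=dataset))

    points = assign_points(estimates, override=points_override)

    rules = []
    for est in sorted(estimates, key=lambda e: (-points[e.feature], e.feature)):
        if est.feature in binaries:
            rules.append(ScoreRule(feature=est.feature, kind="binary-exposure",
                                   direction="present",
                                   points=points[est.feature]))
        else:
            col = frame[est.feature]
            mask = col.notna().to_numpy()
            curve = roc_points(col.to_numpy()[mask], y[mask].astype(bool))
            cut = closest_corner_cutoff(curve, feature=est.feature)
            rules.append(ScoreRule(
                feature=est.feature, kind="dichotomized-continuous",
                direction="greater" if cut.direction == "greater-is-risk" else "less",
                cutoff=float(cut.threshold), points=points[est.feature]))

    if threshold is None:
        ranked_points = sorted((r.points for r in rules), reverse=True)
        threshold = (ranked_points[1] if len(ranked_points) > 1
                     else ranked_points[0]) - 0.5
    return IndexDefinition(name=name, threshold=float(threshold), rules=rules)


def lipi_score(features: dict, index: IndexDefinition) -> dict:
    """Score one patient's feature map against an index.

    Returns ``{"score": int, "predicted": bool}``; prediction is strict:
    score > threshold.  Missing features raise :class:`ScoringError`
    listing every absent feature.
    """
    missing = [r.feature for r in index.rules if r.feature not in features
               or features[r.feature] is None]
    if missing:
        raise ScoringError(f"missing feature(s) for scoring: {missing}")
    score = sum(r.points for r in index.rules if r.satisfied(features[r.feature]))
    return {"score": int(score), "predicted": score > index.threshold}


def score_cohort(cohort: Cohort, index: IndexDefinition,
                 dataset: str = "baseline") -> pd.DataFrame:
    """Score every patient; one row per patient with score and prediction."""
    from .association import _analysis_frame

    binary = tuple(r.feature for r in index.rules if r.kind == "binary-exposure")
    frame, y = _analysis_frame(cohort, dataset, binary_drugs=binary)
    rows = []
    for pid, row in frame.iterrows():
        res = lipi_score(row.to_dict(), index)
        rows.append({"patient_id": pid, "score": res["score"],
                     "predicted": res["predicted"], "outcome": bool(y[len(rows)])})
    return pd.DataFrame(rows).set_index("patient_id")
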