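"""Longitudinal cohort data model, CSV I/O, and descriptive statistics.

A cohort is a set of patients followed over roughly one year, each with a
schedule of visits carrying immunophenotype counts (cells x10^6/L), monocyte
TLR2 mean fluorescence intensity (arbitrary units), disease-activity scores
(SLEDAI, BILAG), and treatment exposure.  The outcome is the development of
an infectious event during follow-up.

Units are stored exactly as measured; no conversion happens inside the
pipeline.  Missing feature values are handled complete-case per analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, SchemaError, ValidationError

#: Columns every cohort CSV must carry, in canonical order.
REQUIRED_COLUMNS = (
    "patient_id",
    "day",
    "infected",
    "infection_day",
    "severe",
    "followup_days",
    "sledai",
    "bilag",
    "prednisone_mg_day",
    "drugs",
)

#: Daily prednisone dose categories (mg/day): low <= 7.5 < medium <= 30 < high.
PREDNISONE_LOW_MAX = 7.5
PREDNISONE_MEDIUM_MAX = 30.0


@dataclass(frozen=True)
class Visit:
    """One study visit: measurements and treatment active on that day."""

    patient_id: str
    day: int
    features: dict[str, float]
    sledai: float | None = None
    bilag: float | None = None
    prednisone_mg_day: float = 0.0
    drugs: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.day < 0:
            raise ValidationError(f"visit day must be >= 0, got {self.day}")
        for name, value in self.features.items():
            if value is not None and not math.isnan(value) and value < 0:
                raise ValidationError(f"feature {name!r} negative at day {self.day}")
        for score, label in ((self.sledai, "sledai"), (self.bilag, "bilag")):
            if score is not None and score < 0:
                raise ValidationError(f"{label} must be >= 0")
        if self.prednisone_mg_day < 0:
            raise ValidationError("prednisone_mg_day must be >= 0")


@dataclass(frozen=True)
class PatientRecord:
    """A patient's ordered visit history and infection outcome."""

    patient_id: str
    visits: tuple[Visit, ...]
    infected: bool
    infection_day: int | None = None
    severe: bool | None = None
    followup_days: int = 365

    def __post_init__(self):
        if not self.visits:
            raise ValidationError(f"patient {self.patient_id}: no visits")
        days = [v.day for v in self.visits]
        if days != sorted(days):
            raise ValidationError(f"patient {self.patient_id}: visits not day-sorted")
        if len(set(days)) != len(days):
            raise ValidationError(f"patient {self.patient_id}: duplicate visit day")
        if self.infected:
            if self.infection_day is not None and not (
                0 <= self.infection_day <= self.followup_days
            ):
                raise ValidationError(
                    f"patient {self.patient_id}: infection_day "
                    f"{self.infection_day} outside [0, {self.followup_days}]"
                )
        elif self.infection_day is not None:
            raise ValidationError(
                f"patient {self.patient_id}: infection_day set but infected=False"
            )

    @property
    def baseline(self) -> Visit:
        """The enrollment visit (smallest day)."""
        return self.visits[0]


@dataclass
class Cohort:
    """A validated collection of patient records with a feature catalog."""

    patients: list[PatientRecord]
    feature_catalog: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient_id in cohort")
        if not self.feature_catalog:
            seen: list[str] = []
            for p in self.patients:
                for v in p.visits:
                    for name in v.features:
                        if name not in seen:
                            seen.append(name)
            self.feature_catalog = seen
        else:
            known = set(self.feature_catalog)
            for p in self.patients:
                for v in p.visits:
                    extra = set(v.features) - known
                    if extra:
                        raise ValidationError(
                            f"patient {p.patient_id}: features {sorted(extra)} "
                            "not in catalog"
                        )

    def __len__(self) -> int:
        return len(self.patients)

    def baseline_frame(self, binary_drugs: tuple[str, ...] = ()) -> pd.DataFrame:
        """One row per patient: baseline feature values plus outcome.

        ``binary_drugs`` adds a boolean column per drug, true when the drug
        was active at any visit during follow-up (the exposure definition
        used by the risk screens).
        """
        rows = []
        for p in self.patients:
            row: dict[str, object] = {"patient_id": p.patient_id}
            row.update({f: p.baseline.features.get(f, np.nan) for f in self.feature_catalog})
            for drug in binary_drugs:
                row[drug] = any(drug in v.drugs for v in p.visits)
            row["infected"] = p.infected
            rows.append(row)
        return pd.DataFrame(rows).set_index("patient_id")


@dataclass
class ExposureSummary:
    """Per-patient drug exposure and per-visit prednisone dose category."""

    patient_id: str
    drug: str
    any_use: bool
    prednisone_category_per_visit: list[str]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, str):
        return x.strip().lower() in {"1", "true", "yes"}
    return bool(int(x))


def load_cohort(path, column_map: dict[str, str] | None = None) -> Cohort:
    """Read a cohort CSV (one row per patient-visit) into a validated Cohort.

    ``column_map`` renames raw file columns to the canonical schema, e.g.
    ``{"id": "patient_id"}``.  Rows with unparseable numeric values are
    rejected with row-level diagnostics.
    """
    raw = pd.read_csv(path, dtype=str, comment="#")
    if column_map:
        raw = raw.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    feature_cols = [c for c in raw.columns if c not in REQUIRED_COLUMNS]

    bad_rows = []
    numeric = {}
    for col in ("day", "infection_day", "followup_days", "sledai", "bilag",
                "prednisone_mg_day", *feature_cols):
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = raw[col].notna() & (raw[col].str.strip() != "") & parsed.isna()
        for i in raw.index[bad]:
            bad_rows.append(f"row {i + 2}: column {col!r} value {raw.at[i, col]!r}")
        numeric[col] = parsed
    if bad_rows:
        raise ValidationError("unparseable numeric values:\n" + "\n".join(bad_rows))

    keys = list(zip(raw["patient_id"], numeric["day"]))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate (patient_id, day) rows: {dupes}")

    patients = []
    for pid, grp_idx in raw.groupby("patient_id", sort=False).groups.items():
        idx = sorted(grp_idx, key=lambda i: numeric["day"][i])
        visits = []
        for i in idx:
            drugs_raw = raw.at[i, "drugs"]
            drugs = frozenset(
                d.strip() for d in str(drugs_raw).split(";") if d.strip()
            ) if pd.notna(drugs_raw) else frozenset()
            feats = {
                c: float(numeric[c][i]) for c in feature_cols
                if pd.notna(numeric[c][i])
            }
            visits.append(Visit(
                patient_id=str(pid),
                day=int(numeric["day"][i]),
                features=feats,
                sledai=None if pd.isna(numeric["sledai"][i]) else float(numeric["sledai"][i]),
                bilag=None if pd.isna(numeric["bilag"][i]) else float(numeric["bilag"][i]),
                prednisone_mg_day=0.0 if pd.isna(numeric["prednisone_mg_day"][i])
                else float(numeric["prednisone_mg_day"][i]),
                drugs=drugs,
            ))
        first = idx[0]
        inf_day = numeric["infection_day"][first]
        patients.append(PatientRecord(
            patient_id=str(pid),
            visits=tuple(visits),
            infected=_parse_bool(raw.at[first, "infected"]),
            infection_day=None if pd.isna(inf_day) else int(inf_day),
            severe=None if pd.isna(raw.at[first, "severe"])
            else _parse_bool(raw.at[first, "severe"]),
            followup_days=int(numeric["followup_days"][first]),
        ))
    return Cohort(patients=patients, feature_catalog=feature_cols)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort in the CSV dialect read by :func:`load_cohort`."""
    rows = []
    for p in cohort.patients:
        for v in p.visits:
            row = {
                "patient_id": p.patient_id,
                "day": v.day,
                "infected": int(p.infected),
                "infection_day": "" if p.infection_day is None else p.infection_day,
                "severe": "" if p.severe is None else int(p.severe),
                "followup_days": p.followup_days,
                "sledai": "" if v.sledai is None else v.sledai,
                "bilag": "" if v.bilag is None else v.bilag,
                "prednisone_mg_day": v.prednisone_mg_day,
                "drugs": ";".join(sorted(v.drugs)),
            }
            for f in cohort.feature_catalog:
                val = v.features.get(f)
                row[f] = "" if val is None else np.format_float_positional(val, trim="-")
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Descriptive statistics and group comparisons
# ---------------------------------------------------------------------------

def summarize_feature(cohort: Cohort, feature: str, group_by=None,
                      visit: str = "baseline") -> pd.DataFrame:
    """Median and interquartile range of a feature, per group.

    Groups are defined by ``group_by``: ``None`` (whole cohort),
    ``"infected"``, or a callable ``PatientRecord -> label``.  Values are
    taken from the baseline visit unless ``visit="last"``.  Quartiles use
    linear interpolation (NumPy's default convention).
    """
    if feature not in cohort.feature_catalog:
        raise SchemaError(f"feature {feature!r} not in catalog")
    if group_by is None:
        keyfn = lambda p: "all"
    elif group_by == "infected":
        keyfn = lambda p: "infected" if p.infected else "not_infected"
    else:
        keyfn = group_by

    groups: dict[str, list[float]] = {}
    for p in cohort.patients:
        v = p.baseline if visit == "baseline" else p.visits[-1]
        val = v.features.get(feature)
        if val is not None and not math.isnan(val):
            groups.setdefault(keyfn(p), []).append(val)

    out = []
    for label, vals in groups.items():
        if not vals:
            raise DegenerateDataError(f"group {label!r} has no values for {feature!r}")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out.append({"group": label, "median": med, "q1": q1, "q3": q3, "n": len(vals)})
    if not out:
        raise DegenerateDataError(f"no non-missing values for {feature!r}")
    return pd.DataFrame(out).set_index("group")


def compare_groups(x, y, paired: bool = False, counts: bool = False) -> dict:
    """Two-group comparison: rank tests for measurements, chi-square for counts.

    Unpaired measurements use the Mann-Whitney U test, paired ones the
    Wilcoxon signed-rank test; with ``counts=True``, ``x`` and ``y`` are the
    two rows of a contingency table and a Pearson chi-square test (no
    continuity correction) is applied.  All p-values are two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if counts:
        stat, p, _, _ = stats.chi2_contingency([x, y], correction=False)
        return {"statistic": float(stat), "p": float(p), "test": "chi-square"}
    if paired:
        if len(x) != len(y):
            raise ValidationError("paired comparison requires equal lengths")
        if len(x) < 3:
            raise DegenerateDataError("need n >= 3 per group")
        if np.all(x == y):
            warnings.warn("all paired differences are zero; returning p = 1",
                          stacklevel=2)
            return {"statistic": 0.0, "p": 1.0, "test": "wilcoxon"}
        res = stats.wilcoxon(x, y)
        return {"statistic": float(res.statistic), "p": float(res.pvalue),
                "test": "wilcoxon"}
    if len(x) < 3 or len(y) < 3:
        raise DegenerateDataError("need n >= 3 per group")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if len(x) + len(y) <= 25
                             and len(np.unique(np.concatenate([x, y])))
                             == len(x) + len(y) else "auto")
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "test": "mann-whitney"}


def adjusted_mean_sledai(record: PatientRecord, rule: str = "trapezoid") -> float:
    """Time-weighted mean SLEDAI over the visit span.

    ``"trapezoid"`` integrates the piecewise-linear SLEDAI-versus-day curve
    and divides by the spanned days; ``"step"`` holds each visit's value
    until the next visit.  A single scored visit returns its value.
    """
    pts = [(v.day, v.sledai) for v in record.visits if v.sledai is not None]
    if not pts:
        raise DegenerateDataError(f"patient {record.patient_id}: no SLEDAI values")
    if len(pts) == 1:
        return float(pts[0][1])
    days = np.array([d for d, _ in pts], dtype=float)
    scores = np.array([s for _, s in pts], dtype=float)
    span = days[-1] - days[0]
    if rule == "trapezoid":
        return float(np.trapezoid(scores, days) / span)
    if rule == "step":
        return float(np.sum(scores[:-1] * np.diff(days)) / span)
    raise ValueError(f"unknown rule {rule!r}")


def summarize_exposure(record: PatientRecord, drug: str) -> ExposureSummary:
    """Drug exposure over follow-up plus per-visit prednisone dose category."""
    categories = []
    for v in record.visits:
        if v.prednisone_mg_day <= PREDNISONE_LOW_MAX:
            categories.append("low")
        elif v.prednisone_mg_day <= PREDNISONE_MEDIUM_MAX:
            categories.append("medium")
        else:
            categories.append("high")
    return ExposureSummary(
        patient_id=record.patient_id,
        drug=drug,
        any_use=any(drug in v.drugs for v in record.visits),
        prednisone_category_per_visit=categories,
    )


def net_density(fields) -> float:
    """NET density: mean over microscope fields of structures per 100 cells.

    ``fields`` is a sequence of ``(structures, cells)`` pairs or mappings
    with those keys, typically six 40x fields.
    """
    ratios = []
    for f in fields:
        if isinstance(f, dict):
            structures, cells = f["structures"], f["cells"]
        else:
            structures, cells = f
        if cells <= 0:
            raise ValidationError("field with zero cells")
        ratios.append(structures / cells * 100.0)
    if not ratios:
        raise ValidationError("no fields given")
    return float(np.mean(ratios))
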