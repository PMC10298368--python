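"""Cohort summary tables and system-vs-reference agreement metrics.

Builds the sociodemographic summaries the registry reports (counts by
label × sex and label × age band, with integer-rounded percentage shares),
the female-excess statistic 100 × (F − M) / label total, and the agreement
metrics (accuracy plus macro-averaged precision / recall / F1) used to
compare automatic labels against expert reference labels.

Percentage shares round half away from zero, matching the printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from ._util import raise_validation, round_half_away
from .errors import DomainError

__all__ = [
    "CohortRecord",
    "SummaryTable",
    "AGE_BANDS_DECADES",
    "AGE_BANDS_FORTY",
    "summarize",
    "female_excess",
    "agreement",
    "questionnaire_totals",
    "load_fixture",
    "fixture_cohort",
]

AGE_BANDS_DECADES: tuple[tuple[int, int], ...] = (
    (10, 19),
    (20, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 69),
    (70, 90),
)
AGE_BANDS_FORTY: tuple[tuple[int, int], ...] = ((10, 39), (40, 90))


@dataclass(frozen=True)
class CohortRecord:
    patient_id: str
    sex: str
    age: float
    label: str
    reference_label: str | None = None

    def __post_init__(self):
        if self.age < 0:
            raise_validation("age", self.age, "must be >= 0")
        if self.sex not in ("male", "female"):
            raise_validation("sex", self.sex, "must be male or female")


@dataclass(frozen=True)
class SummaryTable:
    counts_sex: dict[str, dict[str, int]]  # label -> sex -> n
    counts_age: dict[str, dict[tuple[int, int], int]]  # label -> band -> n
    label_totals: dict[str, int]
    band_totals: dict[tuple[int, int], int]
    total: int
    shares: dict[str, int] = field(default_factory=dict)  # label -> rounded %

    def age_share(self, lo: int, hi: int) -> int:
        """Rounded % of the cohort whose age band lies within [lo, hi]."""
        n = sum(v for (b_lo, b_hi), v in self.band_totals.items() if lo <= b_lo and b_hi <= hi)
        return round_half_away(100.0 * n / self.total)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in self.label_totals:
            row: dict = {"label": label}
            row.update(self.counts_sex[label])
            for band, v in self.counts_age[label].items():
                row[f"{band[0]}-{band[1]}"] = v
            row["total"] = self.label_totals[label]
            row["share_pct"] = self.shares[label]
            rows.append(row)
        return pd.DataFrame(rows)


def _band_of(age: float, bands: Sequence[tuple[int, int]]) -> tuple[int, int]:
    for lo, hi in bands:
        if lo <= age <= hi:
            return (lo, hi)
    raise DomainError("age-outside-bands", f"age {age} not covered by {list(bands)}")


def summarize(
    cohort: Sequence[CohortRecord], bands: Sequence[tuple[int, int]] = AGE_BANDS_DECADES
) -> SummaryTable:
    """Count the cohort by label × sex and label × age band, with shares."""
    if not cohort:
        raise_validation("cohort", 0, "must be non-empty")
    bands = tuple(bands)
    labels = sorted({r.label for r in cohort})
    counts_sex = {lb: {"male": 0, "female": 0} for lb in labels}
    counts_age = {lb: {b: 0 for b in bands} for lb in labels}
    band_totals = {b: 0 for b in bands}
    for r in cohort:
        band = _band_of(r.age, bands)
        counts_sex[r.label][r.sex] += 1
        counts_age[r.label][band] += 1
        band_totals[band] += 1
    label_totals = {lb: sum(counts_sex[lb].values()) for lb in labels}
    total = len(cohort)
    shares = {lb: round_half_away(100.0 * n / total) for lb, n in label_totals.items()}
    return SummaryTable(
        counts_sex=counts_sex,
        counts_age=counts_age,
        label_totals=label_totals,
        band_totals=band_totals,
        total=total,
        shares=shares,
    )


def female_excess(cohort: Sequence[CohortRecord], label: str) -> int:
    """100 × (n_female − n_male) / n_label, rounded; negative = male excess."""
    subset = [r for r in cohort if r.label == label]
    if not subset:
        raise DomainError("label-absent", label)
    n_f = sum(1 for r in subset if r.sex == "female")
    n_m = len(subset) - n_f
    return round_half_away(100.0 * (n_f - n_m) / len(subset))


def agreement(cohort: Sequence[CohortRecord]) -> dict[str, float]:
    """Accuracy and macro precision/recall/F1 (%) vs the reference labels."""
    missing = [r.patient_id for r in cohort if r.reference_label is None]
    if missing or not cohort:
        raise DomainError("missing-references", f"records without reference: {missing}")
    y_pred = [r.label for r in cohort]
    y_true = [r.reference_label for r in cohort]
    acc = sum(a == b for a, b in zip(y_true, y_pred)) / len(cohort)
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0
    )
    return {
        "accuracy": 100.0 * acc,
        "precision": 100.0 * float(p),
        "recall": 100.0 * float(r),
        "f1": 100.0 * float(f1),
    }


def questionnaire_totals(catalog: pd.DataFrame) -> dict[str, int]:
    """Column sums over the questionnaire catalog (questions/answers/entries/...)."""
    numeric = catalog.select_dtypes("number")
    if (numeric < 0).any().any():
        raise_validation("catalog", "negative counts", "all counts must be >= 0")
    return {col: int(numeric[col].sum()) for col in numeric.columns}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled cohort/catalog table (``table1``, ``table2``, ``table3``)."""
    with resources.files("refluxdx.data").joinpath(f"{name}.csv").open("r") as fh:
        return pd.read_csv(fh)


def fixture_cohort(name: str) -> list[CohortRecord]:
    """Expand a bundled margin table into records (age = band lower bound).

    Sex and age-band sequences are paired positionally per label, which
    preserves both printed margins exactly; the joint sex × age cells are
    not printed and therefore not modeled.
    """
    df = load_fixture(name)
    records: list[CohortRecord] = []
    i = 0
    for label, g in df.groupby("label", sort=False):
        sexes = [
            s
            for _, r in g[g["axis"] == "sex"].iterrows()
            for s in [str(r["group"])] * int(r["count"])
        ]
        ages = [
            int(str(r["group"]).split("-")[0])
            for _, r in g[g["axis"] == "age"].iterrows()
            for _ in range(int(r["count"]))
        ]
        if len(sexes) != len(ages):
            raise DomainError("infeasible-margins", f"{label}: margin sums differ")
        for sex, age in zip(sexes, ages):
            i += 1
            records.append(CohortRecord(f"F{i:05d}", sex, age, str(label)))
    return records
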