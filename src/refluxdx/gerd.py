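"""GERD phenotyping cascade and combined pH/impedance report categories.

The phenotype cascade assigns exactly one of four labels:

1. **erosive esophagitis** — any Los Angeles grade (A–D) on the selected
   endoscopy, regardless of pH monitoring;
2. **non-erosive reflux disease (NERD)** — negative endoscopy with abnormal
   acid exposure time (AET ≥ cutoff, default 4.0%);
3. **reflux hypersensitivity** — normal acid exposure with a positive
   symptom–reflux association (SAP and/or SI, configurable);
4. **functional heartburn** — normal acid exposure and negative association.

Endoscopy-source selection prefers the most recent in-house procedure;
external examinations are used only when no in-house record exists.

The combined pH/impedance categories summarize a 24-h study for the report
page: pH is pathologic when AET ≥ cutoff; impedance is pathologic at ≥ 80
episodes, borderline at 40–79, normal below. "Pathological acid reflux" is
emitted instead of "pH pathologic & impedance normal" when acid-type
episodes dominate (> half of all episodes).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Sequence

from ._util import check_finite, raise_validation
from .errors import DomainError

__all__ = [
    "EndoscopyRecord",
    "PhImpedanceSummary",
    "GerdConfig",
    "GerdPhenotype",
    "LA_GRADES",
    "GERD_LABELS",
    "PH_IMPEDANCE_CATEGORIES",
    "select_endoscopy",
    "classify_ph_impedance",
    "classify_gerd",
]

LA_GRADES = ("none", "A", "B", "C", "D")
SITES = ("in-house", "external")

GERD_LABELS = (
    "erosive esophagitis",
    "non-erosive reflux disease",
    "reflux hypersensitivity",
    "functional heartburn",
)

PH_IMPEDANCE_CATEGORIES = (
    "pH pathologic & impedance normal",
    "impedance pathologic & pH normal",
    "both pathologic",
    "pathological acid reflux",
    "pH pathologic & impedance borderline",
    "both normal",
)

ASSOCIATION_RULES = ("sap-only", "si-only", "sap-or-si")


@dataclass(frozen=True)
class EndoscopyRecord:
    date: datetime.date
    site: str
    la_grade: str = "none"
    notes: str = ""

    def __post_init__(self):
        if self.site not in SITES:
            raise_validation("site", self.site, f"must be one of {SITES}")
        if self.la_grade not in LA_GRADES:
            raise_validation("la_grade", self.la_grade, f"must be one of {LA_GRADES}")


@dataclass(frozen=True)
class PhImpedanceSummary:
    """Acid-exposure, impedance and symptom-association numbers for one study."""

    aet_total: float  # % of monitoring time with pH < 4
    reflux_episode_count: int
    si: float | None = None  # %
    sap: float | None = None  # %
    demeester: float | None = None
    acid_episode_count: int | None = None  # acid-type subset of the episodes
    on_ppi: bool = False  # metadata only; does not alter the rules

    def __post_init__(self):
        check_finite("aet_total", self.aet_total)
        if not 0 <= self.aet_total <= 100:
            raise_validation("aet_total", self.aet_total, "must be in [0, 100]")
        if self.reflux_episode_count < 0:
            raise_validation(
                "reflux_episode_count", self.reflux_episode_count, "must be >= 0"
            )
        for name in ("si", "sap"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise_validation(name, v, "must be in [0, 100] when present")
        if self.demeester is not None and self.demeester < 0:
            raise_validation("demeester", self.demeester, "must be >= 0")


@dataclass(frozen=True)
class GerdConfig:
    aet_abnormal: float = 4.0  # % AET at or above which pH is pathologic
    episodes_abnormal: int = 80
    episodes_borderline: int = 40
    sap_positive: float = 95.0
    si_positive: float = 50.0
    association_rule: str = "sap-or-si"

    def __post_init__(self):
        if not 0 < self.aet_abnormal < 100:
            raise_validation("aet_abnormal", self.aet_abnormal, "must be in (0, 100)")
        if not 0 <= self.episodes_borderline <= self.episodes_abnormal:
            raise_validation(
                "episodes_borderline",
                self.episodes_borderline,
                "must be <= episodes_abnormal",
            )
        if self.association_rule not in ASSOCIATION_RULES:
            raise_validation(
                "association_rule",
                self.association_rule,
                f"must be one of {ASSOCIATION_RULES}",
            )


@dataclass(frozen=True)
class GerdPhenotype:
    label: str
    trace: tuple[str, ...] = ()


def select_endoscopy(records: Sequence[EndoscopyRecord]) -> EndoscopyRecord:
    """Pick the endoscopy the phenotype rules should use.

    The most recent in-house record wins; external records are considered
    only when no in-house one exists. Date ties break toward the latest
    list position (the record entered last).
    """
    if not records:
        raise DomainError("no-endoscopy", "record list is empty")
    in_house = [r for r in records if r.site == "in-house"]
    pool = in_house or list(records)
    return max(enumerate(pool), key=lambda ir: (ir[1].date, ir[0]))[1]


def _symptom_association_positive(s: PhImpedanceSummary, cfg: GerdConfig) -> bool:
    sap_pos = s.sap is not None and s.sap >= cfg.sap_positive
    si_pos = s.si is not None and s.si >= cfg.si_positive
    if cfg.association_rule == "sap-only":
        return sap_pos
    if cfg.association_rule == "si-only":
        return si_pos
    return sap_pos or si_pos


def classify_ph_impedance(
    s: PhImpedanceSummary, cfg: GerdConfig = GerdConfig()
) -> str:
    """Map a study summary to one of the six combined report categories."""
    ph_pathologic = s.aet_total >= cfg.aet_abnormal
    n = s.reflux_episode_count
    if n >= cfg.episodes_abnormal:
        imp = "pathologic"
    elif n >= cfg.episodes_borderline:
        imp = "borderline"
    else:
        imp = "normal"

    if ph_pathologic and imp == "pathologic":
        return "both pathologic"
    if ph_pathologic and imp == "borderline":
        return "pH pathologic & impedance borderline"
    if ph_pathologic:
        acid = s.acid_episode_count
        if acid is not None and n > 0 and acid > n / 2:
            return "pathological acid reflux"
        return "pH pathologic & impedance normal"
    if imp == "pathologic":
        return "impedance pathologic & pH normal"
    # borderline impedance with normal pH is not pathologic on either axis
    return "both normal"


def classify_gerd(
    endoscopy: EndoscopyRecord,
    s: PhImpedanceSummary | None,
    cfg: GerdConfig = GerdConfig(),
) -> GerdPhenotype:
    """Run the phenotype cascade: endoscopy → acid exposure → association."""
    if endoscopy.la_grade in ("A", "B", "C", "D"):
        return GerdPhenotype(
            "erosive esophagitis",
            (f"la-grade={endoscopy.la_grade}", "-> erosive esophagitis"),
        )
    if s is None:
        raise DomainError(
            "insufficient-data",
            "negative endoscopy requires pH monitoring to phenotype",
        )
    if s.aet_total >= cfg.aet_abnormal:
        return GerdPhenotype(
            "non-erosive reflux disease",
            (
                "la-grade=none",
                f"aet={s.aet_total:g}>= {cfg.aet_abnormal:g}",
                "-> non-erosive reflux disease",
            ),
        )
    if _symptom_association_positive(s, cfg):
        return GerdPhenotype(
            "reflux hypersensitivity",
            (
                "la-grade=none",
                f"aet={s.aet_total:g}<{cfg.aet_abnormal:g}",
                f"association-positive ({cfg.association_rule})",
                "-> reflux hypersensitivity",
            ),
        )
    return GerdPhenotype(
        "functional heartburn",
        (
            "la-grade=none",
            f"aet={s.aet_total:g}<{cfg.aet_abnormal:g}",
            "association-negative",
            "-> functional heartburn",
        ),
    )
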