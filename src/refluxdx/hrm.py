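"""Chicago Classification 3.0 rule engine for high-resolution manometry.

A study is an ordered series of wet swallows (canonically 10). Each swallow
carries the standard pressure-topography metrics:

* **DCI** — distal contractile integral (mmHg·s·cm), contraction vigor;
* **DL** — distal latency (s), time to the contractile deceleration point;
* **IRP** — 4-second integrated relaxation pressure (mmHg) at the
  esophagogastric junction (EGJ);
* largest break (cm) in the 20 mmHg isobaric contour;
* **PEP** — panesophageal pressurization (present/absent).

Swallows are first scored individually (failed / weak / fragmented /
premature / hypercontractile / normal), then the study-level diagnosis is
resolved by the CC 3.0 hierarchy: the median IRP over the study decides
between the EGJ-outflow arm (achalasia types I–III, EGJ outflow obstruction)
and the peristalsis arm (absent contractility, distal esophageal spasm,
hypercontractile "jackhammer" esophagus, ineffective esophageal motility,
fragmented peristalsis, normal motility). Ten diagnoses are reachable, each
with a rule-firing trace for explainability.

All numeric thresholds live in :class:`Cc30Config` and default to the
consensus values (DCI 100 / 450 / 8000 mmHg·s·cm, DL 4.5 s, break 5 cm,
IRP upper limit of normal 15 mmHg, 20% / 50% swallow fractions).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from ._util import check_finite, raise_validation
from .errors import DomainError

__all__ = [
    "SwallowMetrics",
    "Cc30Config",
    "HrmStudy",
    "Cc30Diagnosis",
    "SWALLOW_CLASSES",
    "CC30_LABELS",
    "CC30_CATEGORIES",
    "classify_swallow",
    "median_irp",
    "classify_study",
]

SWALLOW_CLASSES = (
    "failed",
    "weak",
    "fragmented",
    "premature",
    "hypercontractile",
    "normal",
)

#: The ten study-level diagnoses, mapped to their CC 3.0 category.
CC30_CATEGORIES: dict[str, str] = {
    "type I achalasia": "EGJ-outflow disorder",
    "type II achalasia": "EGJ-outflow disorder",
    "type III achalasia": "EGJ-outflow disorder",
    "EGJ outflow obstruction": "EGJ-outflow disorder",
    "absent contractility": "major motility disorder",
    "distal esophageal spasm": "major motility disorder",
    "hypercontractile esophagus (jackhammer)": "major motility disorder",
    "ineffective esophageal motility": "minor motility disorder",
    "fragmented peristalsis": "minor motility disorder",
    "normal motility": "normal",
}

CC30_LABELS = tuple(CC30_CATEGORIES)


@dataclass(frozen=True)
class SwallowMetrics:
    """Metrics of one wet swallow.

    ``dl`` and ``largest_break_cm`` may be absent (``None``): a failed swallow
    has no contractile deceleration point and an intact contour has no break.
    A swallow with PEP present is permitted any DCI.
    """

    dci: float
    dl: float | None = None
    irp4: float | None = None
    largest_break_cm: float | None = None
    pep: bool = False

    def __post_init__(self):
        check_finite("dci", self.dci)
        if self.dci < 0:
            raise_validation("dci", self.dci, "must be >= 0")
        if self.dl is not None:
            check_finite("dl", self.dl)
            if self.dl <= 0:
                raise_validation("dl", self.dl, "must be > 0 when present")
        if self.irp4 is not None:
            check_finite("irp4", self.irp4)
        if self.largest_break_cm is not None:
            check_finite("largest_break_cm", self.largest_break_cm)
            if self.largest_break_cm < 0:
                raise_validation(
                    "largest_break_cm", self.largest_break_cm, "must be >= 0"
                )


@dataclass(frozen=True)
class Cc30Config:
    """Thresholds of the CC 3.0 decision rules (consensus defaults)."""

    dci_failed: float = 100.0  # mmHg·s·cm
    dci_weak: float = 450.0
    dci_hyper: float = 8000.0
    dl_premature: float = 4.5  # s
    break_large_cm: float = 5.0
    irp_uln: float = 15.0  # mmHg, upper limit of normal
    frac_premature: float = 0.20
    frac_pep: float = 0.20
    frac_hyper: float = 0.20
    frac_ineffective: float = 0.50
    frac_fragmented: float = 0.50

    def __post_init__(self):
        if not 0 < self.dci_failed < self.dci_weak < self.dci_hyper:
            raise_validation(
                "dci thresholds",
                (self.dci_failed, self.dci_weak, self.dci_hyper),
                "must satisfy 0 < failed < weak < hyper",
            )
        if self.irp_uln <= 0:
            raise_validation("irp_uln", self.irp_uln, "must be > 0")
        for name in (
            "frac_premature",
            "frac_pep",
            "frac_hyper",
            "frac_ineffective",
            "frac_fragmented",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise_validation(name, v, "must be in (0, 1]")


@dataclass(frozen=True)
class HrmStudy:
    """One patient's ordered swallow series (classification is order-free)."""

    patient_id: str
    swallows: tuple[SwallowMetrics, ...]

    def __post_init__(self):
        object.__setattr__(self, "swallows", tuple(self.swallows))
        if len(self.swallows) < 1:
            raise_validation("swallows", len(self.swallows), "study must be non-empty")


@dataclass(frozen=True)
class Cc30Diagnosis:
    label: str
    category: str
    median_irp: float
    fractions: dict[str, float] = field(default_factory=dict)
    trace: tuple[str, ...] = ()


def classify_swallow(s: SwallowMetrics, cfg: Cc30Config = Cc30Config()) -> str:
    """Score one swallow into exactly one of the six swallow classes.

    Precedence: failed → premature → hypercontractile → fragmented → weak →
    normal. Premature requires preserved vigor (DCI ≥ weak cutoff): a short
    latency with DCI < 450 is a failed/weak swallow, not a premature one.
    """
    if s.dci < cfg.dci_failed:
        return "failed"
    if s.dl is not None and s.dl < cfg.dl_premature and s.dci >= cfg.dci_weak:
        return "premature"
    if s.dci > cfg.dci_hyper:
        return "hypercontractile"
    if (
        s.largest_break_cm is not None
        and s.largest_break_cm > cfg.break_large_cm
        and s.dci >= cfg.dci_weak
    ):
        return "fragmented"
    if s.dci < cfg.dci_weak:
        return "weak"
    return "normal"


def median_irp(study: HrmStudy) -> float:
    """Median of the per-swallow IRP values (mean of the middle pair for even n)."""
    values = [s.irp4 for s in study.swallows if s.irp4 is not None]
    if not values:
        raise DomainError("irp-missing", f"study {study.patient_id} has no irp4 values")
    return float(statistics.median(values))


def classify_study(study: HrmStudy, cfg: Cc30Config = Cc30Config()) -> Cc30Diagnosis:
    """Resolve the study-level CC 3.0 diagnosis.

    With elevated median IRP (≥ ULN) the EGJ-outflow arm applies, in order:
    premature fraction (type III), PEP fraction (type II), 100% failed
    (type I), else EGJ outflow obstruction — the spastic feature outranks
    pressurization when both fractions exceed their cutoffs. With normal
    median IRP: 100% failed (absent contractility), premature fraction
    (distal esophageal spasm), hypercontractile fraction (jackhammer),
    failed+weak fraction (ineffective esophageal motility, evaluated before
    fragmented peristalsis), fragmented fraction, else normal motility.
    """
    n = len(study.swallows)
    classes = [classify_swallow(s, cfg) for s in study.swallows]
    frac = {c: classes.count(c) / n for c in SWALLOW_CLASSES}
    frac["pep"] = sum(1 for s in study.swallows if s.pep) / n
    frac["ineffective"] = frac["failed"] + frac["weak"]
    m = median_irp(study)
    trace = [f"median-irp={m:g}"]

    if m >= cfg.irp_uln:
        trace.append("irp-elevated")
        if frac["premature"] >= cfg.frac_premature:
            trace.append(f"premature-fraction={frac['premature']:g}")
            label = "type III achalasia"
        elif frac["pep"] >= cfg.frac_pep:
            trace.append(f"pep-fraction={frac['pep']:g}")
            label = "type II achalasia"
        elif frac["failed"] == 1.0:
            trace.append("all-failed")
            label = "type I achalasia"
        else:
            trace.append("peristalsis-preserved")
            label = "EGJ outflow obstruction"
    else:
        trace.append("irp-normal")
        if frac["failed"] == 1.0:
            trace.append("all-failed")
            label = "absent contractility"
        elif frac["premature"] >= cfg.frac_premature:
            trace.append(f"premature-fraction={frac['premature']:g}")
            label = "distal esophageal spasm"
        elif frac["hypercontractile"] >= cfg.frac_hyper:
            trace.append(f"hypercontractile-fraction={frac['hypercontractile']:g}")
            label = "hypercontractile esophagus (jackhammer)"
        elif frac["ineffective"] >= cfg.frac_ineffective:
            trace.append(f"ineffective-fraction={frac['ineffective']:g}")
            label = "ineffective esophageal motility"
        elif frac["fragmented"] >= cfg.frac_fragmented:
            trace.append(f"fragmented-fraction={frac['fragmented']:g}")
            label = "fragmented peristalsis"
        else:
            label = "normal motility"
    trace.append(f"-> {label}")
    return Cc30Diagnosis(
        label=label,
        category=CC30_CATEGORIES[label],
        median_irp=m,
        fractions=frac,
        trace=tuple(trace),
    )
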