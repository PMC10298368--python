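"""Seeded synthetic patients with known ground truth for every classifier.

No patient-level data from the source registry is deposited anywhere, so
this module is the package's fixture engine: for each Chicago Classification
3.0 diagnosis and each GERD phenotype it generates raw inputs (swallow
series, endoscopy records, pH-impedance summaries, reflux/symptom event
streams) that the default-configured classifiers provably map back to the
requested label, and it expands margin tables (label × sex, label × age
band) into full labelled cohorts.

Sampling ranges keep at least a 20% margin from every decision threshold so
label assignment is robust to floating-point noise; branches gated on
swallow fractions use 3/10 (vs the 0.20 cutoff) or 7/10 (vs 0.50). The
margins are the documented constants below.

Determinism: one master integer seed, with a named sub-stream per label and
patient (``numpy`` ``SeedSequence`` spawn keys), so the same spec + seed is
byte-identical regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import datetime

import numpy as np

from ._util import sub_rng
from .association import RefluxEpisode, SymptomEvent, compute_association
from .errors import DomainError
from .gerd import GERD_LABELS, EndoscopyRecord, PhImpedanceSummary
from .hrm import CC30_LABELS, HrmStudy, SwallowMetrics

__all__ = [
    "CohortSpec",
    "LabelMargins",
    "LabeledPatient",
    "generate_hrm_study",
    "generate_gerd_case",
    "generate_cohort",
    "table2_cohort_spec",
    "table3_cohort_spec",
]

# per-branch metric ranges, all >= 20% clear of the default thresholds
DCI_FAILED = (0.0, 80.0)  # < 100
DCI_WEAK = (120.0, 360.0)  # 100..450
DCI_NORMAL = (540.0, 6400.0)  # 450..8000
DCI_HYPER = (9600.0, 15000.0)  # > 8000
DL_PREMATURE = (2.0, 3.6)  # < 4.5
DL_NORMAL = (5.4, 8.0)  # >= 4.5
BREAK_LARGE = (6.0, 10.0)  # > 5
IRP_ELEVATED = (18.0, 30.0)  # >= 15
IRP_NORMAL = (3.0, 12.0)  # < 15
AET_ABNORMAL = (4.8, 10.0)  # >= 4.0
AET_NORMAL = (0.5, 3.2)  # < 4.0

DURATION_S = 86400.0  # 24-h recording


def _swallow(rng, dci_range, dl_range=DL_NORMAL, break_range=None, pep=False, irp_range=IRP_NORMAL):
    dci = float(rng.uniform(*dci_range))
    dl = float(rng.uniform(*dl_range)) if dci >= 100 else None
    brk = float(rng.uniform(*break_range)) if break_range else None
    return SwallowMetrics(
        dci=dci,
        dl=dl,
        irp4=float(rng.uniform(*irp_range)),
        largest_break_cm=brk,
        pep=pep,
    )


def generate_hrm_study(target: str, seed: int, n_swallows: int = 10) -> HrmStudy:
    """Generate a swallow series that classifies to ``target`` by construction."""
    if target not in CC30_LABELS:
        raise DomainError("unknown-label", target)
    rng = sub_rng(seed, CC30_LABELS.index(target))
    n = n_swallows
    k = max(3, -(-n * 3 // 10))  # fraction-gated branches: 3 of 10
    k_half = max(4, -(-n * 7 // 10))  # majority-gated branches: 7 of 10

    def mk(spec_list):
        rng.shuffle(spec_list)
        return HrmStudy(patient_id=f"sim-hrm-{target}-{seed}", swallows=tuple(spec_list))

    if target == "type I achalasia":
        sw = [_swallow(rng, DCI_FAILED, irp_range=IRP_ELEVATED) for _ in range(n)]
    elif target == "type II achalasia":
        sw = [
            _swallow(rng, DCI_FAILED, pep=i < k, irp_range=IRP_ELEVATED)
            for i in range(n)
        ]
    elif target == "type III achalasia":
        sw = [
            _swallow(rng, DCI_NORMAL, DL_PREMATURE, irp_range=IRP_ELEVATED)
            if i < k
            else _swallow(rng, DCI_NORMAL, irp_range=IRP_ELEVATED)
            for i in range(n)
        ]
    elif target == "EGJ outflow obstruction":
        sw = [_swallow(rng, DCI_NORMAL, irp_range=IRP_ELEVATED) for _ in range(n)]
    elif target == "absent contractility":
        sw = [_swallow(rng, DCI_FAILED) for _ in range(n)]
    elif target == "distal esophageal spasm":
        sw = [
            _swallow(rng, DCI_NORMAL, DL_PREMATURE) if i < k else _swallow(rng, DCI_NORMAL)
            for i in range(n)
        ]
    elif target == "hypercontractile esophagus (jackhammer)":
        sw = [
            _swallow(rng, DCI_HYPER) if i < k else _swallow(rng, DCI_NORMAL)
            for i in range(n)
        ]
    elif target == "ineffective esophageal motility":
        sw = [
            _swallow(rng, DCI_FAILED if i % 2 else DCI_WEAK)
            if i < k_half
            else _swallow(rng, DCI_NORMAL)
            for i in range(n)
        ]
    elif target == "fragmented peristalsis":
        sw = [
            _swallow(rng, DCI_NORMAL, break_range=BREAK_LARGE)
            if i < k_half
            else _swallow(rng, DCI_NORMAL)
            for i in range(n)
        ]
    else:  # normal motility
        sw = [_swallow(rng, DCI_NORMAL) for _ in range(n)]
    return mk(sw)


@dataclass(frozen=True)
class LabeledPatient:
    patient_id: str
    sex: str
    age: int
    truth_label: str
    raw: dict = field(default_factory=dict)


def _coupled_streams(rng, n_symptoms: int, coupled: bool):
    """Reflux/symptom streams over 24 h; coupled places every symptom 30 s
    after an episode onset, decoupled keeps symptoms >10 min clear of any
    episode so SI = 0 and SAP stays low."""
    n_episodes = max(n_symptoms, 12)
    if coupled:
        onsets = np.sort(rng.uniform(600, DURATION_S - 600, n_episodes))
        episodes = [
            RefluxEpisode(float(t), float(t) + float(rng.uniform(20, 60)))
            for t in onsets
        ]
        chosen = rng.choice(n_episodes, size=n_symptoms, replace=False)
        symptoms = [
            SymptomEvent(float(episodes[i].onset_s) + 30.0, "heartburn")
            for i in sorted(chosen)
        ]
    else:
        onsets = np.sort(rng.uniform(600, DURATION_S / 3, n_episodes))
        episodes = [
            RefluxEpisode(float(t), float(t) + float(rng.uniform(20, 60)))
            for t in onsets
        ]
        symptoms = [
            SymptomEvent(float(t), "heartburn")
            for t in np.sort(rng.uniform(DURATION_S / 2, DURATION_S - 600, n_symptoms))
        ]
    return episodes, symptoms


def generate_gerd_case(target: str, seed: int, patient_id: str | None = None) -> LabeledPatient:
    """Generate endoscopy + pH-impedance inputs classifying to ``target``."""
    if target not in GERD_LABELS:
        raise DomainError("unknown-label", target)
    rng = sub_rng(seed, 100 + GERD_LABELS.index(target))
    pid = patient_id or f"sim-gerd-{target}-{seed}"

    year = int(rng.integers(2010, 2020))
    month = int(rng.integers(1, 13))
    endoscopy = EndoscopyRecord(
        date=datetime.date(year, month, 15),
        site="in-house",
        la_grade=str(rng.choice(["A", "B", "C", "D"]))
        if target == "erosive esophagitis"
        else "none",
    )

    coupled = target == "reflux hypersensitivity"
    n_symptoms = int(rng.integers(8, 15))
    episodes, symptoms = _coupled_streams(rng, n_symptoms, coupled)
    assoc = compute_association(DURATION_S, episodes, symptoms)

    aet_range = (
        AET_ABNORMAL
        if target in ("erosive esophagitis", "non-erosive reflux disease")
        else AET_NORMAL
    )
    if target == "erosive esophagitis" and rng.random() < 0.5:
        aet_range = AET_NORMAL  # endoscopy precedence: pH data may be anything
    summary = PhImpedanceSummary(
        aet_total=float(rng.uniform(*aet_range)),
        reflux_episode_count=len(episodes),
        si=assoc.si,
        sap=assoc.sap,
        acid_episode_count=sum(1 for e in episodes if e.kind == "acid"),
    )
    sex = str(rng.choice(["male", "female"]))
    age = int(rng.integers(18, 80))
    return LabeledPatient(
        patient_id=pid,
        sex=sex,
        age=age,
        truth_label=target,
        raw={
            "endoscopy": [endoscopy],
            "summary": summary,
            "episodes": episodes,
            "symptoms": symptoms,
            "duration_s": DURATION_S,
        },
    )


@dataclass(frozen=True)
class LabelMargins:
    """Per-label cohort margins: sex counts and age-band counts.

    The two margins must sum to the same label total; sexes and age bands
    are paired positionally when the cohort is expanded.
    """

    sex: dict[str, int]
    age_bands: dict[tuple[int, int], int]

    def total(self) -> int:
        return sum(self.sex.values())

    def validate(self, label: str):
        if any(v < 0 for v in self.sex.values()) or any(
            v < 0 for v in self.age_bands.values()
        ):
            raise DomainError("infeasible-margins", f"{label}: negative count")
        if sum(self.sex.values()) != sum(self.age_bands.values()):
            raise DomainError(
                "infeasible-margins",
                f"{label}: sex total {sum(self.sex.values())} != "
                f"age total {sum(self.age_bands.values())}",
            )
        bands = sorted(self.age_bands)
        for (lo1, hi1), (lo2, _) in zip(bands, bands[1:]):
            if lo2 <= hi1:
                raise DomainError("infeasible-margins", f"{label}: overlapping bands")


@dataclass(frozen=True)
class CohortSpec:
    margins: dict[str, LabelMargins]
    seed: int = 0
    kind: str = "gerd"  # gerd | hrm
    with_raw: bool = True

    def __post_init__(self):
        vocab = GERD_LABELS if self.kind == "gerd" else CC30_LABELS
        for label, m in self.margins.items():
            if label not in vocab:
                raise DomainError("unknown-label", label)
            m.validate(label)


def generate_cohort(spec: CohortSpec) -> list[LabeledPatient]:
    """Expand margins into labelled patients; cell counts match exactly."""
    patients: list[LabeledPatient] = []
    idx = 0
    for label in sorted(spec.margins):
        m = spec.margins[label]
        sexes = [s for s in ("male", "female") for _ in range(m.sex.get(s, 0))]
        bands = [band for band in sorted(m.age_bands) for _ in range(m.age_bands[band])]
        for sex, (lo, hi) in zip(sexes, bands):
            idx += 1
            rng = sub_rng(spec.seed, 10_000 + idx)
            age = int(rng.integers(lo, hi + 1))
            pid = f"P{idx:06d}"
            if spec.with_raw:
                if spec.kind == "gerd":
                    base = generate_gerd_case(label, spec.seed + idx, patient_id=pid)
                    raw = base.raw
                else:
                    raw = {"study": generate_hrm_study(label, spec.seed + idx)}
            else:
                raw = {}
            patients.append(
                LabeledPatient(
                    patient_id=pid, sex=sex, age=age, truth_label=label, raw=raw
                )
            )
    return patients


# ---------------------------------------------------------------------------
# Margin fixtures transcribed from the published cohort tables


def _fixture_margins(kind: str) -> dict[str, LabelMargins]:
    from .summary import load_fixture

    df = load_fixture("table2" if kind == "gerd" else "table3")
    out: dict[str, LabelMargins] = {}
    for label, g in df.groupby("label"):
        sex = {
            str(r["group"]): int(r["count"])
            for _, r in g[g["axis"] == "sex"].iterrows()
        }
        bands = {}
        for _, r in g[g["axis"] == "age"].iterrows():
            lo, hi = str(r["group"]).split("-")
            bands[(int(lo), int(hi))] = int(r["count"])
        out[str(label)] = LabelMargins(sex=sex, age_bands=bands)
    return out


def table2_cohort_spec(seed: int = 0, with_raw: bool = False) -> CohortSpec:
    """Cohort spec matching the published GERD-phenotype margin table (n=2052)."""
    return CohortSpec(margins=_fixture_margins("gerd"), seed=seed, kind="gerd", with_raw=with_raw)


def table3_cohort_spec(seed: int = 0, with_raw: bool = False) -> CohortSpec:
    """Cohort spec matching the published manometry margin table (n=133)."""
    return CohortSpec(margins=_fixture_margins("hrm"), seed=seed, kind="hrm", with_raw=with_raw)
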