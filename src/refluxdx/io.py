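"""CSV/JSON readers and writers for the package's documented formats."""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict
from typing import Sequence

import pandas as pd

from .association import AssociationResult, RefluxEpisode, SymptomEvent
from .gerd import EndoscopyRecord, PhImpedanceSummary
from .hrm import Cc30Diagnosis, HrmStudy, SwallowMetrics
from .summary import CohortRecord

__all__ = [
    "read_swallows_csv",
    "write_swallows_csv",
    "read_episodes_csv",
    "read_symptoms_csv",
    "write_episodes_csv",
    "write_symptoms_csv",
    "read_patient_json",
    "read_labels_csv",
    "write_labels_csv",
    "diagnosis_to_dict",
    "association_to_dict",
]

_TRUTHY = {"1", "true", "yes", "present", "y"}


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_swallows_csv(path) -> list[HrmStudy]:
    """One row per swallow: patient_id,swallow_idx,dci,dl,irp4,largest_break_cm,pep."""
    df = pd.read_csv(path)
    studies = []
    for pid, g in df.groupby("patient_id", sort=False):
        g = g.sort_values("swallow_idx") if "swallow_idx" in g else g
        swallows = [
            SwallowMetrics(
                dci=float(row["dci"]),
                dl=_opt(row.get("dl")),
                irp4=_opt(row.get("irp4")),
                largest_break_cm=_opt(row.get("largest_break_cm")),
                pep=str(row.get("pep", "")).strip().lower() in _TRUTHY,
            )
            for _, row in g.iterrows()
        ]
        studies.append(HrmStudy(patient_id=str(pid), swallows=tuple(swallows)))
    return studies


def write_swallows_csv(studies: Sequence[HrmStudy], path):
    rows = [
        {
            "patient_id": st.patient_id,
            "swallow_idx": i,
            "dci": s.dci,
            "dl": s.dl,
            "irp4": s.irp4,
            "largest_break_cm": s.largest_break_cm,
            "pep": int(s.pep),
        }
        for st in studies
        for i, s in enumerate(st.swallows)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_episodes_csv(path) -> list[RefluxEpisode]:
    df = pd.read_csv(path)
    return [
        RefluxEpisode(
            onset_s=float(r["onset_s"]),
            end_s=float(r["end_s"]),
            kind=str(r.get("kind", "acid")) if not pd.isna(r.get("kind")) else "acid",
            proximal=str(r.get("proximal", "")).strip().lower() in _TRUTHY,
        )
        for _, r in df.iterrows()
    ]


def read_symptoms_csv(path) -> list[SymptomEvent]:
    df = pd.read_csv(path)
    return [
        SymptomEvent(onset_s=float(r["onset_s"]), label=str(r.get("label", "symptom")))
        for _, r in df.iterrows()
    ]


def write_episodes_csv(episodes: Sequence[RefluxEpisode], path):
    pd.DataFrame([asdict(e) for e in episodes]).to_csv(path, index=False)


def write_symptoms_csv(symptoms: Sequence[SymptomEvent], path):
    pd.DataFrame([asdict(s) for s in symptoms]).to_csv(path, index=False)


def read_patient_json(path) -> tuple[list[EndoscopyRecord], PhImpedanceSummary | None]:
    """Patient bundle: endoscopy record list + optional pH-impedance summary."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    endoscopy = [
        EndoscopyRecord(
            date=datetime.date.fromisoformat(r["date"]),
            site=r.get("site", "in-house"),
            la_grade=r.get("la_grade", "none"),
            notes=r.get("notes", ""),
        )
        for r in data.get("endoscopy", [])
    ]
    summary = None
    if "ph_impedance" in data and data["ph_impedance"] is not None:
        summary = PhImpedanceSummary(**data["ph_impedance"])
    return endoscopy, summary


def read_labels_csv(path) -> list[CohortRecord]:
    df = pd.read_csv(path)
    return [
        CohortRecord(
            patient_id=str(r["patient_id"]),
            sex=str(r["sex"]),
            age=float(r["age"]),
            label=str(r["label"]),
            reference_label=None
            if "reference_label" not in df.columns or pd.isna(r["reference_label"])
            else str(r["reference_label"]),
        )
        for _, r in df.iterrows()
    ]


def write_labels_csv(cohort: Sequence[CohortRecord], path):
    pd.DataFrame([asdict(r) for r in cohort]).to_csv(path, index=False)


def diagnosis_to_dict(d: Cc30Diagnosis) -> dict:
    return {
        "label": d.label,
        "category": d.category,
        "median_irp": d.median_irp,
        "fractions": dict(d.fractions),
        "trace": list(d.trace),
    }


def association_to_dict(r: AssociationResult) -> dict:
    return {
        "si": r.si,
        "sap": r.sap,
        "ssi": r.ssi,
        "p_one_tailed": r.p_one_tailed,
        "table": {
            "s_plus_r_plus": r.table.s_plus_r_plus,
            "s_plus_r_minus": r.table.s_plus_r_minus,
            "s_minus_r_plus": r.table.s_minus_r_plus,
            "s_minus_r_minus": r.table.s_minus_r_minus,
        },
        "n_symptoms": r.n_symptoms,
        "n_episodes": r.n_episodes,
    }
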