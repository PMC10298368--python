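"""Symptom–reflux association statistics for 24-h pH-impedance monitoring.

Implements the standard windowed association indices computed from a stream
of impedance-detected reflux episodes and patient-reported symptom events:

* **SI** (Symptom Index): % of symptom events preceded by ≥1 reflux episode
  within the association window (default 2 min, inclusive of the onset
  second).
* **SAP** (Symptom Association Probability): the recording is divided into
  consecutive 2-minute windows, each cross-classified as reflux-positive
  (an episode overlaps the window) and symptom-positive (a reflux-associated
  symptom onset falls in the window); SAP = 100 × (1 − p) where p is the
  one-tailed Fisher exact probability of the observed or a stronger
  positive association.
* **SSI** (Symptom Sensitivity Index): % of reflux episodes followed by ≥1
  symptom onset within the window after episode onset.

Degenerate inputs (no symptoms / no episodes) yield absent statistics rather
than zeros, so a missing index is never mistaken for a negative association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from ._util import check_finite, raise_validation
from .errors import DomainError

__all__ = [
    "RefluxEpisode",
    "SymptomEvent",
    "AssociationConfig",
    "ContingencyTable",
    "AssociationResult",
    "window_table",
    "fisher_one_tailed",
    "compute_association",
    "associations_by_label",
]

EPISODE_KINDS = ("acid", "weakly-acid", "weakly-alkaline", "nonacid")


@dataclass(frozen=True)
class RefluxEpisode:
    """One impedance-detected reflux episode, [onset_s, end_s) seconds."""

    onset_s: float
    end_s: float
    kind: str = "acid"
    proximal: bool = False

    def __post_init__(self):
        check_finite("onset_s", self.onset_s)
        check_finite("end_s", self.end_s)
        if self.onset_s < 0:
            raise_validation("onset_s", self.onset_s, "must be >= 0")
        if self.end_s <= self.onset_s:
            raise_validation("end_s", self.end_s, "must be > onset_s")
        if self.kind not in EPISODE_KINDS:
            raise_validation("kind", self.kind, f"must be one of {EPISODE_KINDS}")


@dataclass(frozen=True)
class SymptomEvent:
    onset_s: float
    label: str = "symptom"

    def __post_init__(self):
        check_finite("onset_s", self.onset_s)
        if self.onset_s < 0:
            raise_validation("onset_s", self.onset_s, "must be >= 0")


@dataclass(frozen=True)
class AssociationConfig:
    window_s: float = 120.0
    si_positive: float = 50.0  # %
    sap_positive: float = 95.0  # %
    ssi_positive: float = 10.0  # %

    def __post_init__(self):
        if self.window_s <= 0:
            raise_validation("window_s", self.window_s, "must be > 0")
        for name in ("si_positive", "sap_positive", "ssi_positive"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise_validation(name, v, "must be in [0, 100]")


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 window counts: S = symptom-positive, R = reflux-positive."""

    s_plus_r_plus: int
    s_plus_r_minus: int
    s_minus_r_plus: int
    s_minus_r_minus: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.s_plus_r_plus,
            self.s_plus_r_minus,
            self.s_minus_r_plus,
            self.s_minus_r_minus,
        )

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


@dataclass(frozen=True)
class AssociationResult:
    si: float | None
    sap: float | None
    ssi: float | None
    table: ContingencyTable
    p_one_tailed: float | None
    n_symptoms: int = 0
    n_episodes: int = 0


def _validate_events(
    duration_s: float,
    episodes: Sequence[RefluxEpisode],
    symptoms: Sequence[SymptomEvent],
):
    if duration_s <= 0:
        raise_validation("duration_s", duration_s, "must be > 0")
    bad = [i for i, e in enumerate(episodes) if e.end_s > duration_s]
    bad_sym = [i for i, s in enumerate(symptoms) if not 0 <= s.onset_s < duration_s]
    if bad or bad_sym:
        raise DomainError(
            "events-outside-duration",
            f"episode indices {bad}, symptom indices {bad_sym}",
        )


def _reflux_associated(
    symptom: SymptomEvent, episodes: Sequence[RefluxEpisode], window_s: float
) -> bool:
    # window [onset - w, onset] closed at the onset second; episodes half-open
    t = symptom.onset_s
    return any(e.onset_s <= t and e.end_s > t - window_s for e in episodes)


def window_table(
    duration_s: float,
    episodes: Sequence[RefluxEpisode],
    symptoms: Sequence[SymptomEvent],
    cfg: AssociationConfig = AssociationConfig(),
    meal_masks: Iterable[tuple[float, float]] = (),
) -> ContingencyTable:
    """Cross-classify consecutive windows by reflux and symptom occurrence.

    [0, duration_s) is split into consecutive ``window_s`` bins (last partial
    bin kept). A bin is R+ if any episode overlaps it and S+ if a
    reflux-associated symptom onset falls in it. Bins overlapping a meal
    mask are dropped from the counts.
    """
    _validate_events(duration_s, episodes, symptoms)
    w = cfg.window_s
    masks = list(meal_masks)
    a = b = c = d = 0
    start = 0.0
    while start < duration_s:
        end = min(start + w, duration_s)
        if any(m0 < end and m1 > start for m0, m1 in masks):
            start = end
            continue
        r_pos = any(e.onset_s < end and e.end_s > start for e in episodes)
        s_pos = any(
            start <= s.onset_s < end and _reflux_associated(s, episodes, w)
            for s in symptoms
        )
        if s_pos and r_pos:
            a += 1
        elif s_pos:
            b += 1
        elif r_pos:
            c += 1
        else:
            d += 1
        start = end
    return ContingencyTable(a, b, c, d)


def fisher_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact probability P(X >= a) with margins fixed.

    X is hypergeometric: the count in the (S+, R+) cell over all 2×2 tables
    with the observed margins.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or int(v) != v:
            raise_validation(name, v, "must be a non-negative integer")
    n = a + b + c + d
    if n == 0:
        raise DomainError("degenerate-table", "all four counts are zero")
    return float(hypergeom.sf(a - 1, n, a + b, a + c))


def compute_association(
    duration_s: float,
    episodes: Sequence[RefluxEpisode],
    symptoms: Sequence[SymptomEvent],
    cfg: AssociationConfig = AssociationConfig(),
    meal_masks: Iterable[tuple[float, float]] = (),
) -> AssociationResult:
    """Compute SI, SAP, and SSI for one recording."""
    _validate_events(duration_s, episodes, symptoms)
    table = window_table(duration_s, episodes, symptoms, cfg, meal_masks)
    w = cfg.window_s

    si = sap = ssi = p = None
    if symptoms:
        n_assoc = sum(1 for s in symptoms if _reflux_associated(s, episodes, w))
        si = 100.0 * n_assoc / len(symptoms)
        p = fisher_one_tailed(*table.as_tuple())
        sap = 100.0 * (1.0 - p)
    if episodes:
        n_followed = sum(
            1
            for e in episodes
            if any(e.onset_s <= s.onset_s <= e.onset_s + w for s in symptoms)
        )
        ssi = 100.0 * n_followed / len(episodes)
    return AssociationResult(
        si=si,
        sap=sap,
        ssi=ssi,
        table=table,
        p_one_tailed=p,
        n_symptoms=len(symptoms),
        n_episodes=len(episodes),
    )


def associations_by_label(
    duration_s: float,
    episodes: Sequence[RefluxEpisode],
    symptoms: Sequence[SymptomEvent],
    cfg: AssociationConfig = AssociationConfig(),
    meal_masks: Iterable[tuple[float, float]] = (),
) -> dict[str, AssociationResult]:
    """Per-symptom-label results plus the pooled result under key ``pooled``."""
    out: dict[str, AssociationResult] = {}
    for label in sorted({s.label for s in symptoms}):
        subset = [s for s in symptoms if s.label == label]
        out[label] = compute_association(duration_s, episodes, subset, cfg, meal_masks)
    out["pooled"] = compute_association(duration_s, episodes, symptoms, cfg, meal_masks)
    return out
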