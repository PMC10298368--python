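"""Chicago Classification 3.0 engine: swallow scoring and study diagnosis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from refluxdx.errors import DomainError, ValidationError
from refluxdx.hrm import (
    CC30_CATEGORIES,
    CC30_LABELS,
    Cc30Config,
    HrmStudy,
    SwallowMetrics,
    classify_study,
    classify_swallow,
    median_irp,
)


def _study(swallows, pid="p1"):
    return HrmStudy(patient_id=pid, swallows=tuple(swallows))


def _normal_swallow(irp=5.0):
    return SwallowMetrics(dci=2000, dl=7.0, irp4=irp)


# --- swallow-level scoring ---------------------------------------------------


@pytest.mark.parametrize(
    "metrics,expected",
    [
        (dict(dci=50, dl=3.0), "failed"),
        (dict(dci=2000, dl=3.0), "premature"),
        (dict(dci=1000, dl=6.0, largest_break_cm=6.0), "fragmented"),
        (dict(dci=9000, dl=6.0), "hypercontractile"),
        (dict(dci=200, dl=6.0), "weak"),
        (dict(dci=2000, dl=6.0), "normal"),
        # short latency without vigor is weak, not premature
        (dict(dci=200, dl=3.0), "weak"),
        # a large break needs preserved vigor to count as fragmented
        (dict(dci=200, dl=6.0, largest_break_cm=8.0), "weak"),
        # hypercontractile + short latency resolves premature (spastic wins)
        (dict(dci=9000, dl=3.0), "premature"),
    ],
)
def test_swallow_classes(metrics, expected, cc30_cfg):
    assert classify_swallow(SwallowMetrics(**metrics), cc30_cfg) == expected


def _swallow_class_oracle(s: SwallowMetrics) -> str:
    """Independent non-overlapping class definitions (no precedence chain)."""
    if s.dci < 100:
        return "failed"
    if s.dl is not None and s.dl < 4.5 and s.dci >= 450:
        return "premature"
    if s.dci > 8000:
        return "hypercontractile"
    if s.dci < 450:
        return "weak"
    if s.largest_break_cm is not None and s.largest_break_cm > 5.0:
        return "fragmented"
    return "normal"


@given(
    dci=st.floats(0, 16000),
    dl=st.one_of(st.none(), st.floats(1.0, 10.0)),
    brk=st.one_of(st.none(), st.floats(0, 12)),
)
def test_swallow_classification_matches_definition_oracle(dci, dl, brk):
    s = SwallowMetrics(dci=dci, dl=dl, largest_break_cm=brk)
    assert classify_swallow(s) == _swallow_class_oracle(s)


def test_negative_dci_rejected_naming_field():
    with pytest.raises(ValidationError, match="dci"):
        SwallowMetrics(dci=-1)


# --- median IRP --------------------------------------------------------------


def test_median_irp_single_and_even_pair():
    assert median_irp(_study([SwallowMetrics(dci=0, irp4=10)])) == 10
    assert median_irp(
        _study([SwallowMetrics(dci=0, irp4=5), SwallowMetrics(dci=0, irp4=25)])
    ) == 15


def test_median_irp_matches_sort_oracle():
    rng = np.random.default_rng(7)
    vals = rng.uniform(0, 30, size=10)
    study = _study([SwallowMetrics(dci=0, irp4=float(v)) for v in vals])
    s = np.sort(vals)
    assert median_irp(study) == pytest.approx((s[4] + s[5]) / 2, abs=1e-12)


def test_median_irp_missing_errors():
    with pytest.raises(DomainError, match="irp-missing"):
        median_irp(_study([SwallowMetrics(dci=0)]))


# --- study-level diagnosis ---------------------------------------------------


def test_all_failed_elevated_irp_is_type_i():
    study = _study([SwallowMetrics(dci=0, irp4=25) for _ in range(10)])
    d = classify_study(study)
    assert d.label == "type I achalasia"
    assert d.category == "EGJ-outflow disorder"


def test_pep_fraction_trumps_all_failed_for_type_ii():
    study = _study(
        [SwallowMetrics(dci=0, irp4=25, pep=i < 3) for i in range(10)]
    )
    assert classify_study(study).label == "type II achalasia"


def test_weak_majority_with_normal_irp_is_iem():
    sw = [SwallowMetrics(dci=200, dl=6.0, irp4=5) for _ in range(6)]
    sw += [SwallowMetrics(dci=1000, dl=6.0, irp4=5) for _ in range(4)]
    d = classify_study(_study(sw))
    assert d.label == "ineffective esophageal motility"
    assert d.fractions["ineffective"] == pytest.approx(0.6)


def test_iem_takes_precedence_over_fragmented():
    sw = [SwallowMetrics(dci=200, dl=6.0, irp4=5) for _ in range(5)]
    sw += [
        SwallowMetrics(dci=1000, dl=6.0, irp4=5, largest_break_cm=7.0)
        for _ in range(5)
    ]
    assert classify_study(_study(sw)).label == "ineffective esophageal motility"


def test_all_normal_swallows_give_normal_motility(cc30_cfg):
    study = _study([_normal_swallow() for _ in range(10)])
    d = classify_study(study, cc30_cfg)
    assert d.label == "normal motility"
    assert d.category == "normal"


def test_empty_study_rejected():
    with pytest.raises(ValidationError):
        HrmStudy(patient_id="p", swallows=())


@st.composite
def studies(draw):
    n = draw(st.integers(1, 12))
    sw = [
        SwallowMetrics(
            dci=draw(st.floats(0, 16000)),
            dl=draw(st.one_of(st.none(), st.floats(1.0, 10.0))),
            irp4=draw(st.floats(-5, 40)),
            largest_break_cm=draw(st.one_of(st.none(), st.floats(0, 12))),
            pep=draw(st.booleans()),
        )
        for _ in range(n)
    ]
    return HrmStudy(patient_id="h", swallows=tuple(sw))


@given(studies())
def test_every_study_gets_exactly_one_of_the_ten_labels(study):
    d = classify_study(study)
    assert d.label in CC30_LABELS
    assert d.category == CC30_CATEGORIES[d.label]


@given(studies(), st.randoms(use_true_random=False))
def test_diagnosis_is_order_invariant(study, rnd):
    shuffled = list(study.swallows)
    rnd.shuffle(shuffled)
    permuted = HrmStudy(patient_id=study.patient_id, swallows=tuple(shuffled))
    assert classify_study(permuted).label == classify_study(study).label


@given(studies())
def test_elevated_irp_never_yields_normal_motility(study):
    # raise every IRP so the median crosses the upper limit of normal
    raised = HrmStudy(
        patient_id=study.patient_id,
        swallows=tuple(
            SwallowMetrics(
                dci=s.dci,
                dl=s.dl,
                irp4=(s.irp4 or 0) + 50,
                largest_break_cm=s.largest_break_cm,
                pep=s.pep,
            )
            for s in study.swallows
        ),
    )
    assert classify_study(raised).label != "normal motility"


def test_config_invariants_enforced():
    with pytest.raises(ValidationError):
        Cc30Config(dci_failed=500)  # violates failed < weak
    with pytest.raises(ValidationError):
        Cc30Config(frac_premature=0)
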