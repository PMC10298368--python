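"""Symptom-association statistics: windowing, Fisher exact test, SI/SAP/SSI."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from refluxdx.association import (
    AssociationConfig,
    RefluxEpisode,
    SymptomEvent,
    compute_association,
    fisher_one_tailed,
    window_table,
)
from refluxdx.errors import DomainError


def _ep(onset, end, **kw):
    return RefluxEpisode(onset_s=onset, end_s=end, **kw)


def _sym(onset, label="heartburn"):
    return SymptomEvent(onset_s=onset, label=label)


# --- windowing ---------------------------------------------------------------


def test_empty_streams_give_all_negative_windows(assoc_cfg):
    t = window_table(240, [], [], assoc_cfg)
    assert t.as_tuple() == (0, 0, 0, 2)


def test_single_coupled_event_pair(assoc_cfg):
    t = window_table(240, [_ep(0, 30)], [_sym(60)], assoc_cfg)
    assert t.total == 2
    assert t.s_plus_r_plus == 1
    assert t.as_tuple() == (1, 0, 0, 1)


def test_partial_last_window_is_kept(assoc_cfg):
    t = window_table(250, [], [], assoc_cfg)
    assert t.total == 3


def test_events_outside_duration_are_reported():
    with pytest.raises(DomainError, match="events-outside-duration"):
        window_table(100, [_ep(50, 150)], [])
    with pytest.raises(DomainError, match="symptom indices \\[0\\]"):
        window_table(100, [], [_sym(100)])


def _brute_force_table(duration, episodes, symptoms, w):
    """Second-by-second scan over an integer grid (independent oracle)."""
    duration = int(duration)
    reflux_at = [
        any(e.onset_s <= s < e.end_s for e in episodes) for s in range(duration)
    ]

    def associated(t):
        lo = max(0, int(t - w))
        return any(reflux_at[s] for s in range(lo, int(t) + 1))

    a = b = c = d = 0
    for start in range(0, duration, int(w)):
        end = min(start + int(w), duration)
        r = any(reflux_at[s] for s in range(start, end))
        s_pos = any(start <= sym.onset_s < end and associated(sym.onset_s) for sym in symptoms)
        a += s_pos and r
        b += s_pos and not r
        c += (not s_pos) and r
        d += (not s_pos) and not r
    return (a, b, c, d)


def test_window_table_matches_per_second_oracle(assoc_cfg):
    rng = np.random.default_rng(11)
    duration = 7200
    episodes = []
    for onset in sorted(rng.integers(0, duration - 90, size=25)):
        episodes.append(_ep(int(onset), int(onset) + int(rng.integers(10, 80))))
    symptoms = [_sym(int(t)) for t in sorted(rng.integers(0, duration, size=12))]
    got = window_table(duration, episodes, symptoms, assoc_cfg)
    assert got.as_tuple() == _brute_force_table(duration, episodes, symptoms, 120)


# --- Fisher exact ------------------------------------------------------------


def _enumeration_p(a, b, c, d):
    """Exact upper-tail probability by integer enumeration over fixed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    den = math.comb(n, c1)
    num = sum(
        math.comb(r1, k) * math.comb(n - r1, c1 - k)
        for k in range(a, min(r1, c1) + 1)
    )
    return num / den


def test_fisher_zero_cell_gives_certainty():
    assert fisher_one_tailed(0, 5, 3, 7) == pytest.approx(1.0)


def test_fisher_two_by_two_unit_margins():
    # both tables with margins (1,1)/(1,1) are equally likely
    assert fisher_one_tailed(1, 0, 0, 1) == pytest.approx(0.5, abs=1e-12)


def test_fisher_matches_enumeration_on_reference_table():
    assert fisher_one_tailed(4, 1, 2, 713) == pytest.approx(
        _enumeration_p(4, 1, 2, 713), abs=1e-12
    )


@given(
    st.tuples(
        st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
    ).filter(lambda t: sum(t) > 0)
)
def test_fisher_matches_enumeration_on_small_tables(table):
    a, b, c, d = table
    assert fisher_one_tailed(a, b, c, d) == pytest.approx(
        _enumeration_p(a, b, c, d), abs=1e-12
    )


def test_fisher_degenerate_table_rejected():
    with pytest.raises(DomainError, match="degenerate-table"):
        fisher_one_tailed(0, 0, 0, 0)


def test_fisher_p_decreases_as_association_strengthens():
    # move one window from discordant cells into (S+R+)/(S-R-), margins refixed
    p_weak = fisher_one_tailed(2, 3, 3, 12)
    p_strong = fisher_one_tailed(4, 1, 1, 14)
    assert p_strong < p_weak


# --- SI / SAP / SSI ----------------------------------------------------------


def test_si_counts_reflux_preceded_symptoms(assoc_cfg):
    episodes = [_ep(1000 * i, 1000 * i + 30) for i in range(1, 4)]
    symptoms = [_sym(1000 * i + 60) for i in range(1, 4)]  # 3 preceded
    symptoms += [_sym(500.0 + 1000 * i) for i in range(4, 7)]  # 3 not preceded
    res = compute_association(10000, episodes, symptoms, assoc_cfg)
    assert res.si == pytest.approx(50.0)


def test_no_symptoms_leaves_si_sap_absent_but_ssi_defined(assoc_cfg):
    res = compute_association(3600, [_ep(100, 130)], [], assoc_cfg)
    assert res.si is None and res.sap is None
    assert res.ssi == pytest.approx(0.0)


def test_no_episodes_leaves_ssi_absent(assoc_cfg):
    res = compute_association(3600, [], [_sym(100)], assoc_cfg)
    assert res.ssi is None
    assert res.si == pytest.approx(0.0)


def test_ssi_counts_symptom_followed_episodes(assoc_cfg):
    episodes = [_ep(0, 30), _ep(5000, 5030)]
    res = compute_association(10000, episodes, [_sym(60)], assoc_cfg)
    assert res.ssi == pytest.approx(50.0)


def test_strong_coupling_yields_positive_sap(assoc_cfg):
    rng = np.random.default_rng(23)
    onsets = np.sort(rng.uniform(600, 85000, 10))
    episodes = [_ep(float(t), float(t) + 40) for t in onsets]
    symptoms = [_sym(float(t) + 30) for t in onsets]
    res = compute_association(86400, episodes, symptoms, assoc_cfg)
    assert res.sap is not None and res.sap > 95
    assert res.sap == pytest.approx(
        100 * (1 - _enumeration_p(*res.table.as_tuple())), abs=1e-9
    )
    assert res.si == pytest.approx(100.0)


def test_si_ssi_invariant_under_event_reordering(assoc_cfg):
    episodes = [_ep(100, 130), _ep(4000, 4040), _ep(900, 950)]
    symptoms = [_sym(150), _sym(4010), _sym(7000)]
    fwd = compute_association(10000, episodes, symptoms, assoc_cfg)
    rev = compute_association(10000, episodes[::-1], symptoms[::-1], assoc_cfg)
    assert (fwd.si, fwd.ssi, fwd.table) == (rev.si, rev.ssi, rev.table)


def test_window_aligned_time_shift_preserves_indices(assoc_cfg):
    episodes = [_ep(100, 130), _ep(4000, 4040)]
    symptoms = [_sym(150), _sym(7000)]
    base = compute_association(9600, episodes, symptoms, assoc_cfg)
    shift = 1200.0  # whole number of windows
    shifted = compute_association(
        9600 + shift,
        [_ep(e.onset_s + shift, e.end_s + shift) for e in episodes],
        [_sym(s.onset_s + shift) for s in symptoms],
        assoc_cfg,
    )
    assert shifted.si == base.si and shifted.ssi == base.ssi
    # only empty windows are added: the three informative cells are unchanged
    assert (
        shifted.table.s_plus_r_plus,
        shifted.table.s_plus_r_minus,
        shifted.table.s_minus_r_plus,
    ) == (
        base.table.s_plus_r_plus,
        base.table.s_plus_r_minus,
        base.table.s_minus_r_plus,
    )


def test_meal_masked_windows_are_dropped(assoc_cfg):
    t = window_table(480, [_ep(10, 20)], [], assoc_cfg, meal_masks=[(0, 120)])
    assert t.total == 3
    assert t.s_minus_r_plus == 0  # the episode fell in the masked window


def test_invalid_window_rejected():
    with pytest.raises(Exception):
        AssociationConfig(window_s=0)
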