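"""Session validation and interval-union duration accounting."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import day
from consortkit.bouts import segment_bouts
from consortkit.focal import (
    aggregate_pair,
    compute_pcd,
    subtract_intervals,
    union_length,
    validate_sessions,
)
from consortkit.observations import FocalEvent, FocalSessionHeader

NINE_AM = 9 * 3600.0


def header(sid="S1", observed=1200.0, pauses=(), clock_start=NINE_AM,
           date_n=0, pair=("F01", "F02")):
    return FocalSessionHeader(
        session_id=sid, pair=pair, date=day(date_n), clock_start=clock_start,
        observed_seconds=observed, pause_intervals=tuple(pauses),
    )


def ev(behavior, t0, t1, sid="S1", actor=None, receiver=None, mods=(),
       oos=False):
    return FocalEvent(sid, t0, t1, behavior, actor=actor, receiver=receiver,
                      modifiers=frozenset(mods), out_of_sight=oos)


# ---------------------------------------------------------------------------
# protocol validation

@pytest.mark.parametrize(
    "observed,valid,reason",
    [(899.0, False, "too_short"), (900.0, True, "ok"), (1200.0, True, "ok")],
)
def test_min_duration_boundary(observed, valid, reason):
    """Sessions under 15 min are discarded; exactly 15 min is kept."""
    (v,) = validate_sessions([header(observed=observed)])
    assert v.valid is valid and v.reason == reason


def test_resume_window_boundary():
    at_limit = header(pauses=[(NINE_AM + 600, NINE_AM + 3 * 3600)])
    over = header(pauses=[(NINE_AM + 600, NINE_AM + 3 * 3600 + 60)])
    ok, bad = validate_sessions([at_limit, over])
    assert ok.valid  # resumption at exactly three hours is kept
    assert not bad.valid and bad.reason == "resume_window_exceeded"


def test_duplicate_pair_day_keeps_first_session():
    first = header(sid="S1", clock_start=NINE_AM)
    second = header(sid="S2", clock_start=NINE_AM + 7200)
    res = {v.session_id: v for v in validate_sessions([second, first])}
    assert res["S1"].valid
    assert res["S2"].reason == "duplicate_pair_day"


# ---------------------------------------------------------------------------
# interval-union durations

def pcd_oracle(events, horizon=1200):
    """1-second discretization: mark every second covered by a consort state
    (excluding out-of-sight seconds)."""
    covered = np.zeros(horizon, dtype=bool)
    consort_states = {"embrace", "huddle", "contact_sit", "groom", "cofeed",
                      "travel_together", "mutual_follow", "proximity_3m"}
    for e in events:
        if e.behavior in consort_states:
            covered[int(e.t_start):int(e.t_end)] = True
    for e in events:
        if e.out_of_sight:
            covered[int(e.t_start):int(e.t_end)] = False
    return int(covered.sum())


def test_pcd_union_not_sum(catalog):
    events = [ev("proximity_3m", 0, 300), ev("groom", 100, 400,
                                             actor="F01", receiver="F02")]
    assert compute_pcd(events, catalog) == 400


def test_pcd_disjoint_states(catalog):
    events = [ev("huddle", 0, 100), ev("huddle", 200, 300)]
    assert compute_pcd(events, catalog) == 200


def test_pcd_no_events(catalog):
    assert compute_pcd([], catalog) == 0
    # a lone mount is instantaneous: zero measure on its own
    assert compute_pcd([ev("mount", 50, 50, actor="F01", receiver="F02")],
                       catalog) == 0


def test_pcd_excludes_out_of_sight(catalog):
    events = [ev("proximity_3m", 0, 600), ev(None, 100, 200, oos=True)]
    assert compute_pcd(events, catalog) == 500


def test_separation_truncates_open_states(catalog):
    events = [ev("proximity_3m", 0, 600), ev("separation", 250, 250)]
    assert compute_pcd(events, catalog) == 250


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["proximity_3m", "huddle", "embrace",
                             "contact_sit", "cofeed"]),
            st.integers(min_value=0, max_value=1190),
            st.integers(min_value=1, max_value=400),
        ),
        min_size=0, max_size=8,
    ),
    st.lists(
        st.tuples(st.integers(min_value=0, max_value=1190),
                  st.integers(min_value=1, max_value=200)),
        min_size=0, max_size=2,
    ),
)
def test_pcd_matches_discretization_oracle(catalog, states, oos):
    """Union-measure accounting agrees with brute-force 1-second binning on
    integer-second fixtures."""
    events = [ev(code, t0, min(t0 + dur, 1200)) for code, t0, dur in states]
    events += [ev(None, t0, min(t0 + dur, 1200), oos=True) for t0, dur in oos]
    assert compute_pcd(events, catalog) == pcd_oracle(events)


def test_union_and_subtract_primitives():
    assert union_length([(0, 10), (5, 20), (30, 40)]) == 30
    assert subtract_intervals([(0, 10)], [(2, 4), (6, 8)]) == [
        (0, 2), (4, 6), (8, 10)
    ]


# ---------------------------------------------------------------------------
# per-pair aggregation

@pytest.fixture()
def bout_summary():
    from conftest import scan

    (summary,) = segment_bouts([scan("F01", "F02", 0),
                                scan("F01", "F02", 1)])
    return summary


def test_aggregate_pair_counts_and_durations(catalog, bout_summary):
    s1 = [
        ev("proximity_3m", 0, 1000),
        ev("mount", 10, 10, actor="F01", receiver="F02",
           mods=["pelvic_movement"]),
        ev("mount", 20, 20, actor="F01", receiver="F02"),
        ev("mount", 30, 30, actor="F01", receiver="F02",
           mods=["pelvic_movement"]),
        ev("mount", 40, 40, actor="F02", receiver="F01"),
        ev("embrace", 0, 50),
        ev("huddle", 40, 90),
    ]
    s2 = [ev("groom", 100, 160, sid="S2", actor="F02", receiver="F01")]
    summary = aggregate_pair(
        [(header(sid="S1"), s1), (header(sid="S2", date_n=1), s2)],
        bout_summary, catalog,
    )
    assert summary.TOD == 2400
    assert summary.PCD == 1000 + 60
    assert dict(summary.mounts_by_actor) == {"F01": 3, "F02": 1}
    assert summary.total_mounts == 4
    assert summary.pelvic_mounts == 2
    assert summary.IBC_seconds == 90  # union of [0,50] and [40,90]
    assert summary.GR_seconds == 60
    assert summary.recurrence_rate == 1
    assert summary.days_observed == 2


def test_removing_ibc_does_not_change_mounts(catalog, bout_summary):
    events = [
        ev("proximity_3m", 0, 500),
        ev("huddle", 0, 100),
        ev("mount", 10, 10, actor="F01", receiver="F02"),
    ]
    with_ibc = aggregate_pair([(header(), events)], bout_summary, catalog)
    without = aggregate_pair(
        [(header(), [e for e in events if e.behavior != "huddle"])],
        bout_summary, catalog,
    )
    assert with_ibc.IBC_seconds == 100 and without.IBC_seconds == 0
    assert with_ibc.total_mounts == without.total_mounts == 1
    assert with_ibc.PCD == without.PCD  # huddle lies inside proximity


def test_pair_summary_invariants_hold(catalog, bout_summary):
    events = [ev("huddle", 0, 1200)]
    summary = aggregate_pair([(header(), events)], bout_summary, catalog)
    assert 0 <= summary.IBC_seconds <= summary.PCD <= summary.TOD
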