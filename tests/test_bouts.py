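"""Bout segmentation: gap rule, vd-contact extension, per-female activity."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import day, scan
from consortkit.bouts import (
    attach_vd_contact_days,
    consort_activity,
    recurrence_summary,
    segment_bouts,
)
from consortkit.observations import Individual


def brute_force_partition(dates: list[int], gap_days: int = 3) -> list[list[int]]:
    """Enumerate every contiguous partition and keep the one satisfying the
    gap predicate: within a bout every adjacent pair of dates is at most
    gap_days + 1 apart; across a bout boundary, more than gap_days + 1.
    """
    dates = sorted(dates)
    n = len(dates)
    valid = []
    for cuts in range(2 ** max(0, n - 1)):
        parts, cur = [], [dates[0]]
        for i in range(1, n):
            if cuts >> (i - 1) & 1:
                parts.append(cur)
                cur = [dates[i]]
            else:
                cur.append(dates[i])
        parts.append(cur)
        ok = all(
            b - a <= gap_days + 1
            for part in parts
            for a, b in zip(part, part[1:])
        ) and all(
            parts[j + 1][0] - parts[j][-1] > gap_days + 1
            for j in range(len(parts) - 1)
        )
        if ok:
            valid.append(parts)
    assert len(valid) == 1, "gap predicate must determine a unique partition"
    return valid[0]


# ---------------------------------------------------------------------------
# vd-contact extension

def test_vd_day_adjacent_to_mount_retained():
    records = [scan("A", "B", 10), scan("A", "B", 11, mount=False, vd=True)]
    assert len(attach_vd_contact_days(records)) == 2


def test_vd_day_far_from_mount_dropped():
    records = [scan("A", "B", 10), scan("A", "B", 20, mount=False, vd=True)]
    kept = attach_vd_contact_days(records)
    assert [r.date for r in kept] == [day(10)]


def test_vd_chain_extends_through_retained_vd_day():
    records = [
        scan("A", "B", 10),
        scan("A", "B", 11, mount=False, vd=True),
        scan("A", "B", 12, mount=False, vd=True),
    ]
    assert len(attach_vd_contact_days(records)) == 3


def test_empty_records():
    assert attach_vd_contact_days([]) == []
    assert segment_bouts([]) == []


# ---------------------------------------------------------------------------
# gap rule

@pytest.mark.parametrize(
    "offsets,expected_rr",
    [
        ([0, 4], 1),  # 3 intervening days: same bout
        ([0, 5], 2),  # 4 intervening days: new bout
        ([0], 1),
        ([0, 1, 2, 6, 11], 2),
    ],
)
def test_gap_rule_boundaries(offsets, expected_rr):
    records = [scan("A", "B", n) for n in offsets]
    (summary,) = segment_bouts(records)
    assert summary.recurrence_rate == expected_rr
    assert summary.days_observed == len(offsets)


def test_pair_without_mount_excluded():
    records = [scan("A", "B", 10, mount=False, vd=True),
               scan("A", "B", 11, mount=False, vd=True)]
    assert segment_bouts(records) == []


def test_bout_date_bookkeeping():
    records = [scan("A", "B", n) for n in (0, 2, 9)]
    (summary,) = segment_bouts(records)
    first, second = summary.bouts
    assert first.start_date == day(0) and first.end_date == day(2)
    assert second.start_date == second.end_date == day(9)
    assert sum(b.n_days for b in summary.bouts) == summary.days_observed


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.sets(st.integers(min_value=0, max_value=39), min_size=1, max_size=12))
def test_segmentation_matches_brute_force(dates):
    """The gap rule's output equals exhaustive partition enumeration."""
    expected = brute_force_partition(sorted(dates))
    records = [scan("A", "B", n) for n in dates]
    (summary,) = segment_bouts(records)
    got = [[(b - day(0)).days for b in bout.observation_dates]
           for bout in summary.bouts]
    assert got == expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=39), min_size=1, max_size=10,
                unique=True))
def test_record_order_never_matters(dates):
    records = [scan("A", "B", n) for n in dates]
    forward = segment_bouts(records)
    backward = segment_bouts(list(reversed(records)))
    assert forward == backward


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.sets(st.integers(min_value=0, max_value=39), min_size=1, max_size=10),
    st.integers(min_value=0, max_value=39),
)
def test_adding_a_date_never_decreases_days(dates, extra):
    base = [scan("A", "B", n) for n in dates]
    more = [scan("A", "B", n) for n in dates | {extra}]
    (s1,) = segment_bouts(base)
    (s2,) = segment_bouts(more)
    assert s2.days_observed >= s1.days_observed


# ---------------------------------------------------------------------------
# per-female activity

@pytest.fixture()
def activity_roster():
    return [
        Individual("A", "F", 8.0, "m1", "parous"),
        Individual("B", "F", 9.0, "m1", "parous"),
        Individual("C", "F", 10.0, "m2", "parous"),
        Individual("D", "F", 11.0, "m2", "parous"),
        Individual("E", "F", 12.0, "m3", "parous"),
        Individual("M1", "M", 9.0, "m3", "not_applicable"),
    ]


def test_two_bouts_same_partner(activity_roster):
    records = [scan("A", "B", 0), scan("A", "B", 10)]
    table = consort_activity(records, activity_roster).set_index("female_id")
    assert table.loc["A", "homo_consorts"] == 2
    assert table.loc["A", "homo_partners"] == 1


def test_inactive_female_has_zero_counts(activity_roster):
    records = [scan("A", "B", 0)]
    table = consort_activity(records, activity_roster).set_index("female_id")
    assert table.loc["E", "homo_consorts"] == 0
    assert table.loc["E", "total_consorts"] == 0
    assert len(table) == 5  # every mature female appears


def test_multiple_partners_counted_separately(activity_roster):
    records = [scan("A", "B", 0), scan("A", "C", 0), scan("A", "D", 5),
               scan("A", "E", 20), scan("A", "M1", 3, pair_type="MF")]
    table = consort_activity(records, activity_roster).set_index("female_id")
    assert table.loc["A", "homo_partners"] == 4
    assert table.loc["A", "homo_consorts"] == 4
    assert table.loc["A", "het_partners"] == 1
    assert table.loc["A", "total_consorts"] == 5


def test_recurrence_summary_reports_both_denominators():
    records = ([scan("A", "B", n) for n in (0, 10, 20, 30)]
               + [scan("C", "D", 0)])
    summaries = segment_bouts(records)
    rec = recurrence_summary(summaries)
    assert rec["all_pairs"]["n"] == 2
    assert rec["all_pairs"]["mean"] == pytest.approx(2.5)
    assert rec["recurring_pairs"]["n"] == 1
    assert rec["recurring_pairs"]["mean"] == pytest.approx(4.0)
    assert rec["all_pairs"]["max"] == 4
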