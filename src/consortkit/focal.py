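"""Focal-session validation and per-pair duration/frequency accounting.

Sessions are validated against the observation protocol: a 20-min session
is kept only if at least 15 min (75%) were actually observed, any pause was
resumed within three hours of the original start, and it is the pair's only
session that day.

Durations are computed as *interval unions*, never as summed per-behavior
durations: a pair grooming while sitting in proximity is in consort once,
not twice.  This guarantees PCD <= TOD and IBC <= PCD.  Out-of-sight
intervals are excluded from every union, and an explicit separation event
truncates any state still open at that moment.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

from .bouts import PairBoutSummary
from .ethogram import PELVIC_MOVEMENT, EthogramCatalog
from .observations import FocalEvent, FocalSessionHeader, ObservationError

logger = logging.getLogger(__name__)

#: a session with less than this many observed seconds (< 75% of 20 min) is discarded
MIN_SESSION_SECONDS = 900.0
#: a paused session must resume within this many hours of its original start
RESUME_WINDOW_HOURS = 3.0


@dataclass(frozen=True)
class SessionValidity:
    session_id: str
    valid: bool
    reason: str  # ok | too_short | resume_window_exceeded | duplicate_pair_day
    observed_seconds: float


@dataclass(frozen=True)
class PairSummary:
    """Per-pair focal aggregates plus the scan-level stability measures."""

    pair_id: tuple[str, str]
    n_valid_sessions: int
    TOD: float
    PCD: float
    mounts_by_actor: tuple[tuple[str, int], ...]
    total_mounts: int
    pelvic_mounts: int
    IBC_seconds: float
    GR_seconds: float
    recurrence_rate: int
    days_observed: int

    def __post_init__(self) -> None:
        eps = 1e-6
        if not (0 - eps <= self.PCD <= self.TOD + eps):
            raise ObservationError(
                f"pair {self.pair_id}: PCD {self.PCD} outside [0, TOD={self.TOD}]"
            )
        for name, val in (("IBC_seconds", self.IBC_seconds),
                          ("GR_seconds", self.GR_seconds)):
            if not (0 - eps <= val <= self.PCD + eps):
                raise ObservationError(
                    f"pair {self.pair_id}: {name} {val} outside [0, PCD={self.PCD}]"
                )
        if self.pelvic_mounts > self.total_mounts:
            raise ObservationError(
                f"pair {self.pair_id}: pelvic mounts exceed total mounts"
            )
        if self.total_mounts != sum(n for _, n in self.mounts_by_actor):
            raise ObservationError(
                f"pair {self.pair_id}: total_mounts inconsistent with "
                "mounts_by_actor"
            )


# ---------------------------------------------------------------------------
# interval arithmetic (closed-open intervals on the session clock)

def union_length(intervals: list[tuple[float, float]]) -> float:
    """Length of the union of possibly-overlapping intervals."""
    total = 0.0
    end = float("-inf")
    for a, b in sorted(intervals):
        if b <= end:
            continue
        total += b - max(a, end)
        end = b
    return total


def subtract_intervals(
    intervals: list[tuple[float, float]], holes: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Remove ``holes`` from each interval, returning the remaining pieces."""
    if not holes:
        return [iv for iv in intervals if iv[1] > iv[0]]
    holes = sorted(holes)
    out: list[tuple[float, float]] = []
    for a, b in intervals:
        cur = a
        for ha, hb in holes:
            if hb <= cur or ha >= b:
                continue
            if ha > cur:
                out.append((cur, ha))
            cur = max(cur, hb)
            if cur >= b:
                break
        if cur < b:
            out.append((cur, b))
    return out


def _consort_state_intervals(
    events: list[FocalEvent], catalog: EthogramCatalog, codes: frozenset[str]
) -> list[tuple[float, float]]:
    """State intervals for ``codes``, after separation truncation and
    out-of-sight exclusion."""
    separations = sorted(
        e.t_start for e in events
        if e.behavior is not None and e.behavior in catalog.separation_codes
    )
    holes = [(e.t_start, e.t_end) for e in events if e.out_of_sight]
    intervals = []
    for e in events:
        if e.behavior is None or e.behavior not in codes:
            continue
        if not catalog.is_state(e.behavior):
            continue
        t_end = e.t_end
        for s in separations:
            if e.t_start < s < t_end:
                t_end = s
                break
        if t_end > e.t_start:
            intervals.append((e.t_start, t_end))
    return subtract_intervals(intervals, holes)


def compute_pcd(events: list[FocalEvent], catalog: EthogramCatalog) -> float:
    """Pair consort duration (seconds) for one session's event stream.

    The measure of the union of all intervals during which at least one
    consort-behavior state holds.  Instantaneous consort events (mounts)
    contribute zero measure on their own — the proximity/contact states
    around them carry the duration.  Time out of sight never counts.
    """
    for e in events:
        if e.behavior is not None and e.behavior not in catalog.codes:
            raise ObservationError(
                f"session {e.session_id}: behavior {e.behavior!r} not in catalog"
            )
    return union_length(
        _consort_state_intervals(events, catalog, catalog.consort_behavior_codes)
    )


def validate_sessions(
    headers: list[FocalSessionHeader],
    min_seconds: float = MIN_SESSION_SECONDS,
    resume_hours: float = RESUME_WINDOW_HOURS,
) -> list[SessionValidity]:
    """Classify every session as valid or discarded (with a reason).

    A session is discarded iff it observed fewer than ``min_seconds``
    (strict: exactly 15 min is kept), a pause resumed later than
    ``resume_hours`` after the original start (inclusive bound: resumption
    at exactly three hours is kept), or an earlier session exists for the
    same pair-day.
    """
    first_of_day: dict[tuple[tuple[str, str], object], str] = {}
    for h in sorted(headers, key=lambda h: (h.date, h.clock_start, h.session_id)):
        first_of_day.setdefault((h.pair, h.date), h.session_id)

    out: list[SessionValidity] = []
    discarded: dict[str, int] = defaultdict(int)
    for h in headers:
        reason = "ok"
        if h.observed_seconds < min_seconds:
            reason = "too_short"
        elif any(
            end - h.clock_start > resume_hours * 3600 + 1e-9
            for _, end in h.pause_intervals
        ):
            reason = "resume_window_exceeded"
        elif first_of_day[(h.pair, h.date)] != h.session_id:
            reason = "duplicate_pair_day"
        out.append(
            SessionValidity(
                session_id=h.session_id, valid=reason == "ok", reason=reason,
                observed_seconds=h.observed_seconds,
            )
        )
        if reason != "ok":
            discarded[reason] += 1
    for reason, n in sorted(discarded.items()):
        logger.info("discarded %d session(s): %s", n, reason)
    return out


def aggregate_pair(
    sessions: list[tuple[FocalSessionHeader, list[FocalEvent]]],
    bouts: PairBoutSummary,
    catalog: EthogramCatalog,
) -> PairSummary:
    """Aggregate one pair's valid sessions into a :class:`PairSummary`.

    * ``TOD`` — sum of observed seconds across valid sessions,
    * ``PCD`` — consort-duration union summed across sessions,
    * mounts counted per actor; pelvic mounts are those carrying the
      pelvic-movement modifier,
    * ``IBC_seconds`` — union length of intensive-body-contact states,
    * ``GR_seconds`` — union length of grooming states in both directions.
    """
    if not sessions:
        raise ObservationError("aggregate_pair needs at least one valid session")
    pair = sessions[0][0].pair
    for h, _ in sessions:
        if h.pair != pair:
            raise ObservationError(
                f"aggregate_pair: mixed pairs {pair} and {h.pair}"
            )
    tod = 0.0
    pcd = 0.0
    ibc = 0.0
    gr = 0.0
    mounts: dict[str, int] = defaultdict(int)
    total_mounts = 0
    pelvic = 0
    for header, events in sessions:
        tod += header.observed_seconds
        pcd += compute_pcd(events, catalog)
        ibc += union_length(
            _consort_state_intervals(events, catalog, catalog.ibc_codes)
        )
        gr += union_length(
            _consort_state_intervals(events, catalog, catalog.grooming_codes)
        )
        for e in events:
            if e.behavior in catalog.mount_codes:
                total_mounts += 1
                if e.actor is not None:
                    mounts[e.actor] += 1
                if PELVIC_MOVEMENT in e.modifiers:
                    pelvic += 1
    return PairSummary(
        pair_id=pair,
        n_valid_sessions=len(sessions),
        TOD=tod,
        PCD=pcd,
        mounts_by_actor=tuple(sorted(mounts.items())),
        total_mounts=total_mounts,
        pelvic_mounts=pelvic,
        IBC_seconds=ibc,
        GR_seconds=gr,
        recurrence_rate=bouts.recurrence_rate,
        days_observed=bouts.days_observed,
    )


def aggregate_pairs(
    headers: list[FocalSessionHeader],
    events: list[FocalEvent],
    validity: list[SessionValidity],
    bout_summaries: list[PairBoutSummary],
    catalog: EthogramCatalog,
) -> list[PairSummary]:
    """Aggregate all pairs that have both valid sessions and a bout record.

    Pairs with focal data but zero valid sessions (or no bout summary) are
    excluded with a warning, mirroring the protocol's discard rules.
    """
    valid_ids = {v.session_id for v in validity if v.valid}
    events_by_session: dict[str, list[FocalEvent]] = defaultdict(list)
    for e in events:
        events_by_session[e.session_id].append(e)
    by_pair: dict[tuple[str, str], list] = defaultdict(list)
    pairs_seen = set()
    for h in headers:
        pairs_seen.add(h.pair)
        if h.session_id in valid_ids:
            by_pair[h.pair].append((h, events_by_session.get(h.session_id, [])))
    bouts_by_pair = {b.pair_id: b for b in bout_summaries}

    out: list[PairSummary] = []
    for pair in sorted(pairs_seen):
        if pair not in by_pair:
            logger.warning("pair %s: no valid focal sessions; excluded", pair)
            continue
        if pair not in bouts_by_pair:
            logger.warning("pair %s: focal data but no consort bouts; excluded",
                           pair)
            continue
        out.append(aggregate_pair(by_pair[pair], bouts_by_pair[pair], catalog))
    return out
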