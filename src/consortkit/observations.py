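"""Typed records and CSV readers/writers for the three observation tables.

The pipeline consumes three delimited-text inputs:

* ``roster.csv`` — one row per individual (id, sex, age, matriline,
  reproductive status, sterilized flag).
* ``scans.csv`` — behavioral (scan) sampling log: one row per potential
  consort pair per day, with mount / ventro-dorsal-contact flags.  A pair is
  counted at most once per day regardless of the number of sightings, so
  duplicate (pair, day) rows are collapsed by OR-ing the flags.
* ``focal_sessions.csv`` + ``focal_events.csv`` — 20-minute dyadic focal
  sessions and their timed event streams (seconds from session start).

Column-by-column schemas are documented in ``docs/file_formats.md``.
Validation is total: every malformed row raises a located error rather than
being silently dropped.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass

from .ethogram import EthogramCatalog

logger = logging.getLogger(__name__)

#: minimum ages (years) at which females / males count as sexually mature
FEMALE_MATURITY_AGE = 3.5
MALE_MATURITY_AGE = 4.5
#: females at or above this age class as adult rather than adolescent
ADULT_AGE = 5.0
#: minimum age (years) for the menopausal-like reproductive status
MENOPAUSAL_AGE = 26.0

REPRODUCTIVE_STATUSES = frozenset(
    {"nulliparous", "parous", "lactating", "menopausal_like", "not_applicable"}
)

#: planned focal session length: 20 min, 10 min per partner
PLANNED_SESSION_SECONDS = 1200.0


class ObservationError(ValueError):
    """Raised for schema or invariant violations in observation inputs."""


def canonical_pair(id_a: str, id_b: str) -> tuple[str, str]:
    """Unordered dyad key: the lexicographically sorted id tuple."""
    if id_a == id_b:
        raise ObservationError(f"pair members must differ (got {id_a!r} twice)")
    return (id_a, id_b) if id_a < id_b else (id_b, id_a)


def pair_label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str
    age_years: float
    matriline: str
    reproductive_status: str
    sterilized: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ObservationError(f"{self.id}: sex must be F or M, got {self.sex!r}")
        if self.age_years < 0:
            raise ObservationError(f"{self.id}: negative age {self.age_years}")
        if self.reproductive_status not in REPRODUCTIVE_STATUSES:
            raise ObservationError(
                f"{self.id}: unknown reproductive status "
                f"{self.reproductive_status!r}"
            )
        if self.sex == "M" and self.reproductive_status != "not_applicable":
            raise ObservationError(
                f"{self.id}: male reproductive status must be not_applicable"
            )
        if (
            self.reproductive_status == "menopausal_like"
            and self.age_years < MENOPAUSAL_AGE
        ):
            raise ObservationError(
                f"{self.id}: menopausal_like requires age >= {MENOPAUSAL_AGE}"
            )

    @property
    def is_mature(self) -> bool:
        threshold = FEMALE_MATURITY_AGE if self.sex == "F" else MALE_MATURITY_AGE
        return self.age_years >= threshold

    @property
    def age_class(self) -> str | None:
        """``adolescent`` / ``adult`` for mature females, else None."""
        if self.sex != "F" or not self.is_mature:
            return None
        return "adolescent" if self.age_years < ADULT_AGE else "adult"


@dataclass(frozen=True)
class ScanRecord:
    """One pair-day sighting from the scan-sampling log."""

    date: dt.date
    id_a: str
    id_b: str
    pair_type: str  # "FF" or "MF"
    mount_observed: bool
    vd_contact_observed: bool

    def __post_init__(self) -> None:
        if (self.id_a, self.id_b) != canonical_pair(self.id_a, self.id_b):
            raise ObservationError(
                f"scan record pair ({self.id_a}, {self.id_b}) not canonical"
            )
        if self.pair_type not in ("FF", "MF"):
            raise ObservationError(f"pair_type must be FF or MF, got {self.pair_type!r}")
        if not (self.mount_observed or self.vd_contact_observed):
            raise ObservationError(
                "a scan record exists only if a mount or vd-contact was observed"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass(frozen=True)
class FocalEvent:
    session_id: str
    t_start: float
    t_end: float
    behavior: str | None
    actor: str | None = None
    receiver: str | None = None
    modifiers: frozenset[str] = frozenset()
    out_of_sight: bool = False

    def __post_init__(self) -> None:
        if self.t_start < 0 or self.t_end < self.t_start:
            raise ObservationError(
                f"session {self.session_id}: bad interval "
                f"[{self.t_start}, {self.t_end}]"
            )
        if self.behavior is None and not self.out_of_sight:
            raise ObservationError(
                f"session {self.session_id}: event needs a behavior code "
                "unless it marks an out-of-sight interval"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class FocalSessionHeader:
    session_id: str
    pair: tuple[str, str]
    date: dt.date
    clock_start: float  # seconds since midnight
    planned_seconds: float = PLANNED_SESSION_SECONDS
    observed_seconds: float = 0.0
    pause_intervals: tuple[tuple[float, float], ...] = ()
    focal_schedule: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.observed_seconds > self.planned_seconds + 1e-9:
            raise ObservationError(
                f"session {self.session_id}: observed_seconds "
                f"{self.observed_seconds} exceeds planned {self.planned_seconds}"
            )
        if self.focal_schedule:
            total = sum(s for _, s in self.focal_schedule)
            if abs(total - self.observed_seconds) > 1.0:
                raise ObservationError(
                    f"session {self.session_id}: focal_schedule totals {total}, "
                    f"expected observed_seconds {self.observed_seconds}"
                )
            for ind, _ in self.focal_schedule:
                if ind not in self.pair:
                    raise ObservationError(
                        f"session {self.session_id}: focal individual {ind} "
                        "not in the session pair"
                    )


# ---------------------------------------------------------------------------
# parsing helpers

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _parse_bool(text: str, where: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ObservationError(f"{where}: cannot parse boolean {text!r}")


def _parse_date(text: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError as exc:
        raise ObservationError(f"{where}: bad ISO date {text!r}") from exc


def _parse_clock(text: str, where: str) -> float:
    parts = text.strip().split(":")
    if len(parts) not in (2, 3):
        raise ObservationError(f"{where}: bad clock time {text!r}")
    try:
        nums = [float(p) for p in parts]
    except ValueError as exc:
        raise ObservationError(f"{where}: bad clock time {text!r}") from exc
    h, m = nums[0], nums[1]
    s = nums[2] if len(nums) == 3 else 0.0
    return h * 3600 + m * 60 + s


def _format_clock(seconds: float) -> str:
    seconds = round(seconds)
    h, rem = divmod(int(seconds), 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


def _rows(path):
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ObservationError(f"{path}: empty file, header required")
        for lineno, row in enumerate(reader, start=2):
            yield lineno, row


def _get(row: dict, key: str, where: str) -> str:
    if key not in row or row[key] is None:
        raise ObservationError(f"{where}: missing column {key!r}")
    return row[key]


# ---------------------------------------------------------------------------
# roster

ROSTER_COLUMNS = ["id", "sex", "age_years", "matriline", "reproductive_status",
                  "sterilized"]


def read_roster(path) -> list[Individual]:
    """Read and validate the population roster.

    Logs the counts of sexually mature females and males; raises a located
    :class:`ObservationError` on any malformed row.
    """
    individuals: list[Individual] = []
    seen: set[str] = set()
    for lineno, row in _rows(path):
        where = f"{path}:{lineno}"
        ind_id = _get(row, "id", where).strip()
        if ind_id in seen:
            raise ObservationError(f"{where}: duplicate individual id {ind_id!r}")
        seen.add(ind_id)
        try:
            ind = Individual(
                id=ind_id,
                sex=_get(row, "sex", where).strip(),
                age_years=float(_get(row, "age_years", where)),
                matriline=_get(row, "matriline", where).strip(),
                reproductive_status=_get(row, "reproductive_status", where).strip(),
                sterilized=_parse_bool(row.get("sterilized", "0"), where),
            )
        except ObservationError as exc:
            raise ObservationError(f"{where}: {exc}") from None
        except ValueError as exc:
            raise ObservationError(f"{where}: {exc}") from None
        individuals.append(ind)
    n_f = sum(1 for i in individuals if i.sex == "F" and i.is_mature)
    n_m = sum(1 for i in individuals if i.sex == "M" and i.is_mature)
    if not individuals:
        logger.warning("roster %s is empty", path)
    logger.info("roster %s: %d mature females, %d mature males", path, n_f, n_m)
    return individuals


def write_roster(individuals: list[Individual], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_COLUMNS)
        for ind in individuals:
            writer.writerow(
                [ind.id, ind.sex, ind.age_years, ind.matriline,
                 ind.reproductive_status, int(ind.sterilized)]
            )


# ---------------------------------------------------------------------------
# scan log

SCAN_COLUMNS = ["date", "id_a", "id_b", "pair_type", "mount_observed",
                "vd_contact_observed"]


def _expected_pair_type(pair: tuple[str, str], by_id: dict[str, Individual],
                        where: str) -> str:
    sexes = []
    for ind_id in pair:
        if ind_id not in by_id:
            raise ObservationError(f"{where}: id {ind_id!r} not in roster")
        sexes.append(by_id[ind_id].sex)
    return "FF" if sexes == ["F", "F"] else ("MF" if "M" in sexes and "F" in sexes
                                             else "MM")


def read_scan_log(path, roster: list[Individual]) -> list[ScanRecord]:
    """Read the scan-sampling log, canonicalizing pairs and de-duplicating.

    Duplicate (pair, date) rows collapse with a logical OR of the mount /
    vd-contact flags (a pair counts once per day however often it was seen);
    each collapse is logged.
    """
    by_id = {ind.id: ind for ind in roster}
    merged: dict[tuple[tuple[str, str], dt.date], ScanRecord] = {}
    for lineno, row in _rows(path):
        where = f"{path}:{lineno}"
        id_a = _get(row, "id_a", where).strip()
        id_b = _get(row, "id_b", where).strip()
        try:
            pair = canonical_pair(id_a, id_b)
        except ObservationError as exc:
            raise ObservationError(f"{where}: {exc}") from None
        expected = _expected_pair_type(pair, by_id, where)
        pair_type = _get(row, "pair_type", where).strip()
        if pair_type != expected:
            raise ObservationError(
                f"{where}: pair_type {pair_type!r} does not match roster sexes "
                f"(expected {expected})"
            )
        date = _parse_date(_get(row, "date", where), where)
        mount = _parse_bool(_get(row, "mount_observed", where), where)
        vd = _parse_bool(_get(row, "vd_contact_observed", where), where)
        key = (pair, date)
        if key in merged:
            prev = merged[key]
            logger.warning(
                "%s: duplicate sighting for pair %s on %s; OR-ing flags",
                where, pair_label(pair), date,
            )
            mount = mount or prev.mount_observed
            vd = vd or prev.vd_contact_observed
        try:
            merged[key] = ScanRecord(
                date=date, id_a=pair[0], id_b=pair[1], pair_type=pair_type,
                mount_observed=mount, vd_contact_observed=vd,
            )
        except ObservationError as exc:
            raise ObservationError(f"{where}: {exc}") from None
    return sorted(merged.values(), key=lambda r: (r.pair, r.date))


def write_scan_log(records: list[ScanRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCAN_COLUMNS)
        for r in sorted(records, key=lambda r: (r.pair, r.date)):
            writer.writerow(
                [r.date.isoformat(), r.id_a, r.id_b, r.pair_type,
                 int(r.mount_observed), int(r.vd_contact_observed)]
            )


# ---------------------------------------------------------------------------
# focal log

SESSION_COLUMNS = ["session_id", "id_a", "id_b", "date", "clock_start",
                   "planned_seconds", "observed_seconds", "pauses",
                   "focal_a_seconds", "focal_b_seconds"]
EVENT_COLUMNS = ["session_id", "t_start", "t_end", "behavior", "actor",
                 "receiver", "modifiers", "out_of_sight"]


def _parse_pauses(text: str, where: str) -> tuple[tuple[float, float], ...]:
    text = text.strip()
    if not text:
        return ()
    out = []
    for chunk in text.split(";"):
        try:
            a, b = chunk.split("-")
        except ValueError as exc:
            raise ObservationError(f"{where}: bad pause interval {chunk!r}") from exc
        out.append((_parse_clock(a, where), _parse_clock(b, where)))
    return tuple(out)


def read_focal_log(
    sessions_path, events_path, catalog: EthogramCatalog,
    roster: list[Individual],
) -> tuple[list[FocalSessionHeader], list[FocalEvent]]:
    """Read focal session headers and their event streams.

    Events are cross-checked against the catalog (mode, modifiers,
    directionality, session membership) and returned sorted by
    (session_id, t_start).
    """
    by_id = {ind.id: ind for ind in roster}
    headers: list[FocalSessionHeader] = []
    by_session: dict[str, FocalSessionHeader] = {}
    for lineno, row in _rows(sessions_path):
        where = f"{sessions_path}:{lineno}"
        sid = _get(row, "session_id", where).strip()
        if sid in by_session:
            raise ObservationError(f"{where}: duplicate session id {sid!r}")
        id_a = _get(row, "id_a", where).strip()
        id_b = _get(row, "id_b", where).strip()
        for ind_id in (id_a, id_b):
            if ind_id not in by_id:
                raise ObservationError(f"{where}: id {ind_id!r} not in roster")
        pair = canonical_pair(id_a, id_b)
        observed = float(_get(row, "observed_seconds", where))
        fa = float(row.get("focal_a_seconds") or 0.0)
        fb = float(row.get("focal_b_seconds") or 0.0)
        schedule = ((pair[0], fa), (pair[1], fb)) if fa or fb else ()
        try:
            header = FocalSessionHeader(
                session_id=sid,
                pair=pair,
                date=_parse_date(_get(row, "date", where), where),
                clock_start=_parse_clock(_get(row, "clock_start", where), where),
                planned_seconds=float(row.get("planned_seconds")
                                      or PLANNED_SESSION_SECONDS),
                observed_seconds=observed,
                pause_intervals=_parse_pauses(row.get("pauses", ""), where),
                focal_schedule=schedule,
            )
        except ObservationError as exc:
            raise ObservationError(f"{where}: {exc}") from None
        headers.append(header)
        by_session[sid] = header

    events: list[FocalEvent] = []
    for lineno, row in _rows(events_path):
        where = f"{events_path}:{lineno}"
        sid = _get(row, "session_id", where).strip()
        if sid not in by_session:
            raise ObservationError(f"{where}: unknown session id {sid!r}")
        header = by_session[sid]
        behavior = _get(row, "behavior", where).strip() or None
        out_of_sight = _parse_bool(row.get("out_of_sight", "0"), where)
        t_start = float(_get(row, "t_start", where))
        t_end = float(_get(row, "t_end", where))
        modifiers = frozenset(
            m.strip() for m in (row.get("modifiers") or "").split(";") if m.strip()
        )
        actor = (row.get("actor") or "").strip() or None
        receiver = (row.get("receiver") or "").strip() or None
        if t_end > header.planned_seconds + 1e-9:
            raise ObservationError(
                f"{where}: t_end {t_end} exceeds planned session length "
                f"{header.planned_seconds}"
            )
        if behavior is not None:
            if behavior not in catalog.codes:
                raise ObservationError(f"{where}: behavior {behavior!r} not in catalog")
            bdef = catalog.by_code(behavior)
            bad_mods = modifiers - bdef.modifiers
            if bad_mods:
                raise ObservationError(
                    f"{where}: modifiers {sorted(bad_mods)} not allowed on "
                    f"{behavior!r}"
                )
            if bdef.mode == "event" and t_end != t_start:
                raise ObservationError(
                    f"{where}: {behavior!r} is an instantaneous event but "
                    f"t_end != t_start"
                )
            if bdef.mode == "state" and t_end <= t_start:
                raise ObservationError(
                    f"{where}: state {behavior!r} needs t_end > t_start"
                )
            if bdef.directional:
                if actor is None or receiver is None:
                    raise ObservationError(
                        f"{where}: directional behavior {behavior!r} needs actor "
                        "and receiver"
                    )
                for ind_id in (actor, receiver):
                    if ind_id not in header.pair:
                        raise ObservationError(
                            f"{where}: {ind_id!r} is not a member of session "
                            f"{sid}'s pair"
                        )
        try:
            events.append(
                FocalEvent(
                    session_id=sid, t_start=t_start, t_end=t_end,
                    behavior=behavior, actor=actor, receiver=receiver,
                    modifiers=modifiers, out_of_sight=out_of_sight,
                )
            )
        except ObservationError as exc:
            raise ObservationError(f"{where}: {exc}") from None
    events.sort(key=lambda e: (e.session_id, e.t_start, e.t_end))
    return headers, events


def write_focal_log(
    headers: list[FocalSessionHeader], events: list[FocalEvent],
    sessions_path, events_path,
) -> None:
    with open(sessions_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_COLUMNS)
        for h in headers:
            sched = dict(h.focal_schedule)
            pauses = ";".join(
                f"{_format_clock(a)}-{_format_clock(b)}" for a, b in h.pause_intervals
            )
            writer.writerow(
                [h.session_id, h.pair[0], h.pair[1], h.date.isoformat(),
                 _format_clock(h.clock_start), h.planned_seconds,
                 h.observed_seconds, pauses,
                 sched.get(h.pair[0], 0.0), sched.get(h.pair[1], 0.0)]
            )
    with open(events_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for e in sorted(events, key=lambda e: (e.session_id, e.t_start, e.t_end)):
            writer.writerow(
                [e.session_id, e.t_start, e.t_end, e.behavior or "",
                 e.actor or "", e.receiver or "", ";".join(sorted(e.modifiers)),
                 int(e.out_of_sight)]
            )
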