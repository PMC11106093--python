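"""Consort-bout segmentation of pair-day sighting series.

A consort is an exclusive dyadic association that, by definition, must
include at least one observed mount.  A pair's sightings across the season
are segmented into *bouts*: maximal runs of observation days in which no
more than ``gap_days`` (default 3) unobserved days intervene between
consecutive sightings — equivalently, consecutive dates at most
``gap_days + 1`` calendar days apart.  Resumption after a longer gap starts
a new, independent bout.

Ventro-dorsal contact sitting extends a consort: a day on which a pair was
seen only in vd-contact still counts as a consort day when it immediately
precedes or follows a consort day (see :func:`attach_vd_contact_days`).

Per pair this yields the two scan-level stability measures: the recurrence
rate ``RR`` (number of independent bouts) and ``days_observed`` (distinct
consort days across all bouts).
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .observations import Individual, ObservationError, ScanRecord, pair_label

logger = logging.getLogger(__name__)

#: maximum number of intervening unobserved days within one bout
DEFAULT_GAP_DAYS = 3


@dataclass(frozen=True)
class ConsortBout:
    pair_id: tuple[str, str]
    observation_dates: tuple[dt.date, ...]
    mount_dates: tuple[dt.date, ...]

    @property
    def start_date(self) -> dt.date:
        return self.observation_dates[0]

    @property
    def end_date(self) -> dt.date:
        return self.observation_dates[-1]

    @property
    def n_days(self) -> int:
        return len(self.observation_dates)


@dataclass(frozen=True)
class PairBoutSummary:
    pair_id: tuple[str, str]
    pair_type: str
    bouts: tuple[ConsortBout, ...]

    @property
    def recurrence_rate(self) -> int:
        """RR: the number of independent bouts the pair formed."""
        return len(self.bouts)

    @property
    def days_observed(self) -> int:
        """Total distinct consort days, irrespective of bout structure."""
        return sum(b.n_days for b in self.bouts)


def attach_vd_contact_days(records: list[ScanRecord]) -> list[ScanRecord]:
    """Filter vd-contact-only sightings down to those extending a consort.

    Mount days are always retained.  A vd-contact-only day is retained iff
    it is exactly one calendar day before or after an already-retained day
    of the same pair; retention propagates (a retained vd day can carry the
    chain a further day), but a vd-only day with no such link is dropped and
    logged.  Records must already be canonicalized and de-duplicated.
    """
    by_pair: dict[tuple[str, str], list[ScanRecord]] = defaultdict(list)
    for rec in records:
        by_pair[rec.pair].append(rec)

    kept: list[ScanRecord] = []
    for pair, recs in by_pair.items():
        retained = {r.date for r in recs if r.mount_observed}
        vd_only = sorted(r.date for r in recs if not r.mount_observed)
        changed = True
        while changed:
            changed = False
            for d in vd_only:
                if d in retained:
                    continue
                if (d - dt.timedelta(days=1)) in retained or (
                    d + dt.timedelta(days=1)
                ) in retained:
                    retained.add(d)
                    changed = True
        for r in recs:
            if r.date in retained:
                kept.append(r)
            else:
                logger.info(
                    "pair %s: vd-contact-only day %s not adjacent to a consort "
                    "day; dropped", pair_label(pair), r.date,
                )
    kept.sort(key=lambda r: (r.pair, r.date))
    return kept


def segment_bouts(
    records: list[ScanRecord], gap_days: int = DEFAULT_GAP_DAYS
) -> list[PairBoutSummary]:
    """Segment each pair's retained sighting dates into consort bouts.

    Consecutive dates remain in one bout iff separated by at most
    ``gap_days`` intervening unobserved days (date difference
    <= ``gap_days + 1``).  Pairs with no mount day at all violate the
    consort definition and are excluded with a warning.  ``records`` should
    have passed through :func:`attach_vd_contact_days`.
    """
    by_pair: dict[tuple[str, str], list[ScanRecord]] = defaultdict(list)
    for rec in records:
        by_pair[rec.pair].append(rec)

    summaries: list[PairBoutSummary] = []
    for pair in sorted(by_pair):
        recs = sorted(by_pair[pair], key=lambda r: r.date)
        if not any(r.mount_observed for r in recs):
            logger.warning(
                "pair %s: no mount observed on any day; excluded (not a consort)",
                pair_label(pair),
            )
            continue
        bouts: list[ConsortBout] = []
        run: list[ScanRecord] = [recs[0]]
        for rec in recs[1:]:
            if (rec.date - run[-1].date).days <= gap_days + 1:
                run.append(rec)
            else:
                bouts.append(_make_bout(pair, run))
                run = [rec]
        bouts.append(_make_bout(pair, run))
        summaries.append(
            PairBoutSummary(pair_id=pair, pair_type=recs[0].pair_type,
                            bouts=tuple(bouts))
        )
    return summaries


def _make_bout(pair: tuple[str, str], run: list[ScanRecord]) -> ConsortBout:
    return ConsortBout(
        pair_id=pair,
        observation_dates=tuple(r.date for r in run),
        mount_dates=tuple(r.date for r in run if r.mount_observed),
    )


def consort_activity(
    records: list[ScanRecord],
    roster: list[Individual],
    gap_days: int = DEFAULT_GAP_DAYS,
) -> pd.DataFrame:
    """Per-female consort activity over the season.

    Returns one row per sexually mature female in the roster (inactive
    females appear with zeros) with columns:

    ``homo_consorts`` / ``het_consorts``
        number of female-female / male-female bouts she participates in,
    ``homo_partners`` / ``het_partners``
        distinct partners in each mode,
    ``total_consorts`` / ``total_partners``
        sums over both modes (a female with several partners in one day has
        each counted separately, which bout-level counting guarantees).
    """
    by_id = {ind.id: ind for ind in roster}
    for rec in records:
        for ind_id in rec.pair:
            if ind_id not in by_id:
                raise ObservationError(f"scan id {ind_id!r} not in roster")

    summaries = segment_bouts(attach_vd_contact_days(records), gap_days=gap_days)
    counts: dict[str, dict[str, object]] = {}
    females = [i for i in roster if i.sex == "F" and i.is_mature]
    for ind in females:
        counts[ind.id] = {
            "homo_consorts": 0, "het_consorts": 0,
            "homo_partners": set(), "het_partners": set(),
        }
    for summ in summaries:
        mode = "homo" if summ.pair_type == "FF" else "het"
        for member in summ.pair_id:
            if member not in counts:
                continue  # male side of an MF pair
            partner = summ.pair_id[0] if member == summ.pair_id[1] else summ.pair_id[1]
            counts[member][f"{mode}_consorts"] += summ.recurrence_rate
            counts[member][f"{mode}_partners"].add(partner)

    rows = []
    for ind in females:
        c = counts[ind.id]
        rows.append(
            {
                "female_id": ind.id,
                "age_years": ind.age_years,
                "age_class": ind.age_class,
                "reproductive_status": ind.reproductive_status,
                "matriline": ind.matriline,
                "homo_consorts": c["homo_consorts"],
                "het_consorts": c["het_consorts"],
                "homo_partners": len(c["homo_partners"]),
                "het_partners": len(c["het_partners"]),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["female_id", "age_years", "age_class", "reproductive_status",
                 "matriline", "homo_consorts", "het_consorts", "homo_partners",
                 "het_partners"],
    )
    if not df.empty:
        df["total_consorts"] = df["homo_consorts"] + df["het_consorts"]
        df["total_partners"] = df["homo_partners"] + df["het_partners"]
    return df


def recurrence_summary(summaries: list[PairBoutSummary]) -> dict:
    """Mean/SD/range of RR, reported over two denominators.

    Group-level recurrence is ambiguous about whether it averages over all
    pairs or only over pairs that re-consorted (RR >= 2), so both are
    reported: ``all_pairs`` and ``recurring_pairs``.
    """
    import statistics

    def _stats(rrs: list[int]) -> dict:
        if not rrs:
            return {"n": 0, "mean": None, "sd": None, "min": None, "max": None}
        return {
            "n": len(rrs),
            "mean": statistics.fmean(rrs),
            "sd": statistics.stdev(rrs) if len(rrs) > 1 else 0.0,
            "min": min(rrs),
            "max": max(rrs),
        }

    rrs = [s.recurrence_rate for s in summaries]
    return {
        "all_pairs": _stats(rrs),
        "recurring_pairs": _stats([r for r in rrs if r >= 2]),
    }


def bouts_frame(summaries: list[PairBoutSummary]) -> pd.DataFrame:
    """Flat table of bouts: pair_id, bout_index, start/end dates, n_days."""
    rows = []
    for summ in summaries:
        for i, bout in enumerate(summ.bouts, start=1):
            rows.append(
                {
                    "pair_id": pair_label(summ.pair_id),
                    "pair_type": summ.pair_type,
                    "bout_index": i,
                    "start_date": bout.start_date.isoformat(),
                    "end_date": bout.end_date.isoformat(),
                    "n_days": bout.n_days,
                }
            )
    return pd.DataFrame(
        rows, columns=["pair_id", "pair_type", "bout_index", "start_date",
                       "end_date", "n_days"]
    )


def summary_frame(summaries: list[PairBoutSummary]) -> pd.DataFrame:
    """Per-pair table: RR and days_observed."""
    rows = [
        {
            "pair_id": pair_label(s.pair_id),
            "pair_type": s.pair_type,
            "RR": s.recurrence_rate,
            "days_observed": s.days_observed,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=["pair_id", "pair_type", "RR",
                                       "days_observed"])
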