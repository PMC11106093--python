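"""Synthetic mating-season generator.

Emulates the observation design the pipeline expects: a roster of ~76
mature females and ~49 mature males, a ~126-day season of pair-day scan
sightings with gap-structured consort bouts (including a 12-day mid-season
observation blackout), and one 20-minute focal session per female-female
pair per detected consort day.

The generative core is a latent per-pair *bond strength* b ~ Uniform(0, 1)
that couples three observables:

* bout length (days) is a bond-proportional shift ``coupling_duration * b``
  plus geometric day-to-day noise, so expected length grows linearly in b,
* each of the ``max_bouts - 1`` re-consort opportunities succeeds with a
  Bernoulli hazard increasing in ``coupling_recurrence * b``,
* expected intensive-body-contact seconds per session grow with
  ``coupling_ibc * b`` (multiplicative log-normal noise).

Mounting frequency, pelvic movement, mounting reciprocity and grooming are
generated *independently* of the bond, so only the body-contact channel
carries the bond signal.  Setting all three couplings to zero gives a null
season in which intensive body contact is unrelated to consort stability.

Ground truth (bonds, true bout schedules, per-session intensities) is
returned and serialized separately; the analysis pipeline never reads it.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np

from .observations import (
    PLANNED_SESSION_SECONDS,
    FocalEvent,
    FocalSessionHeader,
    Individual,
    ScanRecord,
    canonical_pair,
    pair_label,
)

#: minimum calendar days between one bout's last retained day and the next
#: bout's first; leaves room for ±1-day vd-contact extensions while keeping
#: bouts separated by more than the 3-day gap rule
_BOUT_MARGIN_DAYS = 7


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the season simulator.

    The defaults are the "effect" preset: couplings strong enough that the
    bond signal is recoverable from a single simulated season of 26 pairs.
    Use :meth:`null` for the uncoupled control.
    """

    seed: int = 0
    n_females: int = 76
    n_males: int = 49
    season_days: int = 126
    season_start: dt.date = dt.date(2019, 9, 26)
    n_ff_pairs: int = 26
    #: 1-based season day indices with no observation (default: a 12-day
    #: mid-season holiday block)
    blackout_days: tuple[int, ...] = tuple(range(80, 92))

    # bond -> observable couplings (zero = no effect)
    coupling_ibc: float = 280.0  # IBC seconds per session per unit bond
    coupling_duration: float = 6.0  # extra expected bout days per unit bond
    coupling_recurrence: float = 1.3  # re-consort hazard per unit bond

    # bond-independent behavior rates
    mount_rate: float = 4.0  # expected mounts per full 20-min session
    pelvic_prob: float = 0.5
    reciprocity_conc: float = 2.0  # Beta concentration of actor shares
    ibc_base_seconds: float = 20.0  # bond-free IBC seconds per session
    ibc_noise_sd: float = 0.2  # log-scale SD of IBC multiplicative noise
    groom_mean_seconds: float = 120.0
    vd_contact_prob: float = 0.25  # vd-contact flag on a mount day
    vd_extension_prob: float = 0.3  # vd-only day adjacent to a bout edge

    # observation process
    detection_prob: float = 0.95  # per pair-day sighting probability
    invalid_session_frac: float = 0.05  # sessions made short / late-resumed

    # bond-free baselines of the bout process; the re-consort hazard is
    # clip(recurrence_base + coupling_recurrence * bond, 0, 0.95), so a
    # negative base makes weak-bond pairs single-bout with certainty
    bout_base_extra_days: float = 0.5
    recurrence_base: float = -0.15
    max_bouts: int = 4
    max_ff_partners: int = 4

    # heterosexual background activity
    het_active_prob: float = 0.91
    het_partner_mean: float = 4.0

    # roster composition (counts rescale with n_females)
    n_adolescent: int = 10
    n_nulliparous_adult: int = 2
    n_lactating: int = 7
    n_menopausal: int = 5
    n_matrilines: int = 17

    def __post_init__(self) -> None:
        for name in ("pelvic_prob", "detection_prob", "invalid_session_frac",
                     "het_active_prob", "vd_contact_prob", "vd_extension_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("coupling_ibc", "coupling_duration", "coupling_recurrence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_females <= 0:
            raise ValueError("n_females must be positive (no analyzable population)")
        if self.season_days < 2:
            raise ValueError("season_days must be at least 2")
        if self.n_ff_pairs < 1:
            raise ValueError("n_ff_pairs must be positive")

    @classmethod
    def effect(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """The documented effect preset (the defaults)."""
        return cls(seed=seed, **overrides)

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Uncoupled control: the bond drives nothing.

        All three couplings are zero; the re-consort base hazard is raised
        to a bond-free 0.25 so recurrence still varies across pairs.
        """
        overrides.setdefault("recurrence_base", 0.25)
        return cls(
            seed=seed, coupling_ibc=0.0, coupling_duration=0.0,
            coupling_recurrence=0.0, **overrides,
        )

    def day_to_date(self, day: int) -> dt.date:
        return self.season_start + dt.timedelta(days=day - 1)


@dataclass
class GroundTruth:
    """What the simulator actually did; never consumed by the pipeline."""

    bonds: dict[str, float] = field(default_factory=dict)
    #: pair label -> list of bouts, each {"mount_days": [...], "vd_days": [...]}
    #: as ISO dates
    bout_schedules: dict[str, list[dict]] = field(default_factory=dict)
    #: session_id -> generative intensities
    session_intensities: dict[str, dict] = field(default_factory=dict)

    def pair_days(self, label: str) -> int:
        return sum(
            len(b["mount_days"]) + len(b["vd_days"])
            for b in self.bout_schedules[label]
        )

    def pair_bouts(self, label: str) -> int:
        return len(self.bout_schedules[label])

    def to_json(self) -> str:
        return json.dumps(
            {
                "bonds": self.bonds,
                "bout_schedules": self.bout_schedules,
                "session_intensities": self.session_intensities,
            },
            indent=1,
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())


# ---------------------------------------------------------------------------
# roster

def _scaled(count: int, config: SyntheticConfig) -> int:
    return max(0, round(count * config.n_females / 76))


def generate_roster(config: SyntheticConfig) -> list[Individual]:
    """Deterministic roster with the default demographic mix.

    Composition mirrors a large provisioned macaque group: ~10 adolescent
    females (3.5-5 y), ~12 nulliparous, ~52 parous, ~7 lactating and ~5
    menopausal-like (>= 26 y) among 76 mature females, across 17 matrilines
    of unequal size; 49 mature males.
    """
    rng = np.random.default_rng([int(config.seed) % 2**31, 11])
    n_adol = _scaled(config.n_adolescent, config)
    n_nulli = _scaled(config.n_nulliparous_adult, config)
    n_lact = _scaled(config.n_lactating, config)
    n_meno = _scaled(config.n_menopausal, config)
    n_parous = config.n_females - n_adol - n_nulli - n_lact - n_meno
    if n_parous < 0:
        raise ValueError("status composition infeasible for n_females")

    mat_weights = np.array(
        [0.6**i for i in range(config.n_matrilines)], dtype=float
    )
    mat_weights /= mat_weights.sum()
    mat_names = [f"mat{i + 1:02d}" for i in range(config.n_matrilines)]

    individuals: list[Individual] = []
    specs = (
        [("nulliparous", 3.5, 4.5, False)] * n_adol
        + [("nulliparous", 5.0, 8.0, False)] * n_nulli
        + [("lactating", 6.0, 20.0, False)] * n_lact
        + [("menopausal_like", 26.0, 31.0, True)] * n_meno
        + [("parous", 6.0, 25.0, True)] * n_parous
    )
    for i, (status, lo, hi, maybe_sterile) in enumerate(specs, start=1):
        individuals.append(
            Individual(
                id=f"F{i:02d}",
                sex="F",
                age_years=round(float(rng.uniform(lo, hi)), 1),
                matriline=str(rng.choice(mat_names, p=mat_weights)),
                reproductive_status=status,
                sterilized=bool(maybe_sterile and rng.random() < 0.85),
            )
        )
    for i in range(1, config.n_males + 1):
        individuals.append(
            Individual(
                id=f"M{i:02d}",
                sex="M",
                age_years=round(float(rng.uniform(4.5, 25.0)), 1),
                matriline=str(rng.choice(mat_names, p=mat_weights)),
                reproductive_status="not_applicable",
            )
        )
    return individuals


# ---------------------------------------------------------------------------
# season

def _observable(config: SyntheticConfig) -> np.ndarray:
    blackout = set(config.blackout_days)
    return np.array(
        [d for d in range(1, config.season_days + 1) if d not in blackout],
        dtype=int,
    )


def _fits(start: int, length: int, config: SyntheticConfig,
          blackout: set[int]) -> bool:
    if start < 1 or start + length - 1 > config.season_days:
        return False
    return all(d not in blackout for d in range(start, start + length))


def _place_bouts(
    lengths: list[int], config: SyntheticConfig, blackout: set[int],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Place bouts (start, length) left to right with a safety margin.

    Bouts that no longer fit are shortened and, failing that, dropped.
    """
    placed: list[tuple[int, int]] = []
    cursor = 1
    for i, length in enumerate(lengths):
        needed_after = sum(lengths[i + 1:]) + _BOUT_MARGIN_DAYS * len(lengths[i + 1:])
        while length >= 1:
            latest = config.season_days - length + 1 - needed_after
            feasible = [
                st for st in range(cursor, latest + 1)
                if _fits(st, length, config, blackout)
            ]
            if feasible:
                st = int(rng.choice(feasible))
                placed.append((st, length))
                cursor = st + length - 1 + _BOUT_MARGIN_DAYS
                break
            length -= 1
    return placed


def _select_ff_pairs(
    females: list[str], config: SyntheticConfig, rng: np.random.Generator
) -> list[tuple[str, str]]:
    pool_size = min(len(females), max(2, round(config.n_ff_pairs * 35 / 26)))
    pool = list(rng.choice(females, size=pool_size, replace=False))
    pairs: list[tuple[str, str]] = []
    counts: dict[str, int] = {}
    attempts = 0
    while len(pairs) < config.n_ff_pairs and attempts < 10000:
        attempts += 1
        a, b = rng.choice(pool, size=2, replace=False)
        pair = canonical_pair(str(a), str(b))
        if pair in pairs:
            continue
        if (counts.get(pair[0], 0) >= config.max_ff_partners
                or counts.get(pair[1], 0) >= config.max_ff_partners):
            continue
        pairs.append(pair)
        counts[pair[0]] = counts.get(pair[0], 0) + 1
        counts[pair[1]] = counts.get(pair[1], 0) + 1
    if len(pairs) < config.n_ff_pairs:
        raise ValueError("could not select the requested number of FF pairs")
    return pairs


def _session_events(
    sid: str, pair: tuple[str, str], observed: float, bond: float,
    actor_share: float, config: SyntheticConfig, rng: np.random.Generator,
    truth: GroundTruth,
) -> list[FocalEvent]:
    events: list[FocalEvent] = []
    prox_end = round(float(rng.uniform(0.7, 1.0)) * observed, 1)
    events.append(FocalEvent(sid, 0.0, prox_end, "proximity_3m"))

    n_mounts = int(rng.poisson(config.mount_rate * observed
                               / PLANNED_SESSION_SECONDS))
    for t in np.sort(rng.uniform(0.0, prox_end, size=n_mounts)):
        t = round(float(t), 1)
        actor_first = rng.random() < actor_share
        actor = pair[0] if actor_first else pair[1]
        receiver = pair[1] if actor_first else pair[0]
        mods = frozenset({"pelvic_movement"}) if rng.random() < config.pelvic_prob \
            else frozenset()
        events.append(FocalEvent(sid, t, t, "mount", actor=actor,
                                 receiver=receiver, modifiers=mods))

    ibc_target = (config.ibc_base_seconds + config.coupling_ibc * bond) * float(
        np.exp(rng.normal(0.0, config.ibc_noise_sd))
    )
    ibc_target = min(ibc_target, 0.6 * prox_end)
    truth.session_intensities[sid] = {
        "bond": round(bond, 4), "ibc_target_seconds": round(ibc_target, 1),
    }
    if ibc_target >= 5.0:
        n_chunks = 1 if ibc_target < 60 or rng.random() < 0.5 else 2
        chunk_lens = [ibc_target / n_chunks] * n_chunks
        free = prox_end - ibc_target
        gaps = rng.uniform(0.0, 1.0, size=n_chunks + 1)
        gaps = gaps / gaps.sum() * free
        t = 0.0
        for j, length in enumerate(chunk_lens):
            t += float(gaps[j])
            start, end = round(t, 1), round(t + length, 1)
            if end > start:
                code = "huddle" if j % 2 == 0 else "embrace"
                events.append(FocalEvent(sid, start, end, code))
            t += length

    groom = min(float(rng.exponential(config.groom_mean_seconds)), 0.5 * prox_end)
    if groom >= 5.0:
        start = round(float(rng.uniform(0.0, prox_end - groom)), 1)
        a_grooms = rng.random() < 0.5
        events.append(
            FocalEvent(sid, start, round(start + groom, 1), "groom",
                       actor=pair[0] if a_grooms else pair[1],
                       receiver=pair[1] if a_grooms else pair[0])
        )
    events.sort(key=lambda e: (e.t_start, e.t_end))
    return events


def generate_season(
    config: SyntheticConfig, roster: list[Individual]
) -> tuple[list[ScanRecord], list[FocalSessionHeader], list[FocalEvent],
           GroundTruth]:
    """Simulate one mating season over a roster.

    Returns scan records (FF consorts plus heterosexual background), focal
    session headers and events for the FF pairs, and the ground truth.
    Bit-identical output for identical config (same seed included).
    """
    rng = np.random.default_rng([int(config.seed) % 2**31, 23])
    blackout = set(config.blackout_days)
    truth = GroundTruth()
    females = [i.id for i in roster if i.sex == "F" and i.is_mature]
    males = [i.id for i in roster if i.sex == "M" and i.is_mature]
    if len(females) < 2:
        raise ValueError("need at least two mature females")

    scans: list[ScanRecord] = []
    headers: list[FocalSessionHeader] = []
    events: list[FocalEvent] = []

    # --- female-female consorts -------------------------------------------
    pairs = _select_ff_pairs(females, config, rng)
    for p_idx, pair in enumerate(pairs):
        label = pair_label(pair)
        bond = float(rng.uniform(0.0, 1.0))
        truth.bonds[label] = round(bond, 4)
        actor_share = float(rng.beta(config.reciprocity_conc,
                                     config.reciprocity_conc))

        hazard = min(0.95, max(0.0, config.recurrence_base
                               + config.coupling_recurrence * bond))
        n_bouts = 1 + int(rng.binomial(config.max_bouts - 1, hazard))
        # bond-dependent shift plus geometric day-to-day noise
        shift = int(round(config.coupling_duration * bond))
        noise_mean = 1.0 + config.bout_base_extra_days
        lengths = [shift + int(rng.geometric(1.0 / noise_mean))
                   for _ in range(n_bouts)]

        schedule: list[dict] = []
        prev_edge = -10**6
        for start, length in _place_bouts(lengths, config, blackout, rng):
            mount_days = list(range(start, start + length))
            vd_days = []
            before, after = start - 1, start + length
            if (rng.random() < config.vd_extension_prob
                    and _fits(before, 1, config, blackout)
                    and before - prev_edge >= 5):
                vd_days.append(before)
            if (rng.random() < config.vd_extension_prob
                    and _fits(after, 1, config, blackout)):
                vd_days.append(after)
            prev_edge = max(mount_days + vd_days)
            schedule.append(
                {
                    "mount_days": [config.day_to_date(d).isoformat()
                                   for d in mount_days],
                    "vd_days": [config.day_to_date(d).isoformat()
                                for d in vd_days],
                }
            )
            for day in mount_days:
                if rng.random() >= config.detection_prob:
                    continue
                date = config.day_to_date(day)
                scans.append(
                    ScanRecord(date, pair[0], pair[1], "FF", True,
                               rng.random() < config.vd_contact_prob)
                )
                sid = f"P{p_idx:03d}D{day:03d}"
                clock_start = float(32400 + rng.uniform(0, 25200))
                pauses: tuple = ()
                observed = PLANNED_SESSION_SECONDS
                if rng.random() < config.invalid_session_frac:
                    if rng.random() < 0.5:
                        observed = float(rng.uniform(300, 890))
                    else:
                        pauses = ((clock_start + 5400.0,
                                   clock_start + 3 * 3600.0
                                   + float(rng.uniform(60, 3600))),)
                if rng.random() < 0.11:
                    schedule_split = ((pair[0], observed), (pair[1], 0.0))
                else:
                    schedule_split = ((pair[0], observed / 2),
                                      (pair[1], observed / 2))
                headers.append(
                    FocalSessionHeader(
                        session_id=sid, pair=pair, date=date,
                        clock_start=clock_start,
                        planned_seconds=PLANNED_SESSION_SECONDS,
                        observed_seconds=observed, pause_intervals=pauses,
                        focal_schedule=schedule_split,
                    )
                )
                events.extend(
                    _session_events(sid, pair, observed, bond, actor_share,
                                    config, rng, truth)
                )
            for day in vd_days:
                if rng.random() >= config.detection_prob:
                    continue
                scans.append(
                    ScanRecord(config.day_to_date(day), pair[0], pair[1],
                               "FF", False, True)
                )
        truth.bout_schedules[label] = schedule

    # --- heterosexual background ------------------------------------------
    observable = _observable(config)
    for fem in females:
        if rng.random() >= config.het_active_prob or not males:
            continue
        n_partners = min(1 + int(rng.poisson(config.het_partner_mean)),
                         min(len(males), 14))
        partners = rng.choice(males, size=n_partners, replace=False)
        for male in partners:
            pair = canonical_pair(fem, str(male))
            n_bouts_mf = 1 + int(rng.geometric(0.7)) - 1
            n_bouts_mf = min(n_bouts_mf + 1 if rng.random() < 0.2 else n_bouts_mf,
                             3)
            starts: list[int] = []
            for _ in range(n_bouts_mf):
                for _attempt in range(8):
                    cand = int(rng.choice(observable))
                    if all(abs(cand - s) >= 6 for s in starts):
                        starts.append(cand)
                        break
            for st in sorted(starts):
                length = 1 + int(rng.poisson(0.4))
                for day in range(st, st + length):
                    if day in blackout or day > config.season_days:
                        continue
                    if rng.random() >= config.detection_prob:
                        continue
                    scans.append(
                        ScanRecord(config.day_to_date(day), pair[0], pair[1],
                                   "MF", True, False)
                    )

    # collapse accidental duplicate (pair, date) rows by OR, as a reader would
    merged: dict[tuple, ScanRecord] = {}
    for rec in scans:
        key = (rec.pair, rec.date)
        if key in merged:
            prev = merged[key]
            rec = ScanRecord(
                rec.date, rec.id_a, rec.id_b, rec.pair_type,
                rec.mount_observed or prev.mount_observed,
                rec.vd_contact_observed or prev.vd_contact_observed,
            )
        merged[key] = rec
    scans = sorted(merged.values(), key=lambda r: (r.pair, r.date))
    headers.sort(key=lambda h: h.session_id)
    events.sort(key=lambda e: (e.session_id, e.t_start, e.t_end))
    return scans, headers, events, truth


def generate_corpus(config: SyntheticConfig, out_dir) -> None:
    """Write a full synthetic corpus (roster, scans, focal logs, truth)."""
    import os

    from .observations import write_focal_log, write_roster, write_scan_log

    os.makedirs(out_dir, exist_ok=True)
    roster = generate_roster(config)
    scans, headers, events, truth = generate_season(config, roster)
    write_roster(roster, os.path.join(out_dir, "roster.csv"))
    write_scan_log(scans, os.path.join(out_dir, "scans.csv"))
    write_focal_log(headers, events,
                    os.path.join(out_dir, "focal_sessions.csv"),
                    os.path.join(out_dir, "focal_events.csv"))
    truth.save(os.path.join(out_dir, "ground_truth.json"))
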