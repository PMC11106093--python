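"""Derived per-pair behavioral indices.

From a pair's focal aggregates, five indices describe the *quality* of a
consort, each normalized so that pairs followed for longer do not trivially
score higher:

* ``M``   — mounts per second of focal observation (total_mounts / TOD),
* ``PM``  — pelvic-movement rate: fraction of mounts involving rubbing,
  grinding or thrusting (undefined when no mounts occurred),
* ``MR``  — mounting reciprocity: 100 minus the absolute difference of the
  partners' percentage shares of active mounts; 100 = fully reciprocal,
  0 = fully one-sided (undefined when no mounts occurred),
* ``IBC_rate`` — fraction of focal time in intensive body contact,
* ``GR_rate``  — fraction of focal time grooming (either direction).

Undefined values propagate as NaN and are excluded pairwise downstream
(zero would mean something else: complete one-sidedness for MR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .focal import PairSummary
from .observations import ObservationError, pair_label

#: column order of the pair-metrics table (scan-level stability measures
#: first, then the focal behavioral indices)
METRIC_COLUMNS = ["pair_id", "days_observed", "RR", "PCD", "MR", "PM", "M",
                  "IBC_rate", "GR_rate"]

#: the eight variables entering the stability correlation matrix
STABILITY_VARIABLES = ["days_observed", "RR", "PCD", "MR", "PM", "M",
                       "IBC_rate", "GR_rate"]


@dataclass(frozen=True)
class PairMetrics:
    pair_id: tuple[str, str]
    M: float
    PM: float  # NaN when total mounts = 0
    MR: float  # NaN when total mounts = 0
    IBC_rate: float
    GR_rate: float
    PCD: float
    RR: int
    days_observed: int


def mounting_reciprocity(mounts_by_actor: Mapping[str, int]) -> float:
    """Mounting reciprocity MR = 100 − |%active_A − %active_B|.

    ``mounts_by_actor`` maps each partner to her active-mount count (zero
    entries may be omitted).  Returns NaN when no mounts occurred; the
    result is symmetric in partner labels and lies in [0, 100].
    """
    if len(mounts_by_actor) > 2:
        raise ObservationError(
            f"mounting reciprocity is dyadic; got {len(mounts_by_actor)} actors"
        )
    counts = list(mounts_by_actor.values())
    if any(c < 0 for c in counts):
        raise ObservationError("mount counts must be non-negative")
    total = sum(counts)
    if total == 0:
        return math.nan
    while len(counts) < 2:
        counts.append(0)
    p_a, p_b = (100.0 * c / total for c in counts)
    return 100.0 - abs(p_a - p_b)


def pelvic_movement_rate(pelvic_mounts: int, total_mounts: int) -> float:
    """PM = pelvic-movement mounts / total mounts; NaN when no mounts."""
    if pelvic_mounts < 0 or total_mounts < 0:
        raise ObservationError("mount counts must be non-negative")
    if pelvic_mounts > total_mounts:
        raise ObservationError(
            f"pelvic mounts ({pelvic_mounts}) exceed total mounts ({total_mounts})"
        )
    if total_mounts == 0:
        return math.nan
    return pelvic_mounts / total_mounts


def compute_metrics(summary: PairSummary) -> PairMetrics:
    """All indices for one pair; requires TOD > 0 (excluded upstream otherwise)."""
    if summary.TOD <= 0:
        raise ObservationError(
            f"pair {pair_label(summary.pair_id)}: TOD must be positive "
            "(pairs without valid focal time are excluded upstream)"
        )
    return PairMetrics(
        pair_id=summary.pair_id,
        M=summary.total_mounts / summary.TOD,
        PM=pelvic_movement_rate(summary.pelvic_mounts, summary.total_mounts),
        MR=mounting_reciprocity(dict(summary.mounts_by_actor)),
        IBC_rate=summary.IBC_seconds / summary.TOD,
        GR_rate=summary.GR_seconds / summary.TOD,
        PCD=summary.PCD,
        RR=summary.recurrence_rate,
        days_observed=summary.days_observed,
    )


def metrics_frame(metrics: list[PairMetrics]) -> pd.DataFrame:
    """One row per pair, columns in Table-style order (see METRIC_COLUMNS).

    Rates stay in native units: mounts per second and fractions of focal
    time; PCD in seconds.
    """
    rows = [
        {
            "pair_id": pair_label(m.pair_id),
            "days_observed": m.days_observed,
            "RR": m.RR,
            "PCD": m.PCD,
            "MR": m.MR,
            "PM": m.PM,
            "M": m.M,
            "IBC_rate": m.IBC_rate,
            "GR_rate": m.GR_rate,
        }
        for m in metrics
    ]
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
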