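"""From one focal session's event stream to the pair-level indices.

Durations are interval unions (grooming while in proximity is counted
once), mounts are counted per actor, and every index is normalized by the
pair's total observed focal time (TOD).
"""

import datetime as dt

from consortkit import (
    aggregate_pair,
    compute_metrics,
    default_catalog,
    segment_bouts,
)
from consortkit.observations import FocalEvent, FocalSessionHeader, ScanRecord

catalog = default_catalog()
pair = ("FA", "FB")
date = dt.date(2019, 10, 5)

header = FocalSessionHeader(
    session_id="S1", pair=pair, date=date, clock_start=9.5 * 3600,
    observed_seconds=1200.0, focal_schedule=(("FA", 600.0), ("FB", 600.0)),
)
events = [
    FocalEvent("S1", 0, 1000, "proximity_3m"),            # within 3 m
    FocalEvent("S1", 60, 60, "mount", actor="FA", receiver="FB",
               modifiers=frozenset({"pelvic_movement"})),
    FocalEvent("S1", 200, 200, "mount", actor="FB", receiver="FA"),
    FocalEvent("S1", 220, 220, "mount", actor="FA", receiver="FB"),
    FocalEvent("S1", 300, 540, "huddle"),                 # intensive contact
    FocalEvent("S1", 500, 620, "groom", actor="FA", receiver="FB"),
]

(bouts,) = segment_bouts([ScanRecord(date, *pair, "FF", True, False)])
summary = aggregate_pair([(header, events)], bouts, catalog)
m = compute_metrics(summary)

print(f"TOD = {summary.TOD:.0f} s, PCD = {summary.PCD:.0f} s "
      "(union of consort states, not a sum)")
print(f"mounts: {dict(summary.mounts_by_actor)}, pelvic = {summary.pelvic_mounts}")
print(f"M   = {m.M:.5f} mounts/s of focal time")
print(f"PM  = {m.PM:.3f} (pelvic-movement mounts / all mounts)")
print(f"MR  = {m.MR:.1f} (100 = fully reciprocal mounting)")
print(f"IBC = {m.IBC_rate:.4f} of focal time in full-surface body contact")
print(f"GR  = {m.GR_rate:.4f} of focal time grooming")
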