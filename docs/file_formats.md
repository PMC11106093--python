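# Input file formats

All inputs are comma-delimited UTF-8 text with a required header row.
Validation is total: a malformed row raises an error naming the file and
line, never a silent drop.

## roster.csv

One row per individual.

| column | type | notes |
|---|---|---|
| `id` | string | unique |
| `sex` | `F` / `M` | |
| `age_years` | non-negative real | females mature at ≥ 3.5 y, males at ≥ 4.5 y; females < 5 y are adolescents |
| `matriline` | string | maternal lineage label |
| `reproductive_status` | `nulliparous` / `parous` / `lactating` / `menopausal_like` / `not_applicable` | `menopausal_like` requires age ≥ 26; males are `not_applicable` |
| `sterilized` | boolean (`0/1`, `true/false`) | |

## scans.csv

One row per pair-day sighting from scan (behavioral) sampling. Duplicate
(pair, date) rows are collapsed with a logical OR of the two flags and a
logged warning; pairs are stored under the lexicographically sorted id
tuple, so `(B,A)` and `(A,B)` are the same pair.

| column | type | notes |
|---|---|---|
| `date` | ISO-8601 date | |
| `id_a`, `id_b` | roster ids | must differ; both must resolve |
| `pair_type` | `FF` / `MF` | cross-checked against roster sexes |
| `mount_observed` | boolean | at least one of the two flags must be true |
| `vd_contact_observed` | boolean | ventro-dorsal contact sitting |

## focal_sessions.csv

One row per focal session (one session per pair per day).

| column | type | notes |
|---|---|---|
| `session_id` | string | unique; referenced by events |
| `id_a`, `id_b` | roster ids | the focal pair |
| `date` | ISO-8601 date | |
| `clock_start` | `HH:MM[:SS]` | time of day; drives the 3-hour resume rule |
| `planned_seconds` | real | default 1200 |
| `observed_seconds` | real | ≤ planned; pauses excluded |
| `pauses` | `HH:MM:SS-HH:MM:SS;...` | optional; clock intervals of interrupted observation |
| `focal_a_seconds`, `focal_b_seconds` | real | per-partner observation split; must total `observed_seconds` |

## focal_events.csv

One row per timed behavioral event, in seconds from session start.

| column | type | notes |
|---|---|---|
| `session_id` | string | must have a header row |
| `t_start`, `t_end` | real seconds | `0 ≤ t_start ≤ t_end ≤ planned_seconds`; instantaneous events have `t_end = t_start`, states `t_end > t_start` |
| `behavior` | catalog code | empty only for out-of-sight intervals |
| `actor`, `receiver` | roster ids | required for directional behaviors; must be the session pair |
| `modifiers` | `;`-separated codes | e.g. `pelvic_movement` (mounts only) |
| `out_of_sight` | boolean | marks an unobserved interval; excluded from all durations |

## Ethogram YAML

`load_ethogram` accepts a mapping with:

```yaml
behaviors:
  - code: mount
    label: sexual mount (any posture)
    category: mount            # mount | intensive_body_contact | contact_sitting |
                               # grooming | other_affiliative | proximity | separation
    mode: event                # event (instantaneous) | state (has duration)
    modifiers: [pelvic_movement]
    directional: true
  # ...
consort_behavior_codes: [mount, embrace, contact_sit, huddle, groom,
                         cofeed, travel_together, mutual_follow, proximity_3m]
ibc_codes: [huddle, embrace]   # must be a subset of the consort set
proximity_radius_m: 3
```

Codes must be unique; widening `ibc_codes` beyond full-surface contact is
accepted with a warning. The built-in default (`load_ethogram("default")`)
is printed by `python -c "import consortkit, sys; consortkit.ethogram.write_ethogram(consortkit.default_catalog(), sys.stdout)"`.
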