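# Methods

`consortkit` analyzes female–female consortship stability in seasonally
breeding macaques from two complementary observation streams: a
scan-sampling log of pair-day sightings and timed 20-minute focal sessions
of consorting pairs. This note documents the models, rules and numerical
choices the package implements, and what the synthetic-season tests do and
do not establish.

## Consort definition and bout segmentation

A *consort* is a dyadic association operationally requiring at least one
observed mount (intromission is not required; female–female mounts count).
Scan sampling records each potential consort pair at most once per day,
whatever the number of sightings, so the unit of analysis is the pair-day.

**Gap rule.** A pair's sighting days form one *bout* as long as no more
than `gap_days` (default 3) unobserved days intervene between consecutive
sightings — i.e., consecutive dates at most `gap_days + 1` calendar days
apart stay together, and a silence of four or more days starts a new,
independent bout. The two resulting per-pair stability measures are the
recurrence rate `RR` (number of bouts) and `days_observed` (distinct
consort days across bouts).

**Ventro-dorsal contact extension.** A day on which the pair was seen only
sitting in ventro-dorsal contact still counts as a consort day when it
immediately precedes or follows a consort day. We implement this as an
iterative ±1-day closure seeded at mount days: a retained vd-contact day
can carry the chain one further day, and retained vd days participate in
gap bridging like any other consort day. A vd-only day not reachable by
the closure is dropped (logged). A pair whose record contains no mount day
at all is excluded: it never met the consort definition.

**Observation breaks.** The season calendar may contain a blackout block
(e.g., a 12-day holiday closure) with no observation effort. The default
behavior is literal: a blackout gap longer than the gap rule splits bouts
like any other silence. The synthetic generator never schedules bouts
across the blackout, which keeps ground-truth recovery well defined.

## Focal protocol and duration accounting

Each focal session is planned at 1200 s (10 min per partner). A session is
discarded iff

* it observed fewer than 900 s (< 75%; *exactly* 15 min is kept),
* a pause resumed more than three hours after the session's original
  start (resumption at exactly three hours is kept), or
* an earlier session already exists for the same pair-day.

Only observed time counts toward `observed_seconds`; pauses are excluded.
This is an interpretation — the protocol does not state whether pause time
is subtracted — and is flagged here as such.

**Interval unions.** All durations are measures of interval unions, never
sums of per-behavior durations. The pair consort duration `PCD` is the
union length of every interval in which at least one consort-behavior
state holds (3 m proximity, contact sitting, huddling, embracing,
grooming, cofeeding, coordinated travel). A pair grooming while in
proximity is in consort once, not twice, which guarantees `PCD ≤ TOD` and
`IBC ≤ PCD`. Mount events are instantaneous and contribute zero measure on
their own; the contact/proximity states around them carry the duration.
Separation beyond the 3 m radius is encoded as the absence of any consort
state; an explicit `separation` event, if a recorder logs one, truncates
states still open at that moment. Out-of-sight intervals are excluded from
every union.

## Pair-level indices

With `TOD` the pair's summed observed focal seconds:

* `M = total_mounts / TOD` (mounts per second of focal time),
* `PM = pelvic_mounts / total_mounts` — the fraction of mounts with
  rubbing/grinding/thrusting; undefined when no mounts occurred,
* `MR = 100 − |%active_A − %active_B|` — mounting reciprocity from the
  partners' percentage shares of active mounts; 100 is fully reciprocal,
  0 fully one-sided. The absolute difference is forced by the index's
  [0, 100] range and its two anchor cases (50/50 → 100, 100/0 → 0);
  without it, label-dependent values up to 200 would occur,
* `IBC_rate = IBC_seconds / TOD` where IBC counts only full-surface,
  mutually maintained contact (huddling, embracing). Grooming and contact
  sitting are deliberately excluded: grooming touches a limited surface
  through the groomer's hands, and contact sitting is passively
  maintained and compatible with other activities,
* `GR_rate = GR_seconds / TOD`, grooming in both directions.

Undefined `PM`/`MR` (mount-free pairs) propagate as missing values and are
excluded pairwise from correlations; zero would carry a different
behavioral meaning (for `MR`, complete one-sidedness). Rates stay in
native units (per second, fractions); output headers say so.

## Statistics

Small samples and heavy ties make rank methods the right default
throughout.

* **Spearman correlations** use average ranks for ties. Two-sided p-values
  come from the t-distribution approximation for pairwise-complete
  `n ≥ 10` and from an *exact* permutation null below that (all `n!` rank
  pairings, vectorized; no Monte-Carlo noise). Constant inputs yield a
  missing correlation with a warning. The correlation matrix uses
  pairwise-complete deletion and reports per-cell `n`.
* **Holm step-down** adjusts each analysis within its own family: the 28
  unique variable pairs of the 8-variable stability matrix, or the 6
  status pairs of a post-hoc battery. Implemented via
  `statsmodels.stats.multitest`; tests pin the hand-computed step-down and
  monotonicity.
* **Mann–Whitney U** is reported as a Z statistic from the tie-corrected
  normal approximation without continuity correction, matching the
  conventional reporting style; **Kruskal–Wallis** (tie-corrected) is the
  omnibus test for three or more groups, with Holm-adjusted pairwise
  Mann–Whitney post-hocs. On tie-free two-group data, H = Z² and the
  p-values coincide, which the tests verify.
* Group-level demography reports the mature male : female ratio to two
  decimals, per-mode activity statistics (mean ± SD, range) over females
  *active in that mode* (a mode with no active females reports empty, not
  zero), and the prevalence of female–female consorting over all analyzed
  females. The access-to-males correlations include inactive females as
  zeros, so `n` equals the analyzed female count.
* The group-level recurrence mean is reported over two denominators (all
  pairs, and only pairs with `RR ≥ 2`) because either convention is
  defensible; downstream consumers can pick.

## Synthetic season generator

The generator exists so that every pipeline stage is testable end to end
without field data, with a known ground truth. It emulates the study
design — a roster of 76 mature females and 49 mature males in 17 unequal
matrilines, a 126-day season with a 12-day blackout, one focal session per
pair per detected consort day — and plants a single latent cause: a
per-pair *bond strength* `b ~ Uniform(0, 1)`.

Generative model per female–female pair:

* bout length in days = `round(coupling_duration · b)` + geometric noise
  (mean 1.5 d). The bond enters as a shift with multiplicative-free noise;
  a plain geometric draw's variance (≈ mean²) would drown the bond signal
  at realistic pair counts,
* number of bouts = 1 + Binomial(`max_bouts − 1`, hazard), each of the
  re-consort opportunities an independent Bernoulli with hazard
  `clip(recurrence_base + coupling_recurrence · b, 0, 0.95)`. The default
  base is −0.15, so weak-bond pairs are single-bout with certainty and the
  observed 1–4 bout range is respected,
* bouts are placed left to right on non-blackout days with a ≥ 7-day
  margin, so ±1-day vd-contact extensions (probability 0.3 per bout edge)
  never merge bouts,
* per session, intensive-body-contact seconds =
  `(ibc_base + coupling_ibc · b) · exp(N(0, ibc_noise_sd))`, capped at 60%
  of the proximity span and split into one or two huddle/embrace states,
* mounts ~ Poisson(4 per 20 min), actor split from a pair-level
  Beta(2, 2) share, pelvic movement with probability 0.5 per mount;
  grooming ~ Exponential(120 s). None of these depend on `b`,
* each pair-day is detected with probability 0.95; 5% of sessions are made
  invalid (too short or late-resumed) to exercise the validation stage;
  heterosexual background consorts give every female a realistic partner
  and consort count distribution (≈ 91% active, ≈ 5 partners).

The *effect preset* (`SyntheticConfig.effect()`, the defaults) uses
`coupling_ibc = 280 s`, `coupling_duration = 6 d`,
`coupling_recurrence = 1.3`, `ibc_noise_sd = 0.2`. These values were
calibrated so that, at 26 pairs, the planted pattern — IBC rate positively
and Holm-significantly associated with days, RR and PCD, with mounting,
pelvic movement, reciprocity and grooming unassociated — is the modal
analysis outcome. The IBC magnitudes (tens to hundreds of seconds per
20-minute session) are assumptions: no per-pair duration table was
available to anchor them. The *null preset* (`SyntheticConfig.null()`)
zeroes all couplings and raises the base re-consort hazard to 0.25 so
recurrence still varies; it is the type-I-error control.

**What the generator does not emulate:** dominance rank and kinship
effects on partner choice, within-day partner switching, seasonal trends
in activity, observer-specific detection bias, spatial structure, weather,
and any hormonal mechanism. Passing tests therefore show that the pipeline
recovers the planted association structure under the stated observation
design — not that real consort data satisfy the generator's independence
assumptions.

## Numerical choices and determinism

* Dates are ISO-8601 calendar days; day arithmetic in whole days, no time
  zones. Event times are real-valued seconds from session start; the
  protocol clock (time of day) is kept separately for the resume rule.
* The canonical dyad key is the lexicographically sorted id tuple;
  direction is handled only where it matters (mount actor, groomer).
* Interval accounting is exact sweep-line arithmetic; aggregate invariants
  (`PCD ≤ TOD`, `IBC ≤ PCD`, pelvic ≤ total mounts) are enforced with a
  1e-6-second tolerance for float accumulation.
* Duplicate scan rows collapse by OR (a pair counts once per day);
  duplicate focal sessions for a pair-day keep the earliest start.
* All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; identical configurations produce byte-identical corpora
  and reports.

## Test problem sizes

The simulation-backed tests use 200 null-preset and 100 effect-preset
replicate seasons of 26 pairs for the calibration checks, 1,000 random
date sets (≤ 12 sightings) against exhaustive cut-point enumeration for
the gap rule, and 1,000 random integer-second event fixtures against
1-second discretization for the duration unions. These sizes give binomial
standard errors of ~2% on the calibration rates while keeping the full
suite around two minutes.

## Known limitations

* The exact p-value conventions of any particular statistics package
  (continuity corrections, exact vs asymptotic switches) vary; agreement
  with other software is approximate in small samples.
* The vd-contact closure is a reading of "a day preceding or following a
  consort day"; chains of vd-only days are retained through the closure,
  which is the permissive interpretation.
* Reproductive-outcome follow-up (births in the next season) and
  hormonal covariates are out of scope; the pipeline stops at the
  behavioral statistical surface.
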