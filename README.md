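# consortkit

Analysis toolkit for **consortship stability** in seasonally breeding
primates, built around female–female consort pairs in Japanese macaques
(*Macaca fuscata*). It takes raw mating-season observation logs —
scan-sampling sightings of consort pairs and timed 20-minute focal
sessions — and produces consort bouts, pair-level behavioral indices, and
the nonparametric statistics that relate behavior to pair-bond stability.
A synthetic season generator with known ground truth makes every stage
testable without field data.

Intended users: behavioral ecologists and primatologists working with
scan + focal sampling designs who want a reproducible, scriptable path
from observation CSVs to a statistical report.

## The measures

From the **scan log** (one row per pair per day), a pair's sightings are
segmented into *bouts*: runs of consort days with at most 3 intervening
unobserved days (a 4-day silence starts a new consort). Days with only
ventro-dorsal contact sitting count when adjacent to a consort day. This
yields per pair

* **RR** — recurrence rate, the number of independent bouts, and
* **days** — total distinct consort days.

From the **focal sessions** (valid iff ≥ 900 s observed, resumed within
3 h, one per pair-day), with TOD the pair's total observed seconds:

* **PCD** — pair consort duration: the *union* of all intervals in a
  consort state (≤ 3 m proximity, contact, grooming, cofeeding, travel),
* **M** = mounts / TOD,
* **PM** = pelvic-movement mounts / mounts,
* **MR** = 100 − |%active-mounts_A − %active-mounts_B| ∈ [0, 100],
* **IBC** = seconds of full-surface body contact (huddling, embracing —
  not grooming, not contact sitting) / TOD,
* **GR** = grooming seconds (both directions) / TOD.

The statistical surface is a Spearman correlation matrix over
(days, RR, PCD, MR, PM, M, IBC, GR) with Holm–Bonferroni correction,
plus Kruskal–Wallis / Mann–Whitney comparisons of consort activity across
age classes and reproductive-status groups. See `docs/methods.md` for
every rule and convention, and `docs/file_formats.md` for the CSV schemas.

## Worked example

```python
import consortkit as ck
from consortkit.synth import SyntheticConfig

cfg = SyntheticConfig.effect(seed=2)      # bond-coupled synthetic season
roster = ck.generate_roster(cfg)
scans, headers, events, _ = ck.generate_season(cfg, roster)
result = ck.analyze(roster, scans, headers, events, seed=2)

print(result.demographics["sex_ratio_m_per_f"])
for a, b in result.correlation.significant(0.05):
    print(a, b, round(result.correlation.rho.loc[a, b], 3))
```

prints

```
0.64
days_observed RR 0.909
days_observed PCD 0.973
days_observed IBC_rate 0.908
RR PCD 0.938
RR IBC_rate 0.803
PCD IBC_rate 0.896
```

The ratio is 49 mature males per 76 analyzed females. The three stability
measures (days, RR, PCD) correlate with each other by construction; the
three `IBC_rate` rows are the planted effect — pairs that huddle and
embrace more stay together longer and reunite more often — while mounting
frequency, pelvic movement, reciprocity and grooming (generated
independently of the bond) show no Holm-significant association. The
scripts in `examples/` walk through each capability
(`01_simulate_season.py`, `02_segment_bouts.py`, `03_pair_metrics.py`,
`04_full_analysis.py`); run them with `python examples/<name>.py`.

A thin CLI covers the same pipeline for shell use:

```sh
consortkit synth --seed 7 --out corpus/
consortkit run --roster corpus/roster.csv --scans corpus/scans.csv \
    --sessions corpus/focal_sessions.csv --events corpus/focal_events.csv \
    --out results/
```

`results/report.json` records input hashes, the configuration actually
used, stage counts, and all statistics.

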