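"""End-to-end analysis of a simulated effect-preset season.

Under the effect preset, a latent pair bond couples intensive body contact
(huddling/embracing) to bout duration and recurrence, while mounting and
grooming are bond-free.  The analysis should therefore flag IBC - and only
IBC - as Holm-significantly correlated with the three stability measures
(days observed, recurrence rate RR, pair consort duration PCD).
"""

import consortkit as ck
from consortkit.synth import SyntheticConfig

cfg = SyntheticConfig.effect(seed=2)
roster = ck.generate_roster(cfg)
scans, headers, events, _ = ck.generate_season(cfg, roster)
result = ck.analyze(roster, scans, headers, events, seed=2)

demo = result.demographics
print(f"{demo['n_females_analyzed']} females analyzed, "
      f"{demo['n_mature_males']} mature males "
      f"(ratio {demo['sex_ratio_m_per_f']})")
print(f"female-female consort prevalence: "
      f"{100 * demo['homosexual_prevalence']:.0f}% of mature females")
print(f"pairs with focal metrics: {len(result.pair_summaries)}")

corr = result.correlation
print("\nSpearman rho (IBC_rate row):")
row = corr.rho.loc["IBC_rate", ["days_observed", "RR", "PCD", "M", "GR_rate"]]
print(row.round(3).to_string())
print("\nHolm-significant associations (adjusted p < 0.05):")
for a, b in corr.significant(0.05):
    print(f"  {a} ~ {b}: rho = {corr.rho.loc[a, b]:+.3f}, "
          f"p_adj = {corr.p_adjusted.loc[a, b]:.4f}")
print("\nAssociations among days/RR/PCD reflect that all three measure "
      "stability; the IBC links are the planted bond effect. Mounting and "
      "grooming rows should be absent.")
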