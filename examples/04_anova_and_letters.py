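"""Factorial ANOVA and LSD letters for one cultivar x trait.

Fits the balanced three-way ANOVA (T x RH x D with all interactions) on the
replicate-level grain weight of the most susceptible preset cultivar, then
assigns compact letters across the 12 treatments plus the control using
Fisher's LSD at alpha = 0.05. Means sharing a letter are statistically
indistinguishable.
"""

from heatscreen import (
    fit_anova,
    generate_trial,
    lsd_with_control,
    six_cultivar_preset,
)

trial = generate_trial(six_cultivar_preset(), seed=42)
obs = trial.observations
sub = obs[(obs.cultivar == "CV6") & (obs.trait == "grain_weight")]

anova = fit_anova(sub)
print("ANOVA, cultivar CV6, grain weight:")
print(anova.table.round(4).to_string(index=False))

grouping = lsd_with_control(trial, "CV6", "grain_weight")
print(f"\nLSD = {grouping.lsd:.3f} (alpha {grouping.alpha}, "
      f"df {grouping.df_residual})")
for group, mean in grouping.means.items():
    print(f"  {group:>14}: {mean:6.2f} {grouping.letters[group]}")
print("\nGroups sharing a letter do not differ at p < 0.05.")
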