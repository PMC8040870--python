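"""Find the treatment that best separates tolerant from susceptible cultivars.

For every temperature x RH x duration treatment, the spread is the difference
between the best and worst cultivar's per-treatment mean MFV. The treatment
with the widest spread is the most informative single screening condition for
a breeding programme.
"""

from heatscreen import screening_discrimination
from heatscreen.datasets import load_reference_mfv

ref = load_reference_mfv()
table = screening_discrimination(
    ref[["cultivar", "temperature_c", "rh_pct", "duration_d", "mean_mfv"]]
)
print(table.round(2).to_string(index=False))

best = table[table.best].iloc[0]
print(
    f"\nRecommended screening treatment: {best.temperature_c:g} degC x "
    f"RH{best.rh_pct:g}% x {best.duration_d:g} d "
    f"(cultivar spread {best.spread:.2f} = {best.max_mfv:.2f} - "
    f"{best.min_mfv:.2f})."
)
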