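# heatscreen

Screening rice cultivars for heat tolerance during grain filling, from
factorial growth-chamber trials that cross daily maximum temperature,
relative humidity (RH) and treatment duration. Rising temperatures over land
are accompanied by falling near-surface humidity, and drier air can aggravate
heat damage to grain weight and milling quality — so tolerance screening has
to look at temperature and humidity jointly. `heatscreen` is for breeders and
crop physiologists who run such trials: it turns replicate-level trait
measurements (thousand-grain weight, head rice rate, chalkiness) into a
single tolerance index per cultivar, identifies the single most
discriminating screening treatment, and provides the supporting inference
(factorial ANOVA with LSD letters, multiple regression with backward AIC
selection).

## The tolerance index

For traits that decline under stress (grain weight, head rice rate), each
cultivar *j*'s cell mean X<sub>ijk</sub> of trait *i* in treatment *k* is
first expressed relative to the same cultivar's unstressed control CK:

    HC_ijk = X_ijk / CK_ij                       (heat-tolerance coefficient)

and min–max normalised over the pool of all cultivars and all treatments of
that trait into a membership function value on [0, 1]:

    MFV_ijk = (HC_ijk − min HC_i) / (max HC_i − min HC_i)

Chalkiness increases under stress and its control values are near zero, so
its MFV is computed on the raw cell means and inverted:

    MFV_ijk = 1 − (X_ijk − min X_i) / (max X_i − min X_i)

The three trait MFVs average into a per-treatment tolerance index, and the
twelve per-treatment indices into a per-cultivar mean MFV used for ranking.
The treatment whose per-treatment indices spread widest across cultivars
(max − min) is the recommended screening condition. The factorial ANOVA
(T × RH × D with all interactions, per cultivar × trait) and the regression

    Y = β₁X₁ + β₂X₂ + β₃X₃ + β₄X₄ + β₁₂X₁X₂ + β₁₃X₁X₃ + β₂₃X₂X₃ + β₁₂₃X₁X₂X₃ + e

(X₁ temperature, X₂ RH, X₃ duration, X₄ the cultivar's control value; terms
removed backwards by AIC under the marginality rule) quantify which factors
drive the damage.

## Worked example

The package bundles the published MFV table of a six-cultivar indica
screening trial (3 temperatures × 2 RH × 2 durations). Ranking the cultivars
(`examples/01_reference_ranking.py`):

```
 rank cultivar  mean_mfv
    1     R168      0.70
    2     IR64      0.55
    3     LY27      0.54
    4      LY6      0.50
    5    ZLY47      0.45
    6    16343      0.44

R168 is the most heat-tolerant cultivar (mean MFV 0.70 across the 12 treatments).
```

R168 retained on average 70 % of the pooled tolerance scale across all
stress combinations; 16343 lost the most. Selecting the screening treatment
(`examples/02_screening_treatment.py`):

```
Recommended screening treatment: 35 degC x RH75% x 15 d (cultivar spread 0.51 = 0.70 - 0.19)
```

At 35 °C the drying penalty is strongest (at 37 °C heat dominates
regardless of humidity), so a long, dry, moderately hot treatment separates
tolerant from susceptible material best.

The remaining examples simulate a trial from the bundled response-surface
generator and run scoring, ANOVA + LSD letters and regression end to end:

```bash
python examples/03_simulate_and_score.py
python examples/04_anova_and_letters.py
python examples/05_regression_selection.py
```

or, from the shell:

```bash
heatscreen run --out results/demo --seed 7
```

## Layout

- `src/heatscreen/` — library: `trial` (tidy-CSV I/O and validation),
  `simulate` (factorial trial generator), `scoring` (HC/MFV, ranking,
  discrimination, RH contrasts), `anova` (balanced three-way ANOVA, LSD
  letters), `regression` (OLS + backward AIC), `pipeline`, `cli`,
  `datasets` (the published MFV table).
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
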