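# Methods

## Scope and data model

`heatscreen` analyses balanced factorial heat-stress trials on rice during
grain filling: a panel of cultivars, a full cross of daily maximum
temperature × relative humidity × duration, an unstressed natural-condition
control per cultivar, and three quality traits measured per replicate —
thousand-grain weight (g), head rice rate (%) and chalkiness (%). The
canonical interchange format is a long (tidy) CSV with one row per replicate
observation; a schema-mapping layer on the reader absorbs files with
different column names, so wide per-trait exports can be ingested after a
one-off melt. The control is an explicit boolean column, not a sentinel
factor level, because the control is ambient growth with no defined
temperature/RH/duration.

## Membership-function scoring

Scoring operates on cell means (replicates averaged first): the tolerance
tables this reproduces carry one value per cultivar × treatment, and only
aggregation yields that shape; replicate-level values feed the ANOVA, where
the residual degrees of freedom require them.

For declining traits the heat-tolerance coefficient HC = X/CK is min–max
normalised over the pool of all cultivars × all non-control treatments of
the trait. Chalkiness rises under stress and has near-zero control values, so
its score is the inverted min–max of the raw cell means. The min–max pool
excludes control cells by default: the control is the reference the
coefficients are built from, not a treatment, and including it (HC ≡ 1)
merely compresses the scale. A `pool_includes_control` switch provides the
alternative. Pools span both durations; restricting them per duration is
possible by filtering the input but is not the default, since the
normalisation is defined over "all treatments". A pool with zero range is an
error (`DegeneratePoolError`), not a silent 0/0.

Trait MFVs average (unweighted) into a per-treatment index, and per-treatment
indices into a per-cultivar mean MFV, all at full precision; rounding to two
decimals happens only at presentation. Ranking sorts descending with ties
broken by cultivar identifier. Screening discrimination is the per-treatment
max − min of the per-treatment indices across cultivars; ties report all
argmax treatments. The RH contrast pairs each cultivar's cell means at the
two humidity levels within every temperature × duration combination and
summarises the paired differences by median and quartiles.

## Synthetic trial generator

The generator emulates the screening design so every stage is testable
without measured data. Its response surface is the simplest one that
reproduces the qualitative structure screening trials report — damage
increasing with temperature and duration, aggravated by dry air most
strongly at 35 °C and negligibly at 37 °C:

    S(T, RH, D) = s_T(T) · (1 + w(T) · (RH_ref − RH)/RH_ref) · (D/D_ref),

clipped to [0, 1], with RH_ref = 85 %, D_ref = 15 d. Declining traits respond
as baseline · (1 − (1 − τ) · S); chalkiness as baseline + (1 − τ) · C_max · S,
where τ ∈ [0, 1] is the cultivar's tolerance (1 = unaffected). Replicates add
independent Gaussian noise truncated at the trait's domain bounds (0, and 100
for percentages) — traits are bounded and replicate scatter in chamber trials
is small relative to the mean, so the truncation bias is negligible.

Defaults (chosen once as realistic chamber-trial values; no effect-size
estimates exist to calibrate against, so they are qualitative):

| parameter | default | rationale |
|---|---|---|
| temperature severity s_T | 0.35 / 0.55 / 0.80 at 33/35/37 °C | monotone, strong damage at 37 °C |
| RH weight w(T) | 0.6 / 1.0 / 0.15 | dry-air penalty peaked at 35 °C, negligible at 37 °C |
| noise sd | 0.35 g (GW), 1.5 % (HR), 1.2 % (CH) | typical n = 3 error-bar magnitudes for these traits |
| C_max | 40 % | chalkiness a fully susceptible cultivar can gain at full stress |
| preset τ | 0.9; 0.6, 0.5, 0.4, 0.3, 0.2 | one strongly tolerant cultivar, the rest spread |
| baselines | GW 23–28 g, HR 55–68 %, CH 2.5–6 % | typical mid-season indica values |

Seeding: one independent `numpy` `SeedSequence([master, cultivar, treatment,
trait])` stream per cell, so results are reproducible and independent of
generation order.

What the generator does **not** emulate: diurnal temperature trajectories
(only the daily-maximum summary enters), trait correlations within a
replicate plant, heteroscedastic or non-Gaussian replicate error, and any
physiological mechanism. Tests passing on synthetic trials therefore
demonstrate the correctness of the statistical machinery and the
recoverability of a known tolerance ordering under this surface — not that
the surface is a faithful model of rice physiology.

## Factorial ANOVA and LSD letters

The three-way fixed-effects decomposition is computed from marginal means of
the balanced data cube; on balanced designs this equals the least-squares
(sum-to-zero effect coding) decomposition and all "types" of sums of squares
coincide, which the test suite verifies against an independent
nested-regression oracle and against `statsmodels.anova_lm`. Unbalanced data
are refused with a list of offending cells — there is deliberately no Type
II/III machinery. Zero residual variance is reported as F = +inf with a flag
rather than an exception. The control is excluded from the factorial (it has
no factor levels).

Mean separation uses Fisher's LSD, t(1 − α/2, df) · √(2·MS_res/n), with
compact letters from the insert-and-absorb algorithm; the resulting letter
classes are the maximal cliques of the non-significance graph (verified
against a `networkx` clique enumeration). When the control is displayed
alongside the twelve treatments (the default, matching how such trials are
plotted), MS_res comes from a one-way ANOVA on the thirteen groups; a flag
excludes the control.

## Regression and backward AIC selection

The design has one row per cultivar × treatment × replicate by default
(n = 216 for the preset shape), or per cell mean (n = 72) via
`granularity="cell_means"` — the treatment-level formulation does not resolve
which was intended, so both are provided. Interaction regressors are raw
products of the factor values. X₄, the cultivar's control mean of the
response trait, absorbs varietal baselines and is never dropped.

OLS estimation is delegated to `statsmodels`; AIC is recomputed as
n·ln(RSS/n) + 2(p + 1) with p the number of mean parameters including the
intercept (+1 for the profiled error variance). Only AIC differences matter
for selection; the convention is fixed so elimination traces are
reproducible. Backward selection greedily removes the single term whose
removal most lowers AIC, restricted to terms not contained in any retained
interaction (marginality) and not forced; it stops at the first local
minimum. Greedy backward search is path-dependent and is not guaranteed to
find the global AIC optimum on adversarial inputs; the oracle tests verify it
against exhaustive marginality-respecting subset search on instances with
well-separated signal, where the optimum is unambiguous.

## Numerical choices and problem sizes

- Internal aggregation at full double precision; two-decimal rounding only in
  report tables and the Markdown summary.
- ANOVA oracle equivalence is asserted to 1e-8 (absolute, scaled by the
  largest SS); SS additivity to 1e-10 relative.
- Null calibration of the ANOVA F tests uses 1,000 simulated null trials and
  requires each term's rejection rate at α = 0.05 to lie in [0.03, 0.07]
  (±3 binomial standard deviations).
- Ranking recovery uses 50 simulated trials; exhaustive-selection
  equivalence 50 instances; letter-display equivalence 200 instances with up
  to 6 groups. These sizes give stable verdicts in seconds while keeping the
  default suite fast.
- Greedy elimination treats an AIC decrease below 1e-10 as no improvement to
  avoid cycling on ties.

## Known limitations

- Balanced designs only; missing cells stop the ANOVA rather than being
  imputed.
- No alternative tolerance indices (stress susceptibility index, geometric
  mean productivity) and no Tukey/Bonferroni post-hoc alternatives.
- The LSD controls the per-comparison, not the family-wise, error rate —
  standard for this screening literature, but letters should be read
  accordingly.
- The bundled published MFV table carries two-decimal rounding; aggregation
  reproduces its printed means within ±0.011, the bound implied by that
  rounding.
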