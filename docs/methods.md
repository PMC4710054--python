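# Methods

This note records the model's assumptions, the defaults that matter, the
numerical choices made where the design was genuinely open, and what the
synthetic data generator does and does not emulate.

## Population and classification

Individuals carry a sample weight, mean weekly consumption and peak
single-day consumption in UK units (1 unit = 8 g ethanol), and shares of
their weekly ethanol over 16 beverage categories. Classification
thresholds are held in grams and applied after unit conversion, so
classification in either currency agrees identically.

Boundary conventions. The guideline boundary (168 g-week men, 112 women)
is itself moderate; the harmful boundary (400/280 g-week) is itself
hazardous — the verbal definitions ("less than" / "more than") leave
equality unassigned, and we close the hazardous band at the top. Binge
status is strict: peak-day intake must exceed 64/48 g. Abstainers are
moderate drinkers with a retained zero-consumption flag (they never
acquire transactions or demand responses). The 11–15 band uses the same
binge thresholds as adults; nothing in the source evidence fixes a
different convention, so this is flagged as a choice.

## Pricing

Policies edit transaction prices only; volumes and weights never change at
this stage. Minimum unit prices floor both sold and usual prices (a legal
floor binds the shelf price as well as promotions). Discount restrictions
raise the sold price to at least usual × (1 − maximum discount fraction).
Policies compose by sequential application in file order, which matters:
a floor followed by a percent rise is not the reverse.

The mean price change per category is weighted by sample weight × ethanol
units — a per-unit-of-ethanol average, matching the model's currency. The
low/high price split within each beverage type has no canonical
definition; the generator simply parameterises the two tiers separately,
and any empirical split point is a configuration concern.

## Demand

The price-to-consumption link is first order in percent space,
Δc = E Δp, with separate 16×16 elasticity matrices for moderate and
hazardous+harmful drinkers (the two segments for which such systems can
be estimated stably). A constant-elasticity multiplicative variant
(Π(1 + Δpⱼ/100)^Eᵢⱼ) is available behind a flag for sensitivity work; it
coincides with the linear form to first order.

Segment-level percent changes apply uniformly to every individual in the
segment; an individual's demand segment is fixed at its **baseline**
drinking level even if the policy moves it across a threshold, because
elasticities were estimated on baseline behaviour. Category-level
consumption factors are floored at zero.

Peak-day consumption updates through linear peak-from-mean models per
sex × age × drinker level: peak′ = max(0, peak + slope·Δmean). Only the
slope enters, so each individual's residual around the fitted line is
preserved. The two-part (probability and scale) formulation of binge
response is simplified to the scale component.

Elasticity uncertainty propagates by multivariate-normal draws of the
flattened coefficient vector through a lower-triangular factor of the
covariance (Cholesky, with a symmetric eigendecomposition fallback for
exactly singular covariances).

## Risk functions, AAF and PIF

The attributable fraction uses the excess-over-total form
AAF = Σw(RR−1)/ΣwRR. Verbal definitions of "implied AAF" are ambiguous;
this form is adopted because it makes the zero-consumption-counterfactual
identity PIF = AAF hold exactly for any population and risk function,
which is the cross-check the calibrations are validated against.

Two-part slope calibration has a closed form: with excess mass
E = Σw·max(0, c−T) and total weight W, the implied AAF is sE/(W+sE),
strictly increasing in s, so s = AAF·W/((1−AAF)·E). The same inversion
fits absolute-risk slopes to observed incident volumes for wholly
attributable harms (for which risk below threshold is zero by
definition, and the PIF reduces to a ratio of excess masses, slope
cancelling). Calibrations with no consumption mass above threshold and a
positive target are reported as infeasible, never silently zeroed.

Default thresholds: acute 4/3 units peak-day (men/women); chronic wholly
attributable 3/2 units per day, converted ×7 to the mean-weekly basis
(the per-day statement on a weekly basis implies this conversion but does
not spell it out). Chronic partially-attributable conditions use
tabulated RR-vs-units curves with monotone linear interpolation, held
flat beyond the tabulated range; the shipped curves are synthetic
stand-ins with the right shape, not transcriptions of published
meta-analyses. Relative-risk curves are assumed equal across age groups
while absolute baseline rates differ by age/sex.

## Projection

Each subgroup is an age cohort starting at its band midpoint, projected
ten years. Future B (do nothing) holds consumption and rates at baseline
— steady state; a trend hook exists but defaults off. Future A scales
each condition's baseline mortality and admission rates by
(1 − lag(t)·PIF), with lag(t) = min(t/10, 1) for chronic conditions and
lag ≡ 1 for acute ones.

Competing mortality within a year is additive across alcohol conditions
plus life-table other-cause mortality (all-cause minus the alcohol
conditions' baseline share, to avoid double counting), capped at 1.
QALYs from an averted death are the remaining utility-weighted life
expectancy, discounted (3.5 %) from the year of death and spread over
remaining life rather than accrued at once. Morbidity uses person-specific
hospitalisations as the prevalence proxy, with per-case-year utility
decrements and treatment costs. Discounting is end of year: a year-1
value is divided by (1+r) once. Costs discount at 1.5 %.

With the 10-year linear lag and constant rates, the cumulative chronic
effect over the horizon is exactly (1+2+…+10)/100 = 5.5/10 of the no-lag
effect — a closed-form identity the tests verify against the year-by-year
computation.

## Crime and workplace

Crime rides on peak-day consumption. Two-part RR functions are fitted per
sex for offender age groups under-16 and 16–25; over-25s reuse the 16–25
fits (an evidence limitation carried over deliberately). Reported volumes
are multiplied by an under-reporting factor before the PIF applies
(multiplier and PIF commute; the order is fixed for clarity). Category
changes are apportioned to subgroups by offender-distribution weights
that split 16–17 and 18–24 equally and decline linearly from 35 up;
apportionment conserves category totals exactly. The mapping from broad
offence categories to the 20 crime classifications is configuration with
a uniform-within-group default.

Absence also rides on peak-day consumption per sex/age cell, calibrated
to per-sex causal attributable fractions; the evidence states no
threshold, so the acute-harm thresholds (4/3 units) are adopted and
flagged. Changes scale baseline absence days by the PIF and by work
participation; non-working-age bands contribute zero.

Unemployment applies only to harmful drinkers, with no lag, on the mean
basis with thresholds 7.1/5 units per day (×7 weekly — essentially the
harmful cut-offs). A single slope shared across sexes is calibrated so the
implied work-probability reduction (excess over total, the same AAF form)
for working-age harmful drinkers equals 6.9 %, with female weights
adjusted by participation rates. Changes scale observed baseline
unemployment by the PIF and are valued at age/sex average salaries;
"lost output due to early death" is excluded to avoid double counting
life-years already valued in the health and crime channels.

## Valuation

VAT is computed on the VAT-inclusive retail price, sales × r/(1+r) with
r = 0.175 — the rate is given, the base is standard UK practice and
config-overridable. Duty is per unit of ethanol by beverage type.
Retailer income is the remainder, so the decomposition re-sums exactly.
Health QALYs are valued at £50,000 and crime-victim QALYs at £81,000, at
the 2006 price level with no inflation adjustment. Policy implementation
costs are excluded. All reporting uses signed changes (policy minus
do-nothing); negative money figures are savings.

## Synthetic data

The generator emulates the *structure* the model needs, not any real
population: right-skewed (log-normal) mean consumption per sex/age cell
(medians 8/4 units-week for men/women, log-scale 1.1, age factors from
0.25 at 11–15 to 1.3 at 18–24); cell-specific abstention (12–60 %);
weights log-normal with unit mean; Dirichlet beverage mixes around
sex-specific preferences; log-normal pence-per-unit prices (medians 32/58
off-trade low/high, 85/135 on-trade) with discounting on 30 % of
off-trade and 10 % of on-trade purchases at Beta(2,6)-distributed depth.
One synthetic week of transactions stands in for a 14-day purchase diary,
with weekly units as the common currency, and per-person ethanol volume
conserved exactly across categories.

The price-distribution calibration maps sold prices through a monotone
piecewise-linear function anchored at the weighted empirical quantiles of
ten target cumulative shares; below the first anchor the first segment's
slope extends (clipped positive), above the last (share 1) prices keep
their offset. Prices are never reordered, and an affine target
distribution is reproduced exactly. With a discrete weighted sample the
achieved CDF matches targets to the interpolation resolution of the
sample, not to machine precision.

What the generator does **not** emulate: survey re-weighting to
population totals, under-reporting of survey consumption, purchase-diary
imputation, seasonal or regional structure, and any empirical
distributional fidelity to England. Passing tests therefore demonstrate
the correctness and self-consistency of the mechanics — calibration
round-trips, conservation and accounting identities, ordering of policy
effects — not predictive accuracy for any real population. The condition
catalogue is 8 synthetic conditions spanning the four harm classes
(chronic/acute × wholly/partially attributable) rather than a full
47-condition table, and the default baseline uses n = 20,000 individuals
at 1,000 persons per unit weight, sizes at which the full 18-policy
comparison completes in well under a minute.

## Known limitations

- Elasticity matrices are inputs; their econometric estimation is out of
  scope.
- No market/supply-side response to price policies; no consumer-surplus
  or supply-chain economics.
- Joint mean-and-peak risk functions are not modelled; protective
  (J-shaped) effects enter only through supplied curves and can be
  toggled off by supplying curves without the protective dip.
- Harms to others (partners, children) and benefit-payment transfers are
  excluded.
- Age-cohort projection assumes within-band drinking distributions are
  stable over time; no birth-cohort dynamics.
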