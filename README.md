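# alcopol

Appraisal of alcohol pricing, promotion and availability policies on
weighted survey microdata: from a declarative policy specification, through
price and elasticity-driven consumption change, to lagged projections of
health, crime and workplace harm and their monetary valuation.

The package is aimed at health-economic and public-health modellers who
want a tested, scriptable implementation of the individual-level
policy-to-harm chain used in national alcohol policy appraisal: minimum
unit prices, general and targeted price rises, discount restrictions, and
relative-change what-ifs for advertising and availability.

## The model

**Population.** A weighted cross-sectional sample of individuals (survey
microdata) with mean weekly consumption and peak single-day consumption in
UK units (1 unit = 8 g ethanol), partitioned into 54 subgroups: 2 sexes ×
9 age bands × 3 drinking levels (moderate ≤ 168/112 g-week for men/women,
harmful > 400/280 g-week, hazardous in between).

**Policy to consumption.** A purchase-level transaction table (16 beverage
categories: beer/wine/spirit/RTD × on/off-trade × low/high price, with
sold and usual pence-per-unit prices) is transformed by the policy; the
vector of 16 volume-weighted mean percent price changes Δp feeds segment
specific 16×16 elasticity matrices E, giving category consumption changes
Δc = E Δp. Those scale each individual's beverage mix; the peak-day
distribution follows through linear peak-from-mean ("binge") models that
preserve each individual's residual.

**Consumption to harm.** Each harm carries a relative-risk function on the
mean-weekly or peak-day basis. Where no published curve exists, a two-part
linear form (RR = 1 up to a threshold T, then 1 + s·(c − T)) is calibrated
so the implied alcohol-attributable fraction

    AAF = Σᵢ wᵢ(RRᵢ − 1) / Σᵢ wᵢ RRᵢ

matches an observed target. A policy scales each baseline harm rate by
(1 − PIF) with the potential impact fraction

    PIF = 1 − Σᵢ wᵢ RR′ᵢ / Σᵢ wᵢ RRᵢ,

which reduces exactly to the AAF under a zero-consumption counterfactual —
the identity all the calibrations rely on. Chronic harms phase in linearly
over 10 years; acute harms, crime, absence and unemployment act
immediately.

**Projection and valuation.** Each subgroup is an age cohort projected 10
years under the policy (Future A) and do-nothing (Future B) scenarios;
deaths and hospitalisations averted are valued through a utility-weighted
life table. QALYs are valued at £50,000 (health) and £81,000 (crime
victim), discounted at 3.5 %; costs at 1.5 %. Sales decompose into
retailer income, duty and VAT (17.5 % of the VAT-inclusive price).

Because the original survey and market-research inputs are confidential,
the `synthetic_data` module generates seeded statistical stand-ins with
the structure the model assumes; all headline numbers below are therefore
properties of the synthetic baseline, not of any real population.

## Worked example

```python
import alcopol

inputs = alcopol.build_inputs(n=20_000, seed=1)       # synthetic baseline
steps = alcopol.POLICY_LIBRARY["minimum_price_50p"]   # 50p/unit floor
result = alcopol.run_policy("minimum_price_50p", steps, inputs)
for key, value in result.row.items():
    print(key, value)
```

prints (seed 1, n = 20,000, ~20 M persons at the default weight scale):

```
consumption_change_pct   -9.18
spending_change_pct       2.85
retailer_revenue_change   2.565e+08
duty_vat_change          -7.673e+07
deaths_averted            1416
health_qalys              2.074e+04
crime_qalys               6852
health_value             -1.089e+09
crime_value              -2.462e+09
workplace_value          -1.723e+09
total_value              -5.273e+09
horizon                   10
```

Read: a 50p minimum unit price cuts mean consumption 9.2 % while consumer
spending rises 2.9 % (cheap alcohol gets dearer faster than volumes fall);
over 10 years roughly 1,400 deaths are averted and about 20,700 health
QALYs gained; negative `*_value` figures are discounted monetary savings
(harm reductions), about £5.3 bn in total across the three channels.

The same appraisal is available from the shell:

```bash
alcopol compare --n 20000 --seed 1 --out comparison.csv   # all 18 policies
alcopol simulate --policy minimum_price_50p --out results/
alcopol generate --out fixtures/                          # synthetic CSVs
alcopol calibrate                                         # fitted slopes
```

## Layout

- `population` — microdata types, subgroup classification, CSV I/O
- `synthetic_data` — seeded generators and the price-distribution calibration
- `pricing` — policy specs, price transforms, the 18-policy library
- `demand` — elasticity application, peak updates, uncertainty sampling
- `risk` — RR curves, AAF/PIF, two-part slope calibration
- `projection` — lag model, life table, Future A/B cohort projection
- `crime_workplace` — crime, absence and unemployment channels
- `valuation` — spending, retailer/duty/VAT split, cost–benefit summary
- `simulate` — end-to-end orchestration; `cli` — the `alcopol` command

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
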