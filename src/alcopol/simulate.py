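"""End-to-end policy appraisal: wire the modules into one pipeline.

``build_inputs`` assembles a seeded synthetic baseline (population,
transactions, calibrated risk functions, life table, crime/workplace/
valuation configuration).  ``run_policy`` takes a policy (a sequence of
steps) through the full chain — price transform, elasticity demand
response, peak revision, per-subgroup potential impact fractions, the
10-year Future A vs Future B cohort projection, crime/workplace channels
and monetary valuation — and returns one summary row plus channel detail.
``run_policies`` maps a policy library to the comparison table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import crime_workplace as cw
from .demand import (BingeModel, ElasticityMatrix, apply_consumption_changes,
                     consumption_change_vector, update_peak)
from .population import (AGE_BANDS, AGE_BAND_MIDPOINT, BEVERAGE_CATEGORIES,
                         SEXES, SubgroupKey, classify_individuals)
from .pricing import (PolicySpec, SEGMENTS, apply_policy,
                      mean_price_change_vector)
from .projection import (COST_DISCOUNT_RATE, ConditionSpec, LagModel,
                         LifeTable, QALY_DISCOUNT_RATE, discount_stream,
                         project_cohort)
from .risk import (ConsumptionState, InfeasibleCalibration, RiskFunction,
                   chronic_wholly_threshold_weekly, fit_two_part_slope,
                   ACUTE_THRESHOLD_UNITS_DAY)
from .synthetic_data import (ConditionConfig, PopulationConfig, PriceConfig,
                             default_crime_categories,
                             default_elasticity_matrices, default_life_table,
                             default_offender_apportionment,
                             default_workplace_params,
                             default_condition_configs, generate_baseline_harms,
                             generate_population, generate_transactions)
from .valuation import (ValuationParams, build_policy_comparison,
                        revenue_decomposition, sales_by_category)

logger = logging.getLogger("alcopol")

WORKING_DAYS_PER_YEAR = 225.0


@dataclass
class ModelInputs:
    """Everything a policy run needs, built once per baseline."""

    individuals: pd.DataFrame            # classified microdata
    transactions: pd.DataFrame
    segment_assignment: pd.Series        # person_id -> demand segment
    elasticities: Mapping[str, ElasticityMatrix]
    binge_model: BingeModel
    harm_table: pd.DataFrame
    condition_configs: Sequence[ConditionConfig]
    risk_functions: Mapping[tuple[str, str, str], RiskFunction]
    life_table: LifeTable
    crime_categories: Sequence[cw.CrimeCategory]
    crime_functions: Mapping
    apportionment: pd.DataFrame
    workplace: cw.WorkplaceParams
    absence_functions: Mapping
    unemployment_function: cw.UnemploymentFunction
    valuation: ValuationParams
    lag_model: LagModel = LagModel()
    population_scale: float = 1000.0     # persons per unit sample weight
    horizon: int = 10


def assign_segments(individuals: pd.DataFrame) -> pd.Series:
    """Demand segment per person from the baseline drinker level:
    moderate, or hazardous_harmful for everyone above the guideline."""
    seg = np.where(individuals["drinker_level"] == "moderate",
                   "moderate", "hazardous_harmful")
    return pd.Series(seg, index=individuals["person_id"].to_numpy())


def build_risk_functions(individuals: pd.DataFrame,
                         harm_table: pd.DataFrame,
                         condition_configs: Sequence[ConditionConfig],
                         ) -> dict[tuple[str, str, str], RiskFunction]:
    """Baseline-calibrated risk function per (condition, sex, age band).

    Acute partially-attributable conditions fit the two-part slope to the
    cell's AAF on the baseline peak distribution; chronic partials carry
    their tabulated curve; wholly-attributable conditions carry only their
    threshold (the PIF for them is the excess-consumption ratio, slope
    cancelling).
    """
    cell_groups = dict(iter(individuals.groupby(["sex", "age_band"])))
    functions: dict[tuple[str, str, str], RiskFunction] = {}
    table = harm_table.set_index(["condition_id", "sex", "age_band"])
    for cond in condition_configs:
        for sex in SEXES:
            for band in AGE_BANDS:
                key = (cond.condition_id, sex, band)
                if cond.attribution == "wholly":
                    threshold = (
                        chronic_wholly_threshold_weekly(sex)
                        if cond.timing == "chronic"
                        else ACUTE_THRESHOLD_UNITS_DAY[sex])
                    functions[key] = RiskFunction(
                        condition_id=cond.condition_id, basis=cond.basis,
                        attribution="wholly", timing=cond.timing,
                        threshold=threshold, slope=1.0, sex=sex)
                elif cond.curve is not None:
                    functions[key] = RiskFunction(
                        condition_id=cond.condition_id, basis=cond.basis,
                        attribution="partially", timing=cond.timing,
                        form="published_curve", curve_x=cond.curve[0],
                        curve_rr=cond.curve[1], sex=sex)
                else:
                    cell = cell_groups.get((sex, band))
                    aaf = float(table.loc[key, "aaf"])
                    threshold = ACUTE_THRESHOLD_UNITS_DAY[sex] \
                        if cond.basis == "peak_day" else \
                        chronic_wholly_threshold_weekly(sex)
                    if cell is None or len(cell) == 0:
                        continue
                    values = cell["peak_day_units"] \
                        if cond.basis == "peak_day" \
                        else cell["mean_weekly_units"]
                    state = ConsumptionState(
                        values.to_numpy(float),
                        cell["weight"].to_numpy(float))
                    try:
                        slope = fit_two_part_slope(state, threshold, aaf)
                    except InfeasibleCalibration:
                        logger.warning(
                            "cannot calibrate %s for (%s, %s); dropping",
                            cond.condition_id, sex, band)
                        continue
                    functions[key] = RiskFunction(
                        condition_id=cond.condition_id, basis=cond.basis,
                        attribution="partially", timing=cond.timing,
                        threshold=threshold, slope=slope, sex=sex)
    return functions


def pif_for_condition(rf: RiskFunction, before: ConsumptionState,
                      after: ConsumptionState) -> float:
    """PIF dispatch: relative-risk ratio for partial conditions, excess
    absolute-risk ratio for wholly-attributable ones (zero risk below
    threshold, slope cancels)."""
    if rf.attribution == "wholly":
        excess_before = float(np.sum(
            before.weights * np.maximum(0.0, before.values - rf.threshold)))
        if excess_before <= 0.0:
            return 0.0
        excess_after = float(np.sum(
            after.weights * np.maximum(0.0, after.values - rf.threshold)))
        return 1.0 - excess_after / excess_before
    from .risk import potential_impact_fraction
    return potential_impact_fraction(rf, before, after)


def build_inputs(n: int = 20_000, seed: int = 1,
                 population_scale: float = 1000.0,
                 horizon: int = 10) -> ModelInputs:
    """Assemble the synthetic baseline and calibrate everything that only
    depends on it.  All randomness derives from ``seed``."""
    pop_config = PopulationConfig(n=n, seed=seed)
    individuals = classify_individuals(generate_population(pop_config))
    price_config = PriceConfig(seed=seed + 1)
    transactions = generate_transactions(individuals, price_config)
    segment = assign_segments(individuals)
    condition_configs = default_condition_configs()
    harm_table = generate_baseline_harms(condition_configs)
    risk_functions = build_risk_functions(
        individuals, harm_table, condition_configs)
    crime_categories = default_crime_categories()
    crime_functions = cw.fit_crime_functions(individuals, crime_categories)
    workplace = default_workplace_params()
    absence_functions = cw.fit_absence_functions(
        individuals, workplace.absence_aaf)
    unemployment_function = cw.calibrate_unemployment(individuals, workplace)
    return ModelInputs(
        individuals=individuals,
        transactions=transactions,
        segment_assignment=segment,
        elasticities=default_elasticity_matrices(),
        binge_model=pop_config.binge_model(),
        harm_table=harm_table,
        condition_configs=condition_configs,
        risk_functions=risk_functions,
        life_table=default_life_table(),
        crime_categories=crime_categories,
        crime_functions=crime_functions,
        apportionment=default_offender_apportionment(crime_categories),
        workplace=workplace,
        absence_functions=absence_functions,
        unemployment_function=unemployment_function,
        valuation=ValuationParams(),
        population_scale=population_scale,
        horizon=horizon,
    )


@dataclass
class PolicyResult:
    """Comparison row plus full channel detail for one policy."""

    name: str
    row: dict
    individuals_after: pd.DataFrame
    transactions_after: pd.DataFrame
    health_by_subgroup: pd.DataFrame
    crime_by_category: pd.DataFrame
    workplace_detail: dict


def _demand_adjusted_transactions(transactions: pd.DataFrame,
                                  segment: pd.Series,
                                  changes_by_segment: Mapping[str, np.ndarray],
                                  relative_factor: float) -> pd.DataFrame:
    """Scale transaction volumes by the category consumption changes of
    each purchaser's segment (and any uniform relative change)."""
    out = transactions.copy()
    cat_index = pd.Index(BEVERAGE_CATEGORIES)
    cat_pos = cat_index.get_indexer(out["category"])
    seg = out["person_id"].map(segment).to_numpy()
    factors = np.full(len(out), relative_factor)
    for segment_name, dc in changes_by_segment.items():
        mask = seg == segment_name
        factors[mask] *= np.maximum(0.0, 1.0 + np.asarray(dc)[cat_pos[mask]]
                                    / 100.0)
    out["units"] = out["units"].to_numpy(float) * factors
    return out


def run_policy(name: str, steps: Sequence[PolicySpec],
               inputs: ModelInputs) -> PolicyResult:
    """Appraise one policy end to end against the do-nothing future."""
    logger.info("run_policy: %s with %d step(s) [%s]", name, len(steps),
                ", ".join(s.kind for s in steps))
    price_steps = [s for s in steps
                   if s.kind != "relative_consumption_change"]
    relative_steps = [s for s in steps
                      if s.kind == "relative_consumption_change"]

    # --- price transform and demand response -----------------------------
    txns_before = inputs.transactions
    txns_after = apply_policy(txns_before, price_steps)
    if price_steps:
        pcv = mean_price_change_vector(
            txns_before, txns_after, inputs.segment_assignment)
        changes = {
            seg: consumption_change_vector(
                pcv[seg].to_numpy(), inputs.elasticities[seg])
            for seg in SEGMENTS
        }
    else:
        changes = {seg: np.zeros(len(BEVERAGE_CATEGORIES))
                   for seg in SEGMENTS}
    relative_factor = 1.0
    for step in relative_steps:
        relative_factor *= 1.0 + step.percent / 100.0

    before = inputs.individuals
    after = apply_consumption_changes(
        before, changes, inputs.segment_assignment)
    if relative_factor != 1.0:
        after = after.copy()
        after["mean_weekly_units"] *= relative_factor
    after = update_peak(
        after, before["mean_weekly_units"].to_numpy(float),
        after["mean_weekly_units"].to_numpy(float), inputs.binge_model)

    # --- consumption and purchasing aggregates ---------------------------
    w = before["weight"].to_numpy(float)
    total_before = float(np.sum(w * before["mean_weekly_units"]))
    total_after = float(np.sum(w * after["mean_weekly_units"]))
    consumption_change_pct = 100.0 * (total_after / total_before - 1.0)

    txns_demand = _demand_adjusted_transactions(
        txns_after, inputs.segment_assignment, changes, relative_factor)
    sales_before = sales_by_category(txns_before)
    sales_after = sales_by_category(txns_demand)
    rev_before = revenue_decomposition(sales_before, inputs.valuation)
    rev_after = revenue_decomposition(sales_after, inputs.valuation)
    scale = inputs.population_scale
    spending_change_pct = 100.0 * (
        sales_after["sales"].sum() / sales_before["sales"].sum() - 1.0)
    retailer_change = scale * float(
        rev_after["retailer"].sum() - rev_before["retailer"].sum())
    duty_vat_change = scale * float(
        (rev_after["duty"] + rev_after["vat"]).sum()
        - (rev_before["duty"] + rev_before["vat"]).sum())

    # --- health: PIFs and cohort projection per subgroup ------------------
    table = inputs.harm_table.set_index(["condition_id", "sex", "age_band"])
    health_rows = []
    totals = {"deaths": 0.0, "admissions": 0.0, "qalys": 0.0, "cost": 0.0}
    groups_before = dict(iter(before.groupby(
        ["sex", "age_band", "drinker_level"])))
    after_indexed = after.set_index(before.index)
    for (sex, band, level), grp_before in groups_before.items():
        grp_after = after_indexed.loc[grp_before.index]
        weights = grp_before["weight"].to_numpy(float)
        subgroup_pop = float(weights.sum()) * scale
        if subgroup_pop == 0:
            continue
        conditions = []
        for cond in inputs.condition_configs:
            rf = inputs.risk_functions.get((cond.condition_id, sex, band))
            if rf is None:
                continue
            col = ("peak_day_units" if cond.basis == "peak_day"
                   else "mean_weekly_units")
            state_b = ConsumptionState(
                grp_before[col].to_numpy(float), weights)
            state_a = ConsumptionState(
                grp_after[col].to_numpy(float), weights)
            pif = pif_for_condition(rf, state_b, state_a)
            rates = table.loc[(cond.condition_id, sex, band)]
            conditions.append(ConditionSpec(
                condition_id=cond.condition_id, timing=cond.timing,
                mortality_rate=float(rates["mortality_rate"]),
                admission_rate=float(rates["admission_rate"]),
                pif=pif,
                utility_decrement=float(rates["utility_decrement"]),
                unit_cost=float(rates["unit_cost"])))
        result = project_cohort(
            subgroup_pop, sex, AGE_BAND_MIDPOINT[band], conditions,
            inputs.life_table, horizon=inputs.horizon,
            lag_model=inputs.lag_model,
            subgroup=SubgroupKey(sex, band, level))
        health_rows.append({
            "sex": sex, "age_band": band, "drinker_level": level,
            **result.cumulative})
        totals["deaths"] += result.deaths_averted
        totals["admissions"] += result.admissions_averted
        totals["qalys"] += result.qalys_gained
        totals["cost"] += result.cost_change
    health_by_subgroup = pd.DataFrame(health_rows)

    # --- crime ------------------------------------------------------------
    crime_by_category, _ = cw.crime_pif_and_volumes(
        before, after, inputs.crime_functions, inputs.crime_categories,
        inputs.apportionment)
    crime_qalys_annual = float(crime_by_category["victim_qaly_change"].sum())
    crime_cost_annual = float(crime_by_category["cost_change"].sum())
    horizon = inputs.horizon
    crime_qalys = discount_stream(
        [crime_qalys_annual] * horizon, QALY_DISCOUNT_RATE)
    crime_cost = discount_stream(
        [crime_cost_annual] * horizon, COST_DISCOUNT_RATE)

    # --- workplace ---------------------------------------------------------
    absence = cw.absence_change(
        before, after, inputs.absence_functions,
        inputs.workplace.baseline_absence_days,
        inputs.workplace.participation)
    salary = inputs.workplace.average_salary
    absence["cost_change"] = [
        row.days_change * salary.get((row.sex, row.age_band), 0.0)
        / WORKING_DAYS_PER_YEAR
        for row in absence.itertuples()
    ]
    unemployment = cw.unemployment_change(
        before, after, inputs.unemployment_function, inputs.workplace)
    absence_cost_annual = float(absence["cost_change"].sum())
    unemployment_cost_annual = float(unemployment["cost_change"].sum())
    workplace_cost = discount_stream(
        [absence_cost_annual + unemployment_cost_annual] * horizon,
        COST_DISCOUNT_RATE)

    # --- valuation ----------------------------------------------------------
    from .valuation import value_outcomes
    summary = value_outcomes(
        health={"qalys_gained": totals["qalys"],
                "cost_change": totals["cost"]},
        crime={"qalys_gained": crime_qalys, "cost_change": crime_cost},
        workplace={"absence_cost_change": discount_stream(
            [absence_cost_annual] * horizon, COST_DISCOUNT_RATE),
            "unemployment_cost_change": discount_stream(
            [unemployment_cost_annual] * horizon, COST_DISCOUNT_RATE)},
        params=inputs.valuation)

    row = {
        "policy": name,
        "consumption_change_pct": consumption_change_pct,
        "spending_change_pct": spending_change_pct,
        "retailer_revenue_change": retailer_change,
        "duty_vat_change": duty_vat_change,
        "deaths_averted": totals["deaths"],
        "health_qalys": totals["qalys"],
        "crime_qalys": crime_qalys,
        "health_value": summary["health_total"],
        "crime_value": summary["crime_total"],
        "workplace_value": summary["workplace_total"],
        "total_value": summary["grand_total"],
        "horizon": horizon,
    }
    return PolicyResult(
        name=name, row=row, individuals_after=after,
        transactions_after=txns_demand,
        health_by_subgroup=health_by_subgroup,
        crime_by_category=crime_by_category,
        workplace_detail={"absence": absence,
                          "unemployment": unemployment,
                          "workplace_cost_10y": workplace_cost})


def run_policies(policies: Mapping[str, Sequence[PolicySpec]],
                 inputs: ModelInputs) -> pd.DataFrame:
    """Run a policy library and assemble the comparison table."""
    rows = [run_policy(name, steps, inputs).row
            for name, steps in policies.items()]
    return build_policy_comparison(rows)
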