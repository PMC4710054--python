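"""Crime, workplace absence and unemployment harm channels.

All three channels reuse the attributable-fraction machinery: a two-part
linear relative-risk function is calibrated so its implied AAF on the
baseline consumption distribution matches an observed attribution target,
and a policy's consumption change then scales the observed baseline volume
(crimes, absence days, unemployed persons) by (1 - PIF).

Crime rides on peak-day consumption with functions fitted per sex for two
offender age groups (under 16 and 16-25); over-25s reuse the 16-25
functions.  Reported crime volumes are inflated by an under-reporting
multiplier before the PIF is applied, and category-level changes are
apportioned to subgroups by offender-distribution weights.  Absence also
rides on peak-day consumption per sex/age cell.  Unemployment rides on
mean consumption, applies only to harmful drinkers (thresholds 7.1
units/day men, 5 women on the mean basis), has no time lag, and is
calibrated to a target reduction in the probability of being in work, with
female effects adjusted by work-participation rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .population import AGE_BANDS, SEXES
from .risk import (ConsumptionState, InfeasibleCalibration, RiskFunction,
                   evaluate_rr, fit_two_part_slope,
                   potential_impact_fraction)

#: Offender age groups with fitted crime risk functions.  Over-25s reuse
#: the 16-25 functions (a stated evidence limitation, kept as-is).
CRIME_AGE_GROUPS = ("under16", "16-25", "over25")

_BAND_TO_CRIME_GROUP = {
    "11-15": "under16", "16-17": "16-25", "18-24": "16-25",
    "25-34": "over25", "35-44": "over25", "45-54": "over25",
    "55-64": "over25", "65-74": "over25", "75+": "over25",
}

#: Group whose fitted function each group evaluates with.
_EFFECTIVE_GROUP = {"under16": "under16", "16-25": "16-25",
                    "over25": "16-25"}

WORKING_AGE_BANDS = ("16-17", "18-24", "25-34", "35-44", "45-54", "55-64")

#: Mean-basis unemployment thresholds in units/day (converted x7 to weekly).
UNEMPLOYMENT_THRESHOLD_UNITS_DAY = {"male": 7.1, "female": 5.0}

#: Target reduction in the probability of being in work for harmful
#: drinkers, used to calibrate the unemployment risk function.
WORK_PROBABILITY_REDUCTION = 0.069

#: Peak-day thresholds for the absence risk functions; the evidence base
#: states no threshold, so the acute-harm cut-offs (4/3 units) are adopted
#: as the convention.
ABSENCE_THRESHOLD_UNITS_DAY = {"male": 4.0, "female": 3.0}


def crime_age_group(age_band: str) -> str:
    return _BAND_TO_CRIME_GROUP[age_band]


@dataclass
class CrimeCategory:
    """One of the 20 crime classifications with its attribution target."""

    category_id: str
    baseline_volume: float          # reported offences / year
    multiplier: float = 1.0         # under-reporting uplift
    unit_cost: float = 0.0          # £ per offence (justice + anticipation)
    victim_qaly_loss: float = 0.0   # QALYs lost per offence
    aaf: float = 0.2                # attributable fraction target

    def __post_init__(self) -> None:
        if self.baseline_volume < 0 or self.multiplier < 0 \
                or self.unit_cost < 0 or self.victim_qaly_loss < 0:
            raise ValueError("crime category parameters must be >= 0")
        if not 0.0 <= self.aaf < 1.0:
            raise ValueError("crime AAF must be in [0, 1)")


def _peak_states_by_cell(individuals: pd.DataFrame,
                         ) -> dict[tuple[str, str], ConsumptionState]:
    """Peak-day ConsumptionState per (sex, crime age group)."""
    df = individuals.assign(
        crime_group=individuals["age_band"].map(_BAND_TO_CRIME_GROUP))
    return {
        (sex, group): ConsumptionState(
            grp["peak_day_units"].to_numpy(float),
            grp["weight"].to_numpy(float))
        for (sex, group), grp in df.groupby(["sex", "crime_group"])
    }


def fit_crime_functions(individuals: pd.DataFrame,
                        categories: Sequence[CrimeCategory],
                        thresholds: Mapping[str, float] | None = None,
                        ) -> dict[tuple[str, str, str], RiskFunction]:
    """Calibrate per (category, sex, fitted age group) peak-basis RR
    functions to each category's AAF on the baseline distribution.

    Functions are fitted for under16 and 16-25 only; over25 evaluation
    reuses the 16-25 fit.
    """
    if thresholds is None:
        thresholds = ABSENCE_THRESHOLD_UNITS_DAY
    states = _peak_states_by_cell(individuals)
    functions: dict[tuple[str, str, str], RiskFunction] = {}
    for cat in categories:
        for sex in SEXES:
            for group in ("under16", "16-25"):
                state = states.get((sex, group))
                if state is None or state.weights.sum() == 0:
                    continue
                try:
                    slope = fit_two_part_slope(state, thresholds[sex],
                                               cat.aaf)
                except InfeasibleCalibration:
                    # no binge mass in the cell: crime risk stays flat there
                    continue
                functions[(cat.category_id, sex, group)] = RiskFunction(
                    condition_id=f"crime:{cat.category_id}",
                    basis="peak_day", attribution="partially",
                    timing="acute", threshold=thresholds[sex],
                    slope=slope, sex=sex)
    return functions


def _pooled_crime_sums(individuals: pd.DataFrame, category_id: str,
                       functions: Mapping[tuple[str, str, str], RiskFunction],
                       ) -> float:
    """sum_i w_i RR_i over the whole population, with each person's RR
    taken from its sex/age-group function (over-25 reusing 16-25)."""
    total = 0.0
    df = individuals.assign(
        crime_group=individuals["age_band"].map(_BAND_TO_CRIME_GROUP))
    for (sex, group), grp in df.groupby(["sex", "crime_group"]):
        fitted_group = _EFFECTIVE_GROUP[group]
        rf = functions.get((category_id, sex, fitted_group))
        if rf is None:
            total += float(grp["weight"].sum())  # RR = 1 when no function
            continue
        rr = evaluate_rr(rf, grp["peak_day_units"].to_numpy(float))
        total += float(np.sum(grp["weight"].to_numpy(float) * rr))
    return total


def crime_pif_and_volumes(individuals_before: pd.DataFrame,
                          individuals_after: pd.DataFrame,
                          functions: Mapping[tuple[str, str, str],
                                             RiskFunction],
                          categories: Sequence[CrimeCategory],
                          apportionment: pd.DataFrame | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-category offence changes under a consumption change.

    Effective baseline = reported volume x under-reporting multiplier;
    revised = effective x (1 - PIF) with the PIF pooled over the whole
    population using each cell's risk function.  If ``apportionment``
    (rows = (sex, age_band), one column per category, columns summing to 1)
    is given, category changes are also split to subgroups, conserving
    category totals exactly.
    """
    if len(individuals_before) != len(individuals_after):
        raise ValueError("before/after populations are misaligned")
    rows = []
    for cat in categories:
        wrr_before = _pooled_crime_sums(
            individuals_before, cat.category_id, functions)
        wrr_after = _pooled_crime_sums(
            individuals_after, cat.category_id, functions)
        pif = 1.0 - wrr_after / wrr_before
        effective = cat.baseline_volume * cat.multiplier
        change = -effective * pif
        rows.append({
            "category_id": cat.category_id,
            "baseline_volume": cat.baseline_volume,
            "effective_baseline": effective,
            "pif": pif,
            "offence_change": change,
            "cost_change": change * cat.unit_cost,
            "victim_qaly_change": -change * cat.victim_qaly_loss,
        })
    by_category = pd.DataFrame(rows).set_index("category_id")
    by_subgroup = None
    if apportionment is not None:
        col_sums = apportionment.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValueError(
                "apportionment weights must sum to 1 per category")
        by_subgroup = apportionment.mul(
            by_category["offence_change"], axis=1)
    return by_category, by_subgroup


def fit_absence_functions(individuals: pd.DataFrame,
                          absence_aaf: Mapping[str, float],
                          thresholds: Mapping[str, float] | None = None,
                          ) -> dict[tuple[str, str], RiskFunction]:
    """Peak-basis absence RR functions per (sex, age band), calibrated to
    per-sex causal attributable fractions."""
    if thresholds is None:
        thresholds = ABSENCE_THRESHOLD_UNITS_DAY
    functions = {}
    for (sex, band), grp in individuals.groupby(["sex", "age_band"]):
        if band not in WORKING_AGE_BANDS:
            continue
        state = ConsumptionState(grp["peak_day_units"].to_numpy(float),
                                 grp["weight"].to_numpy(float))
        if state.weights.sum() == 0:
            continue
        try:
            slope = fit_two_part_slope(state, thresholds[sex],
                                       absence_aaf[sex])
        except InfeasibleCalibration:
            continue
        functions[(sex, band)] = RiskFunction(
            condition_id="workplace:absence", basis="peak_day",
            attribution="partially", timing="acute",
            threshold=thresholds[sex], slope=slope, sex=sex)
    return functions


def absence_change(individuals_before: pd.DataFrame,
                   individuals_after: pd.DataFrame,
                   functions: Mapping[tuple[str, str], RiskFunction],
                   baseline_absence_days: Mapping[tuple[str, str], float],
                   participation: Mapping[tuple[str, str], float],
                   ) -> pd.DataFrame:
    """Absence days changed per (sex, age band).

    Change = -baseline days x PIF, scaled by work participation;
    non-working-age bands contribute zero.
    """
    rows = []
    groups_after = dict(iter(individuals_after.groupby(["sex", "age_band"])))
    for (sex, band), before in individuals_before.groupby(
            ["sex", "age_band"]):
        rf = functions.get((sex, band))
        if rf is None or band not in WORKING_AGE_BANDS:
            rows.append({"sex": sex, "age_band": band, "pif": 0.0,
                         "days_change": 0.0})
            continue
        after = groups_after[(sex, band)]
        state_b = ConsumptionState(before["peak_day_units"].to_numpy(float),
                                   before["weight"].to_numpy(float))
        state_a = ConsumptionState(after["peak_day_units"].to_numpy(float),
                                   after["weight"].to_numpy(float))
        pif = potential_impact_fraction(rf, state_b, state_a)
        base = baseline_absence_days.get((sex, band), 0.0)
        part = participation.get((sex, band), 0.0)
        rows.append({"sex": sex, "age_band": band, "pif": pif,
                     "days_change": -base * pif * part})
    return pd.DataFrame(rows)


@dataclass
class WorkplaceParams:
    """Workplace-harm configuration.

    Thresholds are units/day on the mean basis; the work-probability
    reduction target drives the unemployment calibration; baselines,
    salaries and participation are keyed by (sex, age band).
    """

    unemployment_thresholds_units_day: Mapping[str, float] = field(
        default_factory=lambda: dict(UNEMPLOYMENT_THRESHOLD_UNITS_DAY))
    work_probability_reduction: float = WORK_PROBABILITY_REDUCTION
    baseline_absence_days: Mapping[tuple[str, str], float] = field(
        default_factory=dict)
    baseline_unemployed: Mapping[tuple[str, str], float] = field(
        default_factory=dict)
    average_salary: Mapping[tuple[str, str], float] = field(
        default_factory=dict)
    participation: Mapping[tuple[str, str], float] = field(
        default_factory=dict)
    absence_aaf: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.05, "female": 0.03})

    def __post_init__(self) -> None:
        for sex, t in self.unemployment_thresholds_units_day.items():
            if t <= 0:
                raise ValueError(f"unemployment threshold for {sex} must "
                                 "be > 0")
        if not 0.0 <= self.work_probability_reduction < 1.0:
            raise ValueError("work probability reduction must be in [0, 1)")

    def threshold_weekly(self, sex: str) -> float:
        return self.unemployment_thresholds_units_day[sex] * 7.0


@dataclass
class UnemploymentFunction:
    """Calibrated mean-basis unemployment RR function.

    A single slope shared across sexes with sex-specific weekly thresholds;
    by construction it applies only to harmful drinkers — anyone below the
    harmful threshold has RR = 1 and contributes no unemployment effect.
    """

    thresholds_weekly: Mapping[str, float]
    slope: float

    def evaluate_rr(self, sex, mean_weekly_units) -> np.ndarray:
        c = np.asarray(mean_weekly_units, dtype=float)
        sexes = np.atleast_1d(np.asarray(sex))
        t = np.vectorize(self.thresholds_weekly.__getitem__)(sexes)
        return 1.0 + self.slope * np.maximum(0.0, c - t)


def _harmful_excess(individuals: pd.DataFrame, params: WorkplaceParams,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean consumption, participation-scaled weights, weekly thresholds)
    for working-age harmful drinkers."""
    if "drinker_level" not in individuals.columns:
        raise ValueError("individuals need a drinker_level column")
    mask = (individuals["drinker_level"] == "harmful") \
        & individuals["age_band"].isin(WORKING_AGE_BANDS)
    sub = individuals[mask]
    if len(sub) == 0:
        raise InfeasibleCalibration(
            "no working-age harmful drinkers to calibrate on")
    part = np.array([
        params.participation.get((sex, band), 1.0)
        for sex, band in zip(sub["sex"], sub["age_band"])
    ])
    weights = sub["weight"].to_numpy(float) * part
    thresholds = np.array([params.threshold_weekly(s) for s in sub["sex"]])
    return sub["mean_weekly_units"].to_numpy(float), weights, thresholds


def implied_work_reduction(function: UnemploymentFunction,
                           individuals: pd.DataFrame,
                           params: WorkplaceParams) -> float:
    """Implied fractional reduction in work probability for the harmful
    group: excess unemployment risk over total, sum w(RR-1) / sum w RR."""
    values, weights, thresholds = _harmful_excess(individuals, params)
    rr = 1.0 + function.slope * np.maximum(0.0, values - thresholds)
    wrr = float(np.sum(weights * rr))
    return (wrr - float(np.sum(weights))) / wrr


def calibrate_unemployment(individuals: pd.DataFrame,
                           params: WorkplaceParams) -> UnemploymentFunction:
    """Fit the unemployment slope so the implied work-probability reduction
    for working-age harmful drinkers equals the target (default 6.9%)."""
    target = params.work_probability_reduction
    thresholds_weekly = {s: params.threshold_weekly(s) for s in SEXES}
    if target == 0.0:
        return UnemploymentFunction(thresholds_weekly, 0.0)
    values, weights, thresholds = _harmful_excess(individuals, params)
    excess = float(np.sum(weights * np.maximum(0.0, values - thresholds)))
    if excess <= 0.0:
        raise InfeasibleCalibration(
            "no harmful-drinker consumption mass above the unemployment "
            "thresholds")
    total_weight = float(np.sum(weights))
    slope = target * total_weight / ((1.0 - target) * excess)
    return UnemploymentFunction(thresholds_weekly, slope)


def unemployment_change(individuals_before: pd.DataFrame,
                        individuals_after: pd.DataFrame,
                        function: UnemploymentFunction,
                        params: WorkplaceParams) -> pd.DataFrame:
    """Unemployed persons and salary-valued cost changed per (sex, band).

    Change = -baseline unemployed x PIF over the cell's harmful drinkers
    (baseline level); moderate and hazardous drinkers contribute exactly
    zero by construction.  No time lag applies.
    """
    if "drinker_level" not in individuals_before.columns:
        raise ValueError("individuals need a baseline drinker_level column")
    after_mean = pd.Series(
        individuals_after["mean_weekly_units"].to_numpy(float),
        index=individuals_after["person_id"])
    rows = []
    for (sex, band), before in individuals_before.groupby(
            ["sex", "age_band"]):
        if band not in WORKING_AGE_BANDS:
            rows.append({"sex": sex, "age_band": band, "pif": 0.0,
                         "persons_change": 0.0, "cost_change": 0.0})
            continue
        harmful = before[before["drinker_level"] == "harmful"]
        base_unemployed = params.baseline_unemployed.get((sex, band), 0.0)
        if len(harmful) == 0 or base_unemployed == 0.0:
            rows.append({"sex": sex, "age_band": band, "pif": 0.0,
                         "persons_change": 0.0, "cost_change": 0.0})
            continue
        w = harmful["weight"].to_numpy(float)
        rr_before = function.evaluate_rr(
            harmful["sex"].to_numpy(),
            harmful["mean_weekly_units"].to_numpy(float))
        rr_after = function.evaluate_rr(
            harmful["sex"].to_numpy(),
            after_mean[harmful["person_id"]].to_numpy(float))
        pif = 1.0 - float(np.sum(w * rr_after)) / float(np.sum(w * rr_before))
        persons = -base_unemployed * pif
        salary = params.average_salary.get((sex, band), 0.0)
        rows.append({"sex": sex, "age_band": band, "pif": pif,
                     "persons_change": persons,
                     "cost_change": persons * salary})
    return pd.DataFrame(rows)
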