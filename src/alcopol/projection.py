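"""Ten-year age-cohort projection of health harms: Future A vs Future B.

Each of the 54 subgroups is projected as an age cohort over a 10-year
horizon.  Future B is the do-nothing counterfactual with steady-state
consumption, so its condition-specific rates stay at baseline every year.
Future A applies the policy's potential impact fraction to each condition's
baseline mortality and hospitalisation rates — immediately for acute
conditions, phased in linearly over ``years_to_full_effect`` (default 10)
for chronic ones, so the year-t chronic rate is
baseline * (1 - (t/L) * PIF).

Within each scenario the cohort ages one year at a time; survivors carry
forward after subtracting alcohol-condition deaths and other-cause deaths
from the life table.  Deaths averted in a year are valued in QALYs as the
remaining utility-weighted, discounted life expectancy at the age of death;
morbidity (proxied by person-specific hospitalisations) contributes an
annual QALY decrement and a treatment cost per prevalent case.  QALY
streams are discounted at 3.5%/yr and costs at 1.5%/yr, end-of-year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

QALY_DISCOUNT_RATE = 0.035
COST_DISCOUNT_RATE = 0.015
DEFAULT_HORIZON = 10


@dataclass(frozen=True)
class LagModel:
    """Linear phase-in of chronic risk change: t/L of full effect at year t,
    clamped at 1 from year L onwards."""

    years_to_full_effect: int = 10

    def __post_init__(self) -> None:
        if self.years_to_full_effect < 1:
            raise ValueError("years_to_full_effect must be >= 1")


def lag_fraction(year: int, lag_model: LagModel) -> float:
    """min(year / L, 1); 0 at year 0.  Acute harms bypass the lag entirely
    (handled in annual_rates, not here)."""
    if year < 0:
        raise ValueError("year must be >= 0")
    return min(year / lag_model.years_to_full_effect, 1.0)


@dataclass
class ConditionSpec:
    """Per-condition inputs to the cohort projection for one subgroup."""

    condition_id: str
    timing: str                      # chronic | acute
    mortality_rate: float            # baseline deaths / person-year
    admission_rate: float            # baseline person-specific admissions
    pif: float                       # potential impact fraction under policy
    utility_decrement: float = 0.0   # QALY loss per prevalent case-year
    unit_cost: float = 0.0           # treatment cost per case-year, £

    def __post_init__(self) -> None:
        if self.timing not in ("chronic", "acute"):
            raise ValueError(f"unknown timing {self.timing!r}")
        for name in ("mortality_rate", "admission_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pif > 1.0:
            raise ValueError("PIF cannot exceed 1")


def annual_rates(condition: ConditionSpec, year: int,
                 lag_model: LagModel) -> dict[str, float]:
    """Mortality and admission rates for Future A and B in a model year.

    Chronic: rate_A(t) = baseline * (1 - lag_fraction(t) * PIF); acute
    conditions feel the full PIF from year 1.  Future B stays at baseline.
    """
    if year < 1:
        raise ValueError("model years are 1-based")
    if condition.timing == "chronic":
        effect = lag_fraction(year, lag_model) * condition.pif
    else:
        effect = condition.pif
    factor = 1.0 - effect
    return {
        "mortality_a": condition.mortality_rate * factor,
        "mortality_b": condition.mortality_rate,
        "admission_a": condition.admission_rate * factor,
        "admission_b": condition.admission_rate,
    }


def discount_stream(values_by_year: Sequence[float], annual_rate: float,
                    ) -> float:
    """Present value of an annual stream, end-of-year convention:
    sum_t v_t / (1 + r)^t with t starting at 1."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    values = np.asarray(values_by_year, dtype=float)
    t = np.arange(1, len(values) + 1)
    return float(np.sum(values / (1.0 + annual_rate) ** t))


class LifeTable:
    """All-cause mortality and population-average utility by sex and single
    year of age."""

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "age", "mortality", "utility"}
        if not required <= set(table.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        if ((table["mortality"] < 0) | (table["mortality"] > 1)).any():
            raise ValueError("mortality rates must be in [0, 1]")
        if ((table["utility"] < 0) | (table["utility"] > 1)).any():
            raise ValueError("utilities must be in [0, 1]")
        self._table = table.sort_values(["sex", "age"]).reset_index(drop=True)
        self._min_age = int(self._table["age"].min())
        self._max_age = int(self._table["age"].max())
        self._mortality: dict[str, np.ndarray] = {}
        self._utility: dict[str, np.ndarray] = {}
        for sex, grp in self._table.groupby("sex"):
            ages = grp["age"].to_numpy(int)
            if not np.array_equal(
                    ages, np.arange(self._min_age, self._max_age + 1)):
                raise ValueError(
                    f"life table for {sex} must cover every single year of "
                    f"age {self._min_age}..{self._max_age}")
            self._mortality[sex] = grp["mortality"].to_numpy(float)
            self._utility[sex] = grp["utility"].to_numpy(float)
        self._expectancy_cache: dict[tuple[str, int, float], float] = {}

    @property
    def max_age(self) -> int:
        return self._max_age

    def _index(self, age: int) -> int:
        age = min(int(age), self._max_age)
        if age < self._min_age:
            raise ValueError(f"age {age} below life-table coverage")
        return age - self._min_age

    def mortality(self, sex: str, age: int) -> float:
        return float(self._mortality[sex][self._index(age)])

    def utility(self, sex: str, age: int) -> float:
        return float(self._utility[sex][self._index(age)])

    def discounted_life_expectancy(self, sex: str, age: int,
                                   rate: float = QALY_DISCOUNT_RATE) -> float:
        """Utility-weighted, discounted expected life-years remaining from
        the given age, stepping the life table year by year."""
        key = (sex, int(age), rate)
        cached = self._expectancy_cache.get(key)
        if cached is not None:
            return cached
        surv = 1.0
        total = 0.0
        for t, a in enumerate(range(int(age), self.max_age + 1)):
            q = self.mortality(sex, a)
            # person-years lived this year approximated mid-year for deaths
            lived = surv * (1.0 - q) + 0.5 * surv * q
            total += lived * self.utility(sex, a) / (1.0 + rate) ** t
            surv *= 1.0 - q
            if surv < 1e-12:
                break
        self._expectancy_cache[key] = total
        return total

    def to_csv(self, path: str | Path) -> None:
        self._table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(pd.read_csv(path))


@dataclass
class ProjectionResult:
    """Per-subgroup outcomes of the A-vs-B projection.

    ``annual`` has one row per model year with deaths/admissions averted;
    QALY and cost aggregates are discounted present values.
    """

    subgroup: object
    annual: pd.DataFrame
    deaths_averted: float
    admissions_averted: float
    qalys_gained: float        # discounted at the QALY rate
    cost_change: float         # discounted NHS cost change (A - B), £

    @property
    def cumulative(self) -> dict[str, float]:
        return {
            "deaths_averted": self.deaths_averted,
            "admissions_averted": self.admissions_averted,
            "qalys_gained": self.qalys_gained,
            "cost_change": self.cost_change,
        }


def project_cohort(subgroup_population: float, sex: str, start_age: int,
                   conditions: Sequence[ConditionSpec],
                   life_table: LifeTable,
                   horizon: int = DEFAULT_HORIZON,
                   lag_model: LagModel = LagModel(),
                   qaly_rate: float = QALY_DISCOUNT_RATE,
                   cost_rate: float = COST_DISCOUNT_RATE,
                   subgroup: object = None) -> ProjectionResult:
    """Project one subgroup cohort over the horizon under Futures A and B.

    Mortality within a year is additive across the alcohol conditions plus
    life-table other-cause mortality, capped at 1.  The life table is taken
    as all-cause, so the alcohol-condition baseline share is netted out of
    the other-cause component to avoid double counting.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if start_age + horizon - 1 > life_table.max_age:
        raise ValueError("horizon runs beyond life-table coverage")

    base_mort = sum(c.mortality_rate for c in conditions)
    pop = {"a": float(subgroup_population), "b": float(subgroup_population)}
    rows = []
    qalys_by_year = np.zeros(horizon)
    cost_by_year = np.zeros(horizon)
    for year in range(1, horizon + 1):
        age = start_age + year - 1
        other = max(0.0, life_table.mortality(sex, age) - base_mort)
        deaths = {"a": 0.0, "b": 0.0}
        admissions = {"a": 0.0, "b": 0.0}
        qaly_decrement = {"a": 0.0, "b": 0.0}
        treatment_cost = {"a": 0.0, "b": 0.0}
        for cond in conditions:
            rates = annual_rates(cond, year, lag_model)
            for scen in ("a", "b"):
                d = pop[scen] * rates[f"mortality_{scen}"]
                cases = pop[scen] * rates[f"admission_{scen}"]
                deaths[scen] += d
                admissions[scen] += cases
                qaly_decrement[scen] += cases * cond.utility_decrement
                treatment_cost[scen] += cases * cond.unit_cost
        deaths_averted = deaths["b"] - deaths["a"]
        admissions_averted = admissions["b"] - admissions["a"]
        # QALYs: averted deaths gain remaining discounted life expectancy,
        # discounted back to present from the year of death; morbidity
        # decrements accrue in-year.
        expectancy = life_table.discounted_life_expectancy(
            sex, age + 1, qaly_rate)
        qalys_by_year[year - 1] = (
            deaths_averted * expectancy
            + (qaly_decrement["b"] - qaly_decrement["a"]))
        cost_by_year[year - 1] = treatment_cost["a"] - treatment_cost["b"]
        rows.append({
            "year": year, "age": age,
            "population_a": pop["a"], "population_b": pop["b"],
            "deaths_a": deaths["a"], "deaths_b": deaths["b"],
            "deaths_averted": deaths_averted,
            "admissions_a": admissions["a"], "admissions_b": admissions["b"],
            "admissions_averted": admissions_averted,
        })
        for scen in ("a", "b"):
            total_mort = min(1.0, deaths[scen] / pop[scen] + other
                             if pop[scen] > 0 else 1.0)
            pop[scen] = max(0.0, pop[scen] * (1.0 - total_mort))
    annual = pd.DataFrame(rows)
    return ProjectionResult(
        subgroup=subgroup,
        annual=annual,
        deaths_averted=float(annual["deaths_averted"].sum()),
        admissions_averted=float(annual["admissions_averted"].sum()),
        qalys_gained=discount_stream(qalys_by_year, qaly_rate),
        cost_change=discount_stream(cost_by_year, cost_rate),
    )
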