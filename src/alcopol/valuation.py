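"""Monetary valuation: spending, revenue decomposition, cost-benefit.

Health QALYs are valued at £50,000 and crime-victim QALYs at £81,000
(2006 price level, no inflation adjustment); QALY streams are discounted
at 3.5%/yr and cost streams at 1.5%/yr upstream of this module.  Retail
sales are VAT-inclusive, so the government's VAT take on sales S at rate r
is S * r / (1 + r); duty is a per-unit excise by beverage type; whatever
remains is retailer income.  Workplace harms (absence days, unemployed
persons) are valued at average salaries by age/sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .population import (BEVERAGE_CATEGORIES, category_beverage,
                         category_sector)

HEALTH_QALY_VALUE = 50_000.0
CRIME_QALY_VALUE = 81_000.0
VAT_RATE = 0.175

#: Default duty in pence per unit of ethanol by beverage type.
DEFAULT_DUTY_PENCE_PER_UNIT = {
    "beer": 10.0, "wine": 14.0, "spirit": 18.0, "rtd": 12.0,
}

PENCE_PER_POUND = 100.0


@dataclass
class ValuationParams:
    health_qaly_value: float = HEALTH_QALY_VALUE
    crime_qaly_value: float = CRIME_QALY_VALUE
    vat_rate: float = VAT_RATE
    duty_pence_per_unit: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DUTY_PENCE_PER_UNIT))
    qaly_discount_rate: float = 0.035
    cost_discount_rate: float = 0.015

    def __post_init__(self) -> None:
        if self.health_qaly_value < 0 or self.crime_qaly_value < 0:
            raise ValueError("QALY values must be >= 0")
        if self.vat_rate < 0:
            raise ValueError("VAT rate must be >= 0")
        if any(d < 0 for d in self.duty_pence_per_unit.values()):
            raise ValueError("duty rates must be >= 0")


def _annual_spending(transactions: pd.DataFrame,
                     weeks_per_year: float) -> pd.Series:
    """£/year spending per transaction row (weights applied)."""
    return (transactions["weight"] * transactions["units"]
            * transactions["sold_price"]
            * weeks_per_year / PENCE_PER_POUND)


def spending_change(transactions_before: pd.DataFrame,
                    transactions_after: pd.DataFrame,
                    subgroup_assignment: pd.Series | None = None,
                    weeks_per_year: float = 52.0) -> pd.DataFrame:
    """Change in consumer spending (£/year) per sector and, optionally,
    per subgroup.

    Transactions carry weekly volumes; ``transactions_after`` must carry
    post-policy units (demand response applied) and prices.  Rows need not
    align one-to-one — totals are aggregated per group.
    """
    frames = []
    for label, txns in (("before", transactions_before),
                        ("after", transactions_after)):
        df = pd.DataFrame({
            "sector": txns["category"].map(category_sector),
            "spend": _annual_spending(txns, weeks_per_year),
        })
        if subgroup_assignment is not None:
            df["subgroup"] = txns["person_id"].map(subgroup_assignment)
            if df["subgroup"].isna().any():
                raise ValueError("subgroup assignment missing for some "
                                 "persons")
            keys = ["subgroup", "sector"]
        else:
            keys = ["sector"]
        frames.append(df.groupby(keys, observed=True)["spend"].sum()
                      .rename(label))
    out = pd.concat(frames, axis=1).fillna(0.0)
    out["change"] = out["after"] - out["before"]
    return out


def sales_by_category(transactions: pd.DataFrame,
                      weeks_per_year: float = 52.0) -> pd.DataFrame:
    """Annual weighted sales value (£) and ethanol volume (units) per
    beverage category."""
    df = pd.DataFrame({
        "category": transactions["category"],
        "sales": _annual_spending(transactions, weeks_per_year),
        "units": (transactions["weight"] * transactions["units"]
                  * weeks_per_year),
    })
    out = df.groupby("category", observed=True).sum(numeric_only=True)
    return out.reindex(list(BEVERAGE_CATEGORIES), fill_value=0.0)


def revenue_decomposition(sales: pd.DataFrame,
                          params: ValuationParams) -> pd.DataFrame:
    """Split annual sales per category into retailer, duty and VAT.

    ``sales`` is indexed by category with columns ``sales`` (£, VAT
    inclusive) and ``units``.  VAT = sales * r/(1+r); duty = units x the
    beverage type's duty per unit; retailer = remainder, so the
    decomposition re-sums to sales exactly.
    """
    out = sales.copy()
    r = params.vat_rate
    out["vat"] = out["sales"] * r / (1.0 + r)
    duty_rates = np.array([
        params.duty_pence_per_unit[category_beverage(cat)] / PENCE_PER_POUND
        for cat in out.index
    ])
    out["duty"] = out["units"] * duty_rates
    out["retailer"] = out["sales"] - out["vat"] - out["duty"]
    out["sector"] = [category_sector(c) for c in out.index]
    negative = out["retailer"] < 0
    if negative.any():
        import warnings
        warnings.warn(
            f"duty + VAT exceed sales for categories "
            f"{list(out.index[negative])}", stacklevel=2)
    return out


def value_outcomes(health: Mapping[str, float],
                   crime: Mapping[str, float],
                   workplace: Mapping[str, float],
                   params: ValuationParams | None = None) -> dict[str, float]:
    """Combine the three harm channels into the partial cost-benefit
    summary (all monetary figures £, discounted upstream).

    ``health``: qalys_gained, cost_change (NHS, signed A - B).
    ``crime``: qalys_gained, cost_change (justice system, signed).
    ``workplace``: absence_cost_change, unemployment_cost_change (signed).
    Totals are signed changes (negative = saving / harm reduction valued
    as benefit is reported via the qaly_value lines).
    """
    if params is None:
        params = ValuationParams()
    health_value = (health.get("cost_change", 0.0)
                    - health.get("qalys_gained", 0.0)
                    * params.health_qaly_value)
    crime_value = (crime.get("cost_change", 0.0)
                   - crime.get("qalys_gained", 0.0)
                   * params.crime_qaly_value)
    workplace_value = (workplace.get("absence_cost_change", 0.0)
                       + workplace.get("unemployment_cost_change", 0.0))
    return {
        "health_qaly_value": health.get("qalys_gained", 0.0)
        * params.health_qaly_value,
        "crime_qaly_value": crime.get("qalys_gained", 0.0)
        * params.crime_qaly_value,
        "health_total": health_value,
        "crime_total": crime_value,
        "workplace_total": workplace_value,
        "grand_total": health_value + crime_value + workplace_value,
    }


COMPARISON_COLUMNS = (
    "policy", "consumption_change_pct", "spending_change_pct",
    "retailer_revenue_change", "duty_vat_change", "deaths_averted",
    "health_qalys", "crime_qalys", "health_value", "crime_value",
    "workplace_value", "total_value",
)


def build_policy_comparison(results: Sequence[Mapping[str, float]],
                            ) -> pd.DataFrame:
    """Assemble the one-row-per-policy comparison table.

    Each entry must provide the COMPARISON_COLUMNS fields (policy name plus
    recomputed channel aggregates) and a common ``horizon``; heterogeneous
    horizons are rejected because the cumulative columns would not be
    comparable.
    """
    if len(results) == 0:
        raise ValueError("need at least one policy result")
    horizons = {r.get("horizon") for r in results}
    if len(horizons) > 1:
        raise ValueError(f"heterogeneous horizons: {sorted(horizons)}")
    rows = [{col: r[col] for col in COMPARISON_COLUMNS} for r in results]
    return pd.DataFrame(rows, columns=list(COMPARISON_COLUMNS))
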