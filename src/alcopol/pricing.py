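"""Price-side policy transforms on weighted transaction data.

Transactions are EFS-style purchase records: one row per (person, beverage
category) with an ethanol volume in units, a sold price and a usual
(non-discounted) price in pence per unit, and the purchaser's sample weight.
A policy edits the price columns only — volumes and weights are never
touched — and the induced per-category mean price change (volume-weighted,
split by demand segment) is what feeds the elasticity model downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .population import BEVERAGE_CATEGORIES, category_sector

TRANSACTION_COLUMNS = (
    "person_id", "category", "units", "sold_price", "usual_price", "weight",
)

#: Demand segments for which separate elasticity matrices exist.
SEGMENTS = ("moderate", "hazardous_harmful")

POLICY_KINDS = (
    "minimum_unit_price", "general_price_change", "low_priced_change",
    "discount_restriction", "relative_consumption_change",
)

SCOPES = ("on_trade", "off_trade", "both")


@dataclass(frozen=True)
class PolicySpec:
    """One declarative intervention step.

    price-side kinds edit transactions; ``relative_consumption_change``
    bypasses prices and scales consumption directly (advertising /
    availability what-ifs).  ``categories`` optionally restricts a price
    policy to a subset of the 16 beverage categories.
    """

    kind: str
    floor: float | None = None            # pence/unit
    percent: float | None = None          # percent price or consumption change
    low_price_cutoff: float | None = None  # pence/unit
    max_discount_fraction: float | None = None
    scope: str = "both"
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in POLICY_KINDS:
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.kind == "minimum_unit_price":
            if self.floor is None or self.floor <= 0:
                raise ValueError("minimum_unit_price needs floor > 0")
        if self.kind in ("general_price_change", "low_priced_change",
                         "relative_consumption_change"):
            if self.percent is None or self.percent <= -100:
                raise ValueError(f"{self.kind} needs percent > -100")
        if self.kind == "low_priced_change" and self.low_price_cutoff is None:
            raise ValueError("low_priced_change needs low_price_cutoff")
        if self.kind == "discount_restriction":
            f = self.max_discount_fraction
            if f is None or not 0.0 <= f <= 1.0:
                raise ValueError(
                    "discount_restriction needs max_discount_fraction in "
                    "[0, 1] (0 = total ban)")
        if self.categories is not None:
            unknown = set(self.categories) - set(BEVERAGE_CATEGORIES)
            if unknown:
                raise ValueError(f"unknown categories: {sorted(unknown)}")


def validate_transactions(transactions: pd.DataFrame) -> None:
    missing = set(TRANSACTION_COLUMNS) - set(transactions.columns)
    if missing:
        raise ValueError(f"transactions missing columns: {sorted(missing)}")
    if (transactions["units"] < 0).any() or (transactions["weight"] < 0).any():
        raise ValueError("units and weights must be non-negative")
    if (transactions["sold_price"] <= 0).any() \
            or (transactions["usual_price"] <= 0).any():
        raise ValueError("prices must be positive")
    if (transactions["sold_price"] > transactions["usual_price"] + 1e-9).any():
        raise ValueError("sold price must not exceed usual price")


def _scope_mask(transactions: pd.DataFrame, scope: str,
                categories: Sequence[str] | None) -> np.ndarray:
    cats = transactions["category"]
    if scope == "both":
        mask = np.ones(len(transactions), dtype=bool)
    else:
        sector = scope.split("_")[0]  # on_trade -> on
        mask = cats.map(category_sector).to_numpy() == sector
    if categories is not None:
        mask &= cats.isin(categories).to_numpy()
    return mask


def apply_minimum_unit_price(transactions: pd.DataFrame, floor: float,
                             scope: str = "both",
                             categories: Sequence[str] | None = None,
                             ) -> pd.DataFrame:
    """Raise every in-scope price below the floor to exactly the floor.

    Both sold and usual prices are floored (a legal minimum binds the shelf
    price as well as any promotion); volumes and weights are unchanged.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    out = transactions.copy()
    mask = _scope_mask(out, scope, categories)
    for col in ("sold_price", "usual_price"):
        prices = out[col].to_numpy(float)
        out[col] = np.where(mask, np.maximum(prices, floor), prices)
    return out


def apply_general_price_change(transactions: pd.DataFrame, percent: float,
                               scope: str = "both",
                               low_price_cutoff: float | None = None,
                               categories: Sequence[str] | None = None,
                               ) -> pd.DataFrame:
    """Multiply in-scope prices by (1 + percent/100).

    With ``low_price_cutoff`` set, only transactions whose sold price is
    below the cutoff are changed (targeted low-price rises).
    """
    if percent <= -100:
        raise ValueError("percent must be > -100")
    out = transactions.copy()
    mask = _scope_mask(out, scope, categories)
    if low_price_cutoff is not None:
        mask &= out["sold_price"].to_numpy(float) < low_price_cutoff
    factor = 1.0 + percent / 100.0
    for col in ("sold_price", "usual_price"):
        prices = out[col].to_numpy(float)
        out[col] = np.where(mask, prices * factor, prices)
    return out


def apply_discount_restriction(transactions: pd.DataFrame,
                               max_discount_fraction: float,
                               scope: str = "both",
                               categories: Sequence[str] | None = None,
                               usual_price_cutoff: float | None = None,
                               ) -> pd.DataFrame:
    """Cap discounts at a fraction of the usual price (0 = total ban).

    Sold prices are raised to at least usual * (1 - max_discount_fraction);
    usual prices are untouched.  With ``usual_price_cutoff`` set, only
    products whose usual price is below the cutoff are restricted (bans
    targeted at cheap products).
    """
    if not 0.0 <= max_discount_fraction <= 1.0:
        raise ValueError("max_discount_fraction must be in [0, 1]")
    out = transactions.copy()
    mask = _scope_mask(out, scope, categories)
    if usual_price_cutoff is not None:
        mask &= out["usual_price"].to_numpy(float) < usual_price_cutoff
    permitted_floor = out["usual_price"].to_numpy(float) * (
        1.0 - max_discount_fraction)
    sold = out["sold_price"].to_numpy(float)
    out["sold_price"] = np.where(mask, np.maximum(sold, permitted_floor), sold)
    return out


def apply_policy_step(transactions: pd.DataFrame,
                      policy: PolicySpec) -> pd.DataFrame:
    """Dispatch one price-side policy step; consumption what-ifs are a no-op
    here (handled by the demand module)."""
    if policy.kind == "minimum_unit_price":
        return apply_minimum_unit_price(
            transactions, policy.floor, policy.scope, policy.categories)
    if policy.kind == "general_price_change":
        return apply_general_price_change(
            transactions, policy.percent, policy.scope,
            categories=policy.categories)
    if policy.kind == "low_priced_change":
        return apply_general_price_change(
            transactions, policy.percent, policy.scope,
            low_price_cutoff=policy.low_price_cutoff,
            categories=policy.categories)
    if policy.kind == "discount_restriction":
        return apply_discount_restriction(
            transactions, policy.max_discount_fraction, policy.scope,
            policy.categories, usual_price_cutoff=policy.low_price_cutoff)
    return transactions


def apply_policy(transactions: pd.DataFrame,
                 steps: Iterable[PolicySpec]) -> pd.DataFrame:
    """Apply price-side steps sequentially in the order given.

    Order matters (a floor then a percent rise differs from the reverse),
    so the policy file order is authoritative.
    """
    out = transactions
    for step in steps:
        out = apply_policy_step(out, step)
    return out


def mean_price_change_vector(before: pd.DataFrame, after: pd.DataFrame,
                             segment_assignment: pd.Series) -> pd.DataFrame:
    """Percent change of the mean sold price per category and demand segment.

    ``segment_assignment`` maps person_id to a demand segment.  The mean is
    weighted by weight x units (ethanol-volume weighting, the model's
    per-unit currency).  Categories with no volume in a segment report 0.
    Returns a DataFrame indexed by the 16 categories with one column per
    segment.
    """
    if len(before) != len(after) \
            or not before["category"].equals(after["category"]) \
            or not np.allclose(before["units"], after["units"]) \
            or not before["person_id"].equals(after["person_id"]):
        raise ValueError("before/after transactions are misaligned")
    seg = before["person_id"].map(segment_assignment)
    if seg.isna().any():
        raise ValueError("segment assignment missing for some persons")
    w = before["weight"].to_numpy(float) * before["units"].to_numpy(float)
    frame = pd.DataFrame({
        "category": before["category"].to_numpy(),
        "segment": seg.to_numpy(),
        "w": w,
        "wp_before": w * before["sold_price"].to_numpy(float),
        "wp_after": w * after["sold_price"].to_numpy(float),
    })
    sums = frame.groupby(["segment", "category"], observed=True).sum(
        numeric_only=True)
    result = pd.DataFrame(
        0.0, index=list(BEVERAGE_CATEGORIES), columns=list(SEGMENTS))
    for (segment, category), row in sums.iterrows():
        if row["w"] > 0:
            mean_before = row["wp_before"] / row["w"]
            mean_after = row["wp_after"] / row["w"]
            result.loc[category, segment] = 100.0 * (
                mean_after / mean_before - 1.0)
    return result


# ---------------------------------------------------------------------------
# Policy file I/O and the fixture library of 18 appraisal scenarios.

def load_policy_file(path: str | Path) -> dict[str, list[PolicySpec]]:
    """Read a YAML policy file: {policy name: [step, ...]}."""
    raw = yaml.safe_load(Path(path).read_text())
    policies = {}
    for name, steps in raw.items():
        policies[name] = [
            PolicySpec(**{**step, "categories":
                          tuple(step["categories"])
                          if step.get("categories") else None})
            for step in steps
        ]
    return policies


def save_policy_file(policies: dict[str, list[PolicySpec]],
                     path: str | Path) -> None:
    raw = {
        name: [
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in vars(step).items() if v is not None}
            for step in steps
        ]
        for name, steps in policies.items()
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


_BEER_CATEGORIES = tuple(c for c in BEVERAGE_CATEGORIES
                         if c.startswith("beer"))

#: The 18 standard appraisal scenarios: general and targeted price rises,
#: minimum unit prices, discount restrictions, and relative-change what-ifs
#: for advertising and availability.
POLICY_LIBRARY: dict[str, list[PolicySpec]] = {
    "general_price_+10pct": [
        PolicySpec("general_price_change", percent=10)],
    "general_price_+25pct": [
        PolicySpec("general_price_change", percent=25)],
    "low_priced_off_trade_+25pct": [
        PolicySpec("low_priced_change", percent=25, low_price_cutoff=40,
                   scope="off_trade")],
    "low_priced_on_trade_+25pct": [
        PolicySpec("low_priced_change", percent=25, low_price_cutoff=90,
                   scope="on_trade")],
    "all_low_priced_+10pct": [
        PolicySpec("low_priced_change", percent=10, low_price_cutoff=40,
                   scope="off_trade"),
        PolicySpec("low_priced_change", percent=10, low_price_cutoff=90,
                   scope="on_trade")],
    "minimum_price_15p": [PolicySpec("minimum_unit_price", floor=15)],
    "minimum_price_25p": [PolicySpec("minimum_unit_price", floor=25)],
    "minimum_price_50p": [PolicySpec("minimum_unit_price", floor=50)],
    "minimum_price_70p": [PolicySpec("minimum_unit_price", floor=70)],
    "minimum_price_40p_off_100p_on": [
        PolicySpec("minimum_unit_price", floor=40, scope="off_trade"),
        PolicySpec("minimum_unit_price", floor=100, scope="on_trade")],
    "minimum_price_30p_beer_only": [
        PolicySpec("minimum_unit_price", floor=30,
                   categories=_BEER_CATEGORIES)],
    "ban_off_trade_discounts_over_50pct": [
        PolicySpec("discount_restriction", max_discount_fraction=0.5,
                   scope="off_trade")],
    "ban_off_trade_discounts_over_20pct": [
        PolicySpec("discount_restriction", max_discount_fraction=0.2,
                   scope="off_trade")],
    "total_ban_off_trade_discounting": [
        PolicySpec("discount_restriction", max_discount_fraction=0.0,
                   scope="off_trade")],
    "ban_off_trade_discount_below_30p": [
        PolicySpec("discount_restriction", max_discount_fraction=0.0,
                   scope="off_trade",
                   categories=None, low_price_cutoff=30)],
    "total_advertising_ban": [
        PolicySpec("relative_consumption_change", percent=-26.9)],
    "outlet_density_-10pct_whatif": [
        PolicySpec("relative_consumption_change", percent=13.2)],
    "licensing_hours_-10pct_whatif": [
        PolicySpec("relative_consumption_change", percent=-1.2)],
}
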