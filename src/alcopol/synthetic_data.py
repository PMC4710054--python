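"""Seeded synthetic inputs: survey-like microdata, purchase transactions,
price calibration, and baseline harm/configuration tables.

No public accession exists for the confidential survey and market-research
inputs the model consumes, so this module generates statistically analogous
stand-ins: a GHS-like weighted consumption sample (right-skewed log-normal
mean weekly consumption per sex/age cell, a linear peak-from-mean binge
model, Dirichlet beverage-mix shares over the 16 categories), an EFS-like
transaction table (log-normal pence-per-unit prices with a discounted
sold-price fraction), the linear-interpolation calibration of the price
distribution to target cumulative shares at 10 price points, and baseline
harm-rate, life-table, crime, workplace, duty and elasticity tables.

Everything is bit-reproducible for a fixed seed and config; each generator
logs its seed and a config hash.  The generators aim for the structural
features the model relies on (right skew, weight heterogeneity, mass above
risk thresholds, sub-floor prices, discount incidence) rather than
distributional fidelity to any real country.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crime_workplace import (CrimeCategory, WORKING_AGE_BANDS,
                              WorkplaceParams)
from .demand import BingeModel, ElasticityMatrix, N_CATEGORIES
from .population import (AGE_BANDS, BEVERAGE_CATEGORIES, SEXES,
                         SHARE_COLUMNS, category_beverage,
                         category_sector)
from .projection import LifeTable
from .pricing import SEGMENTS

logger = logging.getLogger("alcopol")


def _config_hash(obj) -> str:
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Population generator

#: Approximate population share of each age band (per sex).
DEFAULT_AGE_SHARES = {
    "11-15": 0.06, "16-17": 0.03, "18-24": 0.11, "25-34": 0.16,
    "35-44": 0.17, "45-54": 0.15, "55-64": 0.13, "65-74": 0.11, "75+": 0.08,
}

DEFAULT_ABSTAINER_FRACTION = {
    **{("male", band): 0.12 for band in AGE_BANDS},
    **{("female", band): 0.18 for band in AGE_BANDS},
    ("male", "11-15"): 0.55, ("female", "11-15"): 0.60,
    ("male", "16-17"): 0.30, ("female", "16-17"): 0.35,
    ("male", "75+"): 0.25, ("female", "75+"): 0.40,
}

#: Median weekly units by sex, modulated by age.
DEFAULT_CONSUMPTION_MEDIAN = {"male": 8.0, "female": 4.0}
DEFAULT_CONSUMPTION_LOG_SCALE = 1.1
DEFAULT_AGE_CONSUMPTION_FACTOR = {
    "11-15": 0.25, "16-17": 0.60, "18-24": 1.30, "25-34": 1.15,
    "35-44": 1.05, "45-54": 1.00, "55-64": 0.90, "65-74": 0.75, "75+": 0.55,
}

#: Peak-from-mean slopes by drinker level (heavier drinkers spread intake
#: over more days, so the marginal peak response declines with level).
DEFAULT_BINGE_SLOPES = {"moderate": 0.35, "hazardous": 0.25,
                        "harmful": 0.18}
DEFAULT_BINGE_INTERCEPT = 0.3
DEFAULT_BINGE_RESIDUAL_SCALE = 1.0

#: Beverage-type preference weights by sex.
DEFAULT_BEVERAGE_PREFERENCE = {
    "male": {"beer": 0.50, "wine": 0.20, "spirit": 0.22, "rtd": 0.08},
    "female": {"beer": 0.15, "wine": 0.50, "spirit": 0.25, "rtd": 0.10},
}
DEFAULT_SECTOR_SPLIT = {"off": 0.6, "on": 0.4}
DEFAULT_TIER_SPLIT = {"low": 0.5, "high": 0.5}
DEFAULT_DIRICHLET_CONCENTRATION = 8.0


@dataclass
class PopulationConfig:
    """Generator settings for the survey-like population.

    ``n`` individuals are allocated to sex x age cells by ``age_shares``
    (half each sex); abstainer status is Bernoulli per cell; drinkers draw
    mean weekly units from a log-normal with cell-specific median and a
    common log-scale; the peak day is a linear function of the mean per
    sex/age/level cell plus a folded-normal residual; beverage shares are
    Dirichlet around sex-specific preference weights.  Sample weights are
    log-normal with unit mean (survey design-weight heterogeneity).
    """

    n: int = 10_000
    seed: int = 0
    age_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_SHARES))
    abstainer_fraction: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ABSTAINER_FRACTION))
    consumption_median: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSUMPTION_MEDIAN))
    consumption_log_scale: float = DEFAULT_CONSUMPTION_LOG_SCALE
    age_consumption_factor: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_CONSUMPTION_FACTOR))
    binge_slopes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BINGE_SLOPES))
    binge_intercept: float = DEFAULT_BINGE_INTERCEPT
    binge_residual_scale: float = DEFAULT_BINGE_RESIDUAL_SCALE
    beverage_preference: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            s: dict(v) for s, v in DEFAULT_BEVERAGE_PREFERENCE.items()})
    dirichlet_concentration: float = DEFAULT_DIRICHLET_CONCENTRATION
    weight_log_scale: float = 0.3

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for key, frac in self.abstainer_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"abstainer fraction {key} not in [0, 1]")
        if self.consumption_log_scale < 0:
            raise ValueError("log scale must be >= 0")
        for prefs in self.beverage_preference.values():
            if any(v < 0 for v in prefs.values()):
                raise ValueError("preference weights must be >= 0")

    def binge_model(self) -> BingeModel:
        return BingeModel.uniform(dict(self.binge_slopes),
                                  self.binge_intercept)

    def category_preferences(self, sex: str) -> np.ndarray:
        """Preference weight over the 16 categories, normalised to 1."""
        weights = np.array([
            self.beverage_preference[sex][category_beverage(cat)]
            * DEFAULT_SECTOR_SPLIT[category_sector(cat)]
            * DEFAULT_TIER_SPLIT[cat.split("_")[2]]
            for cat in BEVERAGE_CATEGORIES
        ])
        return weights / weights.sum()


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Generate the canonical microdata frame; reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    logger.info("generate_population: seed=%s config=%s n=%s",
                config.seed, _config_hash(config), config.n)
    if config.n == 0:
        return pd.DataFrame(columns=[
            "person_id", "sex", "age_band", "weight", "mean_weekly_units",
            "peak_day_units", *SHARE_COLUMNS])

    share_total = sum(config.age_shares.values())
    cells = [(sex, band) for sex in SEXES for band in AGE_BANDS]
    probs = np.array([
        0.5 * config.age_shares[band] / share_total for sex, band in cells])
    counts = rng.multinomial(config.n, probs / probs.sum())

    sexes, bands = [], []
    for (sex, band), count in zip(cells, counts):
        sexes.extend([sex] * count)
        bands.extend([band] * count)
    sexes, bands = np.array(sexes), np.array(bands)
    n = len(sexes)

    abstain_p = np.array([
        config.abstainer_fraction[(s, b)] for s, b in zip(sexes, bands)])
    abstainer = rng.random(n) < abstain_p

    median = np.array([
        config.consumption_median[s] * config.age_consumption_factor[b]
        for s, b in zip(sexes, bands)])
    mean_units = np.where(
        abstainer, 0.0,
        median * np.exp(config.consumption_log_scale
                        * rng.standard_normal(n)))

    # classification needed to pick the binge slope per individual
    from .population import DEFAULT_THRESHOLDS, classify_drinker
    grams = mean_units * DEFAULT_THRESHOLDS.grams_per_unit
    levels = classify_drinker(sexes, grams)
    slopes = np.array([config.binge_slopes[lv] for lv in levels])
    residual = np.abs(rng.standard_normal(n)) * config.binge_residual_scale
    peak = np.where(
        abstainer, 0.0,
        np.maximum(0.0, config.binge_intercept + slopes * mean_units
                   + residual))

    weight = np.exp(config.weight_log_scale * rng.standard_normal(n))
    weight /= weight.mean()

    shares = np.zeros((n, N_CATEGORIES))
    for sex in SEXES:
        mask = sexes == sex
        alpha = (config.category_preferences(sex)
                 * config.dirichlet_concentration)
        gammas = rng.gamma(np.broadcast_to(alpha, (int(mask.sum()),
                                                   N_CATEGORIES)))
        shares[mask] = gammas / gammas.sum(axis=1, keepdims=True)
    shares[abstainer] = 0.0

    df = pd.DataFrame({
        "person_id": [f"p{i:07d}" for i in range(n)],
        "sex": sexes, "age_band": bands, "weight": weight,
        "mean_weekly_units": mean_units, "peak_day_units": peak,
    })
    df[list(SHARE_COLUMNS)] = shares
    return df


# ---------------------------------------------------------------------------
# Transactions and price-distribution calibration

#: Median usual price (pence per unit) by sector and tier; mildly
#: beverage-dependent.
DEFAULT_PRICE_MEDIAN = {
    ("off", "low"): 32.0, ("off", "high"): 58.0,
    ("on", "low"): 85.0, ("on", "high"): 135.0,
}
DEFAULT_BEVERAGE_PRICE_FACTOR = {
    "beer": 0.95, "wine": 1.00, "spirit": 1.05, "rtd": 1.10,
}
DEFAULT_PRICE_LOG_SCALE = 0.25
DEFAULT_DISCOUNT_INCIDENCE = {"off": 0.30, "on": 0.10}
DEFAULT_DISCOUNT_DEPTH_BETA = (2.0, 6.0)   # mean depth 25%
DEFAULT_MAX_DISCOUNT_DEPTH = 0.6


@dataclass
class PriceConfig:
    """Generator settings for the transaction table.

    Usual prices are log-normal per category; a sold price below the usual
    price occurs with sector-specific incidence and a Beta-distributed
    discount depth.  ``calibration_points`` optionally holds per-category
    (prices, cumulative shares) targets for the price-distribution
    calibration; target shares must be non-decreasing and end at 1.
    """

    seed: int = 0
    price_median: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PRICE_MEDIAN))
    beverage_price_factor: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEVERAGE_PRICE_FACTOR))
    price_log_scale: float = DEFAULT_PRICE_LOG_SCALE
    discount_incidence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISCOUNT_INCIDENCE))
    discount_depth_beta: tuple[float, float] = DEFAULT_DISCOUNT_DEPTH_BETA
    max_discount_depth: float = DEFAULT_MAX_DISCOUNT_DEPTH
    calibration_points: Mapping[str, tuple[Sequence[float],
                                           Sequence[float]]] | None = None

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.price_median.values()):
            raise ValueError("price medians must be > 0")
        if any(not 0 <= p <= 1 for p in self.discount_incidence.values()):
            raise ValueError("discount incidence must be in [0, 1]")
        if not 0 <= self.max_discount_depth < 1:
            raise ValueError("max discount depth must be in [0, 1)")
        if self.calibration_points is not None:
            for cat, (prices, shares) in self.calibration_points.items():
                validate_calibration_points(prices, shares)

    def category_median(self, category: str) -> float:
        bev, sector, tier = category.split("_")
        return (self.price_median[(sector, tier)]
                * self.beverage_price_factor[bev])


def validate_calibration_points(prices: Sequence[float],
                                shares: Sequence[float]) -> None:
    prices = np.asarray(prices, dtype=float)
    shares = np.asarray(shares, dtype=float)
    if prices.ndim != 1 or prices.shape != shares.shape:
        raise ValueError("calibration prices and shares must be aligned")
    if np.any(prices <= 0) or np.any(np.diff(prices) <= 0):
        raise ValueError("calibration prices must be positive and strictly "
                         "increasing")
    if np.any(np.diff(shares) < 0) or np.any(shares < 0) \
            or abs(shares[-1] - 1.0) > 1e-9:
        raise ValueError("target cumulative shares must be non-decreasing "
                         "and end at 1")


def generate_transactions(individuals: pd.DataFrame,
                          price_config: PriceConfig,
                          seed: int | None = None) -> pd.DataFrame:
    """One synthetic week of purchases mirroring each drinker's mix.

    Every drinker contributes one transaction per beverage category with
    positive share, with units = share x mean weekly units, so ethanol
    volume is conserved exactly per individual.  Abstainers contribute no
    rows.
    """
    if seed is None:
        seed = price_config.seed
    rng = np.random.default_rng(seed)
    logger.info("generate_transactions: seed=%s config=%s", seed,
                _config_hash(price_config))
    drinkers = individuals[individuals["mean_weekly_units"] > 0]
    shares = drinkers[list(SHARE_COLUMNS)].to_numpy(float)
    units = shares * drinkers["mean_weekly_units"].to_numpy(float)[:, None]
    person_idx, cat_idx = np.nonzero(shares > 0)

    categories = np.array(BEVERAGE_CATEGORIES)[cat_idx]
    medians = np.array([price_config.category_median(c)
                        for c in BEVERAGE_CATEGORIES])[cat_idx]
    usual = medians * np.exp(price_config.price_log_scale
                             * rng.standard_normal(len(cat_idx)))
    sectors = np.array([category_sector(c) for c in BEVERAGE_CATEGORIES])
    incidence = np.array([price_config.discount_incidence[s]
                          for s in sectors])[cat_idx]
    discounted = rng.random(len(cat_idx)) < incidence
    a, b = price_config.discount_depth_beta
    depth = (rng.beta(a, b, size=len(cat_idx))
             * price_config.max_discount_depth)
    sold = np.where(discounted, usual * (1.0 - depth), usual)

    return pd.DataFrame({
        "person_id": drinkers["person_id"].to_numpy()[person_idx],
        "category": categories,
        "units": units[person_idx, cat_idx],
        "sold_price": sold,
        "usual_price": usual,
        "weight": drinkers["weight"].to_numpy(float)[person_idx],
    })


def _cdf_knots(values, weights) -> tuple[np.ndarray, np.ndarray]:
    """Sorted values and their cumulative-share positions (midpoint
    convention, pinned to 0 and 1 at the extremes)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    pos = (np.cumsum(w) - 0.5 * w) / w.sum()
    pos[0], pos[-1] = 0.0, 1.0
    return v, pos


def weighted_quantile(values, weights, q) -> np.ndarray:
    """Weighted quantile, linearly interpolated; exact inverse of
    :func:`weighted_cdf` wherever the values are distinct."""
    v, pos = _cdf_knots(values, weights)
    return np.interp(q, pos, v)


def weighted_cdf(values, weights, x) -> np.ndarray:
    """Weighted empirical CDF with the interpolation convention matching
    :func:`weighted_quantile` (0 at the minimum, 1 at the maximum)."""
    v, pos = _cdf_knots(values, weights)
    return np.interp(x, v, pos)


def _price_map(values: np.ndarray, weights: np.ndarray,
               target_prices: np.ndarray, target_shares: np.ndarray,
               ) -> np.ndarray:
    """Monotone piecewise-linear map sending the weighted empirical price
    quantile at each target share onto the target price.

    Below the first anchor the first segment's slope is extended (clipped
    away from zero to keep prices positive); above the last anchor prices
    keep their offset.  An affine target therefore reproduces the affine
    map exactly.
    """
    anchors = weighted_quantile(values, weights, target_shares)
    # collapse duplicate anchors (flat CDF stretches) keeping monotonicity
    keep = np.concatenate([[True], np.diff(anchors) > 1e-12])
    a, p = anchors[keep], target_prices[keep]
    out = np.interp(values, a, p)
    below = values < a[0]
    if below.any():
        slope = ((p[1] - p[0]) / (a[1] - a[0])) if len(a) > 1 \
            else p[0] / a[0]
        out[below] = np.maximum(p[0] - (a[0] - values[below]) * slope,
                                0.01 * p[0])
    above = values > a[-1]
    out[above] = values[above] + (p[-1] - a[-1])
    return out


def calibrate_price_distribution(transactions: pd.DataFrame,
                                 calibration_points: Mapping[
                                     str, tuple[Sequence[float],
                                                Sequence[float]]],
                                 ) -> pd.DataFrame:
    """Adjust sold prices so the weighted cumulative price distribution
    matches target shares at the calibration price points.

    Applied per beverage category with weights = weight x units.  The
    adjustment is a monotone piecewise-linear map on the price axis, so
    price order is never changed; usual prices are shifted by the same map
    and volumes are untouched.  Categories without calibration targets
    pass through unchanged.
    """
    out = transactions.copy()
    sold = out["sold_price"].to_numpy(float).copy()
    usual = out["usual_price"].to_numpy(float).copy()
    w = out["weight"].to_numpy(float) * out["units"].to_numpy(float)
    for category, (prices, shares) in calibration_points.items():
        validate_calibration_points(prices, shares)
        prices = np.asarray(prices, dtype=float)
        shares = np.asarray(shares, dtype=float)
        mask = (out["category"] == category).to_numpy()
        if not mask.any():
            continue
        sold[mask] = _price_map(sold[mask], w[mask], prices, shares)
        usual[mask] = _price_map(usual[mask], w[mask], prices, shares)
    usual = np.maximum(usual, sold)
    out["sold_price"], out["usual_price"] = sold, usual
    return out


# ---------------------------------------------------------------------------
# Baseline harm-rate tables

@dataclass
class ConditionConfig:
    """Template for one synthetic health condition."""

    condition_id: str
    timing: str                    # chronic | acute
    attribution: str               # wholly | partially
    basis: str                     # mean_weekly | peak_day
    mortality_scale: float         # deaths/person-year at ages 45-54, male
    admission_scale: float         # admissions/person-year, same anchor
    unit_cost: float               # £ per admission-year
    utility_decrement: float       # QALY loss per prevalent case-year
    aaf: Mapping[tuple[str, str], float] | float | None = None
    #: Tabulated RR-vs-consumption curve (x units, RR) for chronic
    #: partially-attributable conditions; synthetic stand-in for a
    #: published curve, interpolated linearly at evaluation.
    curve: tuple[Sequence[float], Sequence[float]] | None = None

    def aaf_for(self, sex: str, band: str) -> float | None:
        if self.aaf is None:
            return None
        if isinstance(self.aaf, Mapping):
            return self.aaf[(sex, band)]
        return float(self.aaf)


#: Age gradient of baseline rates relative to the 45-54 anchor.
_AGE_RATE_FACTOR = {
    "11-15": 0.02, "16-17": 0.05, "18-24": 0.12, "25-34": 0.30,
    "35-44": 0.60, "45-54": 1.00, "55-64": 1.70, "65-74": 2.60, "75+": 4.00,
}
#: Acute harms skew young instead.
_AGE_RATE_FACTOR_ACUTE = {
    "11-15": 0.15, "16-17": 0.60, "18-24": 1.40, "25-34": 1.20,
    "35-44": 1.00, "45-54": 0.80, "55-64": 0.60, "65-74": 0.50, "75+": 0.60,
}
_SEX_RATE_FACTOR = {"male": 1.0, "female": 0.6}


def default_condition_configs() -> list[ConditionConfig]:
    """A compact synthetic condition catalogue spanning the four harm
    classes (stand-in for a full 47-condition table)."""
    aaf_rta = {
        (sex, band): 0.37 if (sex, band) == ("male", "25-34")
        else (0.30 if sex == "male" else 0.18)
        for sex in SEXES for band in AGE_BANDS
    }
    return [
        ConditionConfig("alcoholic_liver_disease", "chronic", "wholly",
                        "mean_weekly", 1.5e-4, 8e-4, 4200.0, 0.18),
        ConditionConfig("alcohol_poisoning", "acute", "wholly",
                        "peak_day", 1.2e-5, 2.5e-4, 900.0, 0.05),
        ConditionConfig("oesophageal_cancer", "chronic", "partially",
                        "mean_weekly", 1.1e-4, 3e-4, 6100.0, 0.25,
                        curve=([0, 7, 14, 28, 56, 112, 200],
                               [1.0, 1.1, 1.3, 1.8, 3.0, 5.5, 9.0])),
        ConditionConfig("hypertensive_disease", "chronic", "partially",
                        "mean_weekly", 6e-5, 1.5e-3, 800.0, 0.06,
                        curve=([0, 7, 14, 28, 56, 112, 200],
                               [1.0, 1.05, 1.15, 1.4, 1.9, 2.8, 3.8])),
        ConditionConfig("epilepsy", "chronic", "partially",
                        "mean_weekly", 2e-5, 5e-4, 1500.0, 0.12,
                        curve=([0, 14, 28, 56, 112, 200],
                               [1.0, 1.1, 1.35, 1.9, 3.2, 5.0])),
        ConditionConfig("road_traffic_accidents", "acute", "partially",
                        "peak_day", 6e-5, 6e-4, 7300.0, 0.15, aaf=aaf_rta),
        ConditionConfig("falls", "acute", "partially",
                        "peak_day", 4e-5, 1.2e-3, 2100.0, 0.10, aaf=0.25),
        ConditionConfig("assault_injury", "acute", "partially",
                        "peak_day", 1.5e-5, 7e-4, 1700.0, 0.08, aaf=0.40),
    ]


def generate_baseline_harms(condition_configs: Sequence[ConditionConfig]
                            | None = None) -> pd.DataFrame:
    """Baseline harm-rate table: one row per condition x sex x age band.

    Columns: condition_id, timing, attribution, basis, sex, age_band,
    mortality_rate, admission_rate, aaf (NaN for wholly-attributable),
    unit_cost, utility_decrement.  Rejects AAFs outside [0, 1] and reports
    any missing cells.
    """
    if condition_configs is None:
        condition_configs = default_condition_configs()
    rows = []
    for cond in condition_configs:
        age_factor = (_AGE_RATE_FACTOR_ACUTE if cond.timing == "acute"
                      else _AGE_RATE_FACTOR)
        for sex in SEXES:
            for band in AGE_BANDS:
                factor = age_factor[band] * _SEX_RATE_FACTOR[sex]
                aaf = cond.aaf_for(sex, band)
                if aaf is not None and not 0.0 <= aaf <= 1.0:
                    raise ValueError(
                        f"AAF for {cond.condition_id} ({sex}, {band}) "
                        f"outside [0, 1]: {aaf}")
                rows.append({
                    "condition_id": cond.condition_id,
                    "timing": cond.timing,
                    "attribution": cond.attribution,
                    "basis": cond.basis,
                    "sex": sex, "age_band": band,
                    "mortality_rate": min(1.0, cond.mortality_scale * factor),
                    "admission_rate": min(1.0, cond.admission_scale * factor),
                    "aaf": np.nan if aaf is None else aaf,
                    "unit_cost": cond.unit_cost,
                    "utility_decrement": cond.utility_decrement,
                })
    table = pd.DataFrame(rows)
    expected = len(condition_configs) * len(SEXES) * len(AGE_BANDS)
    if len(table) != expected:
        raise ValueError("incomplete harm-rate table")
    return table


def validate_harm_table(table: pd.DataFrame,
                        condition_ids: Sequence[str]) -> None:
    """Reject harm tables with missing condition x sex x age cells."""
    gaps = []
    have = set(zip(table["condition_id"], table["sex"], table["age_band"]))
    for cond in condition_ids:
        for sex in SEXES:
            for band in AGE_BANDS:
                if (cond, sex, band) not in have:
                    gaps.append((cond, sex, band))
    if gaps:
        raise ValueError(f"harm table missing {len(gaps)} cells, e.g. "
                         f"{gaps[:5]}")
    bad = table[(table["mortality_rate"] < 0) | (table["mortality_rate"] > 1)
                | (table["admission_rate"] < 0)
                | (table["admission_rate"] > 1)]
    if len(bad):
        raise ValueError("harm rates must lie in [0, 1] per person-year")


# ---------------------------------------------------------------------------
# Other configuration tables

def default_life_table() -> LifeTable:
    """Synthetic all-cause life table: Gompertz mortality with a female
    advantage, and a gently declining population utility norm."""
    rows = []
    for sex in SEXES:
        sex_factor = 1.0 if sex == "male" else 0.82
        for age in range(11, 106):
            mortality = min(0.7, 5e-5 * np.exp(0.088 * (age - 11))
                            * sex_factor)
            utility = max(0.45, 0.94 - 0.0035 * max(0, age - 35))
            rows.append({"sex": sex, "age": age, "mortality": mortality,
                         "utility": utility})
    return LifeTable(pd.DataFrame(rows))


def default_elasticity_matrices() -> dict[str, ElasticityMatrix]:
    """Deterministic elasticity matrices per demand segment: negative
    own-price terms with small positive substitution toward the same
    beverage in other sector/tier slots; heavier drinkers slightly more
    price-responsive (as the purchase-diary estimation found)."""
    own = {"moderate": -0.50, "hazardous_harmful": -0.55}
    cross = 0.02
    matrices = {}
    for segment in SEGMENTS:
        values = np.zeros((N_CATEGORIES, N_CATEGORIES))
        for i, cat_i in enumerate(BEVERAGE_CATEGORIES):
            for j, cat_j in enumerate(BEVERAGE_CATEGORIES):
                if i == j:
                    values[i, j] = own[segment]
                elif category_beverage(cat_i) == category_beverage(cat_j):
                    values[i, j] = cross
        matrices[segment] = ElasticityMatrix(segment, values)
    return matrices


def default_crime_categories() -> list[CrimeCategory]:
    """Twenty synthetic crime classifications across six broad groups."""
    groups = [
        ("violent_disorder", 3, 120_000, 1.8, 2800.0, 0.015, 0.45),
        ("wounding", 4, 90_000, 3.0, 8600.0, 0.030, 0.40),
        ("assault_no_injury", 3, 150_000, 2.2, 1400.0, 0.008, 0.35),
        ("vehicle_theft", 3, 110_000, 1.5, 900.0, 0.002, 0.12),
        ("burglary_robbery_theft", 4, 140_000, 1.6, 1800.0, 0.004, 0.15),
        ("criminal_damage", 3, 160_000, 2.0, 700.0, 0.002, 0.25),
    ]
    categories = []
    for name, count, volume, mult, cost, qaly, aaf in groups:
        for k in range(1, count + 1):
            categories.append(CrimeCategory(
                f"{name}_{k}", baseline_volume=volume / count,
                multiplier=mult, unit_cost=cost, victim_qaly_loss=qaly,
                aaf=aaf))
    assert len(categories) == 20
    return categories


def default_offender_apportionment(categories: Sequence[CrimeCategory],
                                   ) -> pd.DataFrame:
    """Offender-distribution weights per (sex, age band) x category.

    16-17 and 18-24 split the youth share equally; rates decline linearly
    from 35 upwards; columns sum to 1.
    """
    band_weights = {
        "11-15": 0.07, "16-17": 0.105, "18-24": 0.105, "25-34": 0.30,
        "35-44": 0.16, "45-54": 0.12, "55-64": 0.08, "65-74": 0.04,
        "75+": 0.02,
    }
    sex_weights = {"male": 0.8, "female": 0.2}
    index = pd.MultiIndex.from_product([SEXES, AGE_BANDS],
                                       names=["sex", "age_band"])
    base = pd.Series(
        [sex_weights[s] * band_weights[b] for s, b in index], index=index)
    base /= base.sum()
    return pd.DataFrame(
        {cat.category_id: base for cat in categories})


def default_workplace_params() -> WorkplaceParams:
    """Workplace baselines: absence days, unemployment, salaries and
    participation per working-age (sex, band) cell."""
    participation = {
        **{("male", band): 0.85 for band in WORKING_AGE_BANDS},
        **{("female", band): 0.72 for band in WORKING_AGE_BANDS},
        ("male", "16-17"): 0.45, ("female", "16-17"): 0.45,
    }
    salary_by_band = {"16-17": 9_000.0, "18-24": 17_000.0,
                      "25-34": 25_000.0, "35-44": 28_000.0,
                      "45-54": 28_000.0, "55-64": 24_000.0}
    salaries = {
        (sex, band): salary_by_band[band] * (1.0 if sex == "male" else 0.82)
        for sex in SEXES for band in WORKING_AGE_BANDS
    }
    absence_days = {
        (sex, band): 400_000.0 * (1.2 if sex == "male" else 1.0)
        for sex in SEXES for band in WORKING_AGE_BANDS
    }
    unemployed = {
        (sex, band): 60_000.0 * (1.1 if sex == "male" else 0.9)
        for sex in SEXES for band in WORKING_AGE_BANDS
    }
    return WorkplaceParams(
        baseline_absence_days=absence_days,
        baseline_unemployed=unemployed,
        average_salary=salaries,
        participation=participation,
    )
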