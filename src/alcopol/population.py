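"""Survey microdata types and deterministic subgroup classification.

The model population is a weighted cross-sectional sample of individuals
(GHS-style): each record carries a household sample weight, a mean weekly
alcohol consumption (UK units, 1 unit = 8 g ethanol), a peak single-day
consumption, and a mix of shares over 16 beverage categories (beer / wine /
spirit / RTD x on-trade / off-trade x low-priced / high-priced).

Individuals are partitioned into 54 subgroups: 2 sexes x 9 age bands x 3
drinking levels.  Drinking levels follow the UK guideline cut-offs —
moderate (<= 168 g/week men, 112 g/week women), hazardous (above the limit
but not harmful) and harmful (> 400 g/week men, 280 g/week women).  Binge
status is a separate flag: peak-day intake above twice the daily guideline
(> 64 g men, > 48 g women).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GRAMS_PER_UNIT = 8.0

SEXES = ("male", "female")

AGE_BANDS = (
    "11-15", "16-17", "18-24", "25-34", "35-44",
    "45-54", "55-64", "65-74", "75+",
)

#: Lower edge of each band in completed years (bands are half-open on age).
AGE_BAND_START = {
    "11-15": 11, "16-17": 16, "18-24": 18, "25-34": 25, "35-44": 35,
    "45-54": 45, "55-64": 55, "65-74": 65, "75+": 75,
}

#: Representative (midpoint) age used by the cohort projection.
AGE_BAND_MIDPOINT = {
    "11-15": 13, "16-17": 16, "18-24": 21, "25-34": 30, "35-44": 40,
    "45-54": 50, "55-64": 60, "65-74": 70, "75+": 80,
}

DRINKER_LEVELS = ("moderate", "hazardous", "harmful")

BEVERAGE_TYPES = ("beer", "wine", "spirit", "rtd")
SECTORS = ("off", "on")
PRICE_TIERS = ("low", "high")

#: The 16 beverage categories in canonical order.
BEVERAGE_CATEGORIES = tuple(
    f"{bev}_{sector}_{tier}"
    for bev in BEVERAGE_TYPES
    for sector in SECTORS
    for tier in PRICE_TIERS
)

SHARE_COLUMNS = tuple(f"share_{c}" for c in BEVERAGE_CATEGORIES)


def category_sector(category: str) -> str:
    """Return 'on' or 'off' for one of the 16 beverage categories."""
    bev, sector, tier = category.split("_")
    return sector


def category_beverage(category: str) -> str:
    return category.split("_")[0]


@dataclass(frozen=True)
class Thresholds:
    """Classification cut-offs in grams of ethanol.

    ``moderate_max_g``: heaviest weekly intake still within guidelines.
    ``harmful_min_g``: weekly intake strictly above which drinking is
    harmful; equality is classified hazardous (closed upper bound on the
    hazardous band).  ``binge_min_g``: peak-day intake strictly above which
    the individual is a binge drinker.
    """

    moderate_max_g: Mapping[str, float] = field(
        default_factory=lambda: {"male": 168.0, "female": 112.0})
    harmful_min_g: Mapping[str, float] = field(
        default_factory=lambda: {"male": 400.0, "female": 280.0})
    binge_min_g: Mapping[str, float] = field(
        default_factory=lambda: {"male": 64.0, "female": 48.0})
    grams_per_unit: float = GRAMS_PER_UNIT

    def __post_init__(self) -> None:
        for sex in SEXES:
            if not 0 < self.moderate_max_g[sex] < self.harmful_min_g[sex]:
                raise ValueError(
                    f"thresholds for {sex}: need 0 < moderate_max "
                    f"< harmful_min")
            if self.binge_min_g[sex] <= 0:
                raise ValueError(f"binge threshold for {sex} must be > 0")
        if self.grams_per_unit <= 0:
            raise ValueError("grams_per_unit must be > 0")

    def moderate_max_units(self, sex: str) -> float:
        return self.moderate_max_g[sex] / self.grams_per_unit

    def harmful_min_units(self, sex: str) -> float:
        return self.harmful_min_g[sex] / self.grams_per_unit

    def binge_min_units(self, sex: str) -> float:
        return self.binge_min_g[sex] / self.grams_per_unit


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True, order=True)
class SubgroupKey:
    """One of the 54 modelled subgroups: sex x age band x drinking level."""

    sex: str
    age_band: str
    drinker_level: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.drinker_level not in DRINKER_LEVELS:
            raise ValueError(f"unknown drinker level {self.drinker_level!r}")


def all_subgroups() -> list[SubgroupKey]:
    """The 54 subgroup keys in canonical (sex, age, level) order."""
    return [
        SubgroupKey(sex, band, level)
        for sex in SEXES for band in AGE_BANDS for level in DRINKER_LEVELS
    ]


@dataclass
class Individual:
    """A single weighted survey respondent.

    Consumption is in UK units; ``beverage_shares`` maps the 16 categories
    to non-negative shares summing to 1 for drinkers (ignored, and allowed
    empty, for abstainers).
    """

    person_id: str
    sex: str
    age_band: str
    weight: float
    mean_weekly_units: float
    peak_day_units: float
    beverage_shares: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.mean_weekly_units < 0 or self.peak_day_units < 0:
            raise ValueError("consumption must be >= 0")
        if self.mean_weekly_units > 0:
            total = sum(self.beverage_shares.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"beverage shares for drinker {self.person_id} sum to "
                    f"{total}, expected 1")
            if any(v < 0 for v in self.beverage_shares.values()):
                raise ValueError("beverage shares must be non-negative")


def individuals_to_frame(individuals: Iterable[Individual]) -> pd.DataFrame:
    """Build the canonical microdata frame from Individual records."""
    rows = []
    for ind in individuals:
        row = {
            "person_id": ind.person_id,
            "sex": ind.sex,
            "age_band": ind.age_band,
            "weight": ind.weight,
            "mean_weekly_units": ind.mean_weekly_units,
            "peak_day_units": ind.peak_day_units,
        }
        for cat, col in zip(BEVERAGE_CATEGORIES, SHARE_COLUMNS):
            row[col] = float(ind.beverage_shares.get(cat, 0.0))
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["person_id", "sex", "age_band", "weight",
                 "mean_weekly_units", "peak_day_units", *SHARE_COLUMNS],
    )


def _as_grams_array(value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("consumption in grams must be non-negative")
    return arr


def classify_drinker(sex, mean_weekly_grams,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS):
    """Classify weekly intake (grams) into moderate / hazardous / harmful.

    Vectorised: ``sex`` and ``mean_weekly_grams`` may be scalars or aligned
    arrays.  The guideline boundary itself is moderate; the harmful boundary
    itself is hazardous.  Abstainers (0 g) are moderate.
    """
    grams = _as_grams_array(mean_weekly_grams)
    sexes = np.asarray(sex)
    scalar = grams.ndim == 0 and sexes.ndim == 0
    grams, sexes = np.atleast_1d(grams), np.atleast_1d(sexes)
    if sexes.shape != grams.shape:
        sexes = np.broadcast_to(sexes, grams.shape)
    if grams.size == 0:
        return np.empty(0, dtype=object)
    mod_max = np.vectorize(thresholds.moderate_max_g.__getitem__)(sexes)
    harm_min = np.vectorize(thresholds.harmful_min_g.__getitem__)(sexes)
    out = np.where(
        grams <= mod_max, "moderate",
        np.where(grams > harm_min, "harmful", "hazardous"))
    return out.item() if scalar else out


def classify_binge(sex, peak_day_grams,
                   thresholds: Thresholds = DEFAULT_THRESHOLDS):
    """True iff peak-day intake (grams) strictly exceeds the binge cut-off."""
    grams = _as_grams_array(peak_day_grams)
    sexes = np.asarray(sex)
    scalar = grams.ndim == 0 and sexes.ndim == 0
    grams, sexes = np.atleast_1d(grams), np.atleast_1d(sexes)
    if sexes.shape != grams.shape:
        sexes = np.broadcast_to(sexes, grams.shape)
    if grams.size == 0:
        return np.zeros(0, dtype=bool)
    binge_min = np.vectorize(thresholds.binge_min_g.__getitem__)(sexes)
    out = grams > binge_min
    return bool(out.item()) if scalar else out


def classify_individuals(individuals: pd.DataFrame,
                         thresholds: Thresholds = DEFAULT_THRESHOLDS,
                         ) -> pd.DataFrame:
    """Return a copy with ``drinker_level`` and ``binge`` columns added.

    Consumption columns are in units; the gram thresholds are applied after
    conversion, so classification in grams and in units agree identically.
    """
    unknown = set(individuals["age_band"]) - set(AGE_BANDS)
    if unknown:
        raise ValueError(f"unknown age bands: {sorted(unknown)}")
    out = individuals.copy()
    grams_wk = out["mean_weekly_units"].to_numpy(float) * thresholds.grams_per_unit
    grams_day = out["peak_day_units"].to_numpy(float) * thresholds.grams_per_unit
    out["drinker_level"] = classify_drinker(
        out["sex"].to_numpy(), grams_wk, thresholds)
    out["binge"] = classify_binge(out["sex"].to_numpy(), grams_day, thresholds)
    return out


def assign_subgroups(individuals: pd.DataFrame,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS,
                     ) -> dict[str, SubgroupKey]:
    """Map each person_id to its SubgroupKey.

    The assignment is a partition: every individual lands in exactly one of
    the 54 subgroups and total weight is conserved by construction.
    """
    classified = classify_individuals(individuals, thresholds)
    return {
        row.person_id: SubgroupKey(row.sex, row.age_band, row.drinker_level)
        for row in classified.itertuples(index=False)
    }


def subgroup_weights(individuals: pd.DataFrame,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS,
                     ) -> pd.Series:
    """Total sample weight per (sex, age_band, drinker_level) subgroup."""
    classified = classify_individuals(individuals, thresholds)
    return classified.groupby(
        ["sex", "age_band", "drinker_level"], observed=True)["weight"].sum()


# ---------------------------------------------------------------------------
# Microdata I/O: CSV with a JSON sidecar stating column units.

_SCHEMA = {
    "person_id": "opaque identifier",
    "sex": "male|female",
    "age_band": "|".join(AGE_BANDS),
    "weight": "population persons represented (dimensionless weight)",
    "mean_weekly_units": "UK units/week (1 unit = 8 g ethanol)",
    "peak_day_units": "UK units on the heaviest day",
    **{col: "share of weekly ethanol volume, [0, 1]" for col in SHARE_COLUMNS},
}


def write_individuals(individuals: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    individuals.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".schema.json")
    sidecar.write_text(json.dumps(_SCHEMA, indent=2))


def read_individuals(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"person_id", "sex", "age_band", "weight",
               "mean_weekly_units", "peak_day_units"} - set(df.columns)
    if missing:
        raise ValueError(f"microdata file missing columns: {sorted(missing)}")
    return df
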