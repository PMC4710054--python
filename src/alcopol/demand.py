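"""Demand response: elasticity-driven consumption updates.

The price-to-consumption link is first order in percent space: with the
16x16 elasticity matrix E for a demand segment (entry (i, j) = percent
change in consumption of category i per 1% price change of category j) and
the vector dp of mean percent price changes, the segment's vector of
percent consumption changes is dc = E dp.  Those aggregate category changes
are then pushed down onto each individual's beverage mix, the new mean
weekly consumption is the share-weighted sum of the scaled category
volumes, and the peak-day consumption is revised through the linear binge
model for the individual's sex/age/drinker cell while preserving the
individual's residual around the fit.

Elasticity uncertainty is propagated by multivariate-normal draws of the
coefficient vector through a triangular (Cholesky) factor of the supplied
covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .population import (AGE_BANDS, BEVERAGE_CATEGORIES, DRINKER_LEVELS,
                         SEXES, SHARE_COLUMNS)
from .pricing import SEGMENTS

N_CATEGORIES = len(BEVERAGE_CATEGORIES)


@dataclass
class ElasticityMatrix:
    """Own- and cross-price elasticities for one demand segment."""

    segment: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_CATEGORIES, N_CATEGORIES):
            raise ValueError(
                f"elasticity matrix must be {N_CATEGORIES}x{N_CATEGORIES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("elasticity entries must be finite")
        if np.any(np.diag(self.values) > 0):
            warnings.warn(
                f"positive own-price elasticities in segment {self.segment}",
                stacklevel=2)

    @classmethod
    def from_csv(cls, path: str | Path, segment: str) -> "ElasticityMatrix":
        df = pd.read_csv(path, index_col=0)
        df = df.loc[list(BEVERAGE_CATEGORIES), list(BEVERAGE_CATEGORIES)]
        return cls(segment, df.to_numpy(float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(BEVERAGE_CATEGORIES),
                     columns=list(BEVERAGE_CATEGORIES)).to_csv(path)


def consumption_change_vector(price_changes, elasticity: ElasticityMatrix,
                              multiplicative: bool = False) -> np.ndarray:
    """dc_i = sum_j E_ij dp_j, percent in, percent out.

    ``multiplicative=True`` switches to the constant-elasticity form
    dc_i = 100 * (prod_j (1 + dp_j/100)^E_ij - 1), identical to first
    order and offered as a sensitivity variant.
    """
    dp = np.asarray(price_changes, dtype=float)
    if dp.shape != (N_CATEGORIES,):
        raise ValueError(f"price change vector must have {N_CATEGORIES} "
                         f"entries, got shape {dp.shape}")
    if multiplicative:
        if np.any(dp <= -100):
            raise ValueError("price changes must be > -100% in "
                             "multiplicative form")
        log_factors = elasticity.values @ np.log1p(dp / 100.0)
        return 100.0 * np.expm1(log_factors)
    return elasticity.values @ dp


@dataclass
class BingeModel:
    """Linear peak-from-mean models per sex x age band x drinker level.

    ``coefficients`` maps (sex, age_band, drinker_level) to (intercept,
    slope): expected peak_day_units = intercept + slope * mean_weekly_units.
    Only the slope enters the policy update, which shifts each individual's
    peak by slope * (new mean - old mean) so the residual around the fit is
    preserved.
    """

    coefficients: Mapping[tuple[str, str, str], tuple[float, float]]

    def __post_init__(self) -> None:
        for key, (intercept, slope) in self.coefficients.items():
            if not (np.isfinite(intercept) and np.isfinite(slope)):
                raise ValueError(f"non-finite binge coefficients for {key}")

    def slope_for(self, sex: str, age_band: str, level: str) -> float:
        try:
            return self.coefficients[(sex, age_band, level)][1]
        except KeyError:
            raise KeyError(
                f"no binge model for cell ({sex}, {age_band}, {level})")

    @classmethod
    def uniform(cls, slopes_by_level: Mapping[str, float],
                intercept: float = 0.0) -> "BingeModel":
        coeffs = {
            (sex, band, level): (intercept, slopes_by_level[level])
            for sex in SEXES for band in AGE_BANDS
            for level in DRINKER_LEVELS
        }
        return cls(coeffs)


def apply_consumption_changes(individuals: pd.DataFrame,
                              changes_by_segment: Mapping[str, np.ndarray],
                              segment_assignment: pd.Series) -> pd.DataFrame:
    """Adjust each drinker's mean consumption by the category changes of
    its demand segment.

    New mean = sum over categories of share * mean * (1 + dc_cat/100),
    floored at zero per category; shares are re-normalised over the new
    mix.  Abstainers are unchanged.
    """
    out = individuals.copy()
    seg = out["person_id"].map(segment_assignment)
    if seg.isna().any():
        raise ValueError("segment assignment missing for some persons")
    mean = out["mean_weekly_units"].to_numpy(float)
    shares = out[list(SHARE_COLUMNS)].to_numpy(float)
    factors = np.ones((len(out), N_CATEGORIES))
    for segment, dc in changes_by_segment.items():
        dc = np.asarray(dc, dtype=float)
        if dc.shape != (N_CATEGORIES,):
            raise ValueError("category change vector must have 16 entries")
        mask = (seg == segment).to_numpy()
        factors[mask] = np.maximum(0.0, 1.0 + dc / 100.0)
    category_units = shares * mean[:, None] * factors
    new_mean = category_units.sum(axis=1)
    drinker = mean > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        new_shares = np.where(
            (new_mean > 0)[:, None], category_units / new_mean[:, None],
            shares)
    out["mean_weekly_units"] = np.where(drinker, new_mean, mean)
    out[list(SHARE_COLUMNS)] = np.where(drinker[:, None], new_shares, shares)
    return out


def update_peak(individuals: pd.DataFrame, old_mean, new_mean,
                binge_model: BingeModel) -> pd.DataFrame:
    """Revise peak-day consumption through the linear binge model.

    peak' = max(0, peak + slope * (new_mean - old_mean)) with the slope
    looked up per (sex, age band, baseline drinker level); the residual
    around the fitted line is carried over unchanged.  ``individuals`` must
    already carry a ``drinker_level`` column (baseline level).
    """
    if "drinker_level" not in individuals.columns:
        raise ValueError("individuals need a baseline drinker_level column")
    out = individuals.copy()
    slopes = np.array([
        binge_model.slope_for(sex, band, level)
        for sex, band, level in zip(out["sex"], out["age_band"],
                                    out["drinker_level"])
    ])
    delta = np.asarray(new_mean, dtype=float) - np.asarray(old_mean, float)
    out["peak_day_units"] = np.maximum(
        0.0, out["peak_day_units"].to_numpy(float) + slopes * delta)
    return out


def apply_relative_change(individuals: pd.DataFrame, percent: float,
                          binge_model: BingeModel | None = None,
                          ) -> pd.DataFrame:
    """Scale every drinker's mean consumption by (1 + percent/100).

    Used for advertising/availability what-ifs where the evidence gives a
    relative consumption change directly.  If a binge model is supplied the
    peak is revised through it as well.
    """
    if percent <= -100:
        raise ValueError("percent must be > -100")
    out = individuals.copy()
    old_mean = out["mean_weekly_units"].to_numpy(float)
    new_mean = old_mean * (1.0 + percent / 100.0)
    out["mean_weekly_units"] = new_mean
    if binge_model is not None:
        out = update_peak(out, old_mean, new_mean, binge_model)
    return out


@dataclass
class ElasticityUncertainty:
    """Sampling model for elasticity-coefficient uncertainty.

    ``mean`` is the flattened coefficient vector (row-major 16x16 = 256 for
    a full matrix); ``covariance`` its positive semi-definite covariance.
    """

    mean: np.ndarray
    covariance: np.ndarray
    segment: str = "moderate"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        k = self.mean.size
        if self.covariance.shape != (k, k):
            raise ValueError("covariance shape must match mean length")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(self.covariance)
        if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
            raise ValueError("covariance must be positive semi-definite")


def sample_elasticity_matrices(uncertainty: ElasticityUncertainty,
                               n_draws: int, seed: int | None = None,
                               ) -> list[ElasticityMatrix]:
    """Draw elasticity matrices from N(mean, covariance).

    Draws use a lower-triangular factor L with L L^T = covariance (Cholesky
    with a symmetric-eigendecomposition fallback for singular covariances):
    draw = mean + L z, z ~ N(0, I).  Reproducible by seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    k = uncertainty.mean.size
    if k != N_CATEGORIES * N_CATEGORIES:
        raise ValueError(
            "coefficient vector does not flatten to a 16x16 matrix")
    cov = uncertainty.covariance
    try:
        factor = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eigvals, eigvecs = np.linalg.eigh(cov)
        factor = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, k))
    draws = uncertainty.mean[None, :] + z @ factor.T
    return [
        ElasticityMatrix(uncertainty.segment,
                         row.reshape(N_CATEGORIES, N_CATEGORIES))
        for row in draws
    ]
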