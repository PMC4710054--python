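"""Relative-risk curves, attributable fractions and the potential impact
fraction.

Harms are tied to consumption through relative-risk (RR) functions on one of
two bases: mean weekly units (chronic conditions) or peak single-day units
(acute conditions, crime, absence).  Where published continuous curves exist
(chronic partially-attributable conditions) they are supplied as tabulated
RR-vs-units points and interpolated.  Everywhere else a two-part linear form
is used: RR = 1 up to a threshold T and 1 + s*(c - T) above it, with the
slope s calibrated so that the implied alcohol-attributable fraction (AAF)
over the weighted population

    AAF = sum_i w_i (RR_i - 1) / sum_i w_i RR_i

matches an observed target, or (for wholly-attributable harms) so that the
expected incident volume matches the observed volume.

A policy-induced change of the consumption distribution scales each harm's
baseline absolute rate by (1 - PIF) with the potential impact fraction

    PIF = 1 - sum_i w_i RR'_i / sum_i w_i RR_i ,

where RR' is evaluated at post-policy consumption.  Setting the
counterfactual consumption to zero makes the PIF equal the AAF exactly,
which is the calibration/validation identity the whole chain relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Peak-day thresholds (units/day) below which acute RR = 1.
ACUTE_THRESHOLD_UNITS_DAY = {"male": 4.0, "female": 3.0}

#: Mean-consumption thresholds (units/day) for chronic wholly-attributable
#: harms; converted to the weekly basis with x7.
CHRONIC_WHOLLY_THRESHOLD_UNITS_DAY = {"male": 3.0, "female": 2.0}

DAYS_PER_WEEK = 7.0


class InfeasibleCalibration(ValueError):
    """Raised when no slope can reproduce the calibration target
    (e.g. a positive target AAF with no consumption mass above threshold)."""


@dataclass
class ConsumptionState:
    """Weighted basis-consumption values for one scenario.

    ``values`` are on the risk function's basis scale (mean weekly or peak
    day units); ``weights`` are sample weights.
    """

    values: np.ndarray
    weights: np.ndarray
    scenario: str = "baseline"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights must be aligned")
        if np.any(self.values < 0):
            raise ValueError("consumption values must be non-negative")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    def zeroed(self) -> "ConsumptionState":
        """The zero-consumption counterfactual on the same population."""
        return ConsumptionState(
            np.zeros_like(self.values), self.weights, "zero-counterfactual")


@dataclass
class RiskFunction:
    """An RR curve for one condition, either two-part linear or tabulated.

    ``basis`` in {mean_weekly, peak_day}; ``attribution`` in
    {wholly, partially}; ``timing`` in {chronic, acute}; ``form`` in
    {two_part_linear, published_curve}.  For the two-part form ``threshold``
    is in basis units and ``slope`` is the RR increase per unit above it.
    Published curves interpolate linearly between (curve_x, curve_rr) points
    and are held flat beyond the tabulated range.
    """

    condition_id: str
    basis: str = "mean_weekly"
    attribution: str = "partially"
    timing: str = "chronic"
    form: str = "two_part_linear"
    threshold: float = 0.0
    slope: float = 0.0
    curve_x: Sequence[float] | None = None
    curve_rr: Sequence[float] | None = None
    sex: str | None = None
    age_bands: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.basis not in ("mean_weekly", "peak_day"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.attribution not in ("wholly", "partially"):
            raise ValueError(f"unknown attribution {self.attribution!r}")
        if self.timing not in ("chronic", "acute"):
            raise ValueError(f"unknown timing {self.timing!r}")
        if self.form == "two_part_linear":
            if self.threshold < 0 or self.slope < 0:
                raise ValueError("threshold and slope must be >= 0")
        elif self.form == "published_curve":
            x = np.asarray(self.curve_x, dtype=float)
            rr = np.asarray(self.curve_rr, dtype=float)
            if x.ndim != 1 or x.shape != rr.shape or len(x) < 2:
                raise ValueError("curve needs >= 2 aligned (x, RR) points")
            if np.any(np.diff(x) <= 0):
                raise ValueError("curve x must be strictly increasing")
            if np.any(rr < 0):
                raise ValueError("curve RR must be non-negative")
            self.curve_x, self.curve_rr = x, rr
        else:
            raise ValueError(f"unknown form {self.form!r}")


def evaluate_rr(risk_function: RiskFunction, consumption) -> np.ndarray | float:
    """Relative risk at the given basis consumption (scalar or array)."""
    c = np.asarray(consumption, dtype=float)
    if np.any(c < 0):
        raise ValueError("consumption must be non-negative")
    if risk_function.form == "two_part_linear":
        rr = 1.0 + risk_function.slope * np.maximum(
            0.0, c - risk_function.threshold)
    else:
        rr = np.interp(c, risk_function.curve_x, risk_function.curve_rr)
    return float(rr) if np.isscalar(consumption) else rr


def _weighted_rr_sums(risk_function: RiskFunction,
                      state: ConsumptionState) -> tuple[float, float]:
    rr = evaluate_rr(risk_function, state.values)
    w = state.weights
    return float(np.sum(w * rr)), float(np.sum(w))


def implied_aaf(risk_function: RiskFunction, state: ConsumptionState) -> float:
    """Alcohol-attributable fraction implied by the RR curve on a population:
    excess risk over total risk, sum w(RR-1) / sum w RR."""
    wrr, w = _weighted_rr_sums(risk_function, state)
    if w <= 0:
        raise ValueError("population weight must be positive")
    return (wrr - w) / wrr


def potential_impact_fraction(risk_function: RiskFunction,
                              state_before: ConsumptionState,
                              state_after: ConsumptionState) -> float:
    """PIF = 1 - sum w RR_after / sum w RR_before.

    Positive when risk falls; the revised absolute harm rate is
    baseline * (1 - PIF).  Both states must describe the same weighted
    individuals.
    """
    if state_before.values.shape != state_after.values.shape:
        raise ValueError("before/after states must cover the same individuals")
    if not np.allclose(state_before.weights, state_after.weights):
        raise ValueError("before/after weights must agree")
    wrr_before, _ = _weighted_rr_sums(risk_function, state_before)
    wrr_after, _ = _weighted_rr_sums(risk_function, state_after)
    return 1.0 - wrr_after / wrr_before


def _excess_mass(state: ConsumptionState, threshold: float) -> float:
    """sum_i w_i max(0, c_i - T): the weighted consumption mass above T."""
    return float(np.sum(
        state.weights * np.maximum(0.0, state.values - threshold)))


def fit_two_part_slope(state: ConsumptionState, threshold: float,
                       target_aaf: float) -> float:
    """Slope of a two-part linear RR curve reproducing a target AAF.

    With RR_i = 1 + s*max(0, c_i - T) the implied AAF is sE/(W + sE) where
    E = sum w max(0, c - T) and W = sum w, strictly increasing in s, so the
    calibration inverts exactly: s = AAF * W / ((1 - AAF) * E).
    """
    if not 0.0 <= target_aaf < 1.0:
        raise ValueError("target AAF must be in [0, 1)")
    if target_aaf == 0.0:
        return 0.0
    excess = _excess_mass(state, threshold)
    if excess <= 0.0:
        raise InfeasibleCalibration(
            f"target AAF {target_aaf} but no consumption mass above "
            f"threshold {threshold}")
    total_weight = float(np.sum(state.weights))
    return target_aaf * total_weight / ((1.0 - target_aaf) * excess)


def fit_slope_to_incidence(state: ConsumptionState, threshold: float,
                           observed_annual_incidents: float,
                           subgroup_population: float) -> tuple[float, float]:
    """Absolute-risk slope for wholly-attributable harms.

    The absolute risk of an incident is s*max(0, c - T) per person-year —
    zero below threshold by definition of whole attribution.  Sample weights
    are rescaled so they total ``subgroup_population``; the slope is set so
    the expected incident volume equals the observed one.  Returns
    (slope, expected incidents at the fitted slope).
    """
    if observed_annual_incidents < 0:
        raise ValueError("observed incidents must be >= 0")
    if subgroup_population <= 0:
        raise ValueError("subgroup population must be positive")
    if observed_annual_incidents == 0:
        return 0.0, 0.0
    total_weight = float(np.sum(state.weights))
    if total_weight <= 0:
        raise ValueError("population weight must be positive")
    scale = subgroup_population / total_weight
    excess = _excess_mass(state, threshold) * scale
    if excess <= 0.0:
        raise InfeasibleCalibration(
            f"observed incidents {observed_annual_incidents} but no "
            f"consumption mass above threshold {threshold}")
    slope = observed_annual_incidents / excess
    return slope, slope * excess


def fit_acute_partial(condition_id: str, sex: str,
                      peak_state: ConsumptionState, target_aaf: float,
                      threshold: float | None = None) -> RiskFunction:
    """Calibrated two-part RR function for an acute partially-attributable
    harm on the peak-day basis (default thresholds 4 units men / 3 women)."""
    if threshold is None:
        threshold = ACUTE_THRESHOLD_UNITS_DAY[sex]
    slope = fit_two_part_slope(peak_state, threshold, target_aaf)
    return RiskFunction(
        condition_id=condition_id, basis="peak_day", attribution="partially",
        timing="acute", threshold=threshold, slope=slope, sex=sex)


def chronic_wholly_threshold_weekly(sex: str) -> float:
    """Per-day chronic wholly-attributable threshold on the weekly basis."""
    return CHRONIC_WHOLLY_THRESHOLD_UNITS_DAY[sex] * DAYS_PER_WEEK
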