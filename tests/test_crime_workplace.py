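"""Crime, absence and unemployment channels and their calibrations."""

import numpy as np
import pandas as pd
import pytest

from alcopol import crime_workplace as cw
from alcopol.population import classify_individuals
from alcopol.risk import InfeasibleCalibration, implied_aaf
from alcopol.synthetic_data import (default_crime_categories,
                                    default_offender_apportionment,
                                    default_workplace_params)


@pytest.fixture(scope="module")
def categories():
    return default_crime_categories()


@pytest.fixture(scope="module")
def crime_functions(population, categories):
    return cw.fit_crime_functions(population, categories)


@pytest.fixture(scope="module")
def workplace(population):
    return default_workplace_params()


class TestCrime:
    def test_twenty_categories(self, categories):
        assert len(categories) == 20

    def test_no_consumption_change_no_crime_change(self, population,
                                                   crime_functions,
                                                   categories):
        by_cat, _ = cw.crime_pif_and_volumes(
            population, population, crime_functions, categories)
        np.testing.assert_allclose(by_cat["offence_change"], 0.0,
                                   atol=1e-9)

    def test_zero_counterfactual_reduction_equals_aaf(self, population,
                                                      crime_functions,
                                                      categories):
        """All peaks to zero: reduction = pooled AAF x effective volume."""
        zeroed = population.copy()
        zeroed["peak_day_units"] = 0.0
        by_cat, _ = cw.crime_pif_and_volumes(
            population, zeroed, crime_functions, categories)
        cat = categories[0]
        wrr = cw._pooled_crime_sums(population, cat.category_id,
                                    crime_functions)
        total_w = population["weight"].sum()
        pooled_aaf = (wrr - total_w) / wrr
        expected = -cat.baseline_volume * cat.multiplier * pooled_aaf
        assert by_cat.loc[cat.category_id, "offence_change"] \
            == pytest.approx(expected, rel=1e-9)

    def test_apportionment_conserves_category_totals(self, population,
                                                     crime_functions,
                                                     categories):
        apportionment = default_offender_apportionment(categories)
        reduced = population.copy()
        reduced["peak_day_units"] *= 0.8
        by_cat, by_subgroup = cw.crime_pif_and_volumes(
            population, reduced, crime_functions, categories,
            apportionment)
        np.testing.assert_allclose(by_subgroup.sum(axis=0),
                                   by_cat["offence_change"], rtol=1e-12)

    def test_bad_apportionment_rejected(self, population, crime_functions,
                                        categories):
        apportionment = default_offender_apportionment(categories) * 2.0
        with pytest.raises(ValueError, match="sum to 1"):
            cw.crime_pif_and_volumes(population, population,
                                     crime_functions, categories,
                                     apportionment)

    def test_over25_reuses_16_25_functions(self, crime_functions):
        fitted_groups = {key[2] for key in crime_functions}
        assert "over25" not in fitted_groups
        assert "16-25" in fitted_groups


class TestAbsence:
    def test_no_change_and_arithmetic(self, population, workplace):
        functions = cw.fit_absence_functions(population,
                                             workplace.absence_aaf)
        out = cw.absence_change(population, population, functions,
                                workplace.baseline_absence_days,
                                workplace.participation)
        np.testing.assert_allclose(out["days_change"], 0.0, atol=1e-9)

    def test_pif_scales_baseline_days(self, population, workplace):
        functions = cw.fit_absence_functions(population,
                                             workplace.absence_aaf)
        zeroed = population.copy()
        zeroed["peak_day_units"] = 0.0
        out = cw.absence_change(
            population, zeroed, functions,
            {k: 1000.0 for k in workplace.baseline_absence_days},
            {k: 1.0 for k in workplace.participation})
        working = out[out["age_band"].isin(cw.WORKING_AGE_BANDS)]
        np.testing.assert_allclose(working["days_change"],
                                   -1000.0 * working["pif"], rtol=1e-9)

    def test_non_working_age_contributes_zero(self, population, workplace):
        functions = cw.fit_absence_functions(population,
                                             workplace.absence_aaf)
        zeroed = population.copy()
        zeroed["peak_day_units"] = 0.0
        out = cw.absence_change(population, zeroed, functions,
                                workplace.baseline_absence_days,
                                workplace.participation)
        retired = out[~out["age_band"].isin(cw.WORKING_AGE_BANDS)]
        assert (retired["days_change"] == 0).all()


class TestUnemployment:
    def test_calibration_round_trip(self, population, workplace):
        function = cw.calibrate_unemployment(population, workplace)
        reduction = cw.implied_work_reduction(function, population,
                                              workplace)
        assert reduction == pytest.approx(0.069, abs=1e-9)

    def test_zero_target_flat_function(self, population, workplace):
        from dataclasses import replace
        params = replace(workplace, work_probability_reduction=0.0)
        function = cw.calibrate_unemployment(population, params)
        assert function.slope == 0.0

    def test_moderate_and_hazardous_unaffected(self, population,
                                               workplace):
        """Only harmful drinkers enter the unemployment channel: changing
        everyone else's consumption produces exactly zero effect."""
        function = cw.calibrate_unemployment(population, workplace)
        shifted = population.copy()
        non_harmful = shifted["drinker_level"] != "harmful"
        shifted.loc[non_harmful, "mean_weekly_units"] *= 0.5
        out = cw.unemployment_change(population, shifted, function,
                                     workplace)
        np.testing.assert_allclose(out["persons_change"], 0.0, atol=1e-12)

    def test_change_zero_without_consumption_change(self, population,
                                                    workplace):
        function = cw.calibrate_unemployment(population, workplace)
        out = cw.unemployment_change(population, population, function,
                                     workplace)
        np.testing.assert_allclose(out["persons_change"], 0.0, atol=1e-9)
        np.testing.assert_allclose(out["cost_change"], 0.0, atol=1e-6)

    def test_salary_valuation_exact(self, population, workplace):
        function = cw.calibrate_unemployment(population, workplace)
        reduced = population.copy()
        reduced["mean_weekly_units"] *= 0.5
        out = cw.unemployment_change(population, reduced, function,
                                     workplace)
        for row in out.itertuples():
            salary = workplace.average_salary.get(
                (row.sex, row.age_band), 0.0)
            assert row.cost_change == pytest.approx(
                row.persons_change * salary)

    def test_no_harmful_drinkers_infeasible(self, workplace):
        from alcopol.synthetic_data import (PopulationConfig,
                                            generate_population)
        config = PopulationConfig(n=200, seed=1,
                                  consumption_median={"male": 1.0,
                                                      "female": 0.5})
        pop = classify_individuals(generate_population(config))
        assert (pop["drinker_level"] != "harmful").all()
        with pytest.raises(InfeasibleCalibration):
            cw.calibrate_unemployment(pop, workplace)
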