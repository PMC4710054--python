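"""Generators: determinism, calibration contracts, conservation."""

import numpy as np
import pandas as pd
import pytest

from alcopol.population import SHARE_COLUMNS
from alcopol.synthetic_data import (PopulationConfig, PriceConfig,
                                    calibrate_price_distribution,
                                    default_condition_configs,
                                    generate_baseline_harms,
                                    generate_population,
                                    generate_transactions,
                                    validate_harm_table, weighted_cdf,
                                    weighted_quantile)


class TestGeneratePopulation:
    def test_deterministic_for_fixed_seed(self):
        config = PopulationConfig(n=500, seed=11)
        pd.testing.assert_frame_equal(generate_population(config),
                                      generate_population(config))

    def test_different_seed_differs(self):
        a = generate_population(PopulationConfig(n=500, seed=1))
        b = generate_population(PopulationConfig(n=500, seed=2))
        assert not a["mean_weekly_units"].equals(b["mean_weekly_units"])

    def test_empty_population(self):
        assert len(generate_population(PopulationConfig(n=0, seed=0))) == 0

    def test_abstainer_fraction_converges(self):
        config = PopulationConfig(
            n=10_000, seed=3,
            abstainer_fraction={(s, b): 0.2
                                for s in ("male", "female")
                                for b in PopulationConfig().age_shares})
        pop = generate_population(config)
        frac = (pop["mean_weekly_units"] == 0).mean()
        assert frac == pytest.approx(0.2, abs=0.02)  # ~5 binomial sd

    def test_degenerate_log_scale_collapses_consumption(self):
        config = PopulationConfig(n=300, seed=4, consumption_log_scale=0.0)
        pop = generate_population(config)
        for (sex, band), grp in pop[pop["mean_weekly_units"] > 0].groupby(
                ["sex", "age_band"]):
            assert grp["mean_weekly_units"].nunique() == 1

    def test_drinker_shares_sum_to_one(self):
        pop = generate_population(PopulationConfig(n=1000, seed=5))
        drinkers = pop[pop["mean_weekly_units"] > 0]
        np.testing.assert_allclose(
            drinkers[list(SHARE_COLUMNS)].sum(axis=1), 1.0, atol=1e-9)


class TestGenerateTransactions:
    def test_abstainers_have_no_transactions(self, population,
                                             transactions):
        abstainers = set(
            population.loc[population["mean_weekly_units"] == 0,
                           "person_id"])
        assert abstainers.isdisjoint(set(transactions["person_id"]))

    def test_ethanol_volume_conserved_per_person(self, population,
                                                 transactions):
        per_person = transactions.groupby("person_id")["units"].sum()
        drinkers = population[population["mean_weekly_units"] > 0]
        merged = drinkers.set_index("person_id")["mean_weekly_units"]
        np.testing.assert_allclose(per_person[merged.index], merged,
                                   atol=1e-9)

    def test_zero_discount_incidence(self, population):
        config = PriceConfig(seed=2,
                             discount_incidence={"off": 0.0, "on": 0.0})
        txns = generate_transactions(population, config)
        pd.testing.assert_series_equal(txns["sold_price"],
                                       txns["usual_price"],
                                       check_names=False)

    def test_sold_never_exceeds_usual(self, transactions):
        assert (transactions["sold_price"]
                <= transactions["usual_price"] + 1e-12).all()


class TestPriceCalibration:
    def test_identity_when_target_matches_empirical(self, transactions):
        cat = "beer_off_low"
        sub = transactions[transactions["category"] == cat]
        w = (sub["weight"] * sub["units"]).to_numpy()
        shares = np.linspace(0.05, 1.0, 10)
        prices = weighted_quantile(sub["sold_price"].to_numpy(), w, shares)
        out = calibrate_price_distribution(
            transactions, {cat: (prices, shares)})
        np.testing.assert_allclose(
            out.loc[sub.index, "sold_price"], sub["sold_price"], rtol=1e-9)

    def test_adjusted_cdf_hits_targets(self, transactions):
        """Shifted log-normal targets: the adjusted weighted CDF must
        match the target share at each calibration point."""
        cat = "wine_off_high"
        sub = transactions[transactions["category"] == cat]
        w = (sub["weight"] * sub["units"]).to_numpy()
        shares = np.linspace(0.08, 1.0, 10)
        empirical = weighted_quantile(sub["sold_price"].to_numpy(), w,
                                      shares)
        targets = empirical * 1.12 + 3.0  # shifted target distribution
        out = calibrate_price_distribution(
            transactions, {cat: (targets, shares)})
        adjusted = out.loc[sub.index, "sold_price"].to_numpy()
        achieved = weighted_cdf(adjusted, w, targets)
        np.testing.assert_allclose(achieved, shares, atol=1e-6)

    def test_map_is_monotone_and_volume_preserving(self, transactions):
        cat = "spirit_on_low"
        sub = transactions[transactions["category"] == cat]
        w = (sub["weight"] * sub["units"]).to_numpy()
        shares = np.linspace(0.1, 1.0, 10)
        targets = weighted_quantile(sub["sold_price"].to_numpy(), w,
                                    shares) * 0.9
        out = calibrate_price_distribution(transactions,
                                           {cat: (targets, shares)})
        before = sub["sold_price"].to_numpy()
        after = out.loc[sub.index, "sold_price"].to_numpy()
        order = np.argsort(before)
        assert np.all(np.diff(after[order]) >= -1e-9)
        pd.testing.assert_series_equal(out["units"], transactions["units"])

    def test_non_monotone_targets_rejected(self, transactions):
        with pytest.raises(ValueError):
            calibrate_price_distribution(
                transactions,
                {"beer_off_low": ([10, 20, 30], [0.5, 0.4, 1.0])})


class TestBaselineHarms:
    def test_complete_table(self):
        table = generate_baseline_harms()
        configs = default_condition_configs()
        assert len(table) == len(configs) * 18
        validate_harm_table(table, [c.condition_id for c in configs])

    def test_road_traffic_aaf_stored_verbatim(self):
        table = generate_baseline_harms()
        row = table[(table["condition_id"] == "road_traffic_accidents")
                    & (table["sex"] == "male")
                    & (table["age_band"] == "25-34")]
        assert row["aaf"].iloc[0] == 0.37

    def test_missing_cells_reported(self):
        table = generate_baseline_harms()
        truncated = table.iloc[:-3]
        with pytest.raises(ValueError, match="missing"):
            validate_harm_table(truncated,
                                list(table["condition_id"].unique()))

    def test_invalid_aaf_rejected(self):
        from alcopol.synthetic_data import ConditionConfig
        bad = ConditionConfig("x", "acute", "partially", "peak_day",
                              1e-5, 1e-4, 100.0, 0.1, aaf=1.2)
        with pytest.raises(ValueError, match="AAF"):
            generate_baseline_harms([bad])
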