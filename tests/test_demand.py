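"""Elasticity application, consumption updates and uncertainty sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alcopol.demand import (BingeModel, ElasticityMatrix,
                            ElasticityUncertainty, N_CATEGORIES,
                            apply_consumption_changes, apply_relative_change,
                            consumption_change_vector,
                            sample_elasticity_matrices, update_peak)
from alcopol.population import SHARE_COLUMNS


def diag_matrix(value=-0.5, segment="moderate"):
    return ElasticityMatrix(segment, np.eye(N_CATEGORIES) * value)


class TestConsumptionChangeVector:
    def test_diagonal_response(self):
        dc = consumption_change_vector(np.full(16, 10.0), diag_matrix(-0.5))
        np.testing.assert_allclose(dc, -5.0)

    def test_zero_price_change(self):
        dc = consumption_change_vector(np.zeros(16), diag_matrix())
        np.testing.assert_allclose(dc, 0.0)

    def test_cross_term(self):
        values = np.zeros((16, 16))
        values[0, 1] = 0.2
        dp = np.zeros(16)
        dp[1] = 10.0
        with pytest.warns(UserWarning):
            # zero diagonal triggers no warning; positive cross is fine, but
            # build with a tiny positive own-price to exercise the warning
            values[0, 0] = 0.01
            m = ElasticityMatrix("moderate", values)
        assert consumption_change_vector(dp, m)[0] == pytest.approx(2.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consumption_change_vector(np.zeros(15), diag_matrix())

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_additive_in_price_changes(self, seed):
        rng = np.random.default_rng(seed)
        m = ElasticityMatrix(
            "moderate", rng.normal(0, 0.3, (16, 16)) - 0.3 * np.eye(16))
        p1, p2 = rng.normal(0, 5, 16), rng.normal(0, 5, 16)
        np.testing.assert_allclose(
            consumption_change_vector(p1 + p2, m),
            consumption_change_vector(p1, m)
            + consumption_change_vector(p2, m), atol=1e-9)


def segments_for(df):
    return pd.Series("moderate", index=df["person_id"].to_numpy())


class TestApplyConsumptionChanges:
    def test_zero_change_is_identity(self, tiny_individuals):
        out = apply_consumption_changes(
            tiny_individuals, {"moderate": np.zeros(16)},
            segments_for(tiny_individuals))
        pd.testing.assert_frame_equal(out, tiny_individuals)

    def test_single_category_drinker_falls_exactly(self, tiny_individuals):
        df = tiny_individuals.iloc[[0]].copy()
        df[list(SHARE_COLUMNS)] = 0.0
        df["share_beer_off_low"] = 1.0
        dc = np.zeros(16)
        dc[0] = -10.0  # beer_off_low is first in canonical order
        out = apply_consumption_changes(df, {"moderate": dc},
                                        segments_for(df))
        assert out["mean_weekly_units"].iloc[0] == pytest.approx(9.0)

    def test_offsetting_changes_shift_shares(self, tiny_individuals):
        df = tiny_individuals.iloc[[0]].copy()
        df[list(SHARE_COLUMNS)] = 0.0
        df["share_beer_off_low"] = 0.5
        df["share_wine_off_low"] = 0.5
        dc = np.zeros(16)
        dc[0] = -10.0   # beer_off_low
        dc[4] = +10.0   # wine_off_low
        out = apply_consumption_changes(df, {"moderate": dc},
                                        segments_for(df))
        assert out["mean_weekly_units"].iloc[0] == pytest.approx(10.0)
        assert out["share_beer_off_low"].iloc[0] == pytest.approx(0.45)
        assert out["share_wine_off_low"].iloc[0] == pytest.approx(0.55)

    def test_population_ethanol_conservation_oracle(self, population):
        """Aggregate change from individuals equals the share-weighted
        aggregate of category changes (uniform segment)."""
        rng = np.random.default_rng(5)
        dc = rng.uniform(-20, 5, 16)
        seg = segments_for(population)
        out = apply_consumption_changes(population, {"moderate": dc}, seg)
        w = population["weight"].to_numpy()
        mean = population["mean_weekly_units"].to_numpy()
        shares = population[list(SHARE_COLUMNS)].to_numpy()
        oracle = np.sum(
            w[:, None] * shares * mean[:, None] * (1 + dc / 100.0))
        assert np.sum(out["mean_weekly_units"].to_numpy() * w) \
            == pytest.approx(oracle, rel=1e-12)


class TestUpdatePeak:
    def test_no_mean_change_no_peak_change(self, tiny_individuals):
        model = BingeModel.uniform({"moderate": 0.5, "hazardous": 0.5,
                                    "harmful": 0.5})
        df = tiny_individuals.assign(
            drinker_level=["moderate", "hazardous", "harmful"])
        out = update_peak(df, df["mean_weekly_units"],
                          df["mean_weekly_units"], model)
        pd.testing.assert_series_equal(out["peak_day_units"],
                                       df["peak_day_units"])

    def test_linear_update_and_clamp(self, tiny_individuals):
        model = BingeModel.uniform({"moderate": 0.5, "hazardous": 0.5,
                                    "harmful": 0.5})
        df = tiny_individuals.assign(
            drinker_level=["moderate", "hazardous", "harmful"])
        old = df["mean_weekly_units"].to_numpy()
        out = update_peak(df, old, old - 4.0, model)
        assert out["peak_day_units"].iloc[0] == pytest.approx(1.0)  # 3 - 2
        big_drop = update_peak(df, old, old - 100.0, model)
        assert (big_drop["peak_day_units"] >= 0).all()

    def test_missing_cell_rejected(self, tiny_individuals):
        model = BingeModel({("male", "25-34", "moderate"): (0.0, 0.5)})
        df = tiny_individuals.assign(
            drinker_level=["moderate", "hazardous", "harmful"])
        with pytest.raises(KeyError):
            update_peak(df, df["mean_weekly_units"],
                        df["mean_weekly_units"] - 1, model)


class TestRelativeChange:
    def test_scaling(self, tiny_individuals):
        out = apply_relative_change(tiny_individuals, -10.0)
        assert out["mean_weekly_units"].iloc[1] == pytest.approx(27.0)

    def test_zero_is_identity(self, tiny_individuals):
        out = apply_relative_change(tiny_individuals, 0.0)
        pd.testing.assert_frame_equal(out, tiny_individuals)

    def test_weighted_mean_falls_by_stated_percent(self, population):
        out = apply_relative_change(population, -26.9)
        w = population["weight"]
        before = float((w * population["mean_weekly_units"]).sum())
        after = float((w * out["mean_weekly_units"]).sum())
        assert 100.0 * (after / before - 1.0) == pytest.approx(-26.9)


class TestElasticitySampling:
    def test_zero_covariance_returns_mean(self):
        mean = np.full(256, -0.4)
        unc = ElasticityUncertainty(mean, np.zeros((256, 256)))
        draws = sample_elasticity_matrices(unc, 5, seed=0)
        for d in draws:
            np.testing.assert_allclose(d.values.ravel(), mean)

    def test_moments_recovered(self):
        """Monte-Carlo mean and covariance approach the inputs."""
        rng = np.random.default_rng(42)
        k = 256
        mean = rng.normal(-0.5, 0.1, k)
        a = rng.normal(0, 0.02, (k, 4))
        cov = a @ a.T + 1e-6 * np.eye(k)
        unc = ElasticityUncertainty(mean, cov)
        draws = sample_elasticity_matrices(unc, 10_000, seed=3)
        sample = np.array([d.values.ravel() for d in draws])
        se = np.sqrt(np.diag(cov) / len(sample))
        assert np.all(np.abs(sample.mean(0) - mean) < 4 * se + 1e-12)
        sample_cov = np.cov(sample.T)
        assert np.abs(sample_cov - cov).max() < 0.05 * np.abs(cov).max() \
            + 1e-4

    def test_reproducible_by_seed(self):
        unc = ElasticityUncertainty(np.zeros(256), np.eye(256) * 0.01)
        a = sample_elasticity_matrices(unc, 3, seed=9)
        b = sample_elasticity_matrices(unc, 3, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_non_psd_rejected(self):
        cov = np.eye(256)
        cov[0, 0] = -1.0
        with pytest.raises(ValueError):
            ElasticityUncertainty(np.zeros(256), cov)
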