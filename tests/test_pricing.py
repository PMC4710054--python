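"""Price-side policy transforms and the mean price-change vector."""

import numpy as np
import pandas as pd
import pytest

from alcopol.population import BEVERAGE_CATEGORIES
from alcopol.pricing import (POLICY_LIBRARY, PolicySpec, SEGMENTS,
                             apply_discount_restriction,
                             apply_general_price_change,
                             apply_minimum_unit_price, apply_policy,
                             load_policy_file, mean_price_change_vector,
                             save_policy_file)


def make_txns(sold, usual=None, category=None, units=None, weight=None):
    n = len(sold)
    return pd.DataFrame({
        "person_id": [f"p{i}" for i in range(n)],
        "category": category or ["beer_off_low"] * n,
        "units": units or [1.0] * n,
        "sold_price": sold,
        "usual_price": usual or sold,
        "weight": weight or [1.0] * n,
    })


class TestMinimumUnitPrice:
    def test_floor_applied_exactly(self):
        txns = make_txns([30.0, 45.0, 60.0])
        out = apply_minimum_unit_price(txns, 50.0)
        assert list(out["sold_price"]) == [50.0, 50.0, 60.0]
        assert out["sold_price"].min() == 50.0
        pd.testing.assert_series_equal(out["units"], txns["units"])
        pd.testing.assert_series_equal(out["weight"], txns["weight"])

    def test_floor_below_minimum_is_identity(self):
        txns = make_txns([30.0, 45.0])
        out = apply_minimum_unit_price(txns, 29.99)
        pd.testing.assert_frame_equal(out, txns)

    def test_idempotent(self):
        txns = make_txns([10.0, 80.0])
        once = apply_minimum_unit_price(txns, 50.0)
        twice = apply_minimum_unit_price(once, 50.0)
        pd.testing.assert_frame_equal(once, twice)

    def test_scope_restricts_to_sector(self):
        txns = make_txns([20.0, 20.0],
                         category=["beer_off_low", "beer_on_low"])
        out = apply_minimum_unit_price(txns, 50.0, scope="off_trade")
        assert list(out["sold_price"]) == [50.0, 20.0]


class TestGeneralPriceChange:
    def test_percent_rise(self):
        out = apply_general_price_change(make_txns([40.0]), 10.0)
        assert out["sold_price"].iloc[0] == pytest.approx(44.0)

    def test_zero_percent_is_identity(self):
        txns = make_txns([40.0, 55.0])
        pd.testing.assert_frame_equal(
            apply_general_price_change(txns, 0.0), txns)

    def test_cutoff_targets_low_prices_only(self):
        out = apply_general_price_change(make_txns([20.0, 40.0]), 25.0,
                                         low_price_cutoff=30.0)
        assert list(out["sold_price"]) == [25.0, 40.0]

    def test_rejects_impossible_percent(self):
        with pytest.raises(ValueError):
            apply_general_price_change(make_txns([40.0]), -100.0)


class TestDiscountRestriction:
    def test_cap_lifts_sold_price(self):
        out = apply_discount_restriction(
            make_txns([40.0], usual=[100.0]), 0.5)
        assert out["sold_price"].iloc[0] == pytest.approx(50.0)

    def test_total_ban_equalises(self):
        txns = make_txns([40.0, 70.0], usual=[100.0, 80.0])
        out = apply_discount_restriction(txns, 0.0)
        pd.testing.assert_series_equal(
            out["sold_price"], out["usual_price"], check_names=False)

    def test_permitted_discount_untouched(self):
        txns = make_txns([60.0], usual=[100.0])
        out = apply_discount_restriction(txns, 0.5)
        assert out["sold_price"].iloc[0] == 60.0


def test_price_transforms_monotone_and_never_cut_prices(rng):
    """Floors and percent rises preserve the sold-price ordering; every
    transform only ever raises prices and leaves volumes untouched."""
    sold = rng.uniform(10, 150, size=200)
    txns = make_txns(list(sold), usual=list(sold * rng.uniform(1, 1.5, 200)))
    order = np.argsort(txns["sold_price"].to_numpy())
    for out in (apply_minimum_unit_price(txns, 50.0),
                apply_general_price_change(txns, 15.0)):
        assert np.all(np.diff(out["sold_price"].to_numpy()[order]) >= -1e-12)
    for out in (apply_minimum_unit_price(txns, 50.0),
                apply_general_price_change(txns, 15.0),
                apply_discount_restriction(txns, 0.2)):
        assert (out["sold_price"].to_numpy()
                >= txns["sold_price"].to_numpy() - 1e-12).all()
        pd.testing.assert_series_equal(out["units"], txns["units"])


class TestMeanPriceChangeVector:
    def segment_for(self, txns):
        return pd.Series("moderate", index=txns["person_id"].to_numpy())

    def test_identity_gives_zeros(self):
        txns = make_txns([40.0, 60.0])
        pcv = mean_price_change_vector(txns, txns, self.segment_for(txns))
        assert (pcv.to_numpy() == 0).all()
        assert pcv.shape == (16, len(SEGMENTS))

    def test_single_transaction_percent(self):
        before = make_txns([40.0])
        after = make_txns([44.0])
        pcv = mean_price_change_vector(before, after,
                                       self.segment_for(before))
        assert pcv.loc["beer_off_low", "moderate"] == pytest.approx(10.0)

    def test_matches_weighted_mean_oracle(self, rng):
        n = 100
        before = make_txns(list(rng.uniform(20, 120, n)),
                           units=list(rng.uniform(0.5, 5, n)),
                           weight=list(rng.uniform(0.5, 2, n)))
        after = before.copy()
        after["sold_price"] = before["sold_price"] * 1.07
        pcv = mean_price_change_vector(before, after,
                                       self.segment_for(before))
        w = before["weight"] * before["units"]
        oracle = 100.0 * (
            float((w * after["sold_price"]).sum() / w.sum())
            / float((w * before["sold_price"]).sum() / w.sum()) - 1.0)
        assert pcv.loc["beer_off_low", "moderate"] == pytest.approx(oracle)

    def test_misaligned_rejected(self):
        before = make_txns([40.0, 50.0])
        after = make_txns([40.0])
        with pytest.raises(ValueError):
            mean_price_change_vector(before, after,
                                     self.segment_for(before))


def test_policy_spec_validation():
    with pytest.raises(ValueError):
        PolicySpec("minimum_unit_price")              # missing floor
    with pytest.raises(ValueError):
        PolicySpec("discount_restriction", max_discount_fraction=1.5)
    with pytest.raises(ValueError):
        PolicySpec("minimum_unit_price", floor=50, scope="sideways")


def test_policy_library_roundtrip(tmp_path):
    assert len(POLICY_LIBRARY) == 18
    path = tmp_path / "policies.yaml"
    save_policy_file(POLICY_LIBRARY, path)
    back = load_policy_file(path)
    assert back == POLICY_LIBRARY


def test_sequential_application_order_matters():
    txns = make_txns([40.0])
    floor_then_rise = apply_policy(txns, [
        PolicySpec("minimum_unit_price", floor=50),
        PolicySpec("general_price_change", percent=10)])
    rise_then_floor = apply_policy(txns, [
        PolicySpec("general_price_change", percent=10),
        PolicySpec("minimum_unit_price", floor=50)])
    assert floor_then_rise["sold_price"].iloc[0] == pytest.approx(55.0)
    assert rise_then_floor["sold_price"].iloc[0] == pytest.approx(50.0)
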