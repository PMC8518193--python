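"""Unit-cost estimation: outlier screen, purchase summaries, per-minute rates."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from microcoi import (
    DurableAsset,
    HealthWorkerRole,
    PurchaseRecord,
    WorkTimeBasis,
    depreciation_per_minute,
    flag_outliers,
    unit_cost_from_purchases,
    wage_per_minute,
)
from microcoi.cost_inputs import (
    CostInput,
    load_cost_inputs,
    load_purchases,
    load_wages,
)


class TestFlagOutliers:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1.0, 1.2, 1.1], [1.0, 1.2, 1.1]),  # nothing near 3x its peers
            ([1.0, 1.0, 10.0], [1.0, 1.0]),  # 10 >= 3 * median(1, 1)
            ([5.0], [5.0]),  # a single value has no peers
            ([2.0, 2.0, 2.0, 2.0], [2.0, 2.0, 2.0, 2.0]),
        ],
    )
    def test_examples(self, values, expected):
        assert flag_outliers(values) == expected

    def test_order_preserved(self):
        assert flag_outliers([1.2, 1.0, 1.1]) == [1.2, 1.0, 1.1]

    def test_never_returns_empty(self):
        # every zero is >= 3 * 0, so the rule would discard everything
        with pytest.warns(UserWarning):
            assert flag_outliers([0.0, 0.0]) == [0.0, 0.0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no values"):
            flag_outliers([])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            flag_outliers([1.0, -1.0])

    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=12,
        )
    )
    def test_idempotent(self, values):
        once = flag_outliers(values)
        assert flag_outliers(once) == once

    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=12,
        )
    )
    def test_retained_is_subset(self, values):
        kept = flag_outliers(values)
        assert kept
        assert all(v in values for v in kept)


def _purchases(pairs, input_id="gauze"):
    return [
        PurchaseRecord(input_id, f"site_{i}", price, volume)
        for i, (price, volume) in enumerate(pairs)
    ]


class TestUnitCostFromPurchases:
    def test_three_sources(self):
        mean, sd, n = unit_cost_from_purchases(_purchases([(10, 10), (12, 10), (11, 10)]))
        assert mean == pytest.approx(1.1)
        assert sd == pytest.approx(0.1)
        assert n == 3

    def test_single_source_has_zero_sd(self):
        mean, sd, n = unit_cost_from_purchases(_purchases([(5, 1)]))
        assert (mean, sd, n) == (5.0, 0.0, 1)

    def test_outlier_removed_before_summary(self):
        mean, sd, n = unit_cost_from_purchases(_purchases([(10, 10), (10, 10), (100, 10)]))
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)
        assert n == 2

    def test_mixed_input_ids_rejected(self):
        records = _purchases([(10, 10)]) + _purchases([(12, 10)], input_id="cotton")
        with pytest.raises(ValueError, match="mixed"):
            unit_cost_from_purchases(records)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            PurchaseRecord("gauze", "site", 10.0, 0.0)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.1, max_value=1e4),
                st.floats(min_value=1, max_value=1e3),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_mean_within_retained_range(self, pairs):
        records = _purchases(pairs)
        mean, _, _ = unit_cost_from_purchases(records)
        unit_prices = [r.unit_price for r in records]
        assert min(unit_prices) <= mean <= max(unit_prices) + 1e-12


class TestPerMinuteRates:
    def test_depreciation_identity_basis(self):
        basis = WorkTimeBasis()  # 124,800 min/year
        assert depreciation_per_minute(DurableAsset("x", 124_800.0, 1.0), basis) == 1.0
        assert depreciation_per_minute(DurableAsset("x", 624_000.0, 5.0), basis) == 1.0
        assert depreciation_per_minute(DurableAsset("x", 0.0, 3.0), basis) == 0.0

    def test_wage_identity_basis(self):
        basis = WorkTimeBasis()  # 10,400 min/month
        assert wage_per_minute(HealthWorkerRole("physician", 10_400.0), basis) == 1.0
        assert wage_per_minute(HealthWorkerRole("nurse", 5_200.0), basis) == 0.5
        assert wage_per_minute(HealthWorkerRole("cashier", 0.0), basis) == 0.0

    @given(st.floats(min_value=0.0, max_value=1e7), st.floats(min_value=0.5, max_value=40))
    def test_linear_in_money(self, cost, life):
        basis = WorkTimeBasis()
        one = depreciation_per_minute(DurableAsset("x", cost, life), basis)
        two = depreciation_per_minute(DurableAsset("x", 2 * cost, life), basis)
        assert two == pytest.approx(2 * one)
        w1 = wage_per_minute(HealthWorkerRole("nurse", cost if cost < 1e6 else 1e6), basis)
        w2 = wage_per_minute(
            HealthWorkerRole("nurse", 2 * (cost if cost < 1e6 else 1e6)), basis
        )
        assert w2 == pytest.approx(2 * w1)

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="unknown role"):
            HealthWorkerRole("janitor", 1000.0)

    def test_non_positive_life_rejected(self):
        with pytest.raises(ValueError):
            DurableAsset("x", 100.0, 0.0)


class TestLoaders:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "inputs.csv"
        p.write_text(
            "input_id,label,category,basis,mean_unit_cost,sd_unit_cost,n_sources\n"
            "gauze,gauze,disposable_materials,per_item,0.5,0.1,3\n"
            "room,room,infrastructure,per_minute,0.02,0.0,1\n"
            "podo,podophyllin,drugs,per_item,12.0,2.0,5\n"
        )
        inputs = load_cost_inputs(p)
        assert len(inputs) == 3
        assert inputs[0] == CostInput("gauze", "gauze", "disposable_materials",
                                      "per_item", 0.5, 0.1, 3)

    def test_unknown_category_lists_valid_ones(self, tmp_path):
        p = tmp_path / "inputs.csv"
        p.write_text(
            "input_id,label,category,basis,mean_unit_cost,sd_unit_cost,n_sources\n"
            "gauze,gauze,misc,per_item,0.5,0.1,3\n"
        )
        with pytest.raises(ValueError, match="disposable_materials"):
            load_cost_inputs(p)

    def test_error_carries_line_number(self, tmp_path):
        p = tmp_path / "inputs.csv"
        p.write_text(
            "input_id,label,category,basis,mean_unit_cost,sd_unit_cost,n_sources\n"
            "gauze,gauze,drugs,per_item,0.5,0.1,3\n"
            "bad,bad,drugs,per_item,-1.0,0.1,3\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            load_cost_inputs(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "purchases.csv"
        p.write_text("input_id,site,price\ngauze,lima,10\n")
        with pytest.raises(ValueError, match="volume"):
            load_purchases(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "wages.csv"
        p.write_text("role,monthly_salary\n")
        with pytest.raises(ValueError, match="no records"):
            load_wages(p)
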