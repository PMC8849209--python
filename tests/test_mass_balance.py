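"""Net supply, commodity-tree processing and inedible/waste adjustment."""

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nutriflow.errors import BalanceError, DomainError, GraphError
from nutriflow.mass_balance import (
    aggregate_waste_fraction,
    apply_processing,
    consumed_mass,
    net_supply,
)
from nutriflow.schema import BALANCE_COLUMNS, PROCESSING_COLUMNS


def balance(cid="beef", production=0.0, **flows):
    row = {
        "commodity_id": cid, "group_id": "ruminant_meat", "year": 2018,
        "production": production, "imports": 0.0, "exports": 0.0,
        "feed": 0.0, "seed": 0.0, "processing_input": 0.0,
        "other_uses": 0.0, "losses": 0.0,
    }
    row.update(flows)
    return row


class TestNetSupply:
    def test_direct_arithmetic(self):
        # 95% of farm-gate mass reaches the food supply
        assert net_supply(balance(production=100.0, feed=3.0, losses=2.0)) == 95.0

    def test_farm_gate_to_food_95_percent(self):
        # 333 units at the farm gate with 5% non-food flows -> 316.35 as food
        b = balance(production=333.0, feed=5.0, other_uses=5.0, losses=6.65)
        assert net_supply(b) == pytest.approx(316.35, rel=1e-12)

    def test_global_trade_nets_out(self):
        b = balance(production=50.0, imports=10.0, exports=10.0)
        assert net_supply(b, trade_mode="strict_zero") == 50.0

    def test_strict_zero_rejects_net_trade(self):
        b = balance(production=50.0, imports=10.0, exports=3.0)
        with pytest.raises(BalanceError, match="beef"):
            net_supply(b, trade_mode="strict_zero")
        assert net_supply(b, trade_mode="netted") == 57.0

    def test_negative_supply_clamped_to_zero(self):
        assert net_supply(balance(production=5.0, feed=9.0)) == 0.0


class TestProcessing:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=BALANCE_COLUMNS)

    def rules(self, rows):
        return pd.DataFrame(rows, columns=PROCESSING_COLUMNS)

    def test_extraction_distributes_and_residual_exits(self):
        balances = self.frame([
            balance("carcass", production=100.0, processing_input=100.0),
            balance("meat"), balance("offal"), balance("fat"),
        ])
        rules = self.rules([
            {"parent_id": "carcass", "child_id": "meat", "extraction_rate": 0.6},
            {"parent_id": "carcass", "child_id": "offal", "extraction_rate": 0.07},
            {"parent_id": "carcass", "child_id": "fat", "extraction_rate": 0.02},
        ])
        out = apply_processing(balances, rules).set_index("commodity_id")
        assert out.at["meat", "production"] == 60.0
        assert out.at["offal", "production"] == pytest.approx(7.0, rel=1e-12)
        assert out.at["fat", "production"] == pytest.approx(2.0, rel=1e-12)
        gained = (out.at["meat", "production"] + out.at["offal", "production"]
                  + out.at["fat", "production"])
        # residual leaves the food system
        assert 100.0 - gained == pytest.approx(31.0, rel=1e-12)

    def test_no_rules_is_identity(self):
        balances = self.frame([balance("beef", production=10.0)])
        out = apply_processing(balances, self.rules([]))
        pd.testing.assert_frame_equal(out, balances, check_exact=True)

    def test_two_level_chain_composes_rates(self):
        # animal -> carcass -> cuts: 100 * 0.75 * 0.5 = 37.5
        balances = self.frame([
            balance("animal", production=100.0, processing_input=100.0),
            balance("carcass"), balance("cuts"),
        ])
        rules = self.rules([
            {"parent_id": "animal", "child_id": "carcass",
             "extraction_rate": 0.75},
            {"parent_id": "carcass", "child_id": "cuts",
             "extraction_rate": 0.5},
        ])
        out = apply_processing(balances, rules).set_index("commodity_id")
        assert out.at["cuts", "production"] == 37.5
        # the intermediate nets to zero: inflow fully forwarded
        assert out.at["carcass", "production"] == 75.0
        assert out.at["carcass", "processing_input"] == 75.0

    def test_cyclic_rules_rejected(self):
        balances = self.frame([balance("a", production=1.0),
                               balance("b", production=1.0)])
        rules = self.rules([
            {"parent_id": "a", "child_id": "b", "extraction_rate": 0.5},
            {"parent_id": "b", "child_id": "a", "extraction_rate": 0.5},
        ])
        with pytest.raises(GraphError, match="cycle"):
            apply_processing(balances, rules)

    @given(
        throughput=st.integers(min_value=0, max_value=10**6),
        rates=st.lists(
            st.integers(min_value=1, max_value=32), min_size=1, max_size=5
        ).filter(lambda ks: sum(ks) <= 128),
    )
    def test_processing_conserves_mass(self, throughput, rates):
        children = [balance(f"c{i}") for i in range(len(rates))]
        balances = self.frame(
            [balance("p", production=float(throughput),
                     processing_input=float(throughput))] + children
        )
        rules = self.rules([
            {"parent_id": "p", "child_id": f"c{i}",
             "extraction_rate": k / 128}
            for i, k in enumerate(rates)
        ])
        out = apply_processing(balances, rules).set_index("commodity_id")
        gains = sum(out.at[f"c{i}", "production"] for i in range(len(rates)))
        residual = (1.0 - sum(k / 128 for k in rates)) * throughput
        assert gains + residual == pytest.approx(throughput, rel=1e-12)


class TestConsumedMass:
    def test_forced_arithmetic(self):
        r = consumed_mass(100.0, 0.20, 0.10)
        assert (r.consumed, r.inedible_mass, r.wasted_mass) == (72.0, 20.0, 8.0)

    def test_poultry_like_upper_inedible_bound(self):
        # 43% inedible portion leaves 57% edible
        assert consumed_mass(100.0, 0.43, 0.0).edible_available == (
            pytest.approx(57.0, rel=1e-12)
        )

    def test_zero_waste_limit(self):
        r = consumed_mass(80.0, 0.25, 0.0)
        assert r.consumed == r.edible_available

    @pytest.mark.parametrize("inedible,waste", [(-0.1, 0.0), (0.0, 1.0), (1.2, 0.0)])
    def test_fraction_out_of_range_rejected(self, inedible, waste):
        with pytest.raises(DomainError):
            consumed_mass(10.0, inedible, waste)

    @given(
        mass=st.integers(min_value=0, max_value=10**9),
        i=st.integers(min_value=0, max_value=1023),
        w=st.integers(min_value=0, max_value=1023),
    )
    def test_mass_conserved_exactly(self, mass, i, w):
        r = consumed_mass(float(mass), i / 1024, w / 1024)
        assert r.available_as_food == r.edible_available + r.inedible_mass
        assert r.edible_available == r.consumed + r.wasted_mass
        assert r.available_as_food == (
            r.consumed + r.inedible_mass + r.wasted_mass
        )
        assert min(r.consumed, r.inedible_mass, r.wasted_mass) >= 0.0

    @given(
        mass=st.integers(min_value=0, max_value=10**9),
        i1=st.integers(min_value=0, max_value=1023),
        i2=st.integers(min_value=0, max_value=1023),
        w=st.integers(min_value=0, max_value=1023),
    )
    def test_consumed_monotone_in_fractions_and_mass(self, mass, i1, i2, w):
        lo, hi = sorted((i1, i2))
        a = consumed_mass(float(mass), hi / 1024, w / 1024).consumed
        b = consumed_mass(float(mass), lo / 1024, w / 1024).consumed
        assert a <= b
        c = consumed_mass(float(mass) + 1.0, lo / 1024, w / 1024).consumed
        assert c >= b


class TestWasteAggregation:
    def test_population_weighted_mean(self):
        rows = pd.DataFrame(
            [{"kind": "waste", "commodity_id": "beef", "region_id": "a",
              "fraction": 0.1},
             {"kind": "waste", "commodity_id": "beef", "region_id": "b",
              "fraction": 0.2}]
        )
        pops = pd.DataFrame(
            [{"region_id": "a", "year": 2018, "headcount": 1.0e9},
             {"region_id": "b", "year": 2018, "headcount": 3.0e9}]
        )
        assert aggregate_waste_fraction(rows, pops) == pytest.approx(0.175)

    def test_global_row_wins(self):
        rows = pd.DataFrame(
            [{"kind": "waste", "commodity_id": "beef", "region_id": "GLOBAL",
              "fraction": 0.05},
             {"kind": "waste", "commodity_id": "beef", "region_id": "a",
              "fraction": 0.2}]
        )
        pops = pd.DataFrame(columns=["region_id", "year", "headcount"])
        assert aggregate_waste_fraction(rows, pops) == 0.05
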