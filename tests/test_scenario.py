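"""Counterfactual scenarios: removals, scalings, gaps and replacement."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from nutriflow import pipeline
from nutriflow.errors import ScenarioError, TaxonomyError
from nutriflow.scenario import (
    CANNOT_CLOSE,
    ScenarioSpec,
    apply_scenario,
    joint_replacement_multiplier,
    nutrient_gaps,
    replacement_multiplier,
)
from nutriflow.synthetic import (
    MEAT_GROUPS,
    make_supply_fraction_world,
)


class TestApplyScenario:
    def test_identity_scenario_is_bitwise_noop(self, small_world):
        bundle = small_world(seed=2)
        perturbed = apply_scenario(bundle, ScenarioSpec())
        base = pipeline.run(bundle)
        after = pipeline.run(perturbed)
        assert_frame_equal(base.food_mass, after.food_mass, check_exact=True)
        assert_frame_equal(
            base.availability, after.availability, check_exact=True
        )
        assert_frame_equal(
            base.contributions.values, after.contributions.values,
            check_exact=True,
        )

    def test_no_meat_scenario_zeroes_meat_contributions(self, global_2018):
        spec = ScenarioSpec(
            removals=frozenset(MEAT_GROUPS), default_multiplier=1.2
        )
        result = pipeline.run(apply_scenario(global_2018, spec))
        meat_rows = result.contributions.values.loc[list(MEAT_GROUPS)]
        assert (meat_rows.fillna(0.0) == 0.0).all().all()
        display = result.contributions.display().loc[list(MEAT_GROUPS)]
        assert (
            display.isin(["No contribution", "n/a"])
        ).all().all()

    def test_doubling_one_of_two_equal_groups_gives_two_thirds(self):
        # two sources with equal shares; scale one x2 -> 2/3 vs 1/3
        bundle = make_supply_fraction_world("protein", 0.5)
        bal = bundle.balances
        other = bal.iloc[0].copy()
        other["commodity_id"] = "milk"
        other["group_id"] = "dairy"
        bundle.balances = pd.concat(
            [bal, other.to_frame().T], ignore_index=True
        )
        bundle.balances["year"] = bundle.balances["year"].astype("int64")
        comp = bundle.composition.copy()
        milk_comp = comp.copy()
        milk_comp["commodity_id"] = "milk"
        bundle.composition = pd.concat([comp, milk_comp], ignore_index=True)
        bundle.validate(strict=True)

        scaled = apply_scenario(
            bundle, ScenarioSpec(scalings={"dairy": 2.0})
        )
        table = pipeline.run(scaled).contributions
        assert table.values.at["dairy", "protein"] == pytest.approx(
            200.0 / 3.0, rel=1e-12
        )

    def test_removal_never_increases_availability(self, small_world):
        bundle = small_world(seed=6)
        base = pipeline.run(bundle).group_totals.set_index(
            ["group_id", "nutrient_id"]
        )
        removed = pipeline.run(
            apply_scenario(
                bundle, ScenarioSpec(removals=frozenset({"poultry_meat"}))
            )
        ).group_totals.set_index(["group_id", "nutrient_id"])
        joined = base.join(removed, rsuffix="_after", how="left").fillna(0.0)
        assert (joined["bioavailable_after"]
                <= joined["bioavailable"] + 1e-12).all()

    def test_availability_linear_in_multiplier(self, small_world):
        bundle = small_world(seed=8)
        totals = {}
        for m in (0.5, 1.0, 2.0):
            spec = ScenarioSpec(default_multiplier=m)
            r = pipeline.run(apply_scenario(bundle, spec))
            totals[m] = r.group_totals["bioavailable"].to_numpy()
        assert np.allclose(totals[2.0], 4.0 * totals[0.5], rtol=1e-9)
        assert np.allclose(totals[1.0], 2.0 * totals[0.5], rtol=1e-9)

    def test_unknown_group_rejected(self, small_world):
        with pytest.raises(TaxonomyError, match="unobtainium"):
            apply_scenario(
                small_world(seed=0),
                ScenarioSpec(removals=frozenset({"unobtainium"})),
            )

    def test_removed_group_cannot_also_be_scaled(self, small_world):
        with pytest.raises(ScenarioError, match="removed and scaled"):
            apply_scenario(
                small_world(seed=0),
                ScenarioSpec(
                    removals=frozenset({"dairy"}), scalings={"dairy": 2.0}
                ),
            )

    def test_target_year_selects_population(self, global_2018):
        spec = ScenarioSpec(target_year=2030)
        perturbed = apply_scenario(global_2018, spec)
        assert perturbed.global_population() == 8.55e9

    def test_population_override(self, global_2018):
        spec = ScenarioSpec(target_year=2030, population_override=9.0e9)
        perturbed = apply_scenario(global_2018, spec)
        assert perturbed.global_population() == 9.0e9


class TestGaps:
    @pytest.mark.parametrize(
        "fraction, expected_gap",
        [(0.65, 35.0), (1.0, 0.0), (0.0, 100.0)],
    )
    def test_gap_formula(self, fraction, expected_gap):
        world = make_supply_fraction_world("vitamin_b12", fraction)
        gaps = nutrient_gaps(world)
        assert gaps["gap_percent"].iloc[0] == pytest.approx(
            expected_gap, abs=1e-9
        )
        assert bool(gaps["surplus"].iloc[0]) == (fraction >= 1.0)

    def test_surplus_never_reports_gap(self):
        world = make_supply_fraction_world("vitamin_b12", 1.5)
        gaps = nutrient_gaps(world)
        assert gaps["gap_percent"].iloc[0] == 0.0


class TestReplacement:
    def test_sole_supplier_of_half_requirement_doubles(self):
        world = make_supply_fraction_world("vitamin_b12", 0.5)
        m = replacement_multiplier(world, "cereals", [], "vitamin_b12")
        assert m == pytest.approx(2.0, abs=1e-9)

    def test_sufficient_baseline_needs_no_scaling(self):
        world = make_supply_fraction_world("vitamin_b12", 1.25)
        m = replacement_multiplier(world, "cereals", [], "vitamin_b12")
        assert m == 1.0

    def test_dairy_tripling_closes_b12_gap(self, b12_world):
        m = replacement_multiplier(
            b12_world, "dairy", MEAT_GROUPS, "vitamin_b12"
        )
        assert m == pytest.approx(3.0, abs=1e-9)
        spec = ScenarioSpec(
            removals=frozenset(MEAT_GROUPS), scalings={"dairy": m}
        )
        gaps = nutrient_gaps(apply_scenario(b12_world, spec))
        assert gaps.set_index("nutrient_id").at[
            "vitamin_b12", "gap_percent"] <= 1e-9

    def test_fish_quadrupling_closes_b12_gap(self, b12_world):
        m = replacement_multiplier(
            b12_world, "fish_seafood", MEAT_GROUPS, "vitamin_b12"
        )
        assert m == pytest.approx(4.0, abs=1e-9)
        spec = ScenarioSpec(
            removals=frozenset(MEAT_GROUPS), scalings={"fish_seafood": m}
        )
        gaps = nutrient_gaps(apply_scenario(b12_world, spec))
        assert gaps.set_index("nutrient_id").at[
            "vitamin_b12", "gap_percent"] <= 1e-9

    def test_donor_without_nutrient_cannot_close(self, b12_world):
        m = replacement_multiplier(
            b12_world, "cereals", MEAT_GROUPS, "vitamin_b12"
        )
        assert m == CANNOT_CLOSE

    def test_donor_among_removed_rejected(self, b12_world):
        with pytest.raises(ScenarioError, match="dairy"):
            replacement_multiplier(
                b12_world, "dairy", list(MEAT_GROUPS) + ["dairy"],
                "vitamin_b12",
            )

    def test_joint_multiplier_is_max_over_nutrients(self, b12_world):
        m = joint_replacement_multiplier(
            b12_world, "dairy", MEAT_GROUPS, ["vitamin_b12"]
        )
        assert m == pytest.approx(3.0, abs=1e-9)


class TestSpecSerialisation:
    def test_yaml_round_trip(self, tmp_path):
        spec = ScenarioSpec(
            removals=frozenset({"ruminant_meat"}),
            scalings={"dairy": 3.0},
            default_multiplier=1.2,
            target_year=2030,
        )
        path = tmp_path / "scenario.yaml"
        import yaml

        path.write_text(yaml.safe_dump(spec.to_dict()))
        back = ScenarioSpec.from_yaml(path)
        assert back == spec
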