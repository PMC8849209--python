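"""Nutrient conversion, group aggregation, percentage decomposition,
per-capita quantities and the display convention."""

import numpy as np
import pandas as pd
import pytest

from nutriflow import pipeline, scenario
from nutriflow.errors import DomainError, TaxonomyError, UnitError
from nutriflow.nutrient_engine import (
    ContributionTable,
    aggregate_by_group,
    contribution_percentages,
    format_percentage_cell,
    nutrient_availability,
    per_capita_daily,
)
from nutriflow.nutrients import DEFAULT_UNITS, GRAMS_PER_TONNE, NUTRIENTS
from nutriflow.synthetic import MEAT_GROUPS


def food_mass_row(cid, group, consumed):
    return {"commodity_id": cid, "group_id": group, "consumed": consumed}


def comp_row(cid, nutrient, amount, unit=None):
    return {"commodity_id": cid, "nutrient_id": nutrient, "amount": amount,
            "unit": unit or DEFAULT_UNITS[nutrient]}


class TestAvailability:
    def test_tonnes_to_grams_conversion(self):
        # 1 t consumed at 20 g protein / 100 g -> 200,000 g protein
        avail = nutrient_availability(
            pd.DataFrame([food_mass_row("beef", "ruminant_meat", 1.0)]),
            pd.DataFrame([comp_row("beef", "protein", 20.0)]),
            pd.DataFrame(
                [{"commodity_id": "beef", "nutrient_id": "protein",
                  "coefficient": 1.0}]
            ),
            DEFAULT_UNITS,
        )
        assert avail["gross"].iloc[0] == 200_000.0
        assert avail["bioavailable"].iloc[0] == 200_000.0

    def test_offal_digestibility_scales_protein(self):
        avail = nutrient_availability(
            pd.DataFrame([food_mass_row("offal", "offal_and_fats", 2.0)]),
            pd.DataFrame([comp_row("offal", "protein", 18.0)]),
            pd.DataFrame(
                [{"commodity_id": "offal", "nutrient_id": "protein",
                  "coefficient": 0.76}]
            ),
            DEFAULT_UNITS,
        )
        gross = avail["gross"].iloc[0]
        assert avail["bioavailable"].iloc[0] == 0.76 * gross

    def test_coefficient_ignored_for_unscaled_nutrient(self):
        avail = nutrient_availability(
            pd.DataFrame([food_mass_row("beef", "ruminant_meat", 1.0)]),
            pd.DataFrame([comp_row("beef", "iron", 2.5)]),
            pd.DataFrame(columns=["commodity_id", "nutrient_id", "coefficient"]),
            DEFAULT_UNITS,
        )
        assert avail["bioavailable"].iloc[0] == avail["gross"].iloc[0]

    def test_missing_composition_contributes_zero(self):
        avail = nutrient_availability(
            pd.DataFrame([food_mass_row("beef", "ruminant_meat", 5.0)]),
            pd.DataFrame([comp_row("beef", "fiber", np.nan)]),
            pd.DataFrame(columns=["commodity_id", "nutrient_id", "coefficient"]),
            DEFAULT_UNITS,
        )
        assert avail["gross"].iloc[0] == 0.0

    def test_unit_mismatch_raises(self):
        with pytest.raises(UnitError, match="registry"):
            nutrient_availability(
                pd.DataFrame([food_mass_row("beef", "ruminant_meat", 1.0)]),
                pd.DataFrame([comp_row("beef", "protein", 20.0, unit="mg")]),
                pd.DataFrame(
                    columns=["commodity_id", "nutrient_id", "coefficient"]
                ),
                DEFAULT_UNITS,
            )


class TestAggregation:
    def avail(self, rows):
        return pd.DataFrame(
            rows,
            columns=["commodity_id", "group_id", "nutrient_id", "gross",
                     "bioavailable", "unit"],
        )

    def test_single_commodity_groups_are_identity(self):
        avail = self.avail([
            ("beef", "ruminant_meat", "protein", 10.0, 9.0, "g"),
            ("milk", "dairy", "protein", 4.0, 4.0, "g"),
        ])
        out = aggregate_by_group(avail).set_index("group_id")
        assert out.at["ruminant_meat", "gross"] == 10.0
        assert out.at["dairy", "bioavailable"] == 4.0

    def test_equal_commodities_double_the_group(self):
        avail = self.avail([
            ("a", "dairy", "protein", 4.0, 3.0, "g"),
            ("b", "dairy", "protein", 4.0, 3.0, "g"),
        ])
        out = aggregate_by_group(avail)
        assert out["gross"].iloc[0] == 8.0
        assert out["bioavailable"].iloc[0] == 6.0

    def test_unmapped_commodity_is_taxonomy_error(self):
        avail = self.avail([("a", "dairy", "protein", 1.0, 1.0, "g")])
        with pytest.raises(TaxonomyError, match="'a'"):
            aggregate_by_group(avail, taxonomy={"b": "dairy"})


class TestContributions:
    def totals(self, rows):
        return pd.DataFrame(
            rows, columns=["group_id", "nutrient_id", "gross", "bioavailable"]
        )

    def test_sole_supplier_is_100_percent(self):
        table = contribution_percentages(
            self.totals([("meat", "protein", 5.0, 4.0)])
        )
        assert table.values.at["meat", "protein"] == 100.0

    def test_hand_set_shares(self):
        table = contribution_percentages(
            self.totals([
                ("meat", "protein", 0.0, 25.0),
                ("plants", "protein", 0.0, 75.0),
            ])
        )
        assert table.values.at["meat", "protein"] == 25.0
        assert table.values.at["plants", "protein"] == 75.0

    def test_zero_availability_displays_no_contribution(self):
        table = contribution_percentages(
            self.totals([
                ("meat", "fiber", 0.0, 0.0),
                ("plants", "fiber", 0.0, 30.0),
            ])
        )
        assert table.values.at["meat", "fiber"] == 0.0
        assert table.display().at["meat", "fiber"] == "No contribution"

    def test_zero_global_total_is_undefined_not_zero(self):
        table = contribution_percentages(
            self.totals([("meat", "fiber", 0.0, 0.0)])
        )
        assert np.isnan(table.values.at["meat", "fiber"])
        assert table.display().at["meat", "fiber"] == "n/a"

    def test_basis_selects_column(self):
        totals = self.totals([
            ("meat", "protein", 50.0, 10.0),
            ("plants", "protein", 50.0, 90.0),
        ])
        assert contribution_percentages(totals, basis="gross").values.at[
            "meat", "protein"] == 50.0
        assert contribution_percentages(totals, basis="bioavailable").values.at[
            "meat", "protein"] == 10.0


class TestPerCapita:
    def test_one_gram_per_person_day(self):
        # 365 t/year over one million people is 1 g/person/day
        assert per_capita_daily(
            365.0, 1.0e6, grams_per_unit=GRAMS_PER_TONNE
        ) == 1.0

    def test_zero_total(self):
        assert per_capita_daily(0.0, 1.0e6) == 0.0

    def test_nonpositive_population_rejected(self):
        with pytest.raises(DomainError):
            per_capita_daily(1.0, 0.0)

    def test_global_meat_mass_near_115_g(self, global_2018):
        result = pipeline.run(global_2018, focus_groups=MEAT_GROUPS)
        assert result.summary["focus_per_capita_g_day"] == pytest.approx(
            316.0e12 / (7.53e9 * 365.0), rel=1e-9
        )
        assert round(result.summary["focus_per_capita_g_day"]) == 115


class TestDisplayConvention:
    @pytest.mark.parametrize(
        "raw, shown",
        [
            (0.3, "<0.5"),
            (0.0, "No contribution"),
            (20.5, "21"),   # round half up
            (0.5, "1"),
            (11.4, "11"),
            (99.5, "100"),
            (float("nan"), "n/a"),
        ],
    )
    def test_cell_formatting(self, raw, shown):
        assert format_percentage_cell(raw) == shown


class TestPipelineInvariants:
    @pytest.mark.parametrize("seed", [0, 7])
    def test_percentage_columns_sum_to_100(self, small_world, seed):
        result = pipeline.run(small_world(seed=seed))
        sums = result.contributions.sum_over(result.contributions.groups)
        defined = sums.dropna()
        assert np.allclose(defined, 100.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_bioavailable_never_exceeds_gross(self, small_world, seed):
        result = pipeline.run(small_world(seed=seed))
        assert (
            result.availability["bioavailable"]
            <= result.availability["gross"]
        ).all()

    def test_scale_invariance_of_percentages(self, small_world):
        bundle = small_world(seed=4)
        base = pipeline.run(bundle)
        k = 1.7
        scaled_bundle = scenario.apply_scenario(
            bundle, scenario.ScenarioSpec(default_multiplier=k)
        )
        scaled = pipeline.run(scaled_bundle)
        a, b = base.contributions.values, scaled.contributions.values
        assert np.allclose(a.fillna(-1.0), b.fillna(-1.0), atol=1e-9)
        assert np.allclose(
            scaled.per_capita["per_capita_daily"],
            k * base.per_capita["per_capita_daily"],
            rtol=1e-9,
        )

    def test_all_coefficients_one_makes_bases_identical(self, small_world):
        bundle = small_world(seed=5)
        bundle.bioavailability = bundle.bioavailability.assign(coefficient=1.0)
        result_g = pipeline.run(bundle, basis="gross")
        result_b = pipeline.run(bundle, basis="bioavailable")
        pd.testing.assert_frame_equal(
            result_g.contributions.values, result_b.contributions.values,
            check_exact=True,
        )
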