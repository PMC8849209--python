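"""End-to-end pipeline: bundle -> food mass -> availability -> contributions
-> per-capita table -> headline summary."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .mass_balance import food_mass_frame
from .nutrient_engine import (
    ContributionTable,
    aggregate_by_group,
    contribution_percentages,
    format_percentage_cell,
    nutrient_availability,
    per_capita_daily,
)
from .nutrients import GRAMS_PER_TONNE, NUTRIENTS
from .schema import DatasetBundle

PER_CAPITA_COLUMNS = ["nutrient_id", "per_capita_daily", "unit", "basis"]


@dataclass
class PipelineResult:
    """All stage outputs for one bundle run."""

    food_mass: pd.DataFrame
    availability: pd.DataFrame
    group_totals: pd.DataFrame
    contributions: ContributionTable
    per_capita: pd.DataFrame
    population: float
    basis: str
    summary: dict = field(default_factory=dict)


def run(
    bundle: DatasetBundle,
    basis: str = "bioavailable",
    trade_mode: str = "netted",
    focus_groups: Iterable[str] | None = None,
) -> PipelineResult:
    """Run the full model on a bundle.

    ``focus_groups`` (e.g. the five meat groups) drive the headline summary:
    their share of total food mass and of energy/fat/protein availability,
    their per-capita daily mass, and the food-mass share of each focus group
    within the focus total.
    """
    food_mass = food_mass_frame(bundle, trade_mode=trade_mode)
    availability = nutrient_availability(
        food_mass, bundle.composition, bundle.bioavailability, bundle.units
    )
    group_totals = aggregate_by_group(availability)
    contributions = contribution_percentages(group_totals, basis=basis)
    population = bundle.global_population()

    per_capita_rows = []
    for n in NUTRIENTS:
        sel = group_totals[group_totals["nutrient_id"] == n]
        total = float(sel[basis].sum())
        per_capita_rows.append(
            {
                "nutrient_id": n,
                "per_capita_daily": per_capita_daily(total, population),
                "unit": bundle.units[n],
                "basis": basis,
            }
        )
    per_capita = pd.DataFrame(per_capita_rows, columns=PER_CAPITA_COLUMNS)

    result = PipelineResult(
        food_mass=food_mass,
        availability=availability,
        group_totals=group_totals,
        contributions=contributions,
        per_capita=per_capita,
        population=population,
        basis=basis,
    )
    if focus_groups:
        result.summary = headline_summary(result, focus_groups)
    return result


def headline_summary(
    result: PipelineResult, focus_groups: Iterable[str]
) -> dict:
    """Headline numbers for a set of focus groups (typically the meat
    groups): food-mass share, nutrient shares, per-capita mass, and the
    decomposition of the focus food mass over its subgroups."""
    focus = list(focus_groups)
    fm = result.food_mass
    in_focus = fm["group_id"].isin(focus)
    total_mass = float(fm["available_as_food"].sum())
    focus_mass = float(fm.loc[in_focus, "available_as_food"].sum())

    subgroup_shares = {}
    if focus_mass > 0:
        for g in focus:
            mass_g = float(
                fm.loc[fm["group_id"] == g, "available_as_food"].sum()
            )
            subgroup_shares[g] = 100.0 * mass_g / focus_mass

    nutrient_shares = {}
    for n in ("energy", "fat", "protein"):
        if n in result.contributions.values.columns:
            nutrient_shares[n] = float(
                result.contributions.sum_over(focus)[n]
            )

    return {
        "focus_groups": focus,
        "focus_food_mass": focus_mass,
        "total_food_mass": total_mass,
        "focus_food_mass_share_pct": (
            100.0 * focus_mass / total_mass if total_mass > 0 else float("nan")
        ),
        "focus_per_capita_g_day": per_capita_daily(
            focus_mass, result.population, grams_per_unit=GRAMS_PER_TONNE
        ),
        "subgroup_food_mass_shares_pct": subgroup_shares,
        "focus_nutrient_shares_pct": nutrient_shares,
    }


def format_summary(summary: dict) -> str:
    """Plain-text rendering of a headline summary."""
    lines = [
        f"focus groups: {', '.join(summary['focus_groups'])}",
        f"food mass share of total: "
        f"{summary['focus_food_mass_share_pct']:.1f}%",
        f"per-capita availability: "
        f"{summary['focus_per_capita_g_day']:.1f} g/person/day",
    ]
    for n, v in summary["focus_nutrient_shares_pct"].items():
        lines.append(f"share of global {n}: {format_percentage_cell(v)}%")
    lines.append("subgroup shares of focus food mass:")
    for g, v in summary["subgroup_food_mass_shares_pct"].items():
        lines.append(f"  {g}: {format_percentage_cell(v)}%")
    return "\n".join(lines)
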