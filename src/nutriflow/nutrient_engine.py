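"""Conversion of consumed food mass into nutrient availability, food-group
aggregation, percentage-contribution decomposition and per-capita daily
quantities.

Gross availability of nutrient n from commodity c is

    gross(c, n) = consumed_tonnes(c) * 10^4 * amount_per_100g(c, n)

in the registry unit of n (1 t = 10^4 x 100 g).  For protein and the seven
indispensable amino acids the bioavailable quantity additionally carries a
digestibility coefficient in (0, 1]; for every other nutrient bioavailable
equals gross.  Contribution percentages divide each group's total by the
total over ALL groups in the bundle, so columns sum to 100 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, TaxonomyError, UnitError
from .nutrients import (
    BIOAVAILABILITY_NUTRIENTS,
    DAYS_PER_YEAR,
    NUTRIENTS,
    TONNES_TO_100G,
)

logger = logging.getLogger(__name__)

AVAILABILITY_COLUMNS = [
    "commodity_id", "group_id", "nutrient_id", "gross", "bioavailable", "unit",
]

#: Display strings of the contribution table.
NO_CONTRIBUTION = "No contribution"
BELOW_HALF = "<0.5"
UNDEFINED = "n/a"  # nutrient with zero global availability


def nutrient_availability(
    food_mass: pd.DataFrame,
    composition: pd.DataFrame,
    bioavailability: pd.DataFrame,
    units: Mapping[str, str],
) -> pd.DataFrame:
    """Commodity x nutrient gross and bioavailable availability (long form).

    ``food_mass`` is the mass-balance output (needs commodity_id, group_id,
    consumed).  Missing composition values contribute zero, logged once per
    batch with the affected (commodity, nutrient) count.  A composition unit
    disagreeing with the registry raises UnitError.
    """
    bad_units = composition[
        composition["unit"] != composition["nutrient_id"].map(units)
    ]
    if len(bad_units):
        row = bad_units.iloc[0]
        raise UnitError(
            f"composition unit '{row['unit']}' for '{row['nutrient_id']}' "
            f"does not match registry '{units.get(row['nutrient_id'])}'"
        )

    merged = composition.merge(
        food_mass[["commodity_id", "group_id", "consumed"]],
        on="commodity_id",
        how="inner",
    )
    n_missing = int(merged["amount"].isna().sum())
    if n_missing:
        logger.warning(
            "nutrient_availability: %d missing composition value(s) "
            "contribute zero", n_missing
        )
    amount = merged["amount"].fillna(0.0)
    gross = merged["consumed"] * TONNES_TO_100G * amount

    coeff_map = {
        (r.commodity_id, r.nutrient_id): r.coefficient
        for r in bioavailability.itertuples(index=False)
    }
    keys = list(zip(merged["commodity_id"], merged["nutrient_id"]))
    scaled = merged["nutrient_id"].isin(BIOAVAILABILITY_NUTRIENTS).to_numpy()
    coeff = np.array(
        [
            coeff_map.get(k, 1.0) if is_scaled else 1.0
            for k, is_scaled in zip(keys, scaled)
        ]
    )
    bioavailable = gross * coeff

    out = pd.DataFrame(
        {
            "commodity_id": merged["commodity_id"],
            "group_id": merged["group_id"],
            "nutrient_id": merged["nutrient_id"],
            "gross": gross.astype("float64"),
            "bioavailable": bioavailable.astype("float64"),
            "unit": merged["nutrient_id"].map(units),
        }
    )
    return out.sort_values(
        ["commodity_id", "nutrient_id"], ignore_index=True
    )[AVAILABILITY_COLUMNS]


def aggregate_by_group(
    availability: pd.DataFrame, taxonomy: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Sum availability over the commodities of each food group.

    Returns long form: group_id, nutrient_id, gross, bioavailable.  If a
    ``taxonomy`` map is given it overrides/checks the group_id column; an
    unmapped commodity raises TaxonomyError.
    """
    avail = availability
    if taxonomy is not None:
        unmapped = set(avail["commodity_id"]) - set(taxonomy)
        if unmapped:
            raise TaxonomyError(
                f"commodity(ies) {sorted(unmapped)} not mapped to any group"
            )
        avail = avail.assign(group_id=avail["commodity_id"].map(taxonomy))
    if avail["group_id"].isna().any():
        missing = avail.loc[avail["group_id"].isna(), "commodity_id"]
        raise TaxonomyError(
            f"commodity(ies) {sorted(set(missing))} not mapped to any group"
        )
    out = (
        avail.groupby(["group_id", "nutrient_id"], as_index=False)[
            ["gross", "bioavailable"]
        ]
        .sum()
        .sort_values(["group_id", "nutrient_id"], ignore_index=True)
    )
    return out


@dataclass
class ContributionTable:
    """Food-group x nutrient percentage-of-global-availability table.

    ``values`` is a wide frame (index group_id, columns nutrient ids) of raw
    (unrounded) percentages; cells for nutrients with zero global
    availability are NaN (undefined, not 0).  ``basis`` records whether the
    decomposition used gross or bioavailable quantities.
    """

    values: pd.DataFrame
    basis: str = "bioavailable"

    @property
    def groups(self) -> list[str]:
        return list(self.values.index)

    @property
    def nutrients(self) -> list[str]:
        return list(self.values.columns)

    def sum_over(self, groups: Iterable[str]) -> pd.Series:
        """Per-nutrient sum of the raw percentage cells of ``groups``.

        This is the additivity surface: summing subgroup contributions gives
        the aggregate group's contribution, and summing over all groups
        gives 100 for every nutrient with nonzero availability.
        """
        groups = list(groups)
        missing = [g for g in groups if g not in self.values.index]
        if missing:
            raise TaxonomyError(f"unknown group(s) {missing}")
        return self.values.loc[groups].sum(axis=0)

    def display(self) -> pd.DataFrame:
        """Rounded display table (strings), same shape as ``values``."""
        return self.values.map(format_percentage_cell)

    def to_long(self) -> pd.DataFrame:
        """Long form with raw and display columns, for CSV output."""
        long = (
            self.values.rename_axis("group_id")
            .reset_index()
            .melt(
                id_vars="group_id",
                var_name="nutrient_id",
                value_name="percentage",
            )
        )
        long["display"] = long["percentage"].map(format_percentage_cell)
        long["basis"] = self.basis
        return long.sort_values(
            ["group_id", "nutrient_id"], ignore_index=True
        )

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "ContributionTable":
        basis = str(long["basis"].iloc[0]) if len(long) else "bioavailable"
        wide = long.pivot(
            index="group_id", columns="nutrient_id", values="percentage"
        )
        wide.index.name = None
        wide.columns.name = None
        order = [n for n in NUTRIENTS if n in wide.columns] + [
            n for n in wide.columns if n not in NUTRIENTS
        ]
        return cls(values=wide[order].sort_index(), basis=basis)


def contribution_percentages(
    group_totals: pd.DataFrame, basis: str = "bioavailable"
) -> ContributionTable:
    """Decompose global availability into group percentage contributions.

    cell(g, n) = 100 * totals(g, n) / sum_g' totals(g', n).  Because
    bioavailable equals gross for all nutrients outside protein/IAA, the
    ``bioavailable`` basis is exactly the reporting convention that scales
    protein and the amino acids by digestibility and leaves everything else
    gross.
    """
    if basis not in ("gross", "bioavailable"):
        raise ValueError(f"unknown basis '{basis}'")
    wide = group_totals.pivot(
        index="group_id", columns="nutrient_id", values=basis
    ).fillna(0.0)
    wide.index.name = None
    wide.columns.name = None
    totals = wide.sum(axis=0)
    values = pd.DataFrame(
        index=wide.index, columns=wide.columns, dtype="float64"
    )
    for n in wide.columns:
        t = totals[n]
        if t > 0:
            # same scalar expression as the brute-force oracle
            values[n] = [100.0 * g / t for g in wide[n]]
        else:
            values[n] = np.nan  # undefined, not zero
    order = [n for n in NUTRIENTS if n in values.columns] + [
        n for n in values.columns if n not in NUTRIENTS
    ]
    return ContributionTable(values=values[order].sort_index(), basis=basis)


def per_capita_daily(
    total: float,
    population: float,
    days_per_year: float = DAYS_PER_YEAR,
    grams_per_unit: float = 1.0,
) -> float:
    """Annual total -> per-person-per-day quantity.

    ``grams_per_unit`` converts mass units (1e6 for tonnes -> grams);
    nutrient totals are already in registry units and use the default 1.
    """
    if population <= 0:
        raise DomainError(f"population must be positive, got {population}")
    return total * grams_per_unit / (population * days_per_year)


def format_percentage_cell(value: float) -> str:
    """Table display convention for one raw percentage cell.

    Exact zero renders "No contribution"; values in (0, 0.5) render "<0.5";
    undefined (NaN) cells render "n/a"; everything else rounds half-up to an
    integer percent.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNDEFINED
    if value == 0:
        return NO_CONTRIBUTION
    if 0 < value < 0.5:
        return BELOW_HALF
    return str(
        int(Decimal(repr(float(value))).quantize(0, rounding=ROUND_HALF_UP))
    )


def render_display(table: ContributionTable) -> pd.DataFrame:
    """Display table of strings (raw values stay available on the table)."""
    return table.display()
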