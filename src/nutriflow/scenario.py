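"""Counterfactual scenarios: food-group removal, production scaling,
per-nutrient gaps against reference values, and replacement multipliers.

A scenario scales all supply-side flows of a commodity uniformly (production,
trade, feed, losses, processing_input, ...), preserving its food fraction;
removal zeroes the whole ledger.  Gaps compare per-capita daily availability
(bioavailable basis by default) with per-capita reference values:

    gap_percent = max(0, 100 * (1 - available / requirement))
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import pipeline
from .errors import DomainError, ScenarioError, TaxonomyError
from .nutrients import DAYS_PER_YEAR, GLOBAL_REGION
from .schema import MASS_COLUMNS, DatasetBundle

logger = logging.getLogger(__name__)

GAP_COLUMNS = [
    "nutrient_id",
    "available_per_capita_daily",
    "requirement_per_capita_daily",
    "gap_percent",
    "surplus",
]

#: Marker returned when a donor cannot close a gap (zero availability).
CANNOT_CLOSE = float("inf")


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative perturbation of a bundle.

    removals: groups whose commodities are zeroed out.
    scalings: group -> multiplier (>= 0); groups not listed get
    ``default_multiplier``.  A removed group may not also be scaled.
    """

    removals: frozenset = frozenset()
    scalings: Mapping[str, float] = field(default_factory=dict)
    default_multiplier: float = 1.0
    target_year: int | None = None
    population_override: float | None = None

    def validate(self, groups: Iterable[str]) -> None:
        groups = set(groups)
        unknown = (set(self.removals) | set(self.scalings)) - groups
        if unknown:
            raise TaxonomyError(f"unknown group(s) in scenario: {sorted(unknown)}")
        overlap = set(self.removals) & set(self.scalings)
        if overlap:
            raise ScenarioError(
                f"group(s) {sorted(overlap)} both removed and scaled"
            )
        bad = {g: m for g, m in self.scalings.items() if m < 0}
        if bad or self.default_multiplier < 0:
            raise ScenarioError(f"negative multiplier(s): {bad}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioSpec":
        return cls(
            removals=frozenset(d.get("removals", ())),
            scalings=dict(d.get("scalings", {})),
            default_multiplier=float(d.get("default_multiplier", 1.0)),
            target_year=d.get("target_year"),
            population_override=d.get("population_override"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "removals": sorted(self.removals),
            "scalings": dict(self.scalings),
            "default_multiplier": self.default_multiplier,
            "target_year": self.target_year,
            "population_override": self.population_override,
        }


def apply_scenario(bundle: DatasetBundle, spec: ScenarioSpec) -> DatasetBundle:
    """Return a perturbed copy of the bundle.

    Removed groups' commodities get a zero ledger and processing rules into
    them are dropped (that mass leaves the food system).  Other commodities'
    mass columns are multiplied by their group's multiplier.  The identity
    scenario (no removals, all multipliers 1.0) is a bitwise no-op.
    """
    spec.validate(bundle.groups)
    out = bundle.copy()
    bal = out.balances
    taxonomy = bundle.taxonomy

    group = bal["group_id"]
    removed = group.isin(spec.removals)
    multiplier = group.map(
        lambda g: spec.scalings.get(g, spec.default_multiplier)
    ).astype("float64")
    multiplier[removed] = 0.0
    for col in MASS_COLUMNS:
        bal[col] = bal[col] * multiplier

    if len(out.processing):
        child_removed = out.processing["child_id"].map(taxonomy).isin(
            spec.removals
        )
        out.processing = out.processing[~child_removed].reset_index(drop=True)

    if spec.target_year is not None:
        year = int(spec.target_year)
        out.balances["year"] = year
        if spec.population_override is not None:
            pop = out.population
            pop = pop[~((pop["year"] == year)
                        & (pop["region_id"] == GLOBAL_REGION))]
            override = pd.DataFrame(
                [{"region_id": GLOBAL_REGION, "year": year,
                  "headcount": float(spec.population_override)}]
            )
            out.population = pd.concat([pop, override], ignore_index=True)
        elif not (out.population["year"] == year).any():
            raise ScenarioError(
                f"no population row for target year {year} and no override"
            )
    elif spec.population_override is not None:
        year = bundle.reference_year
        pop = out.population
        pop = pop[~((pop["year"] == year)
                    & (pop["region_id"] == GLOBAL_REGION))]
        override = pd.DataFrame(
            [{"region_id": GLOBAL_REGION, "year": year,
              "headcount": float(spec.population_override)}]
        )
        out.population = pd.concat([pop, override], ignore_index=True)
    return out


def nutrient_gaps(
    bundle: DatasetBundle,
    basis: str = "bioavailable",
    trade_mode: str = "netted",
) -> pd.DataFrame:
    """Per-nutrient gap report against the bundle's reference values.

    Nutrients without a requirement row are omitted with a warning.
    gap_percent is in [0, 100] and is 0 iff availability covers the
    requirement.
    """
    req = bundle.requirements
    bad = req[req["per_capita_daily"] <= 0]
    if len(bad):
        raise DomainError(
            f"nonpositive requirement for {list(bad['nutrient_id'])}"
        )
    result = pipeline.run(bundle, basis=basis, trade_mode=trade_mode)
    per_capita = dict(
        zip(result.per_capita["nutrient_id"],
            result.per_capita["per_capita_daily"])
    )
    omitted = [n for n in per_capita if n not in set(req["nutrient_id"])]
    if omitted:
        logger.warning(
            "nutrient_gaps: %d nutrient(s) without reference values omitted",
            len(omitted),
        )
    rows = []
    for row in req.itertuples(index=False):
        a = float(per_capita.get(row.nutrient_id, 0.0))
        r = float(row.per_capita_daily)
        gap = max(0.0, 100.0 * (1.0 - a / r))
        rows.append(
            {
                "nutrient_id": row.nutrient_id,
                "available_per_capita_daily": a,
                "requirement_per_capita_daily": r,
                "gap_percent": gap,
                "surplus": a >= r,
            }
        )
    return pd.DataFrame(rows, columns=GAP_COLUMNS)


def _annual_availability(
    bundle: DatasetBundle, nutrient: str, basis: str
) -> float:
    """Total annual availability of one nutrient over all groups."""
    result = pipeline.run(bundle, basis=basis)
    sel = result.group_totals[result.group_totals["nutrient_id"] == nutrient]
    return float(sel[basis].sum())


def replacement_multiplier(
    bundle: DatasetBundle,
    donor_group: str,
    removed_groups: Iterable[str],
    nutrient: str,
    basis: str = "bioavailable",
) -> float:
    """Smallest m >= 1 scaling the donor so the nutrient's per-capita
    availability meets the requirement with the removed groups zeroed.

    Closed form: with R the per-capita daily requirement, P the population
    and availability affine in the donor multiplier (A(m) = A_other + m *
    A_donor), m = (R*P*365 - A_other) / A_donor.  A_other and A_donor are
    measured by two pipeline evaluations (donor zeroed vs. baseline), which
    also covers the case where part of the donor group's availability flows
    in from unscaled processing parents.  Returns ``inf`` (cannot close)
    when the donor adds nothing.
    """
    removed = frozenset(removed_groups)
    if donor_group in removed:
        raise ScenarioError(
            f"donor group '{donor_group}' is among the removed groups"
        )
    req = bundle.requirements
    row = req[req["nutrient_id"] == nutrient]
    if row.empty:
        raise DomainError(f"no requirement row for nutrient '{nutrient}'")
    requirement = float(row["per_capita_daily"].iloc[0])
    if requirement <= 0:
        raise DomainError(f"nonpositive requirement for '{nutrient}'")

    base_spec = ScenarioSpec(removals=removed)
    zero_spec = ScenarioSpec(removals=removed, scalings={donor_group: 0.0})
    with_donor = apply_scenario(bundle, base_spec)
    without_donor = apply_scenario(bundle, zero_spec)
    a_other = _annual_availability(without_donor, nutrient, basis)
    a_donor = (
        _annual_availability(with_donor, nutrient, basis) - a_other
    )
    population = with_donor.global_population()
    target = requirement * population * DAYS_PER_YEAR
    if a_other >= target:
        return 1.0  # baseline already sufficient
    if a_donor <= 0:
        logger.warning(
            "donor '%s' contributes no %s; gap cannot be closed",
            donor_group, nutrient,
        )
        return CANNOT_CLOSE
    return max(1.0, (target - a_other) / a_donor)


def joint_replacement_multiplier(
    bundle: DatasetBundle,
    donor_group: str,
    removed_groups: Iterable[str],
    nutrients: Iterable[str],
    basis: str = "bioavailable",
) -> float:
    """Multiplier closing every listed nutrient's gap: the max over the
    per-nutrient multipliers (replacement is solved one nutrient at a
    time)."""
    return max(
        replacement_multiplier(bundle, donor_group, removed_groups, n, basis)
        for n in nutrients
    )
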