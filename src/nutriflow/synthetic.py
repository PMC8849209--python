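"""Miniature synthetic worlds with an independent brute-force oracle.

``generate_world`` builds small, fully-specified bundles that emulate the
statistical structure of the real inputs (meat-like waste fractions 2-11%,
inedible portions 8-43%, bioavailability coefficients 0.68-1.0) without any
external data.  ``oracle_outputs`` recomputes every pipeline quantity by
naive per-record Python iteration, independent of the vectorised path, so
the two can be compared exactly.

Exactness by construction: generated masses are small integers and every
fraction, extraction rate, coefficient and composition value sits on a
dyadic grid (denominators 64, 32, powers of two) sized so that all products
and all partial sums arising in the pipeline are exactly representable in
float64.  Summation order is then irrelevant and pipeline-vs-oracle equality
is bitwise, not approximate.

The fixed fixtures (``make_global_2018_world`` and friends) use decimal
magnitudes shaped like published global food-system figures; they are
synthetic constructions, not real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError
from .nutrients import (
    BIOAVAILABILITY_NUTRIENTS,
    DAYS_PER_YEAR,
    DEFAULT_UNITS,
    GLOBAL_REGION,
    INDISPENSABLE_AMINO_ACIDS,
    NUTRIENTS,
    TONNES_TO_100G,
)
from .schema import (
    BALANCE_COLUMNS,
    BIOAVAILABILITY_COLUMNS,
    COMPOSITION_COLUMNS,
    FRACTION_COLUMNS,
    POPULATION_COLUMNS,
    PROCESSING_COLUMNS,
    REQUIREMENT_COLUMNS,
    DatasetBundle,
)

MEAT_GROUPS: tuple[str, ...] = (
    "ruminant_meat",
    "poultry_meat",
    "pig_meat",
    "other_meat",
    "offal_and_fats",
)

NON_MEAT_POOL: tuple[str, ...] = (
    "dairy",
    "cereals",
    "vegetables",
    "fruits",
    "fish_seafood",
    "eggs",
    "legumes",
    "roots_tubers",
)

ANIMAL_GROUPS = set(MEAT_GROUPS) | {"dairy", "fish_seafood", "eggs"}

#: Plausible adult per-capita daily reference values, registry units.
DEFAULT_REQUIREMENTS: dict[str, float] = {
    "carbohydrates": 130.0,
    "energy": 2250.0,
    "fat": 70.0,
    "fiber": 30.0,
    "protein": 50.0,
    "calcium": 1000.0,
    "copper": 0.9,
    "iron": 14.0,
    "magnesium": 400.0,
    "phosphorus": 700.0,
    "potassium": 3500.0,
    "selenium": 55.0,
    "zinc": 11.0,
    "vitamin_a": 800.0,
    "vitamin_b1": 1.2,
    "vitamin_b2": 1.3,
    "vitamin_b5": 5.0,
    "vitamin_b6": 1.4,
    "vitamin_b9": 400.0,
    "vitamin_b12": 2.4,
    "vitamin_c": 80.0,
    "vitamin_e": 13.0,
    "cystine": 0.29,
    "histidine": 0.7,
    "leucine": 2.9,
    "lysine": 2.1,
    "methionine": 0.73,
    "threonine": 1.05,
    "tryptophan": 0.28,
}

#: Dyadic quantum per nutrient for generated compositions (amount = j * q,
#: j integer in [1, 64]); spans roughly the realistic per-100 g magnitude
#: of each nutrient class.
_COMPOSITION_QUANTUM: dict[str, float] = {
    "carbohydrates": 1.0,
    "energy": 4.0,
    "fat": 0.5,
    "fiber": 0.25,
    "protein": 0.5,
    "calcium": 8.0,
    "copper": 1.0 / 64,
    "iron": 0.125,
    "magnesium": 4.0,
    "phosphorus": 8.0,
    "potassium": 16.0,
    "selenium": 1.0,
    "zinc": 0.25,
    "vitamin_a": 8.0,
    "vitamin_b1": 1.0 / 32,
    "vitamin_b2": 1.0 / 32,
    "vitamin_b5": 1.0 / 16,
    "vitamin_b6": 1.0 / 32,
    "vitamin_b9": 4.0,
    "vitamin_b12": 1.0 / 16,
    "vitamin_c": 1.0,
    "vitamin_e": 0.25,
    "cystine": 1.0 / 32,
    "histidine": 1.0 / 32,
    "leucine": 1.0 / 16,
    "lysine": 1.0 / 16,
    "methionine": 1.0 / 32,
    "threonine": 1.0 / 32,
    "tryptophan": 1.0 / 64,
}


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a generated world.

    The default fraction ranges are the meat-like study conditions: in-home
    waste 2-11% (regional spread), inedible portion 8-43% (by meat type),
    bioavailability coefficients 0.68-1.0.
    """

    n_commodities: int = 14
    n_groups: int = 8
    seed: int = 0
    waste_range: tuple[float, float] = (0.02, 0.11)
    inedible_range: tuple[float, float] = (0.08, 0.43)
    bioavailability_range: tuple[float, float] = (0.68, 1.0)
    composition_sparsity: float = 0.1
    population: float = 7.53e9
    year: int = 2018

    def validate(self) -> None:
        if self.n_groups < 7:
            raise DomainError(
                "n_groups must be >= 7 (five meat-like groups plus at least "
                "two non-meat groups)"
            )
        if self.n_groups > 5 + len(NON_MEAT_POOL):
            raise DomainError(
                f"n_groups must be <= {5 + len(NON_MEAT_POOL)}"
            )
        if self.n_commodities < self.n_groups + 1:
            raise DomainError(
                "n_commodities must be >= n_groups + 1 (one commodity per "
                "group plus a processing parent)"
            )
        for name, (lo, hi) in (
            ("waste_range", self.waste_range),
            ("inedible_range", self.inedible_range),
        ):
            if not (0.0 <= lo <= hi < 1.0):
                raise DomainError(f"{name} {lo, hi} not within [0, 1)")
        lo, hi = self.bioavailability_range
        if not (0.0 < lo <= hi <= 1.0):
            raise DomainError(
                f"bioavailability_range {lo, hi} not within (0, 1]"
            )
        if not (0.0 <= self.composition_sparsity < 1.0):
            raise DomainError("composition_sparsity must be in [0, 1)")
        if self.population <= 0:
            raise DomainError("population must be positive")
        # dyadic grids must be non-empty for the configured ranges
        for name, (lo, hi), den in (
            ("waste_range", self.waste_range, 64),
            ("inedible_range", self.inedible_range, 64),
            ("bioavailability_range", self.bioavailability_range, 32),
        ):
            if math.ceil(lo * den) > math.floor(hi * den):
                raise DomainError(
                    f"{name} {lo, hi} too narrow for the 1/{den} sampling grid"
                )


def _grid_fraction(rng, lo: float, hi: float, den: int) -> float:
    """Sample a fraction on the 1/den grid inside [lo, hi]."""
    k_lo = math.ceil(lo * den)
    k_hi = math.floor(hi * den)
    return float(rng.integers(k_lo, k_hi + 1)) / den


def generate_world(config: WorldConfig) -> DatasetBundle:
    """Deterministically generate a small validated bundle from a seed.

    The world always contains the five meat-like groups plus at least two
    non-meat groups, and one processing chain whose child is the
    offal-and-fats commodity.  Same config (and seed) gives a byte-identical
    bundle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    year = config.year

    groups = list(MEAT_GROUPS) + list(NON_MEAT_POOL[: config.n_groups - 5])

    # one commodity per group, then a carcass parent, then random extras
    commodities: list[tuple[str, str]] = [  # (commodity_id, group_id)
        (f"{g}_{i:02d}", g) for i, g in enumerate(groups)
    ]
    parent_id = "ruminant_carcass"
    commodities.append((parent_id, "ruminant_meat"))
    n_extra = config.n_commodities - len(commodities)
    extra_groups = rng.choice(len(groups), size=n_extra)
    for j, gi in enumerate(extra_groups):
        commodities.append((f"{groups[gi]}_x{j:02d}", groups[gi]))

    offal_id = next(c for c, g in commodities if g == "offal_and_fats")
    taxonomy = dict(commodities)

    # --- balances: small integer ledgers --------------------------------
    balance_rows = []
    for cid, gid in commodities:
        production = float(rng.integers(8, 65))
        cap = max(1, int(production) // 8)
        feed = float(rng.integers(0, cap + 1))
        seed_use = float(rng.integers(0, cap + 1))
        other = float(rng.integers(0, cap + 1))
        losses = float(rng.integers(0, cap + 1))
        processing_input = 0.0
        if cid == parent_id:
            # the whole carcass stream is processed
            processing_input = production
            feed = seed_use = other = losses = 0.0
        balance_rows.append(
            {
                "commodity_id": cid,
                "group_id": gid,
                "year": year,
                "production": production,
                "imports": 0.0,
                "exports": 0.0,
                "feed": feed,
                "seed": seed_use,
                "processing_input": processing_input,
                "other_uses": other,
                "losses": losses,
            }
        )
    balances = pd.DataFrame(balance_rows, columns=BALANCE_COLUMNS)

    ruminant_meat_id = next(
        c for c, g in commodities if g == "ruminant_meat" and c != parent_id
    )
    processing = pd.DataFrame(
        [
            {"parent_id": parent_id, "child_id": ruminant_meat_id,
             "extraction_rate": 0.5},
            {"parent_id": parent_id, "child_id": offal_id,
             "extraction_rate": 0.25},
        ],
        columns=PROCESSING_COLUMNS,
    )

    # --- fractions -------------------------------------------------------
    fraction_rows = []
    for cid, gid in commodities:
        meatlike = gid in MEAT_GROUPS
        ilo, ihi = config.inedible_range if meatlike else (0.0, 0.45)
        wlo, whi = config.waste_range if meatlike else (0.01, 0.15)
        fraction_rows.append(
            {"kind": "inedible", "commodity_id": cid,
             "region_id": GLOBAL_REGION,
             "fraction": _grid_fraction(rng, ilo, ihi, 64)}
        )
        fraction_rows.append(
            {"kind": "waste", "commodity_id": cid,
             "region_id": GLOBAL_REGION,
             "fraction": _grid_fraction(rng, wlo, whi, 64)}
        )
    fractions = pd.DataFrame(fraction_rows, columns=FRACTION_COLUMNS)

    # --- bioavailability (skip one non-meat commodity: default-1.0 path) -
    lo, hi = config.bioavailability_range
    skip = {c for c, g in commodities if g not in ANIMAL_GROUPS}
    skip = {sorted(skip)[0]} if skip else set()
    bio_rows = [
        {"commodity_id": cid, "nutrient_id": n,
         "coefficient": _grid_fraction(rng, lo, hi, 32)}
        for cid, _g in commodities
        if cid not in skip
        for n in BIOAVAILABILITY_NUTRIENTS
    ]
    bioavailability = pd.DataFrame(bio_rows, columns=BIOAVAILABILITY_COLUMNS)

    # --- composition: full grid, dyadic amounts, structured zeros --------
    comp_rows = []
    for cid, gid in commodities:
        meatlike = gid in MEAT_GROUPS
        missing = rng.random(len(NUTRIENTS)) < config.composition_sparsity
        # log-uniform integer multiplier in [1, 64]
        js = np.rint(2.0 ** rng.uniform(0.0, 6.0, size=len(NUTRIENTS)))
        for n, miss, j in zip(NUTRIENTS, missing, js):
            if meatlike and n == "fiber":
                amount = 0.0  # animal flesh carries no fiber
            elif gid not in ANIMAL_GROUPS and n == "vitamin_b12":
                amount = 0.0  # plant foods carry no B12
            elif miss:
                amount = np.nan
            else:
                amount = float(int(j)) * _COMPOSITION_QUANTUM[n]
            comp_rows.append(
                {"commodity_id": cid, "nutrient_id": n, "amount": amount,
                 "unit": DEFAULT_UNITS[n]}
            )
    composition = pd.DataFrame(comp_rows, columns=COMPOSITION_COLUMNS)

    population = pd.DataFrame(
        [
            {"region_id": GLOBAL_REGION, "year": year,
             "headcount": float(config.population)},
            {"region_id": GLOBAL_REGION, "year": year + 12,
             "headcount": float(round(config.population * 1.136))},
        ],
        columns=POPULATION_COLUMNS,
    )

    requirements = pd.DataFrame(
        [{"nutrient_id": n, "per_capita_daily": DEFAULT_REQUIREMENTS[n]}
         for n in NUTRIENTS],
        columns=REQUIREMENT_COLUMNS,
    )

    bundle = DatasetBundle(
        balances=balances,
        processing=processing,
        composition=composition,
        fractions=fractions,
        bioavailability=bioavailability,
        population=population,
        requirements=requirements,
        units=dict(DEFAULT_UNITS),
    )
    bundle.validate(strict=True)
    return bundle


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def oracle_outputs(
    bundle: DatasetBundle,
    basis: str = "bioavailable",
    trade_mode: str = "netted",
) -> dict[str, pd.DataFrame]:
    """Recompute every pipeline quantity by naive per-record iteration.

    Independent of the vectorised path: plain dicts and Python loops, no
    pandas arithmetic.  Output schemas (columns, ordering, dtypes) are
    identical to the pipeline's so frames can be compared exactly.
    Intended for small bundles (<= 100 commodities).
    """
    if len(bundle.balances) > 100:
        raise DomainError("oracle is for small bundles (<= 100 commodities)")

    balances = {
        r["commodity_id"]: dict(r)
        for r in bundle.balances.to_dict("records")
    }
    taxonomy = {cid: b["group_id"] for cid, b in balances.items()}

    # -- processing: Kahn's algorithm, forwarding inflow down chains ------
    rules = bundle.processing.to_dict("records")
    children: dict[str, list[tuple[str, float]]] = {}
    indegree: dict[str, int] = {}
    for r in rules:
        children.setdefault(r["parent_id"], []).append(
            (r["child_id"], float(r["extraction_rate"]))
        )
        indegree.setdefault(r["parent_id"], indegree.get(r["parent_id"], 0))
        indegree[r["child_id"]] = indegree.get(r["child_id"], 0) + 1
    queue = sorted(n for n in children if indegree.get(n, 0) == 0)
    seen = set()
    while queue:
        parent = queue.pop(0)
        seen.add(parent)
        throughput = balances[parent]["processing_input"]
        for child, rate in children.get(parent, []):
            gain = rate * throughput
            balances[child]["production"] = (
                balances[child]["production"] + gain
            )
            if child in children:
                balances[child]["processing_input"] = (
                    balances[child]["processing_input"] + gain
                )
            indegree[child] -= 1
            if indegree.get(child, 0) == 0 and child in children:
                queue.append(child)
                queue.sort()

    # -- fractions --------------------------------------------------------
    year = bundle.reference_year
    regional_pop = {
        r["region_id"]: r["headcount"]
        for r in bundle.population.to_dict("records")
        if r["year"] == year and r["region_id"] != GLOBAL_REGION
    }
    inedible: dict[str, float] = {}
    waste_rows: dict[str, list[dict]] = {}
    for r in bundle.fractions.to_dict("records"):
        if r["kind"] == "inedible":
            inedible[r["commodity_id"]] = r["fraction"]
        else:
            waste_rows.setdefault(r["commodity_id"], []).append(r)
    waste: dict[str, float] = {}
    for cid, rows in waste_rows.items():
        glob = [r for r in rows if r["region_id"] == GLOBAL_REGION]
        if glob:
            waste[cid] = glob[0]["fraction"]
            continue
        if all(r["region_id"] in regional_pop for r in rows):
            weights = [regional_pop[r["region_id"]] for r in rows]
        else:
            weights = [1.0] * len(rows)
        num = 0.0
        den = 0.0
        for w, r in zip(weights, rows):
            num += w * r["fraction"]
            den += w
        waste[cid] = num / den

    # -- net supply and food mass -----------------------------------------
    food_rows = []
    for cid in sorted(balances):
        b = balances[cid]
        supply = (
            b["production"] + b["imports"] - b["exports"] - b["feed"]
            - b["seed"] - b["other_uses"] - b["losses"]
            - b["processing_input"]
        )
        if supply < 0:
            supply = 0.0
        i = inedible.get(cid, 0.0)
        w = waste.get(cid, 0.0)
        edible = supply * (1.0 - i)
        inedible_mass = supply - edible
        consumed = edible * (1.0 - w)
        wasted = edible - consumed
        food_rows.append(
            {
                "commodity_id": cid,
                "group_id": b["group_id"],
                "available_as_food": supply,
                "edible_available": edible,
                "consumed": consumed,
                "inedible_mass": inedible_mass,
                "wasted_mass": wasted,
            }
        )
    food_mass = pd.DataFrame(food_rows)
    consumed_of = {r["commodity_id"]: r["consumed"] for r in food_rows}

    # -- availability ------------------------------------------------------
    coeff = {
        (r["commodity_id"], r["nutrient_id"]): r["coefficient"]
        for r in bundle.bioavailability.to_dict("records")
    }
    avail_rows = []
    comp_records = sorted(
        bundle.composition.to_dict("records"),
        key=lambda r: (r["commodity_id"], r["nutrient_id"]),
    )
    for r in comp_records:
        cid = r["commodity_id"]
        if cid not in consumed_of:
            continue
        n = r["nutrient_id"]
        amount = r["amount"]
        if amount is None or (isinstance(amount, float) and math.isnan(amount)):
            amount = 0.0
        gross = consumed_of[cid] * TONNES_TO_100G * amount
        c = coeff.get((cid, n), 1.0) if n in BIOAVAILABILITY_NUTRIENTS else 1.0
        avail_rows.append(
            {
                "commodity_id": cid,
                "group_id": taxonomy[cid],
                "nutrient_id": n,
                "gross": gross,
                "bioavailable": gross * c,
                "unit": bundle.units[n],
            }
        )
    availability = pd.DataFrame(avail_rows)

    # -- group totals ------------------------------------------------------
    totals: dict[tuple[str, str], list[float]] = {}
    for r in avail_rows:
        key = (r["group_id"], r["nutrient_id"])
        if key not in totals:
            totals[key] = [0.0, 0.0]
        totals[key][0] += r["gross"]
        totals[key][1] += r["bioavailable"]
    group_totals = pd.DataFrame(
        [
            {"group_id": g, "nutrient_id": n, "gross": v[0],
             "bioavailable": v[1]}
            for (g, n), v in sorted(totals.items())
        ]
    )

    # -- contributions -----------------------------------------------------
    idx = 0 if basis == "gross" else 1
    groups = sorted({g for g, _n in totals})
    nutrients = [n for n in NUTRIENTS if any((g, n) in totals for g in groups)]
    cells: dict[str, list[float]] = {}
    for n in nutrients:
        t = 0.0
        for g in groups:
            t += totals.get((g, n), [0.0, 0.0])[idx]
        col = []
        for g in groups:
            if t > 0:
                col.append(100.0 * totals.get((g, n), [0.0, 0.0])[idx] / t)
            else:
                col.append(float("nan"))
        cells[n] = col
    contributions = pd.DataFrame(cells, index=groups, dtype="float64")

    # -- per-capita and gaps ----------------------------------------------
    pop_rows = [
        r for r in bundle.population.to_dict("records") if r["year"] == year
    ]
    glob = [r for r in pop_rows if r["region_id"] == GLOBAL_REGION]
    if glob:
        population = glob[0]["headcount"]
    else:
        population = 0.0
        for r in pop_rows:
            population += r["headcount"]

    per_capita_rows = []
    per_capita_of = {}
    for n in NUTRIENTS:
        total = 0.0
        for g in groups:
            total += totals.get((g, n), [0.0, 0.0])[idx]
        pc = total / (population * DAYS_PER_YEAR)
        per_capita_of[n] = pc
        per_capita_rows.append(
            {"nutrient_id": n, "per_capita_daily": pc,
             "unit": bundle.units[n], "basis": basis}
        )
    per_capita = pd.DataFrame(per_capita_rows)

    gap_rows = []
    for r in bundle.requirements.to_dict("records"):
        a = per_capita_of.get(r["nutrient_id"], 0.0)
        rq = r["per_capita_daily"]
        gap = 100.0 * (1.0 - a / rq)
        if gap < 0.0:
            gap = 0.0
        gap_rows.append(
            {
                "nutrient_id": r["nutrient_id"],
                "available_per_capita_daily": a,
                "requirement_per_capita_daily": rq,
                "gap_percent": gap,
                "surplus": a >= rq,
            }
        )
    gaps = pd.DataFrame(gap_rows)

    return {
        "food_mass": food_mass,
        "availability": availability,
        "group_totals": group_totals,
        "contributions": contributions,
        "per_capita": per_capita,
        "gaps": gaps,
    }


# ---------------------------------------------------------------------------
# Fixed fixtures
# ---------------------------------------------------------------------------

def _full_composition(values: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Composition grid from a commodity -> {nutrient: amount} mapping;
    unspecified nutrients are explicit zeros."""
    rows = [
        {"commodity_id": cid, "nutrient_id": n,
         "amount": float(per.get(n, 0.0)), "unit": DEFAULT_UNITS[n]}
        for cid, per in values.items()
        for n in NUTRIENTS
    ]
    return pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)


def _requirements_frame(
    values: Mapping[str, float] | None = None
) -> pd.DataFrame:
    values = dict(DEFAULT_REQUIREMENTS) if values is None else dict(values)
    return pd.DataFrame(
        [{"nutrient_id": n, "per_capita_daily": v} for n, v in values.items()],
        columns=REQUIREMENT_COLUMNS,
    )


#: Digestibility coefficients for meat commodities (within the published
#: 0.83-1 range for meats) and for offal (lower across the board).
_MEAT_BIOAVAILABILITY = {
    "protein": 0.95, "cystine": 0.9, "histidine": 0.92, "leucine": 0.93,
    "lysine": 0.94, "methionine": 0.93, "threonine": 0.92, "tryptophan": 0.9,
}
_OFFAL_BIOAVAILABILITY = {
    "protein": 0.76, "cystine": 0.68, "histidine": 0.7, "leucine": 0.8,
    "lysine": 0.77, "methionine": 0.8, "threonine": 0.76, "tryptophan": 0.69,
}

_GLOBAL_2018_COMPOSITION: dict[str, dict[str, float]] = {
    "beef": {
        "energy": 250.0, "protein": 26.0, "fat": 15.0, "carbohydrates": 0.0,
        "fiber": 0.0, "calcium": 18.0, "copper": 0.08, "iron": 2.6,
        "magnesium": 21.0, "phosphorus": 198.0, "potassium": 318.0,
        "selenium": 26.0, "zinc": 6.3, "vitamin_a": 0.0, "vitamin_b1": 0.07,
        "vitamin_b2": 0.15, "vitamin_b5": 0.65, "vitamin_b6": 0.38,
        "vitamin_b9": 6.0, "vitamin_b12": 2.6, "vitamin_c": 0.0,
        "vitamin_e": 0.4, "cystine": 0.33, "histidine": 0.83, "leucine": 2.1,
        "lysine": 2.2, "methionine": 0.68, "threonine": 1.06,
        "tryptophan": 0.17,
    },
    "chicken": {
        "energy": 215.0, "protein": 18.6, "fat": 15.0, "fiber": 0.0,
        "calcium": 11.0, "copper": 0.05, "iron": 0.9, "magnesium": 20.0,
        "phosphorus": 147.0, "potassium": 189.0, "selenium": 14.0,
        "zinc": 1.3, "vitamin_a": 41.0, "vitamin_b1": 0.06,
        "vitamin_b2": 0.12, "vitamin_b5": 0.91, "vitamin_b6": 0.35,
        "vitamin_b9": 6.0, "vitamin_b12": 0.31, "vitamin_c": 1.6,
        "vitamin_e": 0.3, "cystine": 0.25, "histidine": 0.57, "leucine": 1.4,
        "lysine": 1.6, "methionine": 0.51, "threonine": 0.79,
        "tryptophan": 0.22,
    },
    "pork": {
        "energy": 242.0, "protein": 27.0, "fat": 14.0, "fiber": 0.0,
        "calcium": 19.0, "copper": 0.07, "iron": 0.9, "magnesium": 28.0,
        "phosphorus": 246.0, "potassium": 423.0, "selenium": 38.0,
        "zinc": 2.9, "vitamin_a": 2.0, "vitamin_b1": 0.87, "vitamin_b2": 0.32,
        "vitamin_b5": 0.7, "vitamin_b6": 0.46, "vitamin_b9": 5.0,
        "vitamin_b12": 0.7, "vitamin_c": 0.6, "vitamin_e": 0.29,
        "cystine": 0.32, "histidine": 1.0, "leucine": 2.2, "lysine": 2.3,
        "methionine": 0.71, "threonine": 1.2, "tryptophan": 0.33,
    },
    "game_meat": {
        "energy": 190.0, "protein": 25.0, "fat": 8.0, "fiber": 0.0,
        "calcium": 15.0, "copper": 0.12, "iron": 3.5, "magnesium": 24.0,
        "phosphorus": 220.0, "potassium": 330.0, "selenium": 22.0,
        "zinc": 4.4, "vitamin_a": 0.0, "vitamin_b1": 0.15, "vitamin_b2": 0.3,
        "vitamin_b5": 0.75, "vitamin_b6": 0.4, "vitamin_b9": 7.0,
        "vitamin_b12": 2.0, "vitamin_c": 0.0, "vitamin_e": 0.35,
        "cystine": 0.3, "histidine": 0.8, "leucine": 2.0, "lysine": 2.1,
        "methionine": 0.65, "threonine": 1.0, "tryptophan": 0.3,
    },
    "slaughter_coproducts": {},  # processed entirely; never eaten directly
    "offal_and_fat": {
        "energy": 310.0, "protein": 18.0, "fat": 26.0, "fiber": 0.0,
        "calcium": 9.0, "copper": 9.8, "iron": 6.5, "magnesium": 18.0,
        "phosphorus": 387.0, "potassium": 313.0, "selenium": 40.0,
        "zinc": 4.0, "vitamin_a": 9440.0, "vitamin_b1": 0.19,
        "vitamin_b2": 2.8, "vitamin_b5": 7.2, "vitamin_b6": 1.0,
        "vitamin_b9": 290.0, "vitamin_b12": 59.0, "vitamin_c": 1.3,
        "vitamin_e": 0.4, "cystine": 0.24, "histidine": 0.5, "leucine": 1.6,
        "lysine": 1.4, "methionine": 0.45, "threonine": 0.8,
        "tryptophan": 0.24,
    },
    "milk": {
        "energy": 61.0, "protein": 3.2, "fat": 3.3, "carbohydrates": 4.8,
        "fiber": 0.0, "calcium": 113.0, "copper": 0.01, "iron": 0.03,
        "magnesium": 10.0, "phosphorus": 84.0, "potassium": 132.0,
        "selenium": 3.7, "zinc": 0.37, "vitamin_a": 46.0, "vitamin_b1": 0.05,
        "vitamin_b2": 0.17, "vitamin_b5": 0.37, "vitamin_b6": 0.04,
        "vitamin_b9": 5.0, "vitamin_b12": 0.45, "vitamin_c": 0.0,
        "vitamin_e": 0.07, "cystine": 0.02, "histidine": 0.09,
        "leucine": 0.32, "lysine": 0.26, "methionine": 0.08,
        "threonine": 0.14, "tryptophan": 0.04,
    },
    "wheat": {
        "energy": 340.0, "protein": 13.2, "fat": 2.5, "carbohydrates": 72.0,
        "fiber": 10.7, "calcium": 34.0, "copper": 0.41, "iron": 3.6,
        "magnesium": 137.0, "phosphorus": 357.0, "potassium": 363.0,
        "selenium": 89.0, "zinc": 2.6, "vitamin_a": 0.0, "vitamin_b1": 0.5,
        "vitamin_b2": 0.11, "vitamin_b5": 0.95, "vitamin_b6": 0.41,
        "vitamin_b9": 44.0, "vitamin_b12": 0.0, "vitamin_c": 0.0,
        "vitamin_e": 1.0, "cystine": 0.28, "histidine": 0.32,
        "leucine": 0.93, "lysine": 0.38, "methionine": 0.21,
        "threonine": 0.39, "tryptophan": 0.17,
    },
    "vegetables": {
        "energy": 35.0, "protein": 1.8, "fat": 0.3, "carbohydrates": 7.0,
        "fiber": 2.8, "calcium": 45.0, "copper": 0.07, "iron": 0.8,
        "magnesium": 18.0, "phosphorus": 40.0, "potassium": 250.0,
        "selenium": 0.5, "zinc": 0.35, "vitamin_a": 200.0, "vitamin_b1": 0.07,
        "vitamin_b2": 0.08, "vitamin_b5": 0.3, "vitamin_b6": 0.15,
        "vitamin_b9": 60.0, "vitamin_b12": 0.0, "vitamin_c": 25.0,
        "vitamin_e": 0.6, "cystine": 0.02, "histidine": 0.04,
        "leucine": 0.09, "lysine": 0.09, "methionine": 0.03,
        "threonine": 0.07, "tryptophan": 0.02,
    },
    "fruits": {
        "energy": 60.0, "protein": 0.8, "fat": 0.3, "carbohydrates": 15.0,
        "fiber": 2.2, "calcium": 15.0, "copper": 0.08, "iron": 0.3,
        "magnesium": 12.0, "phosphorus": 18.0, "potassium": 180.0,
        "selenium": 0.2, "zinc": 0.1, "vitamin_a": 30.0, "vitamin_b1": 0.04,
        "vitamin_b2": 0.04, "vitamin_b5": 0.2, "vitamin_b6": 0.09,
        "vitamin_b9": 15.0, "vitamin_b12": 0.0, "vitamin_c": 30.0,
        "vitamin_e": 0.3, "cystine": 0.01, "histidine": 0.01,
        "leucine": 0.03, "lysine": 0.04, "methionine": 0.01,
        "threonine": 0.02, "tryptophan": 0.01,
    },
    "fish": {
        "energy": 120.0, "protein": 20.0, "fat": 4.0, "fiber": 0.0,
        "calcium": 25.0, "copper": 0.06, "iron": 0.7, "magnesium": 30.0,
        "phosphorus": 220.0, "potassium": 380.0, "selenium": 36.0,
        "zinc": 0.6, "vitamin_a": 25.0, "vitamin_b1": 0.08,
        "vitamin_b2": 0.12, "vitamin_b5": 0.8, "vitamin_b6": 0.4,
        "vitamin_b9": 10.0, "vitamin_b12": 3.0, "vitamin_c": 0.0,
        "vitamin_e": 0.6, "cystine": 0.21, "histidine": 0.59,
        "leucine": 1.6, "lysine": 1.8, "methionine": 0.59,
        "threonine": 0.88, "tryptophan": 0.22,
    },
    "eggs": {
        "energy": 143.0, "protein": 12.6, "fat": 9.5, "carbohydrates": 0.7,
        "fiber": 0.0, "calcium": 56.0, "copper": 0.07, "iron": 1.8,
        "magnesium": 12.0, "phosphorus": 198.0, "potassium": 138.0,
        "selenium": 30.7, "zinc": 1.3, "vitamin_a": 160.0, "vitamin_b1": 0.04,
        "vitamin_b2": 0.46, "vitamin_b5": 1.5, "vitamin_b6": 0.17,
        "vitamin_b9": 47.0, "vitamin_b12": 0.89, "vitamin_c": 0.0,
        "vitamin_e": 1.1, "cystine": 0.27, "histidine": 0.31,
        "leucine": 1.09, "lysine": 0.91, "methionine": 0.38,
        "threonine": 0.56, "tryptophan": 0.17,
    },
}


def make_global_2018_world() -> DatasetBundle:
    """Fixed synthetic fixture shaped like the published global 2018 system.

    The five meat groups' available-as-food masses are hard-coded to the
    23/34/32/2/9 percent decomposition of a 316 Mt total (offal arriving
    through a processing chain), meat is ~7% of total food mass, and the
    global population is 7.53e9, putting meat availability near 115
    g/person/day.  All magnitudes are synthetic stand-ins chosen to
    reproduce that structure, not real observations.
    """
    mt = 1.0e6  # tonnes per Mt

    def bal(cid, gid, production, feed=0.0, seed=0.0, processing_input=0.0,
            other_uses=0.0, losses=0.0):
        return {
            "commodity_id": cid, "group_id": gid, "year": 2018,
            "production": production * mt, "imports": 0.0, "exports": 0.0,
            "feed": feed * mt, "seed": seed * mt,
            "processing_input": processing_input * mt,
            "other_uses": other_uses * mt, "losses": losses * mt,
        }

    balances = pd.DataFrame(
        [
            # meat: available-as-food 72.68 / 107.44 / 101.12 / 6.32 / 28.44
            bal("beef", "ruminant_meat", 76.68, losses=4.0),
            bal("chicken", "poultry_meat", 113.44, losses=6.0),
            bal("pork", "pig_meat", 106.12, losses=5.0),
            bal("game_meat", "other_meat", 6.82, losses=0.5),
            bal("slaughter_coproducts", "offal_and_fats", 56.88,
                processing_input=56.88),
            bal("offal_and_fat", "offal_and_fats", 0.0),
            # non-meat bulk of the food system
            bal("milk", "dairy", 900.0, feed=80.0, losses=60.0),
            bal("wheat", "cereals", 1680.0, feed=300.0, seed=60.0,
                losses=120.0),
            bal("vegetables", "vegetables", 1500.0, losses=200.0),
            bal("fruits", "fruits", 820.0, losses=120.0),
            bal("fish", "fish_seafood", 170.0, losses=20.0),
            bal("eggs", "eggs", 84.0, losses=8.0),
        ],
        columns=BALANCE_COLUMNS,
    )

    processing = pd.DataFrame(
        [{"parent_id": "slaughter_coproducts", "child_id": "offal_and_fat",
          "extraction_rate": 0.5}],
        columns=PROCESSING_COLUMNS,
    )

    inedible = {
        "beef": 0.13, "chicken": 0.30, "pork": 0.18, "game_meat": 0.25,
        "offal_and_fat": 0.08, "slaughter_coproducts": 0.0, "milk": 0.0,
        "wheat": 0.0, "vegetables": 0.2, "fruits": 0.25, "fish": 0.35,
        "eggs": 0.12,
    }
    meat_commodities = ("beef", "chicken", "pork", "game_meat",
                       "offal_and_fat")
    regional_waste = {"region_a": 0.02, "region_b": 0.06, "region_c": 0.09,
                      "region_d": 0.11}
    nonmeat_waste = {"milk": 0.07, "wheat": 0.1, "vegetables": 0.15,
                     "fruits": 0.12, "fish": 0.08, "eggs": 0.06,
                     "slaughter_coproducts": 0.0}
    fraction_rows = [
        {"kind": "inedible", "commodity_id": cid, "region_id": GLOBAL_REGION,
         "fraction": f}
        for cid, f in inedible.items()
    ]
    for cid in meat_commodities:
        for region, f in regional_waste.items():
            fraction_rows.append(
                {"kind": "waste", "commodity_id": cid, "region_id": region,
                 "fraction": f}
            )
    for cid, f in nonmeat_waste.items():
        fraction_rows.append(
            {"kind": "waste", "commodity_id": cid,
             "region_id": GLOBAL_REGION, "fraction": f}
        )
    fractions = pd.DataFrame(fraction_rows, columns=FRACTION_COLUMNS)

    bio_rows = []
    plain_meats = ("beef", "chicken", "pork", "game_meat")
    other_protein = {
        "milk": 0.95, "wheat": 0.85, "vegetables": 0.8, "fruits": 0.8,
        "fish": 0.94, "eggs": 0.97,
    }
    for cid in plain_meats:
        for n, c in _MEAT_BIOAVAILABILITY.items():
            bio_rows.append(
                {"commodity_id": cid, "nutrient_id": n, "coefficient": c}
            )
    for n, c in _OFFAL_BIOAVAILABILITY.items():
        bio_rows.append(
            {"commodity_id": "offal_and_fat", "nutrient_id": n,
             "coefficient": c}
        )
    for cid, c in other_protein.items():
        for n in BIOAVAILABILITY_NUTRIENTS:
            bio_rows.append(
                {"commodity_id": cid, "nutrient_id": n, "coefficient": c}
            )
    bioavailability = pd.DataFrame(bio_rows, columns=BIOAVAILABILITY_COLUMNS)

    population = pd.DataFrame(
        [
            {"region_id": GLOBAL_REGION, "year": 2018, "headcount": 7.53e9},
            {"region_id": "region_a", "year": 2018, "headcount": 1.8e9},
            {"region_id": "region_b", "year": 2018, "headcount": 2.2e9},
            {"region_id": "region_c", "year": 2018, "headcount": 1.53e9},
            {"region_id": "region_d", "year": 2018, "headcount": 2.0e9},
            {"region_id": GLOBAL_REGION, "year": 2030, "headcount": 8.55e9},
        ],
        columns=POPULATION_COLUMNS,
    )

    bundle = DatasetBundle(
        balances=balances,
        processing=processing,
        composition=_full_composition(_GLOBAL_2018_COMPOSITION),
        fractions=fractions,
        bioavailability=bioavailability,
        population=population,
        requirements=_requirements_frame(),
        units=dict(DEFAULT_UNITS),
    )
    bundle.validate(strict=True)
    return bundle


def make_b12_replacement_world() -> DatasetBundle:
    """Synthetic world tuned so that closing the vitamin B12 gap after
    removing all meat requires exactly tripling dairy production, or
    quadrupling fish production.

    Constructed by inverting the replacement closed form: with annual
    requirement T = R*P*365, dairy supplies 3T/11, fish 2T/11 and meat 0.6T,
    so (T - 2T/11) / (3T/11) = 3 and (T - 3T/11) / (2T/11) = 4.  Baseline
    availability is 1.05T (no gap with meat present).
    """
    population = 1.0e9
    requirement = 2.4  # ug/person/day
    annual = requirement * DAYS_PER_YEAR * population  # T, in ug

    meat = {  # commodity -> (group, share of 0.6T, ug/100 g)
        "beef": ("ruminant_meat", 0.25, 2.5),
        "chicken": ("poultry_meat", 0.30, 0.9),
        "pork": ("pig_meat", 0.25, 0.7),
        "game_meat": ("other_meat", 0.10, 3.0),
        "offal_and_fat": ("offal_and_fats", 0.10, 20.0),
    }
    b12 = {"milk": 0.4, "fish": 2.0}
    masses = {
        cid: share * 0.6 * annual / (TONNES_TO_100G * conc)
        for cid, (_g, share, conc) in meat.items()
    }
    masses["milk"] = (3.0 / 11.0) * annual / (TONNES_TO_100G * b12["milk"])
    masses["fish"] = (2.0 / 11.0) * annual / (TONNES_TO_100G * b12["fish"])
    masses["wheat"] = 1.0e8

    groups = {cid: g for cid, (g, _s, _c) in meat.items()}
    groups.update({"milk": "dairy", "fish": "fish_seafood",
                   "wheat": "cereals"})
    balances = pd.DataFrame(
        [
            {"commodity_id": cid, "group_id": groups[cid], "year": 2018,
             "production": masses[cid], "imports": 0.0, "exports": 0.0,
             "feed": 0.0, "seed": 0.0, "processing_input": 0.0,
             "other_uses": 0.0, "losses": 0.0}
            for cid in sorted(groups)
        ],
        columns=BALANCE_COLUMNS,
    )
    composition_values = {
        cid: {"vitamin_b12": conc} for cid, (_g, _s, conc) in meat.items()
    }
    composition_values["milk"] = {"vitamin_b12": b12["milk"]}
    composition_values["fish"] = {"vitamin_b12": b12["fish"]}
    composition_values["wheat"] = {"carbohydrates": 72.0}

    bundle = DatasetBundle(
        balances=balances,
        processing=pd.DataFrame(columns=PROCESSING_COLUMNS),
        composition=_full_composition(composition_values),
        fractions=pd.DataFrame(columns=FRACTION_COLUMNS),
        bioavailability=pd.DataFrame(columns=BIOAVAILABILITY_COLUMNS),
        population=pd.DataFrame(
            [{"region_id": GLOBAL_REGION, "year": 2018,
              "headcount": population}],
            columns=POPULATION_COLUMNS,
        ),
        requirements=pd.DataFrame(
            [{"nutrient_id": "vitamin_b12", "per_capita_daily": requirement}],
            columns=REQUIREMENT_COLUMNS,
        ),
        units=dict(DEFAULT_UNITS),
    )
    bundle.validate(strict=True)
    return bundle


def make_supply_fraction_world(
    nutrient: str = "vitamin_b12", supply_fraction: float = 0.65
) -> DatasetBundle:
    """Single-commodity world whose per-capita availability of ``nutrient``
    is exactly ``supply_fraction`` of its reference value (so the gap is
    100*(1 - supply_fraction) percent)."""
    if nutrient not in NUTRIENTS:
        raise DomainError(f"unknown nutrient '{nutrient}'")
    population = 1.0e9
    requirement = DEFAULT_REQUIREMENTS[nutrient]
    conc = 1.0  # registry unit per 100 g
    mass = (
        supply_fraction * requirement * DAYS_PER_YEAR * population
        / (TONNES_TO_100G * conc)
    )
    bundle = DatasetBundle(
        balances=pd.DataFrame(
            [{"commodity_id": "staple", "group_id": "cereals", "year": 2018,
              "production": mass, "imports": 0.0, "exports": 0.0,
              "feed": 0.0, "seed": 0.0, "processing_input": 0.0,
              "other_uses": 0.0, "losses": 0.0}],
            columns=BALANCE_COLUMNS,
        ),
        processing=pd.DataFrame(columns=PROCESSING_COLUMNS),
        composition=_full_composition({"staple": {nutrient: conc}}),
        fractions=pd.DataFrame(columns=FRACTION_COLUMNS),
        bioavailability=pd.DataFrame(columns=BIOAVAILABILITY_COLUMNS),
        population=pd.DataFrame(
            [{"region_id": GLOBAL_REGION, "year": 2018,
              "headcount": population}],
            columns=POPULATION_COLUMNS,
        ),
        requirements=pd.DataFrame(
            [{"nutrient_id": nutrient, "per_capita_daily": requirement}],
            columns=REQUIREMENT_COLUMNS,
        ),
        units=dict(DEFAULT_UNITS),
    )
    bundle.validate(strict=True)
    return bundle
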