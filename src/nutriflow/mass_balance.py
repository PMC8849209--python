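"""Supply-side mass balance: net food supply, commodity-tree processing,
inedible-portion and in-home-waste adjustment.

The accounting per commodity is

    available_as_food = production + imports - exports - feed - seed
                        - other_uses - losses - processing_input
    edible_available  = available_as_food * (1 - inedible_fraction)
    consumed          = edible_available * (1 - waste_fraction)

Inedible portions are removed first, then in-home waste is applied to the
edible mass; the two orders differ numerically and this order is fixed.
Mass is conserved exactly: available = consumed + inedible + wasted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from .errors import BalanceError, DomainError
from .nutrients import GLOBAL_REGION
from .schema import (
    DatasetBundle,
    MASS_COLUMNS,
    TRADE_NET_TOLERANCE,
    processing_graph,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoodMassResult:
    """Per-commodity food-mass decomposition, all in tonnes.

    Invariants (exact): available_as_food = edible_available + inedible_mass
    and edible_available = consumed + wasted_mass.
    """

    commodity_id: str
    available_as_food: float
    edible_available: float
    consumed: float
    inedible_mass: float
    wasted_mass: float


FOOD_MASS_COLUMNS = [
    "commodity_id",
    "group_id",
    "available_as_food",
    "edible_available",
    "consumed",
    "inedible_mass",
    "wasted_mass",
]


def net_supply(balance: Mapping, trade_mode: str = "netted") -> float:
    """Mass available as food, from one commodity's ledger (tonnes).

    production + imports - exports - feed - seed - other_uses - losses -
    processing_input, clamped at zero (with a warning) when negative.
    In ``strict_zero`` mode a nonzero global net trade
    (|imports - exports| > tolerance x production) is an error: world
    imports and exports must cancel.
    """
    if trade_mode not in ("netted", "strict_zero"):
        raise ValueError(f"unknown trade_mode '{trade_mode}'")
    cid = balance.get("commodity_id", "?") if hasattr(balance, "get") else (
        balance["commodity_id"]
    )
    imports = float(balance["imports"])
    exports = float(balance["exports"])
    production = float(balance["production"])
    if trade_mode == "strict_zero":
        if abs(imports - exports) > TRADE_NET_TOLERANCE * max(production, 1.0):
            raise BalanceError(
                f"'{cid}': global net trade {imports - exports} tonnes does "
                "not cancel (strict_zero trade mode)"
            )
    supply = (
        production + imports - exports
        - float(balance["feed"]) - float(balance["seed"])
        - float(balance["other_uses"]) - float(balance["losses"])
        - float(balance["processing_input"])
    )
    if supply < 0:
        logger.warning(
            "net supply of '%s' is negative (%s t); clamped to 0", cid, supply
        )
        supply = 0.0
    return supply


def net_supply_frame(
    balances: pd.DataFrame, trade_mode: str = "netted"
) -> pd.DataFrame:
    """Vectorised net supply per commodity: columns commodity_id, group_id,
    available_as_food."""
    if trade_mode == "strict_zero":
        for row in balances.itertuples(index=False):
            net_supply(row._asdict(), trade_mode="strict_zero")
    supply = (
        balances["production"] + balances["imports"] - balances["exports"]
        - balances["feed"] - balances["seed"] - balances["other_uses"]
        - balances["losses"] - balances["processing_input"]
    )
    neg = supply < 0
    if neg.any():
        for cid in balances.loc[neg, "commodity_id"]:
            logger.warning("net supply of '%s' is negative; clamped to 0", cid)
        supply = supply.clip(lower=0.0)
    return pd.DataFrame(
        {
            "commodity_id": balances["commodity_id"],
            "group_id": balances["group_id"],
            "available_as_food": supply.astype("float64"),
        }
    )


def apply_processing(
    balances: pd.DataFrame, rules: pd.DataFrame
) -> pd.DataFrame:
    """Distribute each parent's processing_input to its children.

    Children gain ``extraction_rate x parent.processing_input`` of
    production; the residual ``(1 - sum(rates))`` share leaves the food
    system (bones, hides, industrial byproducts).  Parents are visited in
    topological order, and mass a child gains is forwarded into its own
    processing_input when the child has outgoing rules, so extraction rates
    compose along multi-level chains (animal -> carcass -> cuts).
    """
    if rules is None or not len(rules):
        return balances.copy()
    g = processing_graph(rules)  # raises GraphError on cycles
    out = balances.copy().set_index("commodity_id", drop=False)
    has_children = set(rules["parent_id"])
    for parent in nx.lexicographical_topological_sort(g):
        if parent not in has_children:
            continue
        throughput = float(out.at[parent, "processing_input"])
        if throughput == 0.0:
            continue
        for _p, child, data in g.out_edges(parent, data=True):
            gain = data["extraction_rate"] * throughput
            out.at[child, "production"] = out.at[child, "production"] + gain
            if child in has_children:
                out.at[child, "processing_input"] = (
                    out.at[child, "processing_input"] + gain
                )
    return out.reset_index(drop=True)


def consumed_mass(
    available_as_food: float,
    inedible_fraction: float,
    waste_fraction: float,
    commodity_id: str = "",
) -> FoodMassResult:
    """Apply inedible-portion then in-home-waste fractions to food mass.

    Fields are derived so the conservation identities hold exactly:
    inedible_mass = available - edible and wasted = edible - consumed.
    """
    for name, f in (("inedible", inedible_fraction), ("waste", waste_fraction)):
        if not (0.0 <= f < 1.0):
            raise DomainError(
                f"{name} fraction {f} outside [0, 1) for '{commodity_id}'"
            )
    if available_as_food < 0:
        raise DomainError(
            f"available_as_food {available_as_food} < 0 for '{commodity_id}'"
        )
    edible = available_as_food * (1.0 - inedible_fraction)
    inedible_mass = available_as_food - edible
    consumed = edible * (1.0 - waste_fraction)
    wasted = edible - consumed
    return FoodMassResult(
        commodity_id=commodity_id,
        available_as_food=available_as_food,
        edible_available=edible,
        consumed=consumed,
        inedible_mass=inedible_mass,
        wasted_mass=wasted,
    )


def aggregate_waste_fraction(
    waste_rows: pd.DataFrame, regional_population: pd.DataFrame
) -> float:
    """Collapse regional waste fractions for one commodity to one global
    fraction.

    A GLOBAL row wins outright.  Otherwise the regional fractions are
    averaged with regional population headcounts as weights (the global
    model carries no regional food masses; population is the proxy under
    equal per-capita supply).  Missing region populations fall back to
    equal weights, with a warning.
    """
    glob = waste_rows[waste_rows["region_id"] == GLOBAL_REGION]
    if not glob.empty:
        return float(glob["fraction"].iloc[0])
    pop = dict(
        zip(regional_population["region_id"], regional_population["headcount"])
    )
    regions = list(waste_rows["region_id"])
    if all(r in pop for r in regions):
        weights = [pop[r] for r in regions]
    else:
        logger.warning(
            "waste aggregation: no population for region(s) %s; using equal "
            "weights", sorted(set(regions) - set(pop)),
        )
        weights = [1.0] * len(regions)
    num = 0.0
    den = 0.0
    for w, f in zip(weights, waste_rows["fraction"]):
        num += w * f
        den += w
    return num / den


def effective_fractions(bundle: DatasetBundle) -> pd.DataFrame:
    """Per-commodity inedible and (globally aggregated) waste fractions.

    Commodities without a record default to 0 for that fraction.
    Columns: commodity_id, inedible_fraction, waste_fraction.
    """
    frac = bundle.fractions
    regional_pop = bundle.regional_population()
    inedible = dict(
        zip(
            frac.loc[frac["kind"] == "inedible", "commodity_id"],
            frac.loc[frac["kind"] == "inedible", "fraction"],
        )
    )
    waste = {}
    waste_rows = frac[frac["kind"] == "waste"]
    for cid, rows in waste_rows.groupby("commodity_id"):
        waste[cid] = aggregate_waste_fraction(rows, regional_pop)
    return pd.DataFrame(
        {
            "commodity_id": bundle.balances["commodity_id"],
            "inedible_fraction": [
                float(inedible.get(c, 0.0))
                for c in bundle.balances["commodity_id"]
            ],
            "waste_fraction": [
                float(waste.get(c, 0.0))
                for c in bundle.balances["commodity_id"]
            ],
        }
    )


def food_mass_frame(
    bundle: DatasetBundle, trade_mode: str = "netted"
) -> pd.DataFrame:
    """Full mass-balance stage: processing, net supply, inedible and waste.

    Returns one row per commodity with the FoodMassResult columns plus
    group_id, sorted by commodity_id.
    """
    balances = apply_processing(bundle.balances, bundle.processing)
    supply = net_supply_frame(balances, trade_mode=trade_mode)
    fractions = effective_fractions(bundle)
    merged = supply.merge(fractions, on="commodity_id", how="left")
    rows = []
    for row in merged.itertuples(index=False):
        res = consumed_mass(
            row.available_as_food,
            row.inedible_fraction,
            row.waste_fraction,
            commodity_id=row.commodity_id,
        )
        rows.append(
            {
                "commodity_id": res.commodity_id,
                "group_id": row.group_id,
                "available_as_food": res.available_as_food,
                "edible_available": res.edible_available,
                "consumed": res.consumed,
                "inedible_mass": res.inedible_mass,
                "wasted_mass": res.wasted_mass,
            }
        )
    out = pd.DataFrame(rows, columns=FOOD_MASS_COLUMNS)
    return out.sort_values("commodity_id", ignore_index=True)
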