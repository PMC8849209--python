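"""Domain types and validation for the dataset bundle.

The bundle mirrors a Food Balance Sheet (FBS) style accounting: per commodity
a supply-side mass ledger in tonnes, a commodity tree of processing rules with
extraction rates, a nutrient composition table per 100 g edible portion,
inedible/waste fractions, bioavailability coefficients for protein and the
indispensable amino acids, population counts and per-capita daily nutrient
reference values.

Tables are held as pandas DataFrames with fixed column schemas; the record
dataclasses below are the single source of truth for those columns.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import BundleValidationError, GraphError
from .nutrients import (
    BIOAVAILABILITY_NUTRIENTS,
    DEFAULT_UNITS,
    GLOBAL_REGION,
    NUTRIENTS,
)

logger = logging.getLogger(__name__)

#: Supply-side mass columns of a commodity balance, all in tonnes.
MASS_COLUMNS: tuple[str, ...] = (
    "production",
    "imports",
    "exports",
    "feed",
    "seed",
    "processing_input",
    "other_uses",
    "losses",
)

#: Tolerance (x production) for strict global trade netting.
TRADE_NET_TOLERANCE: float = 1e-6

#: Slack for the sum of extraction rates of one parent (float-safe <= 1).
EXTRACTION_SUM_TOLERANCE: float = 1e-12


@dataclass(frozen=True)
class CommodityBalance:
    """One commodity's supply-side mass ledger for one year (tonnes)."""

    commodity_id: str
    group_id: str
    year: int
    production: float = 0.0
    imports: float = 0.0
    exports: float = 0.0
    feed: float = 0.0
    seed: float = 0.0
    processing_input: float = 0.0
    other_uses: float = 0.0
    losses: float = 0.0


@dataclass(frozen=True)
class ProcessingRule:
    """Commodity-tree edge: parent mass sent to processing yields
    ``extraction_rate`` x that mass of the child commodity."""

    parent_id: str
    child_id: str
    extraction_rate: float


@dataclass(frozen=True)
class CompositionRecord:
    """Nutrient content per 100 g edible portion; NaN amount marks a missing
    value (contributes zero, with a logged warning at compute time)."""

    commodity_id: str
    nutrient_id: str
    amount: float
    unit: str


@dataclass(frozen=True)
class FractionRecord:
    """Inedible-portion or in-home-waste fraction of food mass.

    Inedible portions vary by commodity only (region_id must be GLOBAL);
    waste varies by region.
    """

    kind: str  # "inedible" | "waste"
    commodity_id: str
    region_id: str
    fraction: float


@dataclass(frozen=True)
class BioavailabilityRecord:
    """Coefficient in (0, 1] applied to protein or an indispensable amino
    acid; commodities without a record default to 1.0 (logged)."""

    commodity_id: str
    nutrient_id: str
    coefficient: float


@dataclass(frozen=True)
class PopulationRecord:
    """Headcount for a region (or GLOBAL) and year."""

    region_id: str
    year: int
    headcount: float


@dataclass(frozen=True)
class RequirementRecord:
    """Per-capita daily reference value, in the nutrient's registry unit."""

    nutrient_id: str
    per_capita_daily: float


def _columns(record_cls) -> list[str]:
    return [f.name for f in fields(record_cls)]


BALANCE_COLUMNS = _columns(CommodityBalance)
PROCESSING_COLUMNS = _columns(ProcessingRule)
COMPOSITION_COLUMNS = _columns(CompositionRecord)
FRACTION_COLUMNS = _columns(FractionRecord)
BIOAVAILABILITY_COLUMNS = _columns(BioavailabilityRecord)
POPULATION_COLUMNS = _columns(PopulationRecord)
REQUIREMENT_COLUMNS = _columns(RequirementRecord)


def frame_of(records: Iterable, record_cls) -> pd.DataFrame:
    """Build a table from record dataclasses (or mappings) with the schema
    columns in canonical order."""
    cols = _columns(record_cls)
    rows = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=cols)
    for c in cols:
        if c in ("year",):
            df[c] = df[c].astype("int64") if len(df) else df[c]
        elif c not in ("commodity_id", "group_id", "parent_id", "child_id",
                       "nutrient_id", "unit", "kind", "region_id"):
            df[c] = df[c].astype("float64")
    return df


@dataclass
class DatasetBundle:
    """The validated ensemble of all input tables.

    Every pipeline stage consumes a bundle.  Masses are tonnes, composition
    per 100 g edible portion, fractions dimensionless, coefficients
    dimensionless, populations persons.
    """

    balances: pd.DataFrame
    processing: pd.DataFrame
    composition: pd.DataFrame
    fractions: pd.DataFrame
    bioavailability: pd.DataFrame
    population: pd.DataFrame
    requirements: pd.DataFrame
    units: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_UNITS))

    # -- convenience views ------------------------------------------------
    @property
    def commodities(self) -> list[str]:
        return sorted(self.balances["commodity_id"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.balances["group_id"].unique())

    @property
    def taxonomy(self) -> dict[str, str]:
        """commodity_id -> group_id (each commodity has exactly one group)."""
        return dict(
            zip(self.balances["commodity_id"], self.balances["group_id"])
        )

    @property
    def reference_year(self) -> int:
        years = self.balances["year"].unique()
        return int(years[0])

    def copy(self) -> "DatasetBundle":
        return DatasetBundle(
            balances=self.balances.copy(),
            processing=self.processing.copy(),
            composition=self.composition.copy(),
            fractions=self.fractions.copy(),
            bioavailability=self.bioavailability.copy(),
            population=self.population.copy(),
            requirements=self.requirements.copy(),
            units=dict(self.units),
        )

    def global_population(self, year: int | None = None) -> float:
        """Headcount for ``year`` (default: the balance reference year).

        A GLOBAL row wins; otherwise regional rows for the year are summed.
        """
        year = self.reference_year if year is None else int(year)
        pop = self.population[self.population["year"] == year]
        if pop.empty:
            raise BundleValidationError(
                [f"population: no rows for year {year}"]
            )
        glob = pop[pop["region_id"] == GLOBAL_REGION]
        if not glob.empty:
            return float(glob["headcount"].iloc[0])
        return float(pop["headcount"].sum())

    def regional_population(self, year: int | None = None) -> pd.DataFrame:
        year = self.reference_year if year is None else int(year)
        pop = self.population[
            (self.population["year"] == year)
            & (self.population["region_id"] != GLOBAL_REGION)
        ]
        return pop

    def validate(self, strict: bool = True) -> list[str]:
        """Validate all invariants; raise BundleValidationError on failure.

        Returns a list of non-fatal warnings (also logged).  In lenient mode
        absent composition cells are tolerated (they are treated as missing
        markers downstream); in strict mode every (commodity, nutrient) pair
        must be present, either with a value or an explicit missing marker.
        """
        problems, warnings = validate_bundle(self, strict=strict)
        if problems:
            raise BundleValidationError(problems)
        for w in warnings:
            logger.warning(w)
        return warnings


def processing_graph(processing: pd.DataFrame) -> nx.DiGraph:
    """Directed parent->child commodity-tree graph; raises GraphError on
    cycles."""
    g = nx.DiGraph()
    for row in processing.itertuples(index=False):
        g.add_edge(row.parent_id, row.child_id,
                   extraction_rate=float(row.extraction_rate))
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise GraphError(f"processing rules contain a cycle: {cycle}")
    return g


def validate_bundle(
    bundle: DatasetBundle, strict: bool = True
) -> tuple[list[str], list[str]]:
    """Collect invariant violations (problems) and non-fatal warnings."""
    problems: list[str] = []
    warnings: list[str] = []

    bal = bundle.balances
    # --- balances --------------------------------------------------------
    for col in BALANCE_COLUMNS:
        if col not in bal.columns:
            problems.append(f"balances: missing column '{col}'")
    if problems:
        return problems, warnings  # column errors make the rest unreadable

    for col in MASS_COLUMNS:
        neg = bal[bal[col] < 0]
        for cid in neg["commodity_id"]:
            problems.append(f"balances: negative {col} for '{cid}'")
    dup = bal.duplicated(subset=["commodity_id", "year"])
    for cid in bal.loc[dup, "commodity_id"]:
        problems.append(f"balances: duplicate commodity/year row '{cid}'")
    multi_group = bal.groupby("commodity_id")["group_id"].nunique()
    for cid in multi_group[multi_group > 1].index:
        problems.append(f"balances: commodity '{cid}' mapped to >1 group")
    if bal["year"].nunique() > 1:
        problems.append(
            "balances: multiple years present; the model runs on a single "
            "reference year (filter before building the bundle)"
        )

    known = set(bal["commodity_id"])

    # --- processing ------------------------------------------------------
    proc = bundle.processing
    for row in proc.itertuples(index=False):
        if not (0.0 < row.extraction_rate <= 1.0):
            problems.append(
                f"processing: extraction_rate {row.extraction_rate} for "
                f"'{row.parent_id}'->'{row.child_id}' outside (0, 1]"
            )
        for cid, role in ((row.parent_id, "parent"), (row.child_id, "child")):
            if cid not in known:
                problems.append(
                    f"processing: {role} '{cid}' has no balance row"
                )
    if len(proc):
        sums = proc.groupby("parent_id")["extraction_rate"].sum()
        for pid, s in sums.items():
            if s > 1.0 + EXTRACTION_SUM_TOLERANCE:
                problems.append(
                    f"processing: extraction rates of parent '{pid}' "
                    f"sum to {s} > 1"
                )
        try:
            processing_graph(proc)
        except GraphError as exc:
            problems.append(str(exc))

    # --- composition -----------------------------------------------------
    comp = bundle.composition
    for cid in set(comp["commodity_id"]) - known:
        problems.append(
            f"composition: unknown commodity '{cid}' (dangling reference)"
        )
    for nid in set(comp["nutrient_id"]) - set(NUTRIENTS):
        problems.append(f"composition: unknown nutrient '{nid}'")
    bad_amount = comp[comp["amount"] < 0]
    for row in bad_amount.itertuples(index=False):
        problems.append(
            f"composition: negative amount for "
            f"('{row.commodity_id}', '{row.nutrient_id}')"
        )
    dup = comp.duplicated(subset=["commodity_id", "nutrient_id"])
    for row in comp.loc[dup].itertuples(index=False):
        problems.append(
            f"composition: duplicate record for "
            f"('{row.commodity_id}', '{row.nutrient_id}')"
        )
    registry = bundle.units
    for nid in NUTRIENTS:
        if nid not in registry:
            problems.append(f"units: registry missing nutrient '{nid}'")
    for nid in set(registry) - set(NUTRIENTS):
        problems.append(f"units: registry has unknown nutrient '{nid}'")
    mism = comp[
        comp["nutrient_id"].isin(registry)
        & (comp["unit"] != comp["nutrient_id"].map(registry))
    ]
    for row in mism.itertuples(index=False):
        problems.append(
            f"composition: unit '{row.unit}' for '{row.nutrient_id}' does "
            f"not match registry '{registry.get(row.nutrient_id)}'"
        )
    if strict:
        have = set(zip(comp["commodity_id"], comp["nutrient_id"]))
        for cid in known:
            missing = [n for n in NUTRIENTS if (cid, n) not in have]
            if missing:
                problems.append(
                    f"composition: commodity '{cid}' lacks records for "
                    f"{len(missing)} nutrient(s) (strict mode requires an "
                    f"explicit missing marker): {missing[:5]}..."
                    if len(missing) > 5
                    else f"composition: commodity '{cid}' lacks records for "
                    f"nutrients {missing} (strict mode requires an explicit "
                    f"missing marker)"
                )
    n_missing = int(comp["amount"].isna().sum())
    if n_missing:
        warnings.append(
            f"composition: {n_missing} missing value(s); they contribute "
            "zero to their nutrient"
        )

    # --- fractions -------------------------------------------------------
    frac = bundle.fractions
    for row in frac.itertuples(index=False):
        if row.kind not in ("inedible", "waste"):
            problems.append(f"fractions: unknown kind '{row.kind}'")
        if not (0.0 <= row.fraction < 1.0):
            problems.append(
                f"fractions: fraction {row.fraction} for "
                f"('{row.kind}', '{row.commodity_id}') outside [0, 1)"
            )
        if row.kind == "inedible" and row.region_id != GLOBAL_REGION:
            problems.append(
                f"fractions: inedible record for '{row.commodity_id}' must "
                f"have region_id {GLOBAL_REGION}, got '{row.region_id}'"
            )
        if row.commodity_id not in known:
            problems.append(
                f"fractions: unknown commodity '{row.commodity_id}'"
            )
    dup = frac.duplicated(subset=["kind", "commodity_id", "region_id"])
    for row in frac.loc[dup].itertuples(index=False):
        problems.append(
            f"fractions: duplicate ('{row.kind}', '{row.commodity_id}', "
            f"'{row.region_id}') record"
        )

    # --- bioavailability -------------------------------------------------
    bio = bundle.bioavailability
    for row in bio.itertuples(index=False):
        if row.nutrient_id not in BIOAVAILABILITY_NUTRIENTS:
            problems.append(
                f"bioavailability: nutrient '{row.nutrient_id}' is not "
                "bioavailability-scaled (protein and the 7 IAA only)"
            )
        if not (0.0 < row.coefficient <= 1.0):
            problems.append(
                f"bioavailability: coefficient {row.coefficient} for "
                f"('{row.commodity_id}', '{row.nutrient_id}') outside (0, 1]"
            )
        if row.commodity_id not in known:
            problems.append(
                f"bioavailability: unknown commodity '{row.commodity_id}'"
            )
    covered = set(bio["commodity_id"]) if len(bio) else set()
    uncovered = known - covered
    if uncovered:
        warnings.append(
            f"bioavailability: {len(uncovered)} commodity(ies) without "
            "coefficients default to 1.0"
        )

    # --- population ------------------------------------------------------
    pop = bundle.population
    bad = pop[pop["headcount"] <= 0]
    for row in bad.itertuples(index=False):
        problems.append(
            f"population: nonpositive headcount for "
            f"('{row.region_id}', {row.year})"
        )
    if not len(pop):
        problems.append("population: table is empty")

    # --- requirements ----------------------------------------------------
    req = bundle.requirements
    for row in req.itertuples(index=False):
        if row.nutrient_id not in NUTRIENTS:
            problems.append(
                f"requirements: unknown nutrient '{row.nutrient_id}'"
            )
        if not row.per_capita_daily > 0:
            problems.append(
                f"requirements: nonpositive reference value for "
                f"'{row.nutrient_id}'"
            )

    return problems, warnings
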