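"""CSV reading and writing for the seven bundle tables and all outputs.

Dialect is fixed: comma-separated, UTF-8, header row, "." decimal.  Floats
are written with Python's shortest-repr formatting so a written table read
back compares exactly (before any display rounding).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .nutrients import NUTRIENTS
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

logger = logging.getLogger(__name__)

#: filename -> (bundle attribute, required columns)
BUNDLE_FILES: dict[str, tuple[str, list[str]]] = {
    "balances.csv": ("balances", BALANCE_COLUMNS),
    "processing.csv": ("processing", PROCESSING_COLUMNS),
    "composition.csv": ("composition", COMPOSITION_COLUMNS),
    "fractions.csv": ("fractions", FRACTION_COLUMNS),
    "bioavailability.csv": ("bioavailability", BIOAVAILABILITY_COLUMNS),
    "population.csv": ("population", POPULATION_COLUMNS),
    "requirements.csv": ("requirements", REQUIREMENT_COLUMNS),
}

_STRING_COLUMNS = {
    "commodity_id", "group_id", "parent_id", "child_id", "nutrient_id",
    "unit", "kind", "region_id", "display", "basis",
}
_INT_COLUMNS = {"year"}
_BOOL_COLUMNS = {"surplus"}


def read_table(path: str | Path, required_columns: list[str]) -> pd.DataFrame:
    """Read one CSV table, enforcing the dialect and column schema."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=",", encoding="utf-8", decimal=".")
    except pd.errors.ParserError as exc:  # malformed line: name the file
        raise ParseError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file (header row required)") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df = df[required_columns]
    for c in required_columns:
        if c in _STRING_COLUMNS:
            df[c] = df[c].astype(str)
        elif c in _INT_COLUMNS:
            df[c] = df[c].astype("int64")
        elif c in _BOOL_COLUMNS:
            df[c] = df[c].astype(bool)
        else:
            df[c] = df[c].astype("float64")
    return df


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write any output table as CSV; a written table reads back equal."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8")
    return path


def read_units(path: str | Path) -> dict[str, str]:
    df = read_table(path, ["nutrient_id", "unit"])
    return dict(zip(df["nutrient_id"], df["unit"]))


def write_units(units: dict[str, str], path: str | Path) -> Path:
    df = pd.DataFrame(
        {"nutrient_id": list(units), "unit": [units[n] for n in units]}
    )
    return write_table(df, path)


def read_bundle(
    directory: str | Path, strictness: str = "strict"
) -> DatasetBundle:
    """Read and validate a bundle from a directory of CSV files.

    In ``lenient`` mode, absent (commodity, nutrient) composition cells are
    filled with explicit missing markers (NaN) and a warning is logged; in
    ``strict`` mode they are validation errors.
    """
    if strictness not in ("strict", "lenient"):
        raise ValueError(f"unknown strictness '{strictness}'")
    directory = Path(directory)
    tables = {}
    for fname, (attr, cols) in BUNDLE_FILES.items():
        fpath = directory / fname
        if not fpath.exists():
            raise ParseError(f"{fpath}: file not found")
        tables[attr] = read_table(fpath, cols)
    units_path = directory / "units.csv"
    if not units_path.exists():
        raise ParseError(f"{units_path}: file not found (units registry)")
    units = read_units(units_path)

    bundle = DatasetBundle(units=units, **tables)
    if strictness == "lenient":
        bundle.composition = _complete_composition(bundle)
    bundle.validate(strict=(strictness == "strict"))
    return bundle


def _complete_composition(bundle: DatasetBundle) -> pd.DataFrame:
    """Fill absent (commodity, nutrient) cells with NaN missing markers."""
    comp = bundle.composition
    have = set(zip(comp["commodity_id"], comp["nutrient_id"]))
    fillers = [
        {"commodity_id": cid, "nutrient_id": n, "amount": np.nan,
         "unit": bundle.units[n]}
        for cid in bundle.commodities
        for n in NUTRIENTS
        if (cid, n) not in have
    ]
    if fillers:
        logger.warning(
            "composition: %d absent cell(s) converted to explicit missing "
            "markers (lenient mode)", len(fillers)
        )
        comp = pd.concat(
            [comp, pd.DataFrame(fillers, columns=COMPOSITION_COLUMNS)],
            ignore_index=True,
        )
    return comp


def write_bundle(bundle: DatasetBundle, directory: str | Path) -> Path:
    """Write the seven bundle tables plus units.csv to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for fname, (attr, _cols) in BUNDLE_FILES.items():
        write_table(getattr(bundle, attr), directory / fname)
    write_units(bundle.units, directory / "units.csv")
    return directory
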