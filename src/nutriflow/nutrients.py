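"""Nutrient vocabulary and the default unit registry.

The model tracks 29 nutrients: five macronutrients (with energy treated as a
composition column in kcal, not derived from macronutrients), eight minerals,
nine vitamins, and seven indispensable amino acids (IAA).  Vitamin A is a
single aggregated quantity; retinol and pro-vitamin A are not separated.

Bioavailability scaling applies only to protein and the seven IAA.  For every
other nutrient the bioavailable quantity equals the gross quantity.
"""

from __future__ import annotations

MACRONUTRIENTS: tuple[str, ...] = (
    "carbohydrates",
    "energy",
    "fat",
    "fiber",
    "protein",
)

MINERALS: tuple[str, ...] = (
    "calcium",
    "copper",
    "iron",
    "magnesium",
    "phosphorus",
    "potassium",
    "selenium",
    "zinc",
)

VITAMINS: tuple[str, ...] = (
    "vitamin_a",
    "vitamin_b1",
    "vitamin_b2",
    "vitamin_b5",
    "vitamin_b6",
    "vitamin_b9",
    "vitamin_b12",
    "vitamin_c",
    "vitamin_e",
)

INDISPENSABLE_AMINO_ACIDS: tuple[str, ...] = (
    "cystine",
    "histidine",
    "leucine",
    "lysine",
    "methionine",
    "threonine",
    "tryptophan",
)

#: All 29 modelled nutrients, in canonical reporting order.
NUTRIENTS: tuple[str, ...] = (
    MACRONUTRIENTS + MINERALS + VITAMINS + INDISPENSABLE_AMINO_ACIDS
)

#: Nutrients whose availability is scaled by a bioavailability coefficient.
BIOAVAILABILITY_NUTRIENTS: tuple[str, ...] = ("protein",) + INDISPENSABLE_AMINO_ACIDS

#: Default unit per nutrient, per 100 g edible portion (composition tables)
#: and per person per day (reference values).  Configurable via units.csv.
DEFAULT_UNITS: dict[str, str] = {
    "carbohydrates": "g",
    "energy": "kcal",
    "fat": "g",
    "fiber": "g",
    "protein": "g",
    "calcium": "mg",
    "copper": "mg",
    "iron": "mg",
    "magnesium": "mg",
    "phosphorus": "mg",
    "potassium": "mg",
    "selenium": "ug",
    "zinc": "mg",
    "vitamin_a": "ug",
    "vitamin_b1": "mg",
    "vitamin_b2": "mg",
    "vitamin_b5": "mg",
    "vitamin_b6": "mg",
    "vitamin_b9": "ug",
    "vitamin_b12": "ug",
    "vitamin_c": "mg",
    "vitamin_e": "mg",
    "cystine": "g",
    "histidine": "g",
    "leucine": "g",
    "lysine": "g",
    "methionine": "g",
    "threonine": "g",
    "tryptophan": "g",
}

#: Multiplying a mass in tonnes by this factor gives the number of 100 g
#: portions it contains (1 t = 10^6 g = 10^4 x 100 g).  Composition values are
#: per 100 g, so ``tonnes * TONNES_TO_100G * amount`` is in registry units.
TONNES_TO_100G: float = 1.0e4

#: Days per year used for per-capita daily quantities.
DAYS_PER_YEAR: float = 365.0

#: Grams per tonne, for per-capita food-mass reporting.
GRAMS_PER_TONNE: float = 1.0e6

#: Sentinel region id for globally-valid records.
GLOBAL_REGION: str = "GLOBAL"

assert len(NUTRIENTS) == 29
assert set(DEFAULT_UNITS) == set(NUTRIENTS)
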