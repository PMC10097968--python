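"""Controlled nutrient vocabulary and unit conversions.

Every nutrient the engine understands is declared in ``data/nutrients.json``
with a single canonical unit (g for macronutrient species, mg for sodium,
minerals and EPA/DHA, ug for heavy metals, glyphosate, folate and B12, IU for
vitamins A and D). Profiles are stored in canonical units; criterion
thresholds written in household or label units (teaspoons of sugar, IU of
vitamin D, grams of salt) are converted here.
"""

from __future__ import annotations

import json
from importlib.resources import files

from .errors import UnsupportedConversionError

_RAW = json.loads(files("foodtiers.data").joinpath("nutrients.json").read_text())

#: nutrient-id -> {"id", "unit", "label"}
NUTRIENTS: dict[str, dict] = {entry["id"]: entry for entry in _RAW["nutrients"]}

#: parent total -> list of species that must not exceed it
SPECIES_SUMS: dict[str, list[str]] = dict(_RAW["species_sums"])

#: relative tolerance for species sums exceeding their parent total
EPS_SUM = 0.05

# Fixed design constants for household/label units.
GRAMS_PER_TEASPOON_SUGAR = 4.2  # USDA household measure, granulated sugar
IU_PER_UG_VITAMIN_D = 40.0
SALT_PER_SODIUM = 2.5  # g salt per g sodium

_METRIC = {"g": 1.0, "mg": 1e-3, "ug": 1e-6}

_SUGAR_IDS = {"sugar_total", "sugar_added", "sucrose", "glucose", "fructose",
              "galactose", "lactose"}


def canonical_unit(nutrient_id: str) -> str:
    return NUTRIENTS[nutrient_id]["unit"]


def is_known(nutrient_id: str) -> bool:
    return nutrient_id in NUTRIENTS


def convert(amount: float, from_unit: str, to_unit: str, nutrient_id: str) -> float:
    """Convert ``amount`` between units for a given nutrient.

    Supported pairs: metric mass prefixes (g/mg/ug) for any nutrient;
    teaspoon <-> g for sugar species; IU <-> ug for vitamin D; and
    mg sodium <-> g salt. Raises :class:`UnsupportedConversionError` for any
    other pair. Conversions are exact arithmetic, so round trips are identity
    to floating-point precision.
    """
    if from_unit == to_unit:
        return amount
    if from_unit in _METRIC and to_unit in _METRIC:
        return amount * _METRIC[from_unit] / _METRIC[to_unit]
    pair = (from_unit, to_unit)
    if nutrient_id in _SUGAR_IDS:
        if pair == ("tsp", "g"):
            return amount * GRAMS_PER_TEASPOON_SUGAR
        if pair == ("g", "tsp"):
            return amount / GRAMS_PER_TEASPOON_SUGAR
    if nutrient_id == "vitamin_d":
        if pair == ("IU", "ug"):
            return amount / IU_PER_UG_VITAMIN_D
        if pair == ("ug", "IU"):
            return amount * IU_PER_UG_VITAMIN_D
    if nutrient_id == "sodium":
        # sodium is canonically mg; salt equivalents are in grams
        if pair == ("mg", "g-salt"):
            return amount * 1e-3 * SALT_PER_SODIUM
        if pair == ("g-salt", "mg"):
            return amount / SALT_PER_SODIUM * 1e3
    raise UnsupportedConversionError(
        f"no conversion defined from {from_unit!r} to {to_unit!r} for nutrient "
        f"{nutrient_id!r}"
    )
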