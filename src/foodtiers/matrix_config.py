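"""The shipped default matrix configuration.

Bundles the 38-criterion, five-level tier configuration, the additive-concern
seed registry, the seed ingredient lexicon, Big-8/Big-9 allergen registries,
the reference nutrient registry, strategy templates, and daily intake
reference constants. Four thresholds are normative anchors of the scheme —
added sugar <= 1 teaspoon (4.2 g) per serving, omega-6 <= 5 g per serving,
omega-6:omega-3 <= 4:1, vitamin D >= 400 IU per serving for dairy — and the
loader refuses any bundle in which they have been altered or removed. The
remaining values are package defaults marked non-normative in the data file.
"""

from __future__ import annotations

import json
from importlib.resources import files

from pydantic import BaseModel, ConfigDict, Field

from .criteria import (
    Criterion,
    RatioPredicate,
    ThresholdPredicate,
)
from .errors import ConfigurationError
from .lexicon import AllergenRegistry, Lexicon
from .product_model import ReferenceRegistry

EXPECTED_CRITERIA = 38
EXPECTED_PER_LEVEL = {1: 12, 2: 5, 3: 9, 4: 8, 5: 4}

#: focus areas every default level-1 gate must cover, with the nutrient or
#: concern that represents each
_LEVEL1_FOCUS = {
    "healthy fats": lambda c: isinstance(c.predicate, ThresholdPredicate)
    and c.predicate.nutrient in ("omega6_total", "fat_trans"),
    "sugars": lambda c: isinstance(c.predicate, ThresholdPredicate)
    and c.predicate.nutrient.startswith("sugar"),
    "additives": lambda c: c.predicate.kind == "forbid-ingredient",
    "salt": lambda c: isinstance(c.predicate, ThresholdPredicate)
    and c.predicate.nutrient == "sodium",
    "heavy metals": lambda c: isinstance(c.predicate, ThresholdPredicate)
    and c.predicate.nutrient in ("lead", "arsenic", "cadmium", "mercury"),
    "pesticides": lambda c: isinstance(c.predicate, ThresholdPredicate)
    and c.predicate.nutrient == "glyphosate",
    "antibiotics": lambda c: c.predicate.kind == "require-attribute"
    and c.predicate.attribute == "antibiotic-free",
}


class IntakeReference(BaseModel):
    model_config = ConfigDict(extra="ignore")

    nutrient: str
    population: str
    lower: float
    upper: float
    unit: str

    def model_post_init(self, __context) -> None:
        if self.lower > self.upper:
            raise ValueError("intake reference lower bound exceeds upper bound")


class MatrixConfiguration(BaseModel):
    model_config = ConfigDict(extra="ignore")

    version: str
    criteria: list[Criterion]
    lists: dict[str, list[str]] = Field(default_factory=dict)
    intake_references: list[IntakeReference] = Field(default_factory=list)

    def criteria_at_level(self, level: int) -> list[Criterion]:
        return [c for c in self.criteria if c.level == level]

    def criterion(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(f"no criterion with id {criterion_id!r}")


def _anchor_violations(config: MatrixConfiguration) -> list[str]:
    """Check that the four normative anchor thresholds are present, verbatim."""
    out: list[str] = []

    def threshold(nutrient, direction, value, level, unit):
        for c in config.criteria:
            p = c.predicate
            if (
                isinstance(p, ThresholdPredicate)
                and p.nutrient == nutrient
                and p.direction == direction
                and p.value == value
                and p.unit == unit
                and c.level == level
            ):
                return True
        return False

    if not threshold("sugar_added", "max", 4.2, 1, "g"):
        out.append("missing anchor: added sugar max 4.2 g/serving at level 1")
    if not threshold("omega6_total", "max", 5.0, 1, "g"):
        out.append("missing anchor: omega-6 max 5 g/serving at level 1")
    if not threshold("vitamin_d", "min", 400.0, 3, "IU"):
        out.append("missing anchor: vitamin D min 400 IU/serving at level 3")
    if not any(
        isinstance(c.predicate, RatioPredicate)
        and c.predicate.numerator == "omega6_total"
        and c.predicate.denominator == "omega3_total"
        and c.predicate.max_value == 4.0
        and c.level == 2
        for c in config.criteria
    ):
        out.append("missing anchor: omega-6:omega-3 ratio max 4 at level 2")
    return out


def validate_matrix(config: MatrixConfiguration) -> list[str]:
    """Return every configuration violation (empty list = valid)."""
    violations: list[str] = []
    n = len(config.criteria)
    if n != EXPECTED_CRITERIA:
        violations.append(f"expected {EXPECTED_CRITERIA} criteria, found {n}")
    ids = [c.id for c in config.criteria]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        violations.append(f"duplicate criterion ids: {dupes}")
    for level in range(1, 6):
        if not config.criteria_at_level(level):
            violations.append(f"level {level} has no criteria")
    for focus, match in _LEVEL1_FOCUS.items():
        if not any(match(c) for c in config.criteria_at_level(1)):
            violations.append(f"no level-1 criterion covers the {focus!r} focus area")
    violations.extend(_anchor_violations(config))
    return violations


def load_matrix(text: str) -> MatrixConfiguration:
    """Parse and validate a matrix configuration, failing loudly with every
    violation listed."""
    raw = json.loads(text)
    try:
        config = MatrixConfiguration.model_validate(raw)
    except Exception as exc:
        raise ConfigurationError([str(exc)]) from exc
    intake_raw = raw.get("intake_references")
    if intake_raw is None:
        config.intake_references = _load_default_intake_references()
    violations = validate_matrix(config)
    if violations:
        raise ConfigurationError(violations)
    return config


def _load_default_intake_references() -> list[IntakeReference]:
    raw = json.loads(
        files("foodtiers.data").joinpath("intake_references.json").read_text()
    )
    return [IntakeReference.model_validate(r) for r in raw["references"]]


def load_default_matrix() -> MatrixConfiguration:
    """Load and validate the bundled default configuration. Pure: repeated
    loads are identical."""
    config = load_matrix(
        files("foodtiers.data").joinpath("matrix.default.json").read_text()
    )
    closure = check_lexicon_closure(config, Lexicon.load_default())
    if closure:
        raise ConfigurationError(closure)
    return config


def check_lexicon_closure(config: MatrixConfiguration, lexicon: Lexicon) -> list[str]:
    """Every ingredient/group referenced by a criterion must resolve in the
    lexicon."""
    out: list[str] = []
    groups = lexicon.known_groups()
    for c in config.criteria:
        p = c.predicate
        if p.kind != "forbid-ingredient":
            continue
        if p.target_kind == "canonical" and p.target not in lexicon.entries:
            out.append(f"criterion {c.id!r}: canonical id {p.target!r} not in lexicon")
        if p.target_kind == "group" and p.target not in groups:
            out.append(f"criterion {c.id!r}: group {p.target!r} not in lexicon")
        if p.concern_category not in lexicon.concern_categories():
            out.append(
                f"criterion {c.id!r}: concern category {p.concern_category!r} "
                f"has no registry entries"
            )
    return out


def lookup_intake_reference(
    config: MatrixConfiguration, nutrient: str, population: str = "adult"
) -> IntakeReference:
    for ref in config.intake_references:
        if ref.nutrient == nutrient and ref.population == population:
            return ref
    raise KeyError(
        f"no intake reference for nutrient {nutrient!r}, population {population!r}"
    )


# convenience re-exports of the other bundled artifacts ----------------------


def load_default_lexicon() -> Lexicon:
    return Lexicon.load_default()


def load_default_references() -> ReferenceRegistry:
    return ReferenceRegistry.default()


def load_allergen_registry(mode: str = "big9") -> AllergenRegistry:
    return AllergenRegistry.load_default(mode)
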