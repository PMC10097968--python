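"""Hierarchical product/component data model, JSON ingestion and validation,
and assumption-tracked nutrient rollup to a per-serving profile.

A product document is a single JSON file: identity, category, serving size,
an optional declared nutrient panel, and a tree of components with mass
fractions. Components either carry their own per-100g (or per-100mL) profile,
or are themselves composed of subcomponents, or — when neither is available —
are filled from a reference nutrient registry, in which case the substitution
is logged as an :class:`AssumptionRecord` so every evaluation stays fully
traceable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib.resources import files
from typing import Iterator, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import vocabulary
from .errors import (
    ParseError,
    ProductValidationError,
    SchemaValidationError,
    UnresolvableComponentError,
)

MAX_COMPONENT_DEPTH = 8
EPS_MASS = 0.01
DECLARED_CONFLICT_REL = 0.20
MIN_PLAUSIBLE_PORTION = 30.0  # g or mL; smaller per-serving portions on a
                              # multi-serve pack trigger a plausibility warning


class Basis(str, Enum):
    PER_SERVING = "per-serving"
    PER_100G = "per-100g"
    PER_100ML = "per-100mL"


class Provenance(str, Enum):
    ASSAYED = "assayed"
    DECLARED = "declared"
    REFERENCE_SUBSTITUTED = "reference-substituted"


class Category(str, Enum):
    DAIRY = "dairy"
    JUICE = "juice"
    ICE_CREAM = "ice-cream"
    CULINARY = "culinary"
    BEVERAGE = "beverage"
    OTHER = "other"


class NutrientProfile(BaseModel):
    """Quantities keyed by controlled-vocabulary nutrient id, one basis."""

    model_config = ConfigDict(extra="forbid")

    basis: Basis
    quantities: dict[str, float] = Field(default_factory=dict)

    @field_validator("quantities")
    @classmethod
    def _check_quantities(cls, q: dict[str, float]) -> dict[str, float]:
        unknown = sorted(k for k in q if not vocabulary.is_known(k))
        if unknown:
            raise ValueError(f"unknown nutrient ids: {', '.join(unknown)}")
        negative = sorted(k for k, v in q.items() if v < 0)
        if negative:
            raise ValueError(f"negative quantities for: {', '.join(negative)}")
        return q

    def get(self, nutrient_id: str) -> Optional[float]:
        return self.quantities.get(nutrient_id)


class Component(BaseModel):
    model_config = ConfigDict(extra="allow")

    id: str
    name: str
    mass_fraction: float = Field(ge=0.0, le=1.0)
    ingredient_statement: Optional[str] = None
    profile: Optional[NutrientProfile] = None
    provenance: Provenance = Provenance.DECLARED
    subcomponents: list["Component"] = Field(default_factory=list)


class Product(BaseModel):
    """Top-level product record. Unknown extra keys are preserved but ignored."""

    model_config = ConfigDict(extra="allow")

    id: str
    name: str
    category: Category
    serving_size: float = Field(gt=0.0)
    serving_unit: str = "g"  # "g" or "mL"
    servings_per_package: int = Field(default=1, ge=1)
    ingredient_statement: str = ""
    components: list[Component] = Field(default_factory=list)
    declared_profile: Optional[NutrientProfile] = None
    claims: list[str] = Field(default_factory=list)
    whitelist_ids: list[str] = Field(default_factory=list)

    @field_validator("serving_unit")
    @classmethod
    def _check_unit(cls, u: str) -> str:
        if u not in ("g", "mL"):
            raise ValueError("serving_unit must be 'g' or 'mL'")
        return u


@dataclass(frozen=True)
class AssumptionRecord:
    """One reference-registry substitution made during profile resolution."""

    component_id: str
    reference_entry_id: str
    substituted_fields: tuple[str, ...]
    note: str

    def to_dict(self) -> dict:
        return {
            "component_id": self.component_id,
            "reference_entry_id": self.reference_entry_id,
            "substituted_fields": list(self.substituted_fields),
            "note": self.note,
        }


@dataclass(frozen=True)
class Finding:
    """One validator finding. ``severity`` is 'error' or 'warning'."""

    severity: str
    rule: str
    path: str
    message: str


# ---------------------------------------------------------------------------
# loading and validation


def _pydantic_violations(exc: ValidationError) -> list[str]:
    out = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        out.append(f"{loc}: {err['msg']}")
    return out


def load_product(document: str) -> Product:
    """Parse and fully validate a product JSON document.

    Raises :class:`ParseError` (with byte offset) on malformed JSON,
    :class:`SchemaValidationError` listing *every* violated field path on
    schema breaches, and :class:`ProductValidationError` when semantic
    invariants (species sums, mass-fraction sums, depth cap, ...) fail.
    """
    try:
        raw = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"malformed JSON at byte offset {exc.pos}: {exc.msg}", offset=exc.pos
        ) from exc
    try:
        product = Product.model_validate(raw)
    except ValidationError as exc:
        raise SchemaValidationError(_pydantic_violations(exc)) from exc
    errors = [f for f in validate_product(product) if f.severity == "error"]
    if errors:
        raise ProductValidationError(errors)
    return product


def _check_species_sums(profile: NutrientProfile, path: str) -> Iterator[Finding]:
    for parent, species in vocabulary.SPECIES_SUMS.items():
        total = profile.quantities.get(parent)
        present = [s for s in species if s in profile.quantities]
        if total is None or not present:
            continue
        sum_species = sum(profile.quantities[s] for s in present)
        if sum_species > total * (1.0 + vocabulary.EPS_SUM) + 1e-12:
            yield Finding(
                "error",
                f"species-sum:{parent}",
                path,
                f"{'+'.join(present)} = {sum_species:.4g} exceeds {parent} = "
                f"{total:.4g} beyond the {vocabulary.EPS_SUM:.0%} tolerance",
            )


def _walk_components(
    components: list[Component], parent_path: str, parent_label: str, depth: int
) -> Iterator[Finding]:
    if depth > MAX_COMPONENT_DEPTH:
        yield Finding(
            "error",
            "depth-cap",
            parent_path,
            f"component nesting exceeds the maximum depth of {MAX_COMPONENT_DEPTH}",
        )
        return
    if components:
        frac_sum = sum(c.mass_fraction for c in components)
        if not math.isclose(frac_sum, 1.0, abs_tol=EPS_MASS):
            yield Finding(
                "error",
                "mass-fraction-sum",
                parent_path,
                f"mass fractions of the subcomponents of {parent_label!r} sum to "
                f"{frac_sum:.4g}, expected 1 within ±{EPS_MASS}",
            )
    for comp in components:
        cpath = f"{parent_path}.{comp.id}"
        if comp.profile is not None:
            if comp.profile.basis == Basis.PER_SERVING:
                yield Finding(
                    "error",
                    "component-basis",
                    cpath,
                    "component profiles must be per-100g or per-100mL; "
                    "per-serving is reserved for the product's declared panel",
                )
            yield from _check_species_sums(comp.profile, cpath)
        yield from _walk_components(comp.subcomponents, cpath, comp.name, depth + 1)


def validate_product(product: Product) -> list[Finding]:
    """Return all invariant violations and warnings. Never raises."""
    findings: list[Finding] = []
    # components without their own profiles may still resolve from the
    # reference registry, so only a product with no components at all and no
    # declared panel is unconditionally profile-less
    if product.declared_profile is None and not product.components:
        findings.append(
            Finding(
                "error",
                "no-profile",
                "product",
                "product has neither a declared profile nor any components",
            )
        )
    if product.declared_profile is not None:
        findings.extend(_check_species_sums(product.declared_profile, "declared_profile"))
    findings.extend(_walk_components(product.components, "components", product.name, 1))
    if (
        product.servings_per_package > 1
        and product.serving_size < MIN_PLAUSIBLE_PORTION
    ):
        package = product.serving_size * product.servings_per_package
        findings.append(
            Finding(
                "warning",
                "portion-plausibility",
                "serving_size",
                f"{package:.0f} {product.serving_unit} pack declares "
                f"{product.servings_per_package} servings — the implied portion of "
                f"{product.serving_size:.1f} {product.serving_unit} is below "
                f"{MIN_PLAUSIBLE_PORTION:.0f} and may not reflect realistic consumption",
            )
        )
    return findings


# ---------------------------------------------------------------------------
# unit conversion (re-exported from the vocabulary for a stable surface)

convert = vocabulary.convert


# ---------------------------------------------------------------------------
# reference registry and profile resolution


def _fold_name(name: str) -> str:
    return "-".join("".join(c if c.isalnum() else " " for c in name.lower()).split())


class ReferenceRegistry:
    """Reference nutrient profiles (per-100g) keyed by entry id.

    Components lacking a profile are matched by their folded name
    ("Grape Juice" -> "grape-juice").
    """

    def __init__(self, entries: dict[str, NutrientProfile]):
        for key, prof in entries.items():
            if prof.basis not in (Basis.PER_100G, Basis.PER_100ML):
                raise ValueError(f"reference entry {key!r} must be per-100g/per-100mL")
        self.entries = dict(entries)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceRegistry":
        raw = json.loads(text)
        return cls(
            {k: NutrientProfile.model_validate(v) for k, v in raw["entries"].items()}
        )

    @classmethod
    def default(cls) -> "ReferenceRegistry":
        return cls.from_json(files("foodtiers.data").joinpath("references.json").read_text())

    def lookup(self, name: str) -> Optional[tuple[str, NutrientProfile]]:
        key = _fold_name(name)
        if key in self.entries:
            return key, self.entries[key]
        return None


@dataclass
class ResolutionResult:
    """Per-serving profile plus the assumption log and any consistency warnings."""

    profile: NutrientProfile
    assumptions: list[AssumptionRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):  # allow ``profile, assumptions = resolve_profile(...)``
        return iter((self.profile, self.assumptions))


def _per_gram(
    comp: Component,
    references: ReferenceRegistry,
    assumptions: list[AssumptionRecord],
    depth: int,
) -> dict[str, float]:
    if depth > MAX_COMPONENT_DEPTH:
        raise ProductValidationError(
            [Finding("error", "depth-cap", comp.id, "component nesting too deep")]
        )
    if comp.profile is not None:
        return {k: v / 100.0 for k, v in comp.profile.quantities.items()}
    if comp.subcomponents:
        total: dict[str, float] = {}
        for sub in comp.subcomponents:
            sub_pg = _per_gram(sub, references, assumptions, depth + 1)
            for k, v in sub_pg.items():
                total[k] = total.get(k, 0.0) + v * sub.mass_fraction
        return total
    hit = references.lookup(comp.name)
    if hit is None:
        raise UnresolvableComponentError(comp.id, comp.name)
    entry_id, profile = hit
    comp.provenance = Provenance.REFERENCE_SUBSTITUTED
    assumptions.append(
        AssumptionRecord(
            component_id=comp.id,
            reference_entry_id=entry_id,
            substituted_fields=tuple(sorted(profile.quantities)),
            note=(
                f"no assay or declared profile for {comp.name!r}; substituted the "
                f"reference entry {entry_id!r}"
            ),
        )
    )
    return {k: v / 100.0 for k, v in profile.quantities.items()}


def resolve_profile(
    product: Product, references: Optional[ReferenceRegistry] = None
) -> ResolutionResult:
    """Roll the component tree up into one per-serving profile.

    Mass-fraction-weighted aggregation over the component tree, rescaled by
    the serving size (per-100mL inputs are treated like per-100g using the
    serving volume; no density model). When a declared panel exists it wins
    over the rollup, with a consistency warning whenever the two disagree by
    more than 20% (relative) on any shared nutrient. Every
    reference-registry substitution appends an :class:`AssumptionRecord`.
    """
    if references is None:
        references = ReferenceRegistry.default()
    assumptions: list[AssumptionRecord] = []
    warnings: list[str] = []

    rolled: Optional[dict[str, float]] = None
    if product.components:
        per_gram: dict[str, float] = {}
        for comp in product.components:
            comp_pg = _per_gram(comp, references, assumptions, 1)
            for k, v in comp_pg.items():
                per_gram[k] = per_gram.get(k, 0.0) + v * comp.mass_fraction
        rolled = {k: v * product.serving_size for k, v in per_gram.items()}

    declared: Optional[dict[str, float]] = None
    if product.declared_profile is not None:
        dp = product.declared_profile
        if dp.basis == Basis.PER_SERVING:
            declared = dict(dp.quantities)
        else:
            declared = {
                k: v * product.serving_size / 100.0 for k, v in dp.quantities.items()
            }

    if declared is None and rolled is None:
        raise ProductValidationError(
            [Finding("error", "no-profile", "product", "no resolvable profile")]
        )

    if declared is not None and rolled is not None:
        for k in sorted(set(declared) & set(rolled)):
            d, r = declared[k], rolled[k]
            scale = max(abs(d), abs(r))
            if scale > 0 and abs(d - r) > DECLARED_CONFLICT_REL * scale:
                warnings.append(
                    f"declared {k} = {d:.4g} disagrees with component rollup "
                    f"{r:.4g} by more than {DECLARED_CONFLICT_REL:.0%}; "
                    f"the declared value was used"
                )
        merged = dict(rolled)
        merged.update(declared)  # declared wins on shared nutrients
        final = merged
    elif declared is not None:
        final = declared
    else:
        final = rolled  # type: ignore[assignment]

    profile = NutrientProfile(
        basis=Basis.PER_SERVING, quantities={k: max(0.0, v) for k, v in final.items()}
    )
    return ResolutionResult(profile=profile, assumptions=assumptions, warnings=warnings)
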