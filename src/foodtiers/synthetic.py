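"""Seeded synthetic product portfolio and scenario fixtures.

No real product portfolio is distributable, so every criterion, the tier
ladder, the reports, and the CLI are exercised against synthetic products
generated here: a seeded random portfolio across dairy / juice / ice-cream /
culinary categories (nutrient panels drawn uniformly from per-category
ranges, optional component nesting, additive inclusions, attribute claims),
per-criterion isolator fixtures that fail exactly one criterion each, and
named before/after re-engineering scenarios (chocolate milk, chocolate ice
cream) whose numeric contents are invented stand-ins.

Determinism: everything is driven by ``random.Random(seed)`` and all floats
are rounded to four decimals before serialization, so the same spec yields
byte-identical documents on any platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .criteria import (
    Criterion,
    ForbidIngredientPredicate,
    ListMembershipPredicate,
    RatioPredicate,
    RequireAttributePredicate,
    ThresholdPredicate,
)
from .engine import Evaluator
from .matrix_config import MatrixConfiguration
from . import vocabulary

ATTRIBUTES = [
    "antibiotic-free",
    "allergen-disclosure",
    "independently-tested",
    "cold-pressed-oils-only",
    "evidence-backed-claims",
    "traceable-sourcing",
    "sustainable-packaging",
    "animal-welfare-certified",
    "environmental-impact-assessed",
]

_SUGAR_SPECIES = ("sucrose", "glucose", "fructose", "galactose", "lactose")


def build_quantities(leaves: dict[str, float]) -> dict[str, float]:
    """Derive totals from leaf species so the species-sum invariants hold by
    construction. ``sucrose`` is raised to cover ``sugar_added`` if needed."""
    q = {k: round(float(v), 4) for k, v in leaves.items() if v is not None}
    added = q.get("sugar_added", 0.0)
    if added > q.get("sucrose", 0.0):
        q["sucrose"] = added
    q["sugar_total"] = round(sum(q.get(s, 0.0) for s in _SUGAR_SPECIES), 4)
    pufa = q.get("omega6_total", 0.0) + q.get("omega3_total", 0.0)
    q["fat_pufa"] = round(max(q.get("fat_pufa", 0.0), pufa), 4)
    q["fat_total"] = round(
        q.get("fat_saturated", 0.0)
        + q.get("fat_trans", 0.0)
        + q.get("fat_mufa", 0.0)
        + q["fat_pufa"],
        4,
    )
    q["fiber_total"] = round(
        q.get("fiber_soluble", 0.0) + q.get("fiber_insoluble", 0.0), 4
    )
    return {k: v for k, v in q.items() if vocabulary.is_known(k)}


# ---------------------------------------------------------------------------
# per-category all-pass templates (leaf values are per serving)

_TEMPLATES: dict[str, dict] = {
    "dairy": {
        "serving_size": 240.0,
        "serving_unit": "mL",
        "statement": "whole milk, cream, inulin, algal oil, natural flavors",
        "leaves": {
            "sugar_added": 3.0, "sucrose": 3.0, "lactose": 9.0,
            "fat_saturated": 4.5, "fat_trans": 0.0, "fat_mufa": 2.0,
            "omega6_total": 1.0, "omega3_total": 0.5, "ala": 0.2,
            "epa": 30.0, "dha": 60.0,
            "fiber_soluble": 2.0, "fiber_insoluble": 1.5,
            "protein": 8.0, "sodium": 105.0,
            "calcium": 280.0, "magnesium": 45.0, "zinc": 1.8, "iron": 2.2,
            "vitamin_d": 450.0, "vitamin_a": 600.0, "vitamin_c": 4.0,
            "vitamin_b6": 0.3, "vitamin_b12": 0.6, "folate": 45.0,
            "lead": 0.1, "arsenic": 0.5, "cadmium": 0.2, "mercury": 0.1,
            "glyphosate": 0.5,
        },
    },
    "juice": {
        "serving_size": 200.0,
        "serving_unit": "mL",
        "statement": "water, grape juice, strawberry puree, inulin, algal oil, ascorbic acid",
        "leaves": {
            "sugar_added": 0.0, "glucose": 4.0, "fructose": 4.2, "sucrose": 1.0,
            "fat_saturated": 0.1, "fat_trans": 0.0, "fat_mufa": 0.1,
            "omega6_total": 0.2, "omega3_total": 0.3, "ala": 0.1,
            "epa": 20.0, "dha": 40.0,
            "fiber_soluble": 2.5, "fiber_insoluble": 1.0,
            "protein": 0.8, "sodium": 30.0,
            "calcium": 20.0, "magnesium": 45.0, "zinc": 1.6, "iron": 2.1,
            "vitamin_c": 40.0, "vitamin_b6": 0.25, "vitamin_b12": 0.4,
            "folate": 45.0,
            "lead": 0.1, "arsenic": 0.6, "cadmium": 0.2, "mercury": 0.05,
            "glyphosate": 0.8,
        },
    },
    "ice-cream": {
        "serving_size": 100.0,
        "serving_unit": "g",
        "statement": "cream, whole milk, erythritol, cocoa powder, guar gum, inulin",
        "leaves": {
            "sugar_added": 3.5, "sucrose": 3.5, "lactose": 4.0,
            "fat_saturated": 6.0, "fat_trans": 0.0, "fat_mufa": 2.5,
            "omega6_total": 0.8, "omega3_total": 0.3, "ala": 0.1,
            "epa": 10.0, "dha": 30.0,
            "fiber_soluble": 2.0, "fiber_insoluble": 1.2,
            "protein": 4.5, "sodium": 60.0,
            "calcium": 220.0, "magnesium": 42.0, "zinc": 1.6, "iron": 2.0,
            "vitamin_b6": 0.22, "vitamin_b12": 0.5, "folate": 42.0,
            "lead": 0.1, "arsenic": 0.4, "cadmium": 0.3, "mercury": 0.05,
            "glyphosate": 0.4,
        },
    },
    "culinary": {
        "serving_size": 30.0,
        "serving_unit": "g",
        "statement": "water, olive oil, tomato paste, garlic, onion powder, sea salt, inulin",
        "leaves": {
            "sugar_added": 1.0, "sucrose": 1.0, "glucose": 0.3, "fructose": 0.3,
            "fat_saturated": 1.0, "fat_trans": 0.0, "fat_mufa": 3.0,
            "omega6_total": 0.9, "omega3_total": 0.3, "ala": 0.2,
            "epa": 5.0, "dha": 5.0,
            "fiber_soluble": 1.8, "fiber_insoluble": 1.4,
            "protein": 3.2, "sodium": 120.0,
            "calcium": 15.0, "magnesium": 41.0, "zinc": 1.6, "iron": 2.1,
            "vitamin_c": 3.0, "vitamin_b6": 0.21, "vitamin_b12": 0.35,
            "folate": 41.0,
            "lead": 0.1, "arsenic": 0.5, "cadmium": 0.3, "mercury": 0.05,
            "glyphosate": 0.6,
        },
    },
}


def all_pass_template(category: str, product_id: str = "template-0001") -> dict:
    """A product document that passes every default criterion in scope for
    its category (tier I-A under the default matrix)."""
    t = _TEMPLATES[category]
    return {
        "id": product_id,
        "name": f"all-pass {category} template",
        "category": category,
        "serving_size": t["serving_size"],
        "serving_unit": t["serving_unit"],
        "servings_per_package": 1,
        "ingredient_statement": t["statement"],
        "claims": list(ATTRIBUTES),
        "whitelist_ids": [],
        "declared_profile": {
            "basis": "per-serving",
            "quantities": build_quantities(t["leaves"]),
        },
        "components": [],
    }


# ---------------------------------------------------------------------------
# random portfolio generator


class GeneratorSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 42
    n: int = Field(default=180, ge=0)
    category_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "dairy": 0.35, "juice": 0.25, "ice-cream": 0.20, "culinary": 0.20,
        }
    )
    additive_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "carrageenan": 0.08,
            "carboxymethylcellulose": 0.03,
            "partially hydrogenated soybean oil": 0.03,
            "hydrogenated vegetable oil": 0.03,
            "soybean oil": 0.10,
            "mono and diglycerides": 0.10,
            "non-GMO citric acid": 0.25,
            "sodium benzoate": 0.05,
        }
    )
    nesting_prob: float = Field(default=0.35, ge=0.0, le=1.0)
    attribute_prob: float = Field(default=0.65, ge=0.0, le=1.0)
    # sourcing declarations are near-universal in regulated dairy supply
    # chains, unlike the aspirational level-4/5 attributes
    antibiotic_free_prob: float = Field(default=0.95, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self):
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category mix proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.category_mix.values()):
            raise ValueError("category mix proportions must be non-negative")
        if any(c not in _TEMPLATES for c in self.category_mix):
            raise ValueError(f"unknown categories in mix: {sorted(self.category_mix)}")
        return self


# uniform per-serving ranges; keys absent here fall back to the template leaf
_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "dairy": {
        "sugar_added": (0.0, 6.0), "lactose": (7.0, 11.0),
        "omega6_total": (0.1, 3.0), "omega3_total": (0.05, 0.9),
        "fat_saturated": (2.0, 7.0), "fat_mufa": (0.5, 3.0),
        "sodium": (30.0, 150.0), "vitamin_d": (0.0, 600.0),
        "calcium": (120.0, 400.0), "vitamin_a": (100.0, 900.0),
        "fiber_soluble": (0.0, 3.0), "fiber_insoluble": (0.0, 2.0),
        "magnesium": (10.0, 70.0), "zinc": (0.3, 2.5), "iron": (0.1, 3.0),
        "vitamin_b6": (0.0, 0.5), "vitamin_b12": (0.0, 1.2), "folate": (5.0, 80.0),
        "protein": (5.0, 10.0),
        "lead": (0.0, 0.4), "arsenic": (0.0, 2.0), "cadmium": (0.0, 1.0),
        "mercury": (0.0, 0.5), "glyphosate": (0.0, 3.0),
    },
    "juice": {
        "sugar_added": (0.0, 6.0), "glucose": (2.0, 8.0), "fructose": (2.0, 9.0),
        "sucrose": (0.0, 3.0),
        "omega6_total": (0.0, 0.6), "omega3_total": (0.0, 0.6),
        "sodium": (5.0, 60.0), "vitamin_c": (2.0, 60.0),
        "fiber_soluble": (0.0, 3.5), "fiber_insoluble": (0.0, 1.5),
        "magnesium": (5.0, 60.0), "zinc": (0.1, 2.0), "iron": (0.1, 2.8),
        "vitamin_b6": (0.0, 0.4), "vitamin_b12": (0.0, 0.8), "folate": (5.0, 70.0),
        "protein": (0.2, 1.5),
        "lead": (0.0, 0.5), "arsenic": (0.0, 4.0), "cadmium": (0.0, 1.2),
        "mercury": (0.0, 0.3), "glyphosate": (0.0, 6.0),
    },
    "ice-cream": {
        "sugar_added": (0.5, 7.0), "lactose": (2.0, 6.0),
        "omega6_total": (0.1, 2.5), "omega3_total": (0.0, 0.6),
        "fat_saturated": (3.0, 9.0), "fat_mufa": (1.0, 4.0),
        "sodium": (30.0, 130.0), "calcium": (80.0, 300.0),
        "fiber_soluble": (0.0, 2.5), "fiber_insoluble": (0.0, 1.8),
        "magnesium": (10.0, 60.0), "zinc": (0.3, 2.2), "iron": (0.1, 2.6),
        "vitamin_b6": (0.0, 0.4), "vitamin_b12": (0.0, 0.9), "folate": (5.0, 60.0),
        "protein": (2.0, 6.0),
        "lead": (0.0, 0.4), "arsenic": (0.0, 1.5), "cadmium": (0.0, 1.0),
        "mercury": (0.0, 0.3), "glyphosate": (0.0, 2.0),
    },
    "culinary": {
        "sugar_added": (0.0, 5.0), "sucrose": (0.0, 2.0), "glucose": (0.0, 1.0),
        "fructose": (0.0, 1.5),
        "omega6_total": (0.1, 4.5), "omega3_total": (0.0, 0.8),
        "fat_saturated": (0.5, 3.0), "fat_mufa": (0.5, 5.0),
        "sodium": (30.0, 180.0),
        "fiber_soluble": (0.0, 2.5), "fiber_insoluble": (0.0, 2.5),
        "magnesium": (5.0, 60.0), "zinc": (0.1, 2.2), "iron": (0.1, 2.8),
        "vitamin_b6": (0.0, 0.4), "vitamin_b12": (0.0, 0.6), "folate": (5.0, 60.0),
        "protein": (0.5, 5.0),
        "lead": (0.0, 0.5), "arsenic": (0.0, 3.0), "cadmium": (0.0, 1.5),
        "mercury": (0.0, 0.4), "glyphosate": (0.0, 8.0),
    },
}

_TRANS_FAT_PROB = 0.08  # fraction of products carrying residual trans fat


def _draw_leaves(rng: random.Random, category: str) -> dict[str, float]:
    leaves = dict(_TEMPLATES[category]["leaves"])
    for key, (lo, hi) in _RANGES[category].items():
        leaves[key] = round(rng.uniform(lo, hi), 4)
    leaves["fat_trans"] = (
        round(rng.uniform(0.1, 0.6), 4) if rng.random() < _TRANS_FAT_PROB else 0.0
    )
    return leaves


def _as_components(
    rng: random.Random, quantities: dict[str, float], serving_size: float
) -> list[dict]:
    """Split a per-serving panel into a concentrate + water component pair.

    The concentrate (30% by mass) carries the full panel per-100g; the water
    component has no profile and resolves from the reference registry,
    exercising the assumption log."""
    frac = 0.3
    per100 = {
        k: round(v / serving_size * 100.0 / frac, 4) for k, v in quantities.items()
    }
    concentrate = {
        "id": "c-base",
        "name": "base concentrate",
        "mass_fraction": frac,
        "provenance": "assayed",
        "profile": {"basis": "per-100g", "quantities": build_quantities(per100)},
        "subcomponents": [],
    }
    if rng.random() < 0.5:
        # one extra nesting level: identical per-gram split keeps the rollup exact
        sub_profile = concentrate.pop("profile")
        concentrate["subcomponents"] = [
            {
                "id": "c-base-a",
                "name": "base concentrate part A",
                "mass_fraction": 0.6,
                "provenance": "assayed",
                "profile": sub_profile,
                "subcomponents": [],
            },
            {
                "id": "c-base-b",
                "name": "base concentrate part B",
                "mass_fraction": 0.4,
                "provenance": "assayed",
                "profile": sub_profile,
                "subcomponents": [],
            },
        ]
    water = {
        "id": "c-water",
        "name": "water",
        "mass_fraction": round(1.0 - frac, 4),
        "provenance": "declared",
        "subcomponents": [],
    }
    return [concentrate, water]


def generate(spec: GeneratorSpec) -> list[dict]:
    """Generate ``spec.n`` valid product documents, deterministically."""
    rng = random.Random(spec.seed)
    categories = sorted(spec.category_mix)
    weights = [spec.category_mix[c] for c in categories]
    docs: list[dict] = []
    for i in range(spec.n):
        category = rng.choices(categories, weights=weights, k=1)[0]
        template = _TEMPLATES[category]
        leaves = _draw_leaves(rng, category)
        quantities = build_quantities(leaves)
        statement = template["statement"]
        for additive in sorted(spec.additive_probs):
            if rng.random() < spec.additive_probs[additive]:
                statement = f"{statement}, {additive}"
        claims = [
            a
            for a in ATTRIBUTES
            if rng.random()
            < (
                spec.antibiotic_free_prob
                if a == "antibiotic-free"
                else spec.attribute_prob
            )
        ]
        doc = {
            "id": f"syn-{spec.seed}-{i:04d}",
            "name": f"synthetic {category} product {i:04d}",
            "category": category,
            "serving_size": template["serving_size"],
            "serving_unit": template["serving_unit"],
            "servings_per_package": rng.choice([1, 1, 1, 4, 6]),
            "ingredient_statement": statement,
            "claims": claims,
            "whitelist_ids": [],
        }
        if rng.random() < spec.nesting_prob:
            doc["declared_profile"] = None
            doc["components"] = _as_components(
                rng, quantities, template["serving_size"]
            )
        else:
            doc["declared_profile"] = {
                "basis": "per-serving",
                "quantities": quantities,
            }
            doc["components"] = []
        docs.append(doc)
    return docs


# ---------------------------------------------------------------------------
# per-criterion coverage fixtures


@dataclass(frozen=True)
class SkipRecord:
    criterion_id: str
    reason: str


@dataclass
class CoverageSet:
    """Isolator fixtures: each document fails exactly the criterion named in
    its ``target_criterion`` key (plus one all-pass document)."""

    documents: list[dict] = field(default_factory=list)
    skips: list[SkipRecord] = field(default_factory=list)


_FORBID_TRIGGERS: dict[tuple[str, str], str] = {
    ("group", "partially-hydrogenated-oils"): "partially hydrogenated soybean oil",
    ("group", "emulsifiers"): "carrageenan",
    ("group", "refined-seed-oils"): "soybean oil",
    ("canonical", "hydrogenated-oil"): "hydrogenated vegetable oil",
}


def _isolator_for(criterion: Criterion, matrix: MatrixConfiguration,
                  index: int) -> Optional[dict]:
    category = criterion.scope[0] if criterion.scope else "dairy"
    doc = all_pass_template(category, product_id=f"iso-{index:03d}-{criterion.id}")
    doc["name"] = f"isolator for {criterion.id}"
    leaves = dict(_TEMPLATES[category]["leaves"])
    pred = criterion.predicate

    def set_omega(omega6: float, omega3: float) -> None:
        leaves["omega6_total"] = omega6
        leaves["omega3_total"] = omega3

    if isinstance(pred, ThresholdPredicate):
        canonical = vocabulary.canonical_unit(pred.nutrient)
        limit = vocabulary.convert(pred.value, pred.unit, canonical, pred.nutrient)
        if pred.direction == "max":
            target = round(limit * 1.2, 4) if limit > 0 else 0.5
            if pred.basis == "per-100g":
                target = round(target / 100.0 * doc["serving_size"], 4)
            leaves[pred.nutrient] = target
            if pred.nutrient == "omega6_total":
                # keep the ratio criterion safely under its cap
                leaves["omega3_total"] = round(target / 3.5, 4)
        else:
            target = round(limit * 0.5, 4)
            if pred.nutrient == "fiber_total":
                # derived total: adjust the leaves it is computed from
                leaves["fiber_soluble"] = round(target * 0.6, 4)
                leaves["fiber_insoluble"] = round(target * 0.4, 4)
            else:
                leaves[pred.nutrient] = target
            if pred.nutrient == "omega3_total":
                leaves["omega6_total"] = round(max(target * 3.0, 0.01), 4)
    elif isinstance(pred, RatioPredicate):
        set_omega(round(pred.max_value * 1.1, 4), 1.0)
    elif isinstance(pred, ForbidIngredientPredicate):
        trigger = _FORBID_TRIGGERS.get((pred.target_kind, pred.target))
        if trigger is None:
            return None
        doc["ingredient_statement"] = f"{doc['ingredient_statement']}, {trigger}"
    elif isinstance(pred, RequireAttributePredicate):
        doc["claims"] = [a for a in doc["claims"] if a != pred.attribute]
    elif isinstance(pred, ListMembershipPredicate):
        members = matrix.lists.get(pred.list_id, [])
        if pred.mode == "exclude":
            if not members:
                return None
            doc["id"] = members[0]
        else:
            return None  # cannot fail an include rule without altering the list
    doc["declared_profile"] = {
        "basis": "per-serving",
        "quantities": build_quantities(leaves),
    }
    doc["target_criterion"] = criterion.id
    return doc


def coverage_fixtures(
    matrix: MatrixConfiguration, evaluator: Optional[Evaluator] = None
) -> CoverageSet:
    """One product per criterion failing exactly that criterion (verified
    against the evaluator), plus one all-pass product. Criteria that cannot
    be isolated yield a documented skip record."""
    if evaluator is None:
        evaluator = Evaluator(matrix=matrix)
    out = CoverageSet()
    from .product_model import Product  # local import to avoid cycle at module load

    for index, criterion in enumerate(matrix.criteria):
        doc = _isolator_for(criterion, matrix, index)
        if doc is None:
            out.skips.append(
                SkipRecord(criterion.id, "no isolating mutation constructible")
            )
            continue
        evaluation = evaluator.evaluate_product(Product.model_validate(doc))
        failed = {o.criterion_id for o in evaluation.outcomes if o.status == "fail"}
        if failed != {criterion.id}:
            out.skips.append(
                SkipRecord(
                    criterion.id,
                    f"not isolable: mutation fails {sorted(failed)} instead of "
                    f"exactly [{criterion.id}]",
                )
            )
            continue
        out.documents.append(doc)
    all_pass = all_pass_template("dairy", product_id="iso-all-pass")
    all_pass["target_criterion"] = None
    out.documents.append(all_pass)
    return out


# ---------------------------------------------------------------------------
# named re-engineering scenarios (synthetic stand-ins)


def named_scenarios() -> dict[str, dict]:
    """Before/after re-engineering fixtures.

    The v1 variants fail level-1 sugar (and, for the ice cream, emulsifier)
    criteria; the v2 variants clear level 1. All numeric contents are
    synthetic stand-ins constructed for these behaviors, not measurements of
    any real product.
    """
    milk_v1 = all_pass_template("dairy", product_id="scn-choc-milk-v1")
    milk_v1["name"] = "chocolate milk v1 (synthetic scenario)"
    milk_v1["ingredient_statement"] = (
        "whole milk, sugar, cocoa powder, natural flavors"
    )
    v1_leaves = dict(_TEMPLATES["dairy"]["leaves"])
    v1_leaves.update({"sugar_added": 9.5, "sucrose": 9.5})
    milk_v1["declared_profile"] = {
        "basis": "per-serving",
        "quantities": build_quantities(v1_leaves),
    }

    milk_v2 = all_pass_template("dairy", product_id="scn-choc-milk-v2")
    milk_v2["name"] = "chocolate milk v2 (synthetic scenario)"
    milk_v2["ingredient_statement"] = (
        "whole milk, cocoa powder, allulose, stevia, inulin, natural flavors"
    )
    v2_leaves = dict(_TEMPLATES["dairy"]["leaves"])
    v2_leaves.update({"sugar_added": 3.8, "sucrose": 3.8})
    milk_v2["declared_profile"] = {
        "basis": "per-serving",
        "quantities": build_quantities(v2_leaves),
    }
    # mid-ladder on purpose: the reformulation clears harm reduction first
    milk_v2["claims"] = [
        "antibiotic-free", "allergen-disclosure", "independently-tested",
    ]

    ice_v1 = all_pass_template("ice-cream", product_id="scn-choc-ice-v1")
    ice_v1["name"] = "chocolate ice cream v1 (synthetic scenario)"
    ice_v1["ingredient_statement"] = (
        "cream, whole milk, sugar, cocoa powder, carrageenan, mono and diglycerides"
    )
    iv1 = dict(_TEMPLATES["ice-cream"]["leaves"])
    iv1.update({"sugar_added": 12.0, "sucrose": 12.0})
    ice_v1["declared_profile"] = {
        "basis": "per-serving",
        "quantities": build_quantities(iv1),
    }

    ice_v2 = all_pass_template("ice-cream", product_id="scn-choc-ice-v2")
    ice_v2["name"] = "chocolate ice cream v2 (synthetic scenario)"
    ice_v2["ingredient_statement"] = (
        "cream, whole milk, erythritol, monk fruit extract, cocoa powder, "
        "guar gum, inulin"
    )
    iv2 = dict(_TEMPLATES["ice-cream"]["leaves"])
    iv2.update({"sugar_added": 3.5, "sucrose": 3.5})
    ice_v2["declared_profile"] = {
        "basis": "per-serving",
        "quantities": build_quantities(iv2),
    }
    ice_v2["claims"] = [
        "antibiotic-free", "allergen-disclosure", "independently-tested",
        "animal-welfare-certified",
    ]

    return {
        "chocolate_milk_v1": milk_v1,
        "chocolate_milk_v2": milk_v2,
        "chocolate_ice_cream_v1": ice_v1,
        "chocolate_ice_cream_v2": ice_v2,
    }
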