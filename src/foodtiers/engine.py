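"""Pipeline facade: resolve -> parse -> evaluate -> tier -> recommend."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .criteria import CriterionOutcome, ProductContext, evaluate_all
from .lexicon import AllergenRegistry, Lexicon, ParsedIngredient
from .matrix_config import MatrixConfiguration, load_default_matrix
from .product_model import (
    AssumptionRecord,
    Product,
    ReferenceRegistry,
    load_product,
    resolve_profile,
)
from .tiers import TierResult, assign_tier, load_strategy_templates, recommend


@dataclass
class ProductEvaluation:
    """Everything the engine derived for one product."""

    product: Product
    context: ProductContext
    outcomes: list[CriterionOutcome]
    tier: TierResult
    allergens: set[str]
    assumptions: list[AssumptionRecord]
    resolution_warnings: list[str] = field(default_factory=list)

    @property
    def unknown_ingredients(self) -> list[str]:
        out = []
        for entry in self.context.parsed_ingredients:
            for item in entry.flatten():
                if item.canonical_id is None and item.raw_span.strip():
                    out.append(item.raw_span)
        return out


class Evaluator:
    """Binds a matrix configuration, lexicon, reference registry, allergen
    registry and strategy templates into a reusable evaluation pipeline."""

    def __init__(
        self,
        matrix: Optional[MatrixConfiguration] = None,
        lexicon: Optional[Lexicon] = None,
        references: Optional[ReferenceRegistry] = None,
        allergen_mode: str = "big9",
        templates: Optional[dict[str, list[str]]] = None,
    ):
        self.matrix = matrix or load_default_matrix()
        self.lexicon = lexicon or Lexicon.load_default()
        self.references = references or ReferenceRegistry.default()
        self.allergens = AllergenRegistry.load_default(allergen_mode)
        self.templates = templates or load_strategy_templates()
        self.engine_version = __version__
        self.config_version = self.matrix.version

    def prepare(self, product: Product) -> tuple[ProductContext, list, list[str]]:
        resolution = resolve_profile(product, self.references)
        parsed = self.lexicon.parse_statement(product.ingredient_statement)
        ctx = ProductContext(
            product=product,
            profile=resolution.profile,
            parsed_ingredients=parsed,
            lexicon=self.lexicon,
            lists=self.matrix.lists,
        )
        return ctx, resolution.assumptions, resolution.warnings

    def evaluate_product(self, product: Product) -> ProductEvaluation:
        ctx, assumptions, warnings = self.prepare(product)
        outcomes = evaluate_all(ctx, self.matrix.criteria)
        tier = assign_tier(outcomes, self.matrix.criteria, assumptions=assumptions)
        tier.recommendations = recommend(tier, self.matrix.criteria, self.templates)
        allergens = self.lexicon.detect_allergens(ctx.parsed_ingredients, self.allergens)
        return ProductEvaluation(
            product=product,
            context=ctx,
            outcomes=outcomes,
            tier=tier,
            allergens=allergens,
            assumptions=assumptions,
            resolution_warnings=warnings,
        )

    def evaluate_document(self, document: str) -> ProductEvaluation:
        return self.evaluate_product(load_product(document))
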