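# foodtiers

A layered, non-averaging rule engine that classifies consumer packaged-food
products into progressive metabolic-health tiers, for food scientists,
reformulation teams, and nutrition informatics developers who need every
verdict to be fully traceable.

## The problem

Front-of-pack scoring schemes typically (a) evaluate per 100 g rather than
per realistic serving, (b) exclude whole product categories, and (c) sum
positive and negative points — so fortified vitamins can "cancel out" excess
sugar ("poison A + antidote B = neutral"). This package implements the
opposite design: declarative criteria organized into **five progressive
levels** that gate six ordered tier labels,

```
III  <  II-C  <  II-B  <  II-A  <  I-B  <  I-A
```

Tier III is the unconditional floor (conventional foods); a product's label
is the highest tier whose gating levels *all* pass. There is no numeric
score and no averaging anywhere: a single failed harm-reduction (level-1)
criterion pins a product at Tier III no matter how many higher-level
positives it collects. The default configuration ships **38 criteria**
(12/5/9/8/4 across the five levels), organized around three physiological
pillars — *feed the gut* (fiber, emulsifier restrictions), *protect the
liver* (sugar, trans fat, contaminant caps), and *support the brain*
(omega-3, omega-6:omega-3 ratio, micronutrients) — plus transparency and
sustainability attributes. Anchor thresholds include:

| rule | threshold | level |
|---|---|---|
| added sugar | ≤ 1 teaspoon (4.2 g) per serving | 1 |
| omega-6 fatty acids | ≤ 5 g per serving | 1 |
| omega-6 : omega-3 ratio | ≤ 4 : 1 | 2 |
| vitamin D (dairy) | ≥ 400 IU per serving | 3 |

Around the tier ladder the package provides:

- **Product model** — hierarchical product/component JSON with mass
  fractions, per-100g component panels rolled up to a per-serving profile,
  and a reference-nutrient registry whose every substitution is logged as an
  explicit assumption record.
- **Ingredient lexicon** — ingredient-statement parsing with canonical
  resolution of synonyms, chemical names, and E-numbers ("acidum citricum",
  "2-hydroxypropane-1,2,3-tricarboxylic acid" and "E330" are all citric
  acid), bounded misspelling tolerance, whole-term matching (a peanut is
  never a tree nut because it contains "nut"), modifier extraction
  ("organic", "non-GMO"), concern neutralization via modifiers or
  whitelists, and Big 8 / Big 9 allergen detection.
- **Reports** — one JSON + Markdown report per product (criterion by
  criterion, tier, recommendations, assumptions) and a portfolio overview
  CSV, all deterministic.
- **Synthetic portfolio** — a seeded generator, per-criterion isolator
  fixtures, and named before/after re-engineering scenarios, so the whole
  engine is testable without proprietary data.

## Worked example

```python
from foodtiers import Evaluator
from foodtiers.product_model import Product
from foodtiers.synthetic import named_scenarios

evaluator = Evaluator()                      # default 38-criterion matrix
doc = named_scenarios()["chocolate_milk_v1"]  # synthetic sugary chocolate milk
result = evaluator.evaluate_product(Product.model_validate(doc))

print(f"tier: {result.tier.label}")
for outcome in result.tier.blocking:
    print(f"blocking: {outcome.criterion_id}: {outcome.explanation}")
for rec in result.tier.recommendations:
    print(f"recommendation: reduce to {rec.target_value} {rec.unit}; "
          f"{len(rec.strategy_texts)} strategies, e.g. {rec.strategy_texts[5]!r}")
print(f"allergens: {sorted(result.allergens)}")
```

prints

```
tier: III
blocking: added-sugar-cap: sugar_added = 9.5 g per serving; rule requires at most 4.2 g; fail
recommendation: reduce to 4.2 g; 9 strategies, e.g. 'Replace sugar with non-caloric sweeteners'
allergens: ['milk']
```

The product carries 9.5 g added sugar per 240 mL serving — more than the
one-teaspoon cap — so it stays at Tier III regardless of its other merits,
and the report proposes concrete sugar-mitigation strategies with the
numeric target (4.2 g) that would clear the gate.

The same pipeline is available from the shell:

```bash
foodtiers synth --out products/ --seed 42 --n 180   # synthetic portfolio
foodtiers validate products/                        # consistency checks
foodtiers evaluate products/ --out reports/         # reports + overview.csv
foodtiers probe --criterion omega6-cap \
  --template products/syn-42-0000.json \
  --nutrient omega6_total --low 0 --high 20         # prints 5.0000
```

## Layout

- `src/foodtiers/` — `product_model`, `lexicon`, `criteria`, `tiers`,
  `matrix_config`, `reporting`, `synthetic`, `engine`, `cli`
- `src/foodtiers/data/` — default matrix, nutrient vocabulary, product JSON
  schema, seed lexicon + additive registry, allergen registries, reference
  nutrient registry, strategy templates, intake references
- `docs/methods.md` — model assumptions, parameter rationale, numerical
  conventions, and known limitations
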