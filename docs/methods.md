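# Methods

## The evaluation model

A product is evaluated as a pure function of (resolved per-serving nutrient
profile, parsed ingredient statement, product metadata) against a list of
declarative criteria. Each criterion carries a level 1–5, a pillar tag
(feed-gut / protect-liver / support-brain / transparency / sustainability),
an optional category scope, and exactly one predicate:

- `threshold(nutrient, max|min, value, unit, basis)` — compared on a
  per-serving or per-100g basis;
- `ratio(numerator, denominator, max)`;
- `forbid-ingredient(group-or-canonical, concern-category, min-confidence)`;
- `require-attribute(attribute)` — matched against the product's declared
  claims;
- `list-membership(list-id, include|exclude)` — named product-id lists from
  the configuration.

The tier label is the highest of `III < II-C < II-B < II-A < I-B < I-A`
whose gating levels all pass. Tier III carries no criteria of its own: it is
the floor. This reading reconciles six ordered labels with five criterion
levels by placing the harm-reduction criteria as the first gate out of III.
Averaging and compensation are deliberately absent: the only aggregation is
logical AND within a level and consecutive-AND across levels.

Assumptions built into the evaluator:

- **Serving basis.** Criteria are evaluated per realistic serving, not per
  100 g, because 100-g reference amounts misrepresent foods never consumed
  in such portions. Per-100g predicates remain available (the basis field)
  and are derived from the per-serving value and the serving size.
- **Boundary conventions.** Max-caps phrased "more than X" fail strictly
  above X (X itself passes); min-floors phrased "at least X" pass at X.
  Criteria without an authoritative phrasing default to inclusive
  boundaries. The `probe_threshold` bisection instrument recovers these
  boundaries empirically to a configurable tolerance (default 1e-6).
- **Missing data fail conservatively.** A criterion whose nutrient was
  neither assayed nor declared fails with an explicit "value unavailable"
  explanation. Gaps must be visible, never silently passed; removing a
  measurement can therefore never flip a verdict from fail to pass.
- **Not-applicable counts as passed** for gating, so scoped criteria (e.g.
  dairy-only vitamin D fortification) cannot trap out-of-scope categories.
  Whether a product could "skip" a level with no applicable criteria at all
  is moot under the default matrix (every level has unscoped criteria).
- **Traceability.** Every outcome carries an explanation citing the measured
  value, the threshold, and the verdict; reports stamp engine and
  configuration versions. There is deliberately no learned or black-box
  component anywhere in the pipeline.

## Profile resolution and the assumption log

Component trees are rolled up bottom-up: a component contributes its
per-100g panel scaled by its mass fraction; sibling fractions must sum to
1 ± 0.01; recursion is capped at depth 8 (cycles and runaway nesting are
errors). The per-gram aggregate is scaled by the serving size. Per-100mL
panels are treated like per-100g using the serving volume — no density
model is applied, an accepted approximation for the water-dominated
beverages this targets.

A component with neither a panel nor subcomponents is filled from the
reference registry by folded name ("Grape Juice" → `grape-juice`), and each
substitution appends an assumption record (component, registry entry,
substituted nutrient ids) that surfaces in the product report. The number of
assumption records always equals the number of reference-substituted
components.

When a product has both a declared panel and a component rollup, the
declared panel wins per nutrient — declared panels are the regulated
artifact — and any shared nutrient disagreeing by more than 20% (relative)
attaches a consistency warning. Trust order for component data is
assayed > declared > reference-substituted.

Species sums are validated with a 5% relative tolerance
(fructose+glucose+galactose+sucrose+lactose ≤ total sugar · 1.05, and
likewise for fat classes and fiber fractions): loose enough for label
rounding, tight enough to catch construction errors. A multi-serve package
whose implied portion is under 30 g/mL draws a plausibility warning (a
"pint = four servings" declaration is rarely how the product is consumed).

## Units

Profiles store canonical units per nutrient (g for macronutrient species,
mg for sodium, minerals, EPA/DHA, µg for heavy metals, glyphosate, folate,
B12, IU for vitamins A and D). Fixed conversion constants: 1 teaspoon
granulated sugar = 4.2 g (USDA household measure); 40 IU vitamin D = 1 µg;
salt = sodium × 2.5. Conversions are exact arithmetic (round-trip identity
to 1e-12 relative).

## Ingredient normalization

Terms are folded (case, punctuation, whitespace; E-numbers collapse to
`E<digits>`), then matched whole-term against whole-alias — substring
containment never matches. Misspelling tolerance uses optimal-string-
alignment Damerau–Levenshtein distance, bounded at 1 for folded terms of
length ≤ 8 and 2 for longer terms; a fuzzy hit is accepted only when the
nearest alias is unique at the minimal distance, never when the alias is a
strict substring of the term, and never for E-number codes (adjacent codes
differ by a single digit). Unresolved terms return an unknown marker, are
treated as benign for concern criteria, and are listed in the report.

The modifier lexicon is a closed, versioned list (organic, non-GMO and its
variants, naturally derived, cold-pressed, extra-virgin, unrefined,
hydrogenated, partially hydrogenated). A *potentially offending* concern is
downgraded to benign by a neutralizing modifier on the entry or by the
product's id on the concern's whitelist (a named list
`whitelist:<concern-category>` in the configuration); *offending* is never
neutralizable. Concern confidence uses an invented three-point scale
(established > probable > suspected); forbid criteria default to
`min_confidence = probable`, so suspected-only concerns do not fail
products.

Shellfish (shrimp/crab/lobster) and finfish are separate allergen
categories per FDA convention; the Big 9 registry is exactly Big 8 plus
sesame. The shipped lexicon is a seed set (~84 entries) meant to be
extended; the additive-concern registry likewise seeds the schema with the
prominent entries (carboxymethylcellulose, carrageenan, BHA, parabens,
bisphenol-A, partially hydrogenated oils, accepted and pending sweeteners)
rather than a complete additive review.

## The default matrix

38 criteria across levels 12/5/9/8/4. Four thresholds are normative anchors
(added sugar 4.2 g/serving; omega-6 5 g/serving; omega-6:omega-3 ≤ 4;
vitamin D ≥ 400 IU/serving for dairy) and the loader refuses a bundle with
any of them altered. The remaining 34 values are reconstructions guided by
the level themes — level 1 covers healthy fats, sugars, additives, salt
(the FDA low-sodium figure, 140 mg/serving), heavy metals, pesticides, and
antibiotics; level 2 adds vegetable-oil rules; level 3 minimum targets for
vitamins, minerals, fatty acids and fiber; level 4 additional vitamin
targets, allergen informatics, independent testing, cold-pressed oils and
protein; level 5 sustainability and traceable sourcing — and are marked
`"normative": false` in the data file. The vitamin D and mineral minimums
reflect a configuration tuned to fortification priorities in the MENA
region; other population profiles are a configuration swap, not code.
Intake references (EPA+DHA 250–500 mg/day for adults, etc.) are stored
alongside for contextual lookups.

## Synthetic data: what it emulates and what it does not

The generator emulates a product portfolio only structurally: per-category
serving sizes, nutrient panels drawn **uniformly** within per-category
ranges (no claim of real market distributions), optional two-level component
nesting with a reference-resolved water component (exercising the
assumption log), additive inclusions by probability, and attribute claims.
Ranges were fixed once so that roughly half of a default portfolio lands at
Tier III, which exercises the recommendation path. Determinism is guaranteed by seeding `random.Random` and rounding all floats
to four decimals before serialization.

Passing tests on synthetic data therefore demonstrate the *engine's*
correctness — boundary semantics, no-compensation, rollup linearity,
determinism — not calibration against real products: real ingredient
statements are messier than the generator's, real nutrient panels are
correlated across nutrients, and the reconstructed non-anchor thresholds
carry no external validation.

The named scenarios (chocolate milk v1/v2, chocolate ice cream v1/v2) are
synthetic stand-ins constructed so that v1 fails the level-1 sugar (and,
for the ice cream, emulsifier) gates and v2 clears them; their numeric
contents are invented.

Problem sizes used by the shipped suites are package choices: the
no-compensation fuzz runs 10,000 random outcome vectors, generator legality
is checked over 2,000 products (plus the 180-product end-to-end determinism
run), and bisection probes use tolerance 1e-6 over [0, 20] g, [0, 1000] IU
and [0, 20] g respectively (~30 criterion evaluations each).

## Known limitations

- No density or moisture modelling (per-100mL ≈ per-100g), no label-image
  OCR, no regulatory rounding rules for printed panels.
- The lexicon is monolingual (English) and seed-scale; chemical-structure
  resolution and ML/embedding matching are out of scope by design (they
  would break traceability).
- Recommendations target only the next tier and only echo numeric
  boundaries plus strategy templates; there is no reformulation search or
  cost model.
- `sugar_added` is tracked as its own quantity and is not structurally tied
  to the sugar-species sum beyond `sucrose ≥ added` in generated fixtures.
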