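{
  "_comment": "Strategy template registry for recommendations, keyed by topic. The sugar set mirrors the engineering-side mitigation strategies for sugar in juice; remaining sets are package defaults.",
  "templates": {
    "sugar": [
      "No added sugars: do not add sugar to products already containing high amounts of sugar",
      "Microbial technology: use organisms to consume the sugar",
      "Nanofiltration: filter out sugar",
      "Fiber: mitigate the impact of fructose with whole fiber",
      "Modify juice-to-water ratio: less juice or juice concentrate, more water",
      "Replace sugar with non-caloric sweeteners",
      "Investigate new sugars and sweetener solutions (allulose, tagatose, protein-based sweeteners, sweetener combinations)",
      "Modifying ingredients: modulators, enhancers, texturizing agents",
      "Portion control: use smaller containers"
    ],
    "omega6": [
      "Replace refined seed oils with low-omega-6 oils such as olive oil",
      "Reformulate fat blend to reduce omega-6 load per serving",
      "Reduce total added oil per serving"
    ],
    "omega3": [
      "Fortify with EPA/DHA from algal or marine oils",
      "Add ALA-rich plant sources (e.g., flax, chia) where compatible with the format"
    ],
    "ratio": [
      "Lower omega-6 by replacing seed oils with olive or high-oleic oils",
      "Raise omega-3 via algal or marine oil fortification to bring the omega-6:omega-3 ratio within target"
    ],
    "trans-fat": [
      "Eliminate partially hydrogenated oils from the formulation",
      "Replace hydrogenated fat systems with unrefined oils or dairy fat"
    ],
    "fiber": [
      "Add soluble fiber (inulin, pectin, chicory root fiber)",
      "Add insoluble fiber or whole-food inclusions"
    ],
    "sodium": [
      "Reduce added salt stepwise with flavor rebalancing",
      "Use potassium-based or mineral salt substitutes where compatible"
    ],
    "contaminants": [
      "Audit and switch suppliers for the contributing raw material",
      "Introduce lot-level contaminant testing with acceptance limits"
    ],
    "micronutrient": [
      "Fortify to the target level with a bioavailable form of the nutrient",
      "Source naturally nutrient-dense ingredients that carry the target nutrient"
    ],
    "concern:emulsifier-gut-inflammation": [
      "Replace the emulsifier/stabilizer with soluble fibers that maintain texture",
      "Re-engineer the process (homogenization, protein functionality) to remove the need for emulsifiers"
    ],
    "concern:artificial-trans-fat": [
      "Remove partially hydrogenated oils; substitute unrefined, extra-virgin oils",
      "Replace hydrogenated fat systems with naturally solid fats"
    ],
    "concern:omega6-excess": [
      "Replace refined seed oils with olive, high-oleic, or algal oils"
    ],
    "additives": [
      "Remove or substitute the flagged additive",
      "Seek a whitelisted or certified variant of the ingredient"
    ],
    "attribute": [
      "Attain and document the required attribute, then declare it in product data"
    ],
    "list": [
      "Resolve the product's presence on the blocking exclusion list"
    ],
    "default": [
      "Reformulate to satisfy the criterion threshold"
    ]
  }
}
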