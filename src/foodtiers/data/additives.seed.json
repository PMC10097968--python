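{
  "_comment": "Additive-concern seed registry, keyed by canonical ingredient id. A small, extensible starting set; the schema (category / status / confidence / neutralizing modifiers) is the contract, not the coverage. Statuses: offending, potentially-offending, benign. Confidences: established, probable, suspected. neutralizing_modifiers may be non-empty only for potentially-offending entries; offending entries are never neutralizable.",
  "entries": {
    "citric-acid": [
      {"concern_category": "GMO-status", "status": "potentially-offending", "confidence": "suspected", "neutralizing_modifiers": ["non-gmo", "naturally-derived"], "citation_note": "commonly produced by fermentation on GM maize feedstock"}
    ],
    "carrageenan": [
      {"concern_category": "emulsifier-gut-inflammation", "status": "potentially-offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "degraded forms linked to intestinal inflammation; replaceable by soluble fibers"}
    ],
    "carboxymethylcellulose": [
      {"concern_category": "emulsifier-gut-inflammation", "status": "offending", "confidence": "established", "neutralizing_modifiers": [], "citation_note": "commercial emulsifier associated with intestinal inflammation"}
    ],
    "polysorbate-80": [
      {"concern_category": "emulsifier-gut-inflammation", "status": "offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "synthetic emulsifier with microbiome effects"}
    ],
    "mono-and-diglycerides": [
      {"concern_category": "emulsifier-gut-inflammation", "status": "potentially-offending", "confidence": "suspected", "neutralizing_modifiers": [], "citation_note": "ubiquitous emulsifier class; evidence weaker than for CMC/polysorbates"}
    ],
    "bha": [
      {"concern_category": "obesogen", "status": "offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "antioxidant preservative with obesogenic potential"}
    ],
    "bht": [
      {"concern_category": "obesogen", "status": "potentially-offending", "confidence": "suspected", "neutralizing_modifiers": [], "citation_note": "related antioxidant preservative"}
    ],
    "parabens": [
      {"concern_category": "obesogen", "status": "offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "preservatives with endocrine-disrupting activity"}
    ],
    "bisphenol-a": [
      {"concern_category": "obesogen", "status": "offending", "confidence": "established", "neutralizing_modifiers": [], "citation_note": "packaging-contact chemical; PPAR-gamma activator"}
    ],
    "chlorpyrifos": [
      {"concern_category": "pesticide-residue", "status": "offending", "confidence": "established", "neutralizing_modifiers": [], "citation_note": "organophosphate insecticide and potential obesogen"}
    ],
    "sodium-benzoate": [
      {"concern_category": "obesogen", "status": "potentially-offending", "confidence": "suspected", "neutralizing_modifiers": [], "citation_note": "preservative"}
    ],
    "partially-hydrogenated-oil": [
      {"concern_category": "artificial-trans-fat", "status": "offending", "confidence": "established", "neutralizing_modifiers": [], "citation_note": "primary dietary source of artificial trans fat; targeted for total elimination"}
    ],
    "hydrogenated-oil": [
      {"concern_category": "artificial-trans-fat", "status": "potentially-offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "fully hydrogenated oils are nominally trans-free but industrially refined"}
    ],
    "soybean-oil": [
      {"concern_category": "omega6-excess", "status": "potentially-offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "refined seed oil rich in omega-6"}
    ],
    "corn-oil": [
      {"concern_category": "omega6-excess", "status": "potentially-offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "refined seed oil rich in omega-6"}
    ],
    "sunflower-oil": [
      {"concern_category": "omega6-excess", "status": "potentially-offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "refined seed oil rich in omega-6"}
    ],
    "cottonseed-oil": [
      {"concern_category": "omega6-excess", "status": "potentially-offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "refined seed oil rich in omega-6"}
    ],
    "canola-oil": [
      {"concern_category": "omega6-excess", "status": "potentially-offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "refined seed oil; lower omega-6 than soybean or corn oil"}
    ],
    "palm-oil": [
      {"concern_category": "sustainability-sourcing", "status": "potentially-offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "sourcing concern; neutralizable via certified-supplier whitelist"}
    ],
    "high-fructose-corn-syrup": [
      {"concern_category": "added-sugar", "status": "offending", "confidence": "established", "neutralizing_modifiers": [], "citation_note": "free-fructose sweetener"}
    ],
    "aspartame": [
      {"concern_category": "sweetener-microbiome", "status": "potentially-offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "non-nutritive sweetener with insulin/microbiome signals"}
    ],
    "sucralose": [
      {"concern_category": "sweetener-microbiome", "status": "potentially-offending", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "non-nutritive sweetener with microbiome signals"}
    ],
    "allulose": [
      {"concern_category": "sweetener-microbiome", "status": "benign", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "rare sugar; favorable metabolic profile; GSO/EFSA approval pending"}
    ],
    "tagatose": [
      {"concern_category": "sweetener-microbiome", "status": "benign", "confidence": "probable", "neutralizing_modifiers": [], "citation_note": "rare sugar; favorable metabolic profile; regulatory review ongoing"}
    ],
    "erythritol": [
      {"concern_category": "sweetener-microbiome", "status": "benign", "confidence": "established", "neutralizing_modifiers": [], "citation_note": "accepted polyol sweetener"}
    ],
    "stevia": [
      {"concern_category": "sweetener-microbiome", "status": "benign", "confidence": "established", "neutralizing_modifiers": [], "citation_note": "accepted plant-derived sweetener"}
    ],
    "monk-fruit-juice-concentrate": [
      {"concern_category": "sweetener-microbiome", "status": "benign", "confidence": "established", "neutralizing_modifiers": [], "citation_note": "accepted fruit-derived sweetener"}
    ]
  }
}
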