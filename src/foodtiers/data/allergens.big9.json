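{
  "mode": "big9",
  "categories": {
    "milk": ["milk", "skim-milk-powder", "cream", "butter", "yogurt", "whey-protein", "casein"],
    "eggs": ["egg"],
    "fish": ["salmon", "tuna", "anchovy", "fish-oil"],
    "shellfish": ["shrimp", "crab", "lobster"],
    "tree-nuts": ["almond", "walnut", "cashew", "hazelnut"],
    "peanuts": ["peanut"],
    "wheat": ["wheat"],
    "soybeans": ["soy", "soy-lecithin"],
    "sesame": ["sesame"]
  }
}
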