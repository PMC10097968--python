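{
  "_comment": "Controlled nutrient vocabulary. Each nutrient carries one canonical unit; all profile quantities are expressed in that unit. species_sums lists parent totals and the species that must not exceed them (within the relative tolerance enforced by the validator).",
  "nutrients": [
    {"id": "sugar_total", "unit": "g", "label": "Total sugar"},
    {"id": "sugar_added", "unit": "g", "label": "Added sugar"},
    {"id": "sucrose", "unit": "g", "label": "Sucrose"},
    {"id": "glucose", "unit": "g", "label": "Glucose"},
    {"id": "fructose", "unit": "g", "label": "Fructose"},
    {"id": "galactose", "unit": "g", "label": "Galactose"},
    {"id": "lactose", "unit": "g", "label": "Lactose"},
    {"id": "fat_total", "unit": "g", "label": "Total fat"},
    {"id": "fat_saturated", "unit": "g", "label": "Saturated fat"},
    {"id": "fat_trans", "unit": "g", "label": "Trans fat"},
    {"id": "fat_mufa", "unit": "g", "label": "Monounsaturated fat"},
    {"id": "fat_pufa", "unit": "g", "label": "Polyunsaturated fat"},
    {"id": "omega6_total", "unit": "g", "label": "Omega-6 fatty acids, total"},
    {"id": "omega3_total", "unit": "g", "label": "Omega-3 fatty acids, total"},
    {"id": "ala", "unit": "g", "label": "Alpha-linolenic acid (ALA)"},
    {"id": "epa", "unit": "mg", "label": "Eicosapentaenoic acid (EPA)"},
    {"id": "dha", "unit": "mg", "label": "Docosahexaenoic acid (DHA)"},
    {"id": "fiber_total", "unit": "g", "label": "Total dietary fiber"},
    {"id": "fiber_soluble", "unit": "g", "label": "Soluble fiber"},
    {"id": "fiber_insoluble", "unit": "g", "label": "Insoluble fiber"},
    {"id": "protein", "unit": "g", "label": "Protein"},
    {"id": "sodium", "unit": "mg", "label": "Sodium"},
    {"id": "choline", "unit": "mg", "label": "Choline"},
    {"id": "copper", "unit": "mg", "label": "Copper"},
    {"id": "magnesium", "unit": "mg", "label": "Magnesium"},
    {"id": "manganese", "unit": "mg", "label": "Manganese"},
    {"id": "iodine", "unit": "mg", "label": "Iodine"},
    {"id": "iron", "unit": "mg", "label": "Iron"},
    {"id": "phosphorus", "unit": "mg", "label": "Phosphorus"},
    {"id": "potassium", "unit": "mg", "label": "Potassium"},
    {"id": "selenium", "unit": "mg", "label": "Selenium"},
    {"id": "zinc", "unit": "mg", "label": "Zinc"},
    {"id": "calcium", "unit": "mg", "label": "Calcium"},
    {"id": "vitamin_a", "unit": "IU", "label": "Vitamin A"},
    {"id": "vitamin_d", "unit": "IU", "label": "Vitamin D"},
    {"id": "vitamin_e", "unit": "mg", "label": "Vitamin E (tocopherols)"},
    {"id": "vitamin_c", "unit": "mg", "label": "Vitamin C (ascorbic acid)"},
    {"id": "thiamine", "unit": "mg", "label": "Vitamin B1 (thiamine)"},
    {"id": "riboflavin", "unit": "mg", "label": "Vitamin B2 (riboflavin)"},
    {"id": "niacin", "unit": "mg", "label": "Niacin"},
    {"id": "pantothenic_acid", "unit": "mg", "label": "Vitamin B5 (pantothenic acid)"},
    {"id": "vitamin_b6", "unit": "mg", "label": "Vitamin B6 (pyridoxine)"},
    {"id": "vitamin_b12", "unit": "ug", "label": "Vitamin B12"},
    {"id": "folate", "unit": "ug", "label": "Total folate"},
    {"id": "lead", "unit": "ug", "label": "Lead"},
    {"id": "arsenic", "unit": "ug", "label": "Arsenic"},
    {"id": "cadmium", "unit": "ug", "label": "Cadmium"},
    {"id": "mercury", "unit": "ug", "label": "Mercury"},
    {"id": "glyphosate", "unit": "ug", "label": "Glyphosate"}
  ],
  "species_sums": {
    "sugar_total": ["sucrose", "glucose", "fructose", "galactose", "lactose"],
    "fat_total": ["fat_saturated", "fat_trans", "fat_mufa", "fat_pufa"],
    "fiber_total": ["fiber_soluble", "fiber_insoluble"]
  }
}
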