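{
  "_comment": "Reference nutrient registry (all profiles per-100g). Used to fill in profiles for components that were not fully tested; every substitution is logged as an assumption. Values are typical food-composition figures, provided as synthetic reference stand-ins for internal testing and fixtures.",
  "entries": {
    "grape-juice": {
      "basis": "per-100g",
      "quantities": {"sugar_total": 14.8, "glucose": 7.2, "fructose": 7.4, "sucrose": 0.2, "sugar_added": 0.0, "fiber_total": 0.2, "fiber_soluble": 0.1, "fiber_insoluble": 0.1, "protein": 0.4, "sodium": 5.0, "potassium": 104.0, "vitamin_c": 0.1, "fat_total": 0.1, "fat_saturated": 0.0, "fat_mufa": 0.0, "fat_pufa": 0.1}
    },
    "grape-juice-concentrate": {
      "basis": "per-100g",
      "quantities": {"sugar_total": 52.0, "glucose": 25.5, "fructose": 26.0, "sucrose": 0.5, "sugar_added": 0.0, "fiber_total": 0.5, "protein": 1.2, "sodium": 15.0, "potassium": 350.0}
    },
    "whole-milk": {
      "basis": "per-100g",
      "quantities": {"sugar_total": 4.8, "lactose": 4.8, "sugar_added": 0.0, "fat_total": 3.3, "fat_saturated": 1.9, "fat_mufa": 0.8, "fat_pufa": 0.2, "fat_trans": 0.0, "omega6_total": 0.12, "omega3_total": 0.08, "protein": 3.2, "sodium": 43.0, "calcium": 113.0, "vitamin_d": 40.0, "vitamin_a": 162.0, "magnesium": 10.0, "zinc": 0.4, "iron": 0.03, "potassium": 132.0, "vitamin_b12": 0.45, "riboflavin": 0.17}
    },
    "skim-milk-powder": {
      "basis": "per-100g",
      "quantities": {"sugar_total": 52.0, "lactose": 52.0, "sugar_added": 0.0, "fat_total": 0.8, "fat_saturated": 0.5, "protein": 36.0, "sodium": 535.0, "calcium": 1257.0, "potassium": 1794.0, "magnesium": 110.0, "zinc": 4.1, "vitamin_b12": 4.0}
    },
    "cream": {
      "basis": "per-100g",
      "quantities": {"sugar_total": 2.9, "lactose": 2.9, "sugar_added": 0.0, "fat_total": 36.0, "fat_saturated": 23.0, "fat_mufa": 9.0, "fat_pufa": 1.5, "fat_trans": 0.0, "protein": 2.1, "sodium": 27.0, "calcium": 66.0, "vitamin_a": 1470.0}
    },
    "sugar": {
      "basis": "per-100g",
      "quantities": {"sugar_total": 99.8, "sucrose": 99.8, "sugar_added": 99.8}
    },
    "cocoa-powder": {
      "basis": "per-100g",
      "quantities": {"sugar_total": 1.8, "sucrose": 1.8, "sugar_added": 0.0, "fat_total": 13.7, "fat_saturated": 8.1, "fat_mufa": 4.6, "fat_pufa": 0.4, "omega6_total": 0.4, "fiber_total": 33.2, "fiber_soluble": 6.0, "fiber_insoluble": 27.2, "protein": 19.6, "sodium": 21.0, "iron": 13.9, "magnesium": 499.0, "zinc": 6.8, "potassium": 1524.0}
    },
    "strawberry-puree": {
      "basis": "per-100g",
      "quantities": {"sugar_total": 4.9, "glucose": 2.0, "fructose": 2.4, "sucrose": 0.5, "sugar_added": 0.0, "fiber_total": 2.0, "fiber_soluble": 0.6, "fiber_insoluble": 1.4, "protein": 0.7, "sodium": 1.0, "vitamin_c": 58.8, "potassium": 153.0}
    },
    "water": {
      "basis": "per-100g",
      "quantities": {"sodium": 0.5}
    },
    "olive-oil": {
      "basis": "per-100g",
      "quantities": {"fat_total": 100.0, "fat_saturated": 13.8, "fat_mufa": 73.0, "fat_pufa": 10.5, "fat_trans": 0.0, "omega6_total": 9.8, "omega3_total": 0.76, "ala": 0.76, "vitamin_e": 14.4}
    },
    "algal-oil": {
      "basis": "per-100g",
      "quantities": {"fat_total": 100.0, "fat_saturated": 25.0, "fat_mufa": 25.0, "fat_pufa": 50.0, "omega3_total": 45.0, "dha": 40000.0, "epa": 2000.0}
    }
  }
}
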