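{
  "_comment": "Daily intake reference ranges per population. epa_dha is the combined EPA+DHA analyte.",
  "references": [
    {"nutrient": "epa_dha", "population": "adult", "lower": 250.0, "upper": 500.0, "unit": "mg/day"},
    {"nutrient": "fiber_total", "population": "adult", "lower": 25.0, "upper": 38.0, "unit": "g/day"},
    {"nutrient": "vitamin_d", "population": "adult", "lower": 600.0, "upper": 800.0, "unit": "IU/day"},
    {"nutrient": "sodium", "population": "adult", "lower": 1500.0, "upper": 2300.0, "unit": "mg/day"}
  ]
}
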