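{
  "_comment": "Non-normative demonstration of the pluggable calculated-ratings interface, in the style of a per-100g traffic-light scheme. Cut points are illustrative package defaults, not any regulator's published values.",
  "name": "traffic-light-demo",
  "bands": [
    {"nutrient": "sugar_total", "basis": "per-100g", "cut_points": [5.0, 22.5], "labels": ["green", "amber", "red"]},
    {"nutrient": "fat_total", "basis": "per-100g", "cut_points": [3.0, 17.5], "labels": ["green", "amber", "red"]},
    {"nutrient": "fat_saturated", "basis": "per-100g", "cut_points": [1.5, 5.0], "labels": ["green", "amber", "red"]},
    {"nutrient": "sodium", "basis": "per-100g", "cut_points": [120.0, 600.0], "labels": ["green", "amber", "red"]}
  ]
}
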