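{
 "drug_label": "ABC/3TC",
 "unit_strength_mg": 120.0,
 "adult_dose_mg": 600.0,
 "steps": [
  [120.0, "1"],
  [180.0, "1.5"],
  [240.0, "2"],
  [300.0, "2.5"],
  [360.0, "3"],
  [600.0, "adult"]
 ]
}
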