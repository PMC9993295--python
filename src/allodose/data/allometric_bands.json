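{
 "source": "allometric",
 "resolution_kg": 0.1,
 "bands": [
  {"lower_kg": 0.0, "upper_kg": 8.2, "dose_mg": 120.0, "label": "1"},
  {"lower_kg": 8.3, "upper_kg": 14.1, "dose_mg": 180.0, "label": "1.5"},
  {"lower_kg": 14.2, "upper_kg": 20.6, "dose_mg": 240.0, "label": "2"},
  {"lower_kg": 20.7, "upper_kg": 27.8, "dose_mg": 300.0, "label": "2.5"},
  {"lower_kg": 27.9, "upper_kg": 35.4, "dose_mg": 360.0, "label": "3"},
  {"lower_kg": 35.5, "upper_kg": null, "dose_mg": 600.0, "label": "adult"}
 ]
}
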