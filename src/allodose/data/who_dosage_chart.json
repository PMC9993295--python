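{
 "source": "WHO-2019 paediatric ARV dosage chart",
 "resolution_kg": 0.1,
 "note": "The printed paediatric chart tops out at 34.9 kg for the adult ABC/3TC tablet; the adult band is left open-topped here so that lookups are total for heavier children, who receive the same adult tablet.",
 "drugs": {
  "ABC/3TC": {
   "formulation": "dispersible tablet 120 mg/60 mg once daily; adult tablet 600 mg/300 mg",
   "unit_strength_mg": 120.0,
   "bands": [
    {"lower_kg": 3.0, "upper_kg": 5.9, "dose_mg": 120.0, "label": "1"},
    {"lower_kg": 6.0, "upper_kg": 9.9, "dose_mg": 180.0, "label": "1.5"},
    {"lower_kg": 10.0, "upper_kg": 13.9, "dose_mg": 240.0, "label": "2"},
    {"lower_kg": 14.0, "upper_kg": 19.9, "dose_mg": 300.0, "label": "2.5"},
    {"lower_kg": 20.0, "upper_kg": 24.9, "dose_mg": 360.0, "label": "3"},
    {"lower_kg": 25.0, "upper_kg": null, "dose_mg": 600.0, "label": "adult"}
   ]
  },
  "LPV/r": {
   "formulation": "granules 40 mg/10 mg per sachet, twice daily",
   "unit_strength_mg": 40.0,
   "bands": [
    {"lower_kg": 3.0, "upper_kg": 5.9, "dose_mg": 80.0, "label": "2 BD"},
    {"lower_kg": 6.0, "upper_kg": 9.9, "dose_mg": 120.0, "label": "3 BD"},
    {"lower_kg": 10.0, "upper_kg": 13.9, "dose_mg": 160.0, "label": "4 BD"},
    {"lower_kg": 14.0, "upper_kg": 19.9, "dose_mg": 200.0, "label": "5 BD"},
    {"lower_kg": 20.0, "upper_kg": 24.9, "dose_mg": 240.0, "label": "6 BD"}
   ]
  },
  "DTG": {
   "formulation": "film-coated tablet 50 mg once daily",
   "unit_strength_mg": 50.0,
   "bands": [
    {"lower_kg": 20.0, "upper_kg": 24.9, "dose_mg": 50.0, "label": "1"},
    {"lower_kg": 25.0, "upper_kg": null, "dose_mg": 50.0, "label": "1"}
   ]
  }
 }
}
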