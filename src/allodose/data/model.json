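{
 "adult_dose_mg": 600.0,
 "reference_weight_kg": 70.0,
 "exponent": 0.75
}
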