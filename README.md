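# allodose

Allometric ¾-power dose scaling for paediatric fixed-dose-combination
dosing: scale an adult antiretroviral dose to a child's body weight,
derive a weight-band dosing table from a tablet formulary, simulate
paediatric cohorts matched to published per-age weight summaries, and
compare dosing strategies with rank-based statistics.

## Who this is for

Clinical pharmacologists and pharmacometricians evaluating weight-band
dosing guidance for children. WHO-style paediatric charts assign every
child in a weight band the same tablet count; the band edges are set by
convention, and children near an edge — especially the 25 kg threshold
at which the adult abacavir/lamivudine (ABC/3TC 600/300 mg) tablet is
given — can receive doses far from what their size warrants. Allometric
scaling offers a principled alternative.

## The model

Metabolic quantities such as drug clearance relate to body weight by a
power law, Y = α·BW^b, with b ≈ 0.75 for clearance. Because the
maintenance dose at steady state is proportional to clearance, the
paediatric dose follows

```
dose_child = dose_adult × (BW_child / 70)^0.75
```

anchored at a 70 kg reference adult. Inverting the relation,

```
BW = 70 × (dose_child / dose_adult)^(1/0.75)
```

gives the body weight at which a child needs exactly a given
dispensable dose — which is how a discrete tablet formulary
({120, 180, 240, 300, 360, 600} mg ABC as multiples of the 120/60 mg
dispersible unit) becomes a weight-band table: the upper edge of each
band is the exact weight for that band's dose, so no child in the band
needs more than it dispenses.

Strategies are compared on tablet counts with a Wilcoxon rank-sum
(Mann–Whitney) test — midranks, tie-corrected variance, 0.5 continuity
correction, exact enumeration for small groups — implemented in this
package and cross-checked against brute-force enumeration and SciPy in
the test suite.

## Worked example

Build the allometric band table from the packaged model and formulary:

```
$ allodose bands build
Body weight (kg)    Dose (mg)    Label  Tablets
<=8.2                     120        1        1
8.3-14.1                  180      1.5      1.5
14.2-20.6                 240        2        2
20.7-27.8                 300      2.5      2.5
27.9-35.4                 360        3        3
>=35.5                    600    adult        5
```

A child at or below 8.2 kg needs one dispersible tablet; the adult
600 mg tablet is not reached until 35.5 kg — under the WHO chart it is
reached at 25 kg.

Simulate an 89-child cohort (ages 2–12) from the packaged per-age
summary specification and compare the two strategies:

```
$ allodose simulate --seed 1 --out cohort.csv
$ allodose compare --cohort cohort.csv --out report.json
   label    weight-band     allometric
--------------------------------------
       1              0              2
     1.5              1             14
       2              7             25
     2.5             14             29
       3             22             17
   adult             45              2

weight-band: mean 3.8 +/- 1.22 tablets; adult dose 50.6%
allometric: mean 2.3 +/- 0.66 tablets; adult dose 2.2%

Mann-Whitney (normal): U=6672.5, z=8.091, p=5.932e-16
Age-weight correlation: r=0.78, r^2=0.61
```

Under the weight-band chart half the cohort (the children at or above
25 kg) lands on the adult dose, skewing the distribution toward high
tablet counts; per-patient allometric scaling centres the distribution
around 2–2.5 tablets, and the difference is highly significant. The
cohort's age–weight correlation (r = 0.78) is reported alongside.

Per-patient scaling is also available directly:

```
$ allodose dose --weight-kg 25
weight 25 kg -> exact 277.2 mg; dispensed 300 mg (2.5 x 120 mg, label '2.5')
```

## Library surface

- `allodose.scaling` — `ScalingModel`, `power_scale`, `allometric_dose`,
  `weight_for_dose`, `Formulary`, `RoundingPolicy`, `round_to_formulary`
- `allodose.bands` — `build_allometric_bands`, `lookup_dose`,
  `parse_table` / `serialize_table`, `WeightBandTable`
- `allodose.cohort` — `default_spec`, `generate_cohort`,
  `summarize_cohort`, `read_cohort` / `write_cohort`
- `allodose.compare` — `BandTableStrategy`, `AllometricStrategy`,
  `assign_doses`, `dose_distribution`, `mann_whitney_u`, `pearson_r`,
  `run_comparison`
- `allodose.fixtures` — packaged WHO chart, reference band table,
  default model/formulary/cohort spec

See `docs/methods.md` for the modelling choices and their rationale.
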