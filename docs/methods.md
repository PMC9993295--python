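# Methods

## Scaling model

The package scales adult quantities to children with a single power
law, Y(BW) = Y_adult · (BW/BW_ref)^b. Defaults: BW_ref = 70 kg,
b = 0.75 — the exponent observed for metabolic rates and drug
clearance, and hence (at steady state) for maintenance dose. The
exponent is restricted to (0, 2]: b = 1 recovers linear per-kg dosing,
b = 0.25 suits time-related quantities. No age-dependent maturation
function is layered on top; for drugs cleared by pathways still
maturing in infancy the pure power law over-predicts clearance, which
is one reason the packaged cohort specification starts at age 2.

Doses are capped at the adult value by default (the model is a
scale-*down* tool; extrapolating above the reference weight is
available via `cap_at_adult=False` but not meaningful for dosing).

## Formulary and rounding

Dispensable doses are the multiples of one dispersible ABC/3TC
120/60 mg unit: {120, 180, 240, 300, 360} mg ABC plus the 600 mg adult
tablet. Doses are tracked in mg of the index drug (abacavir); the
lamivudine component follows the fixed 2:1 co-formulation ratio and
needs no separate arithmetic.

Two rounding conventions are first-class, because they answer
different questions:

- **nearest** (default for per-patient conversion): dispense the step
  closest to the exact scaled dose. Exact midpoints (e.g. 150 mg
  between the 120 and 180 mg steps) break to the *lower* step —
  conservative dosing; overridable via `tie_rule`.
- **ceil** (default for band construction): the smallest step at or
  above the dose, so a band built from it never requires more than it
  dispenses.

## Band-table construction and lookup

For each formulary step d below the adult dose, the band's upper edge
is the exact allometric weight for d — BW_ref·(d/adult)^(1/b) —
rounded half-up to the table resolution (0.1 kg, the granularity of
clinical weight records). The next band starts one resolution step
higher; weights above the last finite edge receive the adult step.
With the default model and formulary the edges are 8.2, 14.1, 20.6,
27.8 and 35.4 kg, with the adult tablet from 35.5 kg.

Lookups quantise the weight to the table resolution first (14.15 kg
records as 14.2 kg and falls in the higher band), which makes every
table a total function with inclusive edges and no dead zones.
Weights below a table's first band map to that band with an
`out_of_range` flag rather than failing: the flag, not an exception,
is the clinical signal that the chart does not cover the child.

The packaged WHO-style chart keeps its published edges (3–5.9, 6–9.9,
10–13.9, 14–19.9, 20–24.9 kg, then the adult tablet). Its printed
adult row tops out at 34.9 kg; the packaged fixture leaves that band
open-topped so heavier children — who receive the same adult tablet —
still resolve.

## Synthetic cohorts

Patient-level records for this kind of chart review are not deposited;
what is published is a per-age summary (count n, mean weight, observed
min–max) plus an overall age–weight Pearson correlation. The generator
treats that summary as the model:

- Within each one-year age stratum, weight is drawn from a **scaled
  Beta** distribution on [min, max]: bounded support guarantees every
  draw honours the printed extremes, and the family is flexible enough
  to be skewed (child weight distributions have long right tails — the
  age-12 stratum here has mean 31.9 kg against a 23.7–58.8 kg range).
- The Beta's two shape parameters are set from two constraints: the
  **mean** equals the printed stratum mean, and the **standard
  deviation** is inferred from the printed range as
  range / max(d_n, √12), where d_n is the expected range of an
  n-observation normal sample (Tippett's constant; ≈ 3.0 at n = 9,
  ≈ 3.6 at n = 17). Reading the extremes as order statistics uses the
  stratum size the range actually came from; the √12 floor stops a
  2-observation range from implying more-than-uniform spread. The
  target variance is clipped just below the two-point feasibility
  bound, and an explicit `sd_kg` per stratum overrides the inference.
- Weights are rounded to 0.1 kg; sex is Bernoulli with the cohort's
  male fraction (40/89 by default) and is carried but unused by dosing.

A range-*truncated normal* centred on the printed mean was considered
and rejected on two measurable grounds: in skewed strata the truncated
mean drifts off the printed mean (by 2.7 kg in the age-12 stratum),
and truncation caps the attainable variance so low that the implied
age–weight correlation saturates near 0.86 — outside the plausible
neighbourhood of the published r = 0.78 — for *any* parent sd. The
Beta parameterisation reproduces the printed means essentially exactly
and yields r ≈ 0.73–0.76 at large replicate counts.

When a specification is scaled up (`CohortSpec.scaled(k)`) the
inferred sd is frozen first: the printed range belongs to the original
n observations, and a larger replicate count must not tighten it.

What passing tests show — and do not show: the generator reproduces
the published per-age means, ranges, counts and the correlation
neighbourhood, so strategy comparisons on synthetic cohorts probe the
same weight structure the published analysis saw. It does not model
growth-chart (z-score) physiology, within-family correlation, secular
trends, or the exact patient weights, so patient-level statistics
(e.g. the exact adult-dose percentage) vary by seed and only the
qualitative contrasts are expected to be stable.

## Rank-sum test

`mann_whitney_u` computes U from midranks. Inference:

- **Exact** (default when the smaller group has ≤ 10 members and the
  enumeration stays below 2²¹ splits): the two-sided p is the fraction
  of all C(N, n_x) rank splits whose U is at least as far from
  n_x·n_y/2 as observed. Ties are handled by enumerating the midrank
  multiset itself.
- **Normal approximation** otherwise: tie-corrected variance
  n_x·n_y/12 · [(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5 continuity
  correction shrinking |U − μ| toward zero.

If every observation in both groups is identical the variance is zero;
the test returns p = 1 with a warning rather than dividing by zero.
At very small group sizes the exact null is coarse, so the
normal-approximation p can differ from the exact p by ~0.1 (more under
heavy ties) near the centre of the distribution — the exact route,
which is what such sizes trigger automatically, is the authoritative
one there.

Tablet counts (dose ÷ 120 mg) are the default comparison scale, the
adult tablet counting as its mg-proportional 5.0 units — the only
self-consistent choice when one formulation change (600 mg in one
tablet) would otherwise discontinuously change the scale; raw mg is
available via `dose_scale="mg"`. Two-sided p throughout; α = 0.05.

## Problem sizes

The test suite exercises the stochastic claims at sizes chosen to make
the checks sharp but cheap: 200 seeds for stratum-mean recovery and
100 seeds for the correlation band at ×10 replicate scale; 100
synthetic 89-child cohorts for the strategy-ordering property; 200
random small-sample pairs for the rank-sum oracle; 1000 random doses
for inversion and rounding properties. The whole suite runs in a few
seconds.

## Known limitations

- The ¾ exponent is assumed, not estimated; no covariates beyond
  weight.
- Band edges optimise nothing — they are the exact inversion of the
  dose model at the formulary steps, not exposure-target optimised.
- The synthetic generator is a stand-in distribution consistent with
  published summaries, not a growth model; see above.
- The Beta-shape inference assumes the printed ranges are genuine
  sample extremes (not winsorised or typo-ed).
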