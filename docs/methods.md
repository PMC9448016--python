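# Methods

## The index

The metric Healthy Eating Index-2015 keeps the structure of the HEI-2015:
13 components, 9 adequacy (total fruits, whole fruits, total vegetables,
greens and beans, whole grains, dairy, total protein foods, seafood and plant
proteins, fatty acids) and 4 moderation (refined grains, sodium, added
sugars, saturated fats), with maximum points summing to 100. All consumption
is expressed as a density per 1000 kcal, so the index is invariant to total
energy intake and comparable across ages and energy needs.

What changes in the metric version is the unit of consumption. Cup and ounce
equivalents presuppose the USDA Food Patterns Equivalents Database; the
metric method instead uses:

- **gram equivalents** for fruit, vegetable and grain components —
  consumed grams × a processing factor;
- **grams of protein** for the two protein components;
- **milligrams of calcium** for dairy;
- unchanged metric measures for the four nutrient-only components
  (the (PUFA+MUFA)/SFA ratio, g sodium/1000 kcal, and added sugars and
  saturated fat as % of energy, at 4 kcal/g and 9 kcal/g respectively).

## The equivalent principle

The processing factor compensates for energy-density change through
preparation and for nothing else (no moisture or yield corrections):

    factor(raw)       = 1
    factor(processed) = energy density processed / energy density raw

Energy density is kcal per 100 g. Legumes are the single exception, kept from
the source food-pattern methodology: cooked legumes score like raw
vegetables (factor 1), and the *uncooked* form gets the energy-density ratio
relative to the cooked reference — the raw/processed roles invert, because
drying, not cooking, is the energy-densifying step for legumes.

Protein and dairy contributions use nutrient content directly, with no
factor. This deliberately replaces the nine subcategory-specific
ounce-equivalent formulas of the imperial food-pattern methodology with one
transparent rule; the known consequence is that nuts and seeds are not
up-weighted, which slightly lowers the protein components of nut-heavy
(e.g. vegetarian) diets relative to the imperial index.

Under the default allocation switch, legume intake is credited
simultaneously to total vegetables, greens and beans, total protein foods,
and seafood and plant proteins (the HEI-2015 convention); the vegetable
credit is in gram equivalents, the protein credit in grams of protein. A
`vegetables_only` switch restricts legumes to the vegetable components.

## Food coding

A five-digit code carries everything scoring needs: component type
(`F/V/G/P/D`, or `X` for foods contributing to no component), group, a
two-digit item number shared by a food's raw and processed forms, and a
processing-state digit (0 raw / 1 processed). Protein and dairy codes stop
after the group digit because their equivalents derive from nutrient content
alone. The group alphabet used here (e.g. `F`: juice / citrus-melon-berry /
other whole fruit; `G`: whole / refined) is this package's own compatible
assignment — it covers every distinction the 13 components need and is
remappable by editing one table in `mhei.codes`.

Processed foods without a raw counterpart in the database are flagged by
`validate_database`; at equivalents time they use an explicit per-record
factor override when present, otherwise factor 1 with a logged warning, so a
pipeline degrades softly rather than aborting on an incomplete database.

## Recipes

Menu items decompose into ingredient mass fractions that sum to ≤ 1 (the
remainder is water/unclassified). When only paired cup-equivalent tables are
available, the fraction is reconstructed exactly as the quotient of the
menu's and the ingredient's cup equivalents per 100 g. The discrepancy
detector compares a declared per-100-g profile against the mass-fraction
recomputation and flags components differing by more than `tol = 0.005` —
half a rounding unit at the two decimals such tables print — using a strict
inequality so that exactly-rounding differences are not flagged.

## Scoring rules

All components score linearly between their standards (the HEI-2015
convention):

- adequacy: `max_points × min(1, density / standard_for_max)`; zero intake
  scores zero;
- moderation: `max_points` at/below `standard_for_max`, 0 at/above
  `standard_for_min`, linear between;
- fatty acids: 10 at ratio ≥ 2.5, 0 at ≤ 1.2, linear between. Degenerate
  cases: no fat at all scores 0 (a diet with no fat source earns no
  fat-quality credit); unsaturated fat with zero saturated fat scores 10
  (the ratio's limit).

Multi-day records are pooled — intake and energy summed before dividing —
which is identical to computing a density on the concatenated days.
Zero-energy record sets are flagged and score 0 on every component, matching
the behaviour of reference HEI implementations for empty recalls. Scores are
kept unrounded; rounding is display-only. The per-subject ("simple") scoring
algorithm is used throughout, consistent with per-subject agreement
analysis; the population-ratio method is out of scope.

### Metric standards (per 1000 kcal)

| Component | Max pts | Standard for max | Standard for min |
| --- | --- | --- | --- |
| Total fruits | 5 | ≥ 141 g eq | 0 |
| Whole fruits | 5 | ≥ 60 g eq | 0 |
| Total vegetables | 5 | ≥ 160 g eq | 0 |
| Greens and beans | 5 | ≥ 29 g eq | 0 |
| Whole grains | 10 | ≥ 31 g eq | 0 |
| Dairy | 10 | ≥ 412 mg calcium | 0 |
| Total protein foods | 5 | ≥ 15.6 g protein | 0 |
| Seafood and plant proteins | 5 | ≥ 3.3 g protein | 0 |
| Fatty acids | 10 | ratio ≥ 2.5 | ratio ≤ 1.2 |
| Refined grains | 10 | ≤ 32 g eq | ≥ 76 g eq |
| Sodium | 10 | ≤ 1.1 g | ≥ 2.0 g |
| Added sugars | 10 | ≤ 6.5 %E | ≥ 26 %E |
| Saturated fats | 10 | ≤ 8 %E | ≥ 16 %E |

The imperial preset uses the original HEI-2015 cup/ounce-equivalent
standards; imperial scoring accepts precomputed equivalent densities (an
FPED-style table) rather than recomputing cup equivalents from grams.

## Calibration

For each food-group, protein and dairy component the metric standard is set
so that a reference cohort's metric consumption fulfils the same proportion
of it as its imperial consumption fulfils of the imperial standard:

    metric standard = mean metric × imperial standard / mean imperial

Cohort means are simple (unweighted) arithmetic means of per-subject
densities; survey weights are out of scope. Intermediates stay unrounded;
the final standard is rounded once, half away from zero, to the nearest gram
equivalent (food groups) or one decimal (protein, dairy). Rounding operates
on the decimal representation so printed-precision inputs behave as a reader
would expect (0.715 → 0.72). The refined-grains minimum is derived as
`metric max × imperial min / imperial max`. The fulfilment-proportion
identity `mean_metric / metric_std = mean_imperial / imperial_std` holds
exactly before rounding, which gives the calibration a recovery property the
tests exploit: planted standards are recovered exactly from noise-free
paired cohorts, and to within sampling error under multiplicative noise.

## Agreement analysis

Bland–Altman uses the literal 1.96 multiplier on the sample SD (n−1) of the
A−B differences. Confidence intervals are normal-theory: bias ± t·SD/√n and
each limit ± t·SD·√(3/n) with t the 97.5th percentile of t(n−1). Pearson's
r is used for totals and Spearman's ρ (average ranks for ties) for
components, whose discrete 0–5/0–10 scales are far from normal. Summaries
report sample SD and the Q3−Q1 IQR with linear-interpolation (type-7)
quantiles — stated explicitly because IQR is method-dependent. Zero-variance
vectors yield a `nan` correlation flag rather than an exception. The plot is
purely presentational; every number on it comes from the statistics
functions.

## Synthetic data

`make_food_db` emits a database covering every code group: raw/processed
pairs whose processing factors equal drawn energy-density ratios (1.2–6),
cooked/uncooked legume pairs (uncooked 2.2–3.6× denser), protein foods with
5–30 g protein/100 g, dairy with 50–800 mg calcium/100 g, and a set of
"staple" foods with single-purpose compositions. `make_cohort` composes each
subject's intake from those staples so that every component density is known
exactly by construction: group targets translate to grams through the
staples' clean compositions, single-nutrient fillers hit the added-sugar,
fatty-acid and sodium targets, and a pure-energy filler tops intake up to
the subject's target energy (2000 ± 300 kcal by default, a realistic adult
range). Profiles: `near_max` places every density at its standard for
maximum score (total 100), `near_min` at/below the standards for minimum
score (total 0), `random` scales standards by per-component multipliers
(default 0.6, roughly the mid consumption a national cohort shows) with
mean-one lognormal noise (sd 0.2). Targets whose energy exceeds the
subject's energy raise an impossible-profile error rather than silently
rescaling.

One integer seed drives everything through fixed stream offsets (food db 0,
cohort 1, paired consumption 2), so artifacts are independently
reproducible. Default cohort sizes are small (n = 50) so the full suite runs
in seconds; the acceptance script uses n = 10 for the scoring ceiling, which
is exact by construction, and n = 5000 where a stochastic recovery bound is
checked.

What the generator does **not** emulate: real foods mix components (a pizza
contributes to five components at once), nutrient patterns are correlated,
and day-to-day intake varies. Passing tests therefore demonstrate the
correctness of the arithmetic and the pipeline's bookkeeping on structurally
realistic data — not that the index has any particular distribution in a
real population.

## Known limitations

- Population-level (ratio-method) scoring, survey weighting and
  age-exclusion rules (e.g. children under 2) are data-preparation concerns
  left to the caller.
- Imperial scoring trusts its input equivalent densities; the package never
  computes cup/ounce equivalents from grams.
- The group alphabet is a compatible stand-in, not a transcription of any
  official taxonomy; users mapping an existing database should review it.
- The fail-soft factor-1 fallback for orphan processed foods biases their
  gram equivalents low when the true factor exceeds 1; the validation report
  lists every record it affects.
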