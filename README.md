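# mhei — metric Healthy Eating Index-2015 scoring toolkit

`mhei` implements the **metric Healthy Eating Index-2015 (mHEI-2015)**, a
13-component diet-quality index for dietary data recorded in grams, as used in
weighed food records and metric food-composition databases. It is aimed at
nutritional epidemiologists and dietitians in metric-system countries who want
HEI-2015-comparable diet-quality scores without converting intakes into USDA
cup and ounce equivalents.

The package provides four things:

1. **A food-coding and gram-equivalent methodology.** Every single food item
   carries a short code (component type `F/V/G/P/D/X`, group, item number,
   processing state). Consumed grams of fruits, vegetables and grains convert
   to *gram equivalents* by a factor that compensates for energy-density
   change through preparation:

   - raw foods: `factor = 1`
   - processed foods: `factor = energy density (processed) / energy density (raw)`
   - legumes invert the rule: the cooked form is the unity reference, so
     uncooked (denser) legumes carry a factor above one.

   Protein foods contribute **grams of protein** and dairy contributes
   **milligrams of calcium** directly — no factor, no yield formulas.
   Multi-ingredient menu items decompose through recipes of mass fractions;
   where only paired cup-equivalent tables exist, the fraction is recovered
   as `menu cup eq per 100 g ÷ ingredient cup eq per 100 g`.

2. **A 13-component scorer.** Densities are per 1000 kcal, making the index
   energy-scale invariant. Adequacy components score
   `max_points × min(1, density/standard)`; moderation components score full
   points at or below one threshold and zero at or above another, linear
   between; the fatty-acid component scores the (PUFA+MUFA)/SFA ratio
   (10 points at ≥ 2.5, 0 at ≤ 1.2). Two standards presets ship: `mhei2015`
   (metric) and `hei2015` (imperial).

3. **A calibration procedure.** Given paired per-subject consumption tables
   from the same cohort in both unit systems, the metric standard for each
   food-group, protein and dairy component is set so the cohort fulfils the
   same proportion of it as of the imperial standard:
   `metric standard = mean metric consumption × imperial standard / mean
   imperial consumption` (per 1000 kcal), rounded once — to the nearest gram
   equivalent, or to one decimal for protein/dairy. Nutrient-only components
   (fatty acids, sodium, added sugars, saturated fats) are already metric and
   pass through unchanged.

4. **Agreement analysis.** Bland–Altman bias and 95 % limits of agreement
   (bias ± 1.96 × SD of the differences) with normal-theory confidence
   intervals, Pearson *r* on totals, Spearman ρ per component, and
   mean ± SD / median (IQR) summary tables, plus a Bland–Altman plot with
   marginal histograms.

A synthetic-data module generates food databases, recipes and intake cohorts
with known ground-truth densities, so the whole pipeline runs with no
external data.

## Worked example

```python
from mhei import MHEI_2015, component_densities, total_score
from mhei.scoring import intake_records
from mhei.simulate import CohortSpec, make_cohort, make_food_db

db = make_food_db(seed=1)
intakes, truth = make_cohort(CohortSpec(n_subjects=3, profile="random", seed=7), db)
for subject, records in intake_records(intakes).items():
    dens = component_densities(records, db)
    score = total_score(dens, MHEI_2015)
    print(subject, f"energy={dens.total_energy_kcal:.0f} kcal",
          f"total={score.total:.1f}")
```

```
S0000 energy=2104 kcal total=67.3
S0001 energy=2158 kcal total=69.8
S0002 energy=2212 kcal total=74.6
```

Each total is out of 100; a score of 67.3 means the subject earns about two
thirds of the available diet-quality points. `score.summary()` shows the
component breakdown — for `S0000`, for example, all four moderation
components (refined grains, sodium, added sugars, saturated fats) earn their
full 10 points while total fruits earns only 1.8 of 5, i.e. fruit density is
about 37 % of the 141 g eq/1000 kcal standard.

The same pipeline is available from the shell:

```sh
mhei simulate --seed 1 --n-subjects 50 --out-dir data/
mhei score --db data/food_db.csv --intakes data/intakes.csv \
     --standards mhei2015 --out scores_metric.csv
mhei compare --scores-a scores_metric.csv --scores-b scores_other.csv \
     --out-dir agreement/
```

## Layout

| Module | Contents |
| --- | --- |
| `mhei.codes` | five-digit food coding system, component allocation |
| `mhei.database` | food-database model, CSV I/O, validation report |
| `mhei.equivalents` | processing factors, gram/nutrient equivalents, recipes |
| `mhei.standards` | scoring-standards schema and the two presets |
| `mhei.scoring` | per-1000-kcal densities, component and total scores |
| `mhei.calibration` | imperial→metric standards calibration |
| `mhei.comparison` | Bland–Altman, correlations, summaries, plotting |
| `mhei.simulate` | synthetic food databases and intake cohorts |
| `mhei.cli` | `mhei` command-line interface |

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
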