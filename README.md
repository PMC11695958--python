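# mpqs — meal protein-quality scoring and meal improvement

Older adults need enough *usable* protein at each meal to maintain muscle
mass, and plant-forward diets make that harder: single plant foods are often
short of one essential amino acid (EAA) — cereals of lysine, legumes of the
sulfur amino acids. Judging a meal therefore takes more than total protein
grams: it takes the digestibility-corrected amount of every EAA, compared to
per-meal requirements.

`mpqs` is a toolkit for dietitians' software and nutrition researchers that

1. **builds** an EAA-annotated food-composition database from delimited
   tables (NEVO-style national data plus foreign amino-acid sources, with
   priority ordering, fallback resolution and per-food-group digestibility
   factors),
2. **scores** meals with the Meal Protein Quality Score (MPQS), and
3. **suggests** concrete meal improvements with three algorithms.

## The score

For a meal with digestible EAA intake $I_e$ (mg) and per-meal thresholds
$T_e$ (mg),

$$\mathrm{MPQS} = 100 \cdot \min_e \, \min\!\left(1, \frac{I_e}{T_e}\right)$$

where the intake of each portion is
$\text{grams} \times \frac{\text{protein}}{100} \times \text{profile}_e
\times \text{digestibility}$. The score is anchored at both ends: **0**
when one EAA is completely absent from the meal, **100** when every EAA
meets its threshold. The EAA with the smallest ratio is the *limiting
amino acid*. Thresholds are body-weight-proportional and fully pluggable;
the shipped default splits FAO/WHO/UNU (2007) adult daily EAA requirements
evenly over three meals.

The three improvement algorithms:

- **gram-by-gram** — replace one food with a similar one (same category /
  frequently co-consumed) at identical grams; rank by the new score.
- **missing piece** — find foods that lift the meal to exactly 100 once
  added; rank ascending by the grams needed (closed form
  $\max_e d_e / c_e$ over the deficits $d_e$ and per-gram contributions
  $c_e$).
- **proportion adjustment** — linear program maximizing the score while the
  meal's total weight is fixed and every portion stays within 50%–200% of
  its current amount.

## Worked example

No real food database ships (national tables are licensing-bound); the
`fixtures` subcommand writes a synthetic but structurally faithful demo
bundle — cereals lysine-poor, legumes sulfur-AA-poor:

```sh
mpqs --seed 6 fixtures demo
mpqs score --table demo/food_table.csv --meal demo/meal.json \
     --profile demo/profile.json --pattern demo/requirement_pattern.json
```

prints (abridged):

```json
{
  "slot": "lunch",
  "mpqs": 60.0,
  "limiting_eaa": "lys",
  "per_eaa": {
    "lys": {"intake_mg": 450.0, "threshold_mg": 750.0, "ratio": 0.6},
    "saa": {"intake_mg": 669.8, "threshold_mg": 375.0, "ratio": 1.79}
  }
}
```

The demo meal (two cereal-group foods, 75 kg user) delivers only 60% of the
lunch lysine threshold, so lysine limits the meal and MPQS = 60. Asking for
improvements:

```sh
mpqs alternatives --table demo/food_table.csv --meal demo/meal.json \
     --profile demo/profile.json --algorithms missing-piece,reproportion --max 3
```

```json
"suggestions": [
  {"algorithm": "missing_piece",
   "payload": {"code": "1010", "grams": 16.12}, "predicted_mpqs": 100.0},
  {"algorithm": "missing_piece",
   "payload": {"code": "1011", "grams": 16.97}, "predicted_mpqs": 100.0},
  {"algorithm": "missing_piece",
   "payload": {"code": "1008", "grams": 24.51}, "predicted_mpqs": 100.0}
]
```

Adding 16.1 g of a dairy item (code 1010) — or 24.5 g of a legume (1008) —
covers the lysine deficit exactly and completes the meal to 100.
Reproportioning alone (halving the lysine-poorest portion in favour of the
better one, total weight unchanged) reaches 63.1: with only lysine-poor
foods on the plate, shifting amounts can't fix the meal, which is precisely
what the rationale strings report.

Every `predicted_mpqs` is recomputed from the modified meal through the
ordinary scoring path, never extrapolated.

## Library use

```python
from mpqs import fixtures, score_meal, missing_piece

table = fixtures.generate_food_table(8, seed=11)
meal = fixtures.generate_deficient_meal(table, "lys", seed=11)
thresholds = fixtures.default_thresholds("lunch")
print(score_meal(meal, table, thresholds).mpqs)
print(missing_piece(meal, table, thresholds)[0])
```

See `docs/methods.md` for the model, parameter defaults, numerical choices
and limitations.

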