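# Methods

## The score

A meal is a list of (food, grams) portions. Each annotated food carries an
amino-acid profile in **mg per g protein** for a configurable ordered list
of essential amino acids (EAAs) and a **digestibility factor** in [0, 1].
The digestible intake of EAA *e* is

    I_e = Σ_portions grams × (protein / 100) × profile_e × digestibility

in absolute mg, and the Meal Protein Quality Score is

    MPQS = 100 × min_e min(1, I_e / T_e)

against per-meal thresholds T_e > 0 (mg). This capped limiting-ratio form
is the limiting-amino-acid convention of protein-quality scoring and is the
simplest function with both anchor properties: MPQS = 0 exactly when some
EAA is absent from the meal, and MPQS = 100 exactly when every EAA reaches
its threshold. It is monotone in every intake and invariant under joint
rescaling of intakes and thresholds (all property-tested).

A **capped-mean** variant, 100 × mean_e min(1, I_e/T_e), is available via
`Config(score_variant="capped_mean")` for sensitivity analysis only. It
violates the zero anchor (one absent EAA no longer forces a zero score) and
the proportion-adjustment linear program is not valid for it, so that
algorithm refuses to run under it.

The *limiting amino acid* is the argmin of I_e/T_e, ties broken by the
configured EAA order so output is deterministic; it is reported as absent
once every ratio reaches 1.

### Assumptions

- EAA intakes are additive across foods and linear in grams.
- A single multiplicative digestibility factor per food applies uniformly
  to all of its amino acids (a PDCAAS-style approximation; true ileal
  digestibility differs per amino acid).
- Per-meal thresholds are independent of the rest of the day's intake.

## Thresholds

Thresholds are body-weight-proportional: T_e = weight × pattern_e(slot),
with the pattern in mg per kg per meal supplied as data (JSON/YAML). The
shipped default divides the FAO/WHO/UNU (2007) adult daily EAA requirements
(his 10, ile 20, leu 39, lys 30, Met+Cys 15, Phe+Tyr 25, thr 15, trp 4,
val 26 mg/kg/day) evenly over three meals, with the safe protein intake of
0.83 g/kg/day as the reference requirement. The even split and the values
themselves are deliberate stand-ins — requirement patterns targeted at
muscle protein synthesis in older adults are an open research question —
so the pattern is data, never code. A per-profile custom protein
requirement rescales all thresholds proportionally (custom / reference),
and dietitians can override individual EAA thresholds; edits must be
positive and name configured EAAs.

## Database construction

Food tables are delimited UTF-8 text with a header (separator and column
names configurable). Rows with malformed numerics are rejected one by one
with row-level diagnostics; duplicate codes and missing required columns
abort the read. Floats are written with `repr`, so write → read round
trips are bit-exact.

A food is annotated with an amino-acid profile only if its protein supplies
at least `en_threshold` percent of its energy (default 1 EN%, protein at
4 kcal/g; a 17 kJ/g convention is selectable when the table's energy column
is in kJ). Zero-energy foods have undefined EN% and are treated as below
any threshold. Resolution per food, in order:

1. the food's own code in the foreign sources, searched in their listed
   priority order (the order is configuration, not hard-coded);
2. an explicit source-protein mapping (food → foreign key of its dominant
   protein source);
3. an explicit comparable-product mapping (no inference — which products
   are "highly comparable" is a curation decision);
4. a recipe: a protein-fraction-weighted mean of component profiles, with
   fractions required to sum to 1 within 1e-6.

Profiles are stored as mg per g protein, which makes rescaling to the
native protein content implicit (mg/100 g ÷ g protein/100 g); an explicit
mg-per-100-g converter (`scale_aa_to_native`) is provided, and a direct
match whose foreign protein content differs from the native value is marked
with provenance `scaled`. Foods above the threshold with no resolution
path go into an `unresolved` report — mirroring the missing-product
feedback loop a deployed tool needs — and are never silently dropped.

Digestibility factors are attached per food group as the
consumption-frequency-weighted mean of known PDCAAS values within the
group; a group with no positive frequency is an error. The factor is
always within the group's PDCAAS extremes (property-tested).

## Improvement algorithms

**Gram-by-gram.** Every candidate with positive similarity to the target
food is simulated as a replacement at identical grams (all other portions
bit-identical, total weight conserved exactly); the top k (default 5, the
middle of the 3–5 range practitioners ask for) by new MPQS are returned,
ties broken by higher similarity then code order. Ranking by new score and
ranking by improvement are identical here because the baseline is fixed.

**Similarity** is a normalized weighted sum of a same-food-group indicator
and the mean co-consumption frequency of the candidate with the *other*
meal items (normalized by the largest frequency in the model). Profile
exclusions (allergens, avoided groups) force similarity to zero. Taste
similarity is an extension point; no taste data ships. Note the
co-consumption term is vacuous for single-item meals — category weight
carries the ranking there.

**Missing piece.** With deficits d_e = max(0, T_e − I_e) and the
candidate's per-gram digestible contributions c_e, the minimal completing
amount is max_{e: d_e>0} d_e/c_e, infeasible if the candidate wholly lacks
a deficient EAA. Candidates are ranked ascending by grams (ties by code).
Every returned suggestion's modified meal rescores to exactly 100. An
optional `max_grams` filter drops implausibly large additions (no default
cap). A meal already at 100 returns no suggestions.

**Proportion adjustment.** Solve

    maximize t
    s.t.  Σ_i x_i = Σ_i g_i            (total weight fixed)
          0.5 g_i ≤ x_i ≤ 2 g_i        (per-portion band)
          Σ_i x_i c_{i,e} ≥ t T_e  ∀e
          0 ≤ t ≤ 1

with scipy's HiGHS solver. The cap t ≤ 1 encodes the score's ceiling and
keeps the problem a pure LP (valid only for the min-based score). The
optimum is generally degenerate, so a second LP with t fixed at t*
minimizes Σ_i |x_i − g_i| via auxiliary variables — a meal already at 100
therefore comes back unchanged. x = g is always feasible, so the adjusted
score never falls below the baseline. Meals with fewer than two positive
portions are returned unchanged with an explanatory rationale (weight
conservation leaves no freedom).

## Numerical choices

- The shared helper `per_gram_contribution` is the single source of the
  grams → digestible-mg conversion, so predicted scores and recomputed
  scores agree to ≤1e-9 by construction (asserted on every suggestion).
- The missing-piece closed form is nudged upward by float ulps (at most
  64, ≈1e-13 relative) until the augmented meal covers every deficit under
  the exact arithmetic the scorer uses; without this, d/c × c can round one
  ulp short of the threshold and the rescored MPQS lands at 99.999…
  instead of 100.
- The LP solution is clipped to the 50%/200% box after the second pass:
  the bounds are hard constraints and HiGHS round-off (~1e-16 relative)
  may sit marginally outside. The second pass allows 1e-9 slack on t* to
  absorb solver tolerance.
- Degenerate inputs: empty meals score as all-zero intake (MPQS 0 for
  positive thresholds); zero-energy foods are unannotatable; zero foreign
  protein cannot be rescaled (error); all-zero group frequencies are an
  error naming the group.

## Synthetic data

The fixture generator emulates the *structure* of a national
food-composition table at toy scale: four group templates (cereals,
legumes, dairy, vegetables) with mean EAA profiles in the range of
published composition data and the complementarity that matters for the
algorithms — cereals lysine-poor, legumes poor in sulfur amino acids.
Per-food profiles get multiplicative lognormal noise with unit mean
(template CVs 0.08–0.15), keeping amounts positive without truncation;
protein, energy and digestibility are uniform within template ranges, and
energy is capped so every generated item clears the 1 EN% filter. Tables
are deterministic given a seed. `generate_deficient_meal` composes meals
limited by a requested EAA, exploiting the fact that the limiting EAA is
invariant under rescaling all grams; the limiting ratio is then set to 0.6
of the default thresholds (75 kg reference user).

What the fixtures do **not** emulate: real NEVO/Frida marginal
distributions, correlations between protein content and profile, mixed
dishes, seasonal or cultural consumption patterns, or realistic
co-consumption structure (the demo co-consumption matrix is sparse random
noise). Passing tests therefore demonstrate algorithmic correctness and
invariants, not real-diet performance; conclusions about actual meals
require a licensed food database and validated requirement patterns.

## Problem sizes

The test suite and the acceptance script run the algorithms on tables of
20–52 foods, 100-meal random batches for the LP checks, and a 0.01 g grid
oracle on 2-item meals — sizes at which the brute-force oracles stay exact
while the whole suite completes in well under a minute. The algorithms
themselves are linear (scoring), O(table) (gram-by-gram, missing piece)
and a ~10-variable LP, so realistic database sizes (~2500 foods) are not a
scaling concern.

## Known limitations

- Uniform per-food digestibility (no per-amino-acid ileal values).
- Equal per-slot threshold split is a stand-in; per-slot overrides are
  supported as data.
- The day aggregate (mean by default, min optionally) is a reporting
  convention, not a validated whole-day adequacy measure.
- Similarity has no taste component and the co-consumption default weight
  is an uninformed 1:1 with category matching.
- Micronutrient and sustainability fields pass through I/O untouched;
  nothing is computed for them.
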