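# Methods

## The score

The package computes an occurrence-based healthy dietary diversity score
for older adults.  The diet is summarised by 20 food-group components.
Thirteen groups cover foods eaten on a daily basis in a French-style diet
(meat excluding poultry; cooked ham; deli meats excluding cooked ham; milk
and fresh dairy products; cheese; refined starches and potatoes;
vegetables; fruits; oils; butter, margarine and fresh cream; salted
aperitif products; sweetened products; sweetened beverages) and are
observed through three 24-h dietary recalls.  Seven groups cover foods
eaten weekly or less (poultry; eggs; fatty fish; lean fish and shellfish;
legumes; nuts; wholemeal or semi-wholemeal products) and are observed
through a ~60-item food propensity questionnaire (FPQ).

Each component rates the number of *consumption occurrences* of its group:

* positive rating (encouraged groups, and all seven FPQ groups):
  `points = occurrences × weight`;
* threshold rating (groups to consume in moderation): one point per
  occurrence up to the threshold, then
  `points = (occurrences − threshold) × weight` with a negative weight.

The printed threshold rule is discontinuous at the threshold — points
earned below it vanish once it is exceeded.  We implement this literal
form as the default and expose a `continuous` mode
(`threshold + (occurrences − threshold) × weight`) as an explicit
alternative, because the design intent ("considered positively until a
threshold") arguably favours continuity.  The total score is the exact sum
of the 20 component points.

### Occurrence counting

A recall declaration counts only if its group's **daily** consumption
reaches half a standard portion (e.g. 25 g for cooked ham's 50 g portion).
Gating is inclusive (≥ half a portion qualifies), matching the worked
cooked-ham rule; a strictness flag flips it to exclusive.  When a day
qualifies, **each declaration** of that group that day counts as one
occurrence, and occurrences are summed over the three recall days.
Ingredient grams from disaggregated dishes pool with simple-food grams of
the same group and day before gating; the alternative (gating dish
ingredients separately) is not exposed because pooling is the only reading
under which the daily gate is well defined at the group level.

Complex dishes are first disaggregated using a recipe table: ingredients
are sorted by descending mass and the smallest prefix reaching 50 % of the
recipe's mass forms the *main ingredients*; ingredients tied in mass with
the last prefix member are included so the rule is order-independent.
Main-ingredient grams are rescaled by declared dish mass over recipe mass.
Dishes without a recipe are logged and routed to the excluded category —
never fatal.

### FPQ processing

Monthly frequencies convert to weekly by dividing by 4.345 (the average
number of weeks in a month, 365/12/7; configurable).  Missing responses
are imputed missForest-style: scikit-learn's `IterativeImputer` with a
random-forest regressor (`max_features="sqrt"` per missForest's `mtry`,
25 trees, minimum leaf 5, at most 10 round-robin iterations), trained on
the observed FPQ columns plus the numeric covariates.  Observed cells are
never modified, imputed values are clamped at zero, and the result is
bitwise reproducible from the seed.  Item frequencies are summed into the
seven scored groups through an editable item→group mapping table.

### Default scoring configuration

The expert-panel portion/weight/threshold table is not fully recoverable,
so the shipped `default_groups.yaml` is a **documented approximation**
faithful to the published structure: positive ratings for the healthful
groups and all seven FPQ groups, threshold ratings with negative weights
for meat excluding poultry, deli meats excluding cooked ham, butter/
margarine/cream, salted aperitif products, sweetened products and
sweetened beverages.  Oils and refined starches, whose rating type is not
stated, are scored positively with weight 1.  Cooked ham's 50 g portion is
the one documented reference value; the other portions follow
ENNS/GEMRCN-style serving conventions.  All of it is meant to be edited;
scores produced with the defaults are comparable across cohorts scored
with the same file (the configuration hash is logged) but are not claimed
to equal the original instrument's values.

## Diet-quality measures

* **SED** (solid energy density, kcal/100 g): total energy over total mass
  of solid foods, pooled across recall days as one ratio (not a mean of
  daily ratios), matching "total energy over the total weight consumed".
* **MAR** (%): mean over 22 nutrients of intake/RDA capped at 1, with sex-
  and age-band-specific RDAs from an external CSV.
* **PANDiet** (0–100): for each of 27 nutrients, the probability that the
  usual intake satisfies its reference under a Gaussian model — mean = the
  observed day-mean, standard error = between-day SD/√n.  Nutrients with a
  lower reference form the adequacy sub-score, those with an upper
  reference the moderation sub-score; the total is their average.  When
  the observed between-day SD is zero, 10 % of the reference value is used
  in its place (configurable variance floor) so constant toy intakes yield
  informative probabilities instead of degenerate 0/1 values.  No
  measurement-error deconvolution (NCI/SPADE-style usual-intake modelling)
  is attempted.

The shipped MAR (22-nutrient) and PANDiet (27-nutrient: 23 adequacy, 4
moderation — sodium, free sugars, saturated fat, cholesterol) reference
CSVs contain **synthetic example values**: the authoritative French
reference values live in dietary-reference publications, not here, and the
example tables are scaled to the synthetic generator's typical intakes so
that demo metrics are informative rather than saturated.  Real analyses
must supply their own tables.

## Validity analysis

Construct validity is assessed by the standard battery: Spearman
correlations of the score with its components and with food-group intakes
(g/d), Pearson correlations with energy, total-food, SED, MAR and PANDiet,
survey-weighted quartile tables, Wilcoxon rank-sum sex tests, ANOVA of
metrics on sex adjusted on score quartiles, and chi-square tests of
socio-demographics across quartiles.  Correlation strengths: high
|r| > 0.5, moderate 0.2 ≤ |r| ≤ 0.5, low |r| < 0.2; the printed rule
leaves |r| = 0.2 unassigned and we close that boundary on the moderate
side, mirroring the closed 0.5 boundary.

Weighted means use the ratio estimator; their variance uses Taylor
linearisation, with influence terms summed within clusters when cluster
identifiers are supplied.  Spearman correlations are computed unweighted
even when a design is present, mirroring common survey practice for
rank-based statistics.  Quartiles come from the weighted empirical CDF of
the score (each individual placed by its midpoint cumulative weight), so
with equal weights group sizes differ by at most one.  Constant inputs
yield "undefined" correlation entries and an explanatory note, never a
crash.

## Synthetic cohorts

The generator emulates the survey structure end to end so every module is
testable without external microdata.  One latent healthiness `h ~ N(0,1)`
per individual drives:

* daily group declaration counts `Poisson(base_rate × exp(loading × h))`
  — defaults give ≈ 58 total score points at `h = 0` with positive
  loadings on fruits/vegetables/wholemeal/fish/legumes/nuts and negative
  on sweets, sweetened beverages, processed meat, butter and aperitif
  products, so default-config totals span roughly 0–110 and adversarial
  extremes reach below −30 and above 100;
* per-declaration grams, log-normal around 0.9× the standard portion
  (σ = 0.35), so most consumption days pass the half-portion gate;
* a 5 % fraction of declarations wrapped into complex dishes with a
  70/30 recipe (main food + excluded sauce), exercising disaggregation;
* FPQ item frequencies proportional to the group rates with log-normal
  noise, mixed per-week/per-month units, and MCAR holes at rate 0.1;
* nutrient intakes = per-group density matrix × day grams + 10 %
  proportional Gaussian noise, clipped at zero.  The density matrix uses
  hand-set macronutrient and energy densities and a nutrient-richness
  multiplier for micronutrients (nutrient-dense groups high, energy-dense
  groups low), which is what makes the score correlate positively with
  MAR/PANDiet and negatively with SED *by construction*;
* covariates (education, physical activity up; smoking, BMI down) with
  modest loadings on `h`, and log-normal sampling weights.

With `energy_neutral=True` every individual's intakes are rescaled so
mean daily energy equals the cohort mean times independent log-normal
noise (σ = 0.08), severing the energy–healthiness link by construction;
this mirrors the validated property that a healthy-diversity score should
not simply track energy intake.

What the generator does **not** emulate: item-level marginal consumption
distributions of any real survey, day-of-week/seasonal structure,
correlated FPQ nonresponse, under-reporting, or a multi-stage sampling
frame (weights are i.i.d.).  Passing tests therefore demonstrate the
correctness and directional behaviour of the machinery, not numeric
reproduction of any published cohort's tables.

## Problem sizes and numerical choices

Tests run the generator at n = 60–2000 individuals (sign-recovery checks
at n = 500 and, for energy neutrality, n = 2000 without FPQ holes, since
that check concerns the generator's energy construction rather than
imputation); the law-of-large-numbers rate check uses n = 5000 at 5 %
tolerance.  The Monte-Carlo cross-check of the PANDiet probability uses
10⁶ draws and a 3-standard-error band.  Occurrence counting is validated
against a naive enumeration oracle on 1000 random small menus, exactly.
Equality of totals with component sums is exact (no tolerance); the
scoring grid checks are exact integer arithmetic.  Ties in quartile
assignment are resolved by stable sort order, with a 10⁻⁹ slack at exact
quarter boundaries so equal-weight cohorts partition identically to the
unweighted case.
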