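# Methods

## Molar scoring model

Dietary Hg binds Se in a 1:1 molar ratio as biologically inert HgSe, so a
food's usefulness as a Se source is judged on molar concentrations
(µmol/kg, = mg/kg × 1000 / molar mass, with Se 78.971 and Hg 200.59
g/mol). The Se:Hg molar ratio flags a surplus (>1); the health benefit
value `HBV_Se = (Se − Hg)/Se × (Se + Hg)` (algebraically `Se − Hg²/Se`)
additionally weights the surplus by the combined burden so that foods
with trace Hg do not produce unbounded ratios. Properties relied on (and
property-tested): sign(HBV) = sign(ratio − 1); HBV ≤ Se with equality iff
Hg = 0; strictly decreasing in Hg; scale-equivariant (×k on both
concentrations multiplies HBV by k and fixes the ratio).

Category summaries use the sample SD (n − 1; a deliberate convention,
documented because sources of such tables rarely state it) and compute
ratio/HBV from **unrounded** molar means — recomputing from rounded
printed values shifts the last digit (e.g. an eggs-type category with
molar means 6.486/0.069 yields 6.49 where the unrounded means give 6.48).
A category with zero mean Hg reports the ratio as an `Inf` sentinel and
HBV = Se (the formula limit). Nondetect concentration cells (`<MDL` or
`<value`) are substituted at half the detection limit — a common
exposure-assessment convention; the fraction is configurable and the
flag is retained on every record for auditability.

## Intake assessment

`EDI = C_i × IR_i / BW`: mg/kg × g/day ≡ µg/day, per kg body weight. The
default body weight (13.87 kg) represents the reference preschool child;
per-child mode uses each child's own weight. Se adequacy is expressed
against the EFSA adequate intake for preschool children, AI_Se = 20
µg/day; the **net** adequacy subtracts the Hg intake mass from the Se
intake mass (`EDI_Se − EDI_Hg`). A molar-equivalent subtraction (Hg mass
rescaled by 78.971/200.59, the Se mass one µg of Hg can sequester) is
available but off by default, since published adequacy tables of this
kind are mass-based.

Two mercury reference doses coexist deliberately and are never
interchanged: the JECFA RfD (0.23 µg/kg-BW/day) drives the hazard
quotient `HQ = EDI/RfD` (flagged only when strictly above 1), while the
US EPA RfDs (Hg 0.0001, Se 0.005 mg/kg/day) drive the consumption limits
`CR_lim = RfD × BW / C_i` (g/day). Monthly limits divide by the portion
size, `CR_mm = CR_lim × T / MS` with T = 30.44 days/month — division,
not multiplication, is what the US EPA method prescribes and what makes
the g/day → portions/month units work. Portions follow two conventions:
Taiwan MOHW exchange servings (defaults: fish 35 g, egg 60 g — the two
values anchored by published portion-limit results; other categories
carry conventional exchange portions and are user-overridable) and the
US EPA child fish meal of 65 g (fish rows only).

`servings_to_meet_ai = AI / (C × serving)` returns the exact real value;
a presentation flag applies a ceiling for foods eaten in whole units
("one egg" from 0.64). Nutrient co-profiles are pure per-serving scaling.

## Population vs per-child aggregation

Published tables of this kind are population-level; whether they are
means of per-child EDIs or mean-concentration × mean-intake is usually
not stated. Both modes are exposed (`population_exposure`,
`per_child_exposure`); the population mode (mean × mean at the default
body weight) is what the calibration reproduces. The package calibration
back-solves mean intake rates from the published gross adequacy
percentages and an *exposure-equivalent* Hg concentration per category
from the net percentages, because the published per-category Hg intakes
are not consistent with any single intake rate times the panel's mean Hg
concentration (they were evidently aggregated from item-level data). The
percentage columns are the calibration basis; they are self-consistent
where the µg/day columns carry rounding slack.

## Growth model

LMS z-scores: `z = ((x/M)^L − 1)/(L·S)` (L ≠ 0), `ln(x/M)/S` at L = 0,
implemented via `expm1`/`log1p` so the two branches join smoothly and the
inverse round-trips to ~1e-15 (tested at 1e-9). For weight-based indices
the restricted-tail rule replaces |z| > 3 by linear extrapolation from
the ±2 and ±3 SD reference values (`z* = 3 + (x − SD3)/(SD3 − SD2)`,
symmetric below); it is the standard convention for weight and is
switchable, since some analyses omit it. L, M, S are linearly
interpolated to the child's age in months within sex × measure; ages
outside the table raise rather than extrapolate.

Hair Hg is dichotomized at 1 µg/g, strictly: 1.0 is "low", matching the
"≤1 µg/g" binning convention. Covariate screening fits each candidate
alone against the outcome and keeps p < 0.2 (joint F-test for
categorical candidates, which enter as indicator sets with the first
level as reference); constant candidates are excluded with a warning.
The final model is OLS of the outcome on one food category's net
adequacy percentage plus the screened covariates, one model per food
(matching how such associations are reported per food; a joint model is
a caller-side variation). Intervals are t-based Wald 95% CIs; missing
data are removed listwise with a logged count; rank-deficient designs
raise, naming the collinear columns. A noiseless (saturated) fit reports
a zero-width CI and p = 0.

## Synthetic-data generator

The generator's defaults are the study conditions of the calibration:

- **Food panel**: 108 samples in 11 categories (fish split 9 marine / 4
  freshwater), independent lognormal Se and Hg per category,
  moment-matched (mu = ln(m²/√(s²+m²)), sigma² = ln(1+s²/m²)) to the
  calibrated means ± SDs. Generator masses derive from the published
  molar summary columns (×M/1000), which carry more significant digits
  for dilute plant foods and are the basis of the scores; this preserves
  the published HBV ordering in expectation (fruits negative and last).
  Se–Hg independence within category is an explicit assumption (no
  dependence information exists); a log-scale correlation hook allows
  sensitivity runs.
- **Cohort**: n = 349 by default; ages uniform on [0.5, 5.3] years (mean
  2.9); sex Bernoulli(0.54 male); hair Hg lognormal matched to 1.11 ±
  1.15 µg/g (tail above 1 µg/g ≈ 38% — slightly lighter than the 42.4%
  observed in the real cohort, i.e. real hair Hg is heavier-tailed than
  lognormal; the family is a parameter, not an assertion); income and
  parity multinomial on the survey marginals. Weight and height come
  from inverting the LMS map at each child's age on latent
  standard-normal scores (weight–height correlation 0.5), so z-score
  recovery is exact by construction.
- **Intakes**: gamma per category (CV 0.5 — a typical FFQ-scale
  between-child spread; only adequacy *levels*, not intake spreads, are
  published) around the back-solved calibration means.
- **Outcomes**: linear in the per-category net adequacy percentages with
  caller-supplied true coefficients (defaults +0.01 eggs, +0.01 fish,
  −0.41 fruits per percentage point — the published effect scale), plus
  optional sex/age/Hg-group shifts and Gaussian noise (σ = 0.5 in the
  shipped simulation, putting the eggs effect at roughly one noise SD);
  every generating parameter is recorded in a truth file.

All generators accept a seed and are reproducible to the byte.

What passing tests show — and what they do not: parameter recovery and
CI coverage hold under the generator's assumptions (independent intakes,
correct linear mean model, homoskedastic noise). Real cohorts have
correlated food intakes, confounding through diet patterns, and
measurement error in FFQ and hair assays; recovery there is not implied.

## Numerical and testing choices

- Tolerances: printed-value checks at one unit in the last printed
  decimal; algebraic identities at 1e-8–1e-12; z-score round-trip 1e-9.
- The shipped LMS fixture is a synthetic smooth reference (labelled as
  such), not an official growth standard; official tables in the same
  CSV layout (sex, age_months, measure, L, M, S) drop in unchanged.
- Simulation sizes: 500 replicates of n = 349 for coverage/recovery,
  1000 replicates for the screening-rate property, 2000 samples per
  category for moment recovery, 10⁵ children for the hair-Hg tail —
  sizes chosen so each Monte-Carlo check has sampling error well inside
  its asserted tolerance.
- The SD of a heavy-tailed lognormal sample is itself a noisy estimator
  (rel. SE ≈ √((kurtosis−1)/4n)); SD-recovery assertions use 3 such
  standard errors where mean-recovery uses a flat 3%.

## Known limitations

Total Hg only — no methylmercury speciation, so limits for plant foods
(low MeHg fraction) are conservative. Point-estimate exposure, no
Monte-Carlo uncertainty propagation. No FFQ instrument parsing: the tidy
per-child × category intake table is the input contract. Nutrient
composition values are user input, not a shipped database.
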