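# Methods

`quercinus` re-implements, as a tested pipeline, the quantitative analysis of
a two-decade garden-dormouse (*Eliomys quercinus*) capture-mark-recapture
study: juvenile age and birth-week reconstruction from a growth curve,
size-corrected body-mass comparison between two monitoring periods,
semi-quantitative fecal diet composition, and a hibernation energy-budget
projection. A synthetic-data generator stands in for the field data so that
every stage is testable without any download. This note documents the models,
their assumptions, the defaults that matter, and the limits of what the
synthetic data can show.

## Growth model and age inversion

Juvenile tibia length (TL, mm) over age t (days) follows the Gompertz curve

    TL(t) = a · exp(−b · exp(−c·t))

with asymptote `a` (mm), scale `b` (dimensionless) and rate `c` (1/day). The
reference parameterisation is a = 31.34 mm, b = 1.22, c = 0.07/day
(R² = 0.99), the values obtained from a reference litter of known birth date
measured weekly to 60 days. `fit_gompertz` estimates the parameters by
nonlinear least squares (Levenberg-Marquardt via `scipy.optimize.curve_fit`),
starting from a₀ = 1.05·max TL, b₀ = ln(a₀/min TL), c₀ = 0.05/day, with
standard errors from the local curvature and R² = 1 − SS_res/SS_tot.

The curve is inverted analytically, t(TL) = −(1/c)·ln(−ln(TL/a)/b), valid for
TL strictly between the birth size a·e^(−b) (≈ 9.25 mm) and the asymptote.
Birth dates are the first capture date minus the rounded estimated age; birth
weeks use ISO-8601 week numbering (a juvenile captured 11 Aug 2005 at the TL
of a 34-day-old is assigned birth date 8 Jul 2005, ISO week 27). Each
individual contributes exactly one estimate, from its first capture.

**Calibration cap.** Because the curve is nearly flat past the reference
litter's 60-day measurement span, the inverse there amplifies 0.3 mm of
measurement noise into errors of weeks. `estimate_birth_weeks` therefore
excludes (with a reason-coded report) individuals whose estimated age exceeds
60 days; the cap is configurable (`max_age_days`, `None` disables).

## Birth-peak detection

Weekly birth counts are smoothed with a discrete Gaussian kernel and peaks
are local maxima with (i) prominence at least a fraction of the global
maximum and (ii) a minimum pairwise separation. Defaults: bandwidth 0.5
weeks, prominence fraction 0.1, separation 3 weeks. These were chosen from a
detectability analysis: for two modes 4 weeks apart whose components have
sd 1.5 weeks, any kernel with bandwidth ≥ 1 week yields an effective sd
≥ 1.8 weeks, which merges the modes (the weaker mode's relative prominence
falls to ~2% in expectation), so a light smoother with a low prominence
threshold and a wider separation guard is the only operating point that can
resolve the documented bimodal-vs-unimodal contrast. Even so, with 60
juveniles per cohort the expected inter-peak dip is only ~20% of the peak
height and sampling noise fills it in roughly a quarter of realizations —
cohorts of this size genuinely cannot be classified with near-certainty, and
the package reports detection rates rather than pretending otherwise.
Detection is invariant to uniform scaling of the counts.

TL (age) at first capture is compared between periods with a two-sided
Mann-Whitney U test: the exact null distribution for combined n ≤ 12 without
ties, the tie-corrected normal approximation otherwise.

## Mixed models

All body-mass models are linear mixed models with a single random intercept
per individual (repeated captures of the same animal are correlated;
within-individual temporal autocorrelation beyond the intercept is not
modelled):

* **Adult BM** (per sex): `BM ~ TL + month + period + month:period +
  T_aminhib + site + (1|ID)`, month a five-level factor May-September with
  May/period 1/female reference coding. TL enters as a body-size correction;
  T_aminhib is the preceding winter's median daily-minimum temperature.
* **Juvenile log BM**: `ln BM ~ TL + birth_week + period + (1|ID)`; TL is an
  age proxy, the period-2 offset measures the change in post-weaning mass
  gain, and a back-transform helper reports on the gram scale.
* **Adult TL**: `TL ~ BM + sex + period + month + (1|ID)` — the check that
  body size itself did not change between periods.

Estimation is REML, profiled over the variance ratio λ = σ²_ID/σ²: for fixed
λ the GLS solution and profiled σ² are closed-form, and the scalar criterion
(n−p)·log(r'V⁻¹r) + log|V| + log|X'V⁻¹X| is minimised by a bracketed scalar
search over a log grid, with λ = 0 preferred whenever its criterion ties the
minimum (flat-likelihood designs then reduce exactly to OLS). V⁻¹ is applied
groupwise by the Woodbury identity. Singular fits (zero random-intercept
variance) are reported, not errors. Model formulas are fixed — there is no
model selection — but optional covariates (site, T_aminhib) are dropped with
a warning when absent or constant in the supplied table, since they would
otherwise make the design rank-deficient.

Denominator degrees of freedom for contrasts use the Satterthwaite
approximation: df = 2f²/(g'Σg) with f = c'Cov(β)c, g its gradient in the
variance components and Σ the inverse observed REML information (finite
differences). Where that computation is unavailable (λ at the zero boundary,
singular information), the residual df n − rank − N_ID + 1 is used.

Estimated marginal means average model predictions over a reference grid
spanning every factor, uniformly over non-requested factors, with continuous
covariates at their observed means; grid cells for unobserved combinations
of interacting factors are dropped with a warning rather than extrapolated.
Tukey-adjusted pairwise p-values come from the studentized-range
distribution, P(Q_{k,ν} ≥ √2·|t|), which at k = 2 reduces to the unadjusted
two-sided t-test.

## Diet composition

Residue areas (mm² per category: arthropods, fruits, seeds, blossoms, buds,
leaves, moss, miscellaneous) are converted to percentage shares per sample
(shares sum to 100; miscellaneous holds unassigned area). Monthly summaries
report median and quartiles per stratum, pooling May and June for adults
because of small field sample sizes (adult strata May/June, July, August,
September; juvenile strata July-September). Frequency of occurrence is the
percentage of samples in a stratum with any residue of a category (threshold
area configurable, default strictly positive).

Count models for the main residues use a log-link negative-binomial GLM
(`statsmodels`, NB2, dispersion α estimated by maximum likelihood; Newton
with BFGS/Nelder-Mead fallbacks near the Poisson boundary). Percentage
shares are rounded half-up to integers before entering the count model.
Individual ID can enter only as an optional fixed blocking factor — a
negative-binomial GLM has no random effects. No correction is attempted for
differential digestibility of food items.

## Hibernation energy budget

Fat-storing hibernators spend the October-April window entirely on reserves
accumulated before entry, so the budget is arithmetic on mean masses: total
loss = BM_entry − BM_exit; daily loss = total/duration; relative daily loss
= 100·(daily loss)/BM_entry. The window is fixed at 1 October - 30 April and
counted inclusively with February always taken as 28 days (212 days), the
only convention consistent with the published chain (39 g over the window →
0.18 g/day). Rates are rounded half-up at two decimals, and the relative
rate uses the rounded daily rate (0.18/105.1 → 0.17%/day). A pre-hibernation
deficit of d grams depletes reserves d/(unrounded daily loss) days earlier,
rounded to the nearest day (10 g → 54 days, projecting emergence on 7 March
of a non-leap spring). Torpor-arousal dynamics, fatty-acid composition and
temperature-dependent consumption are outside the model.

## Synthetic data generator

The generator emulates the study design: two periods (capture years
2003-2005 and 2018-2021), three sites with period-specific weights (one site
is occupied only in period 1, another only in period 2), monthly capture
occasions May-October on the 15th with detection probability 0.75, and
measurements rounded as in the field protocol (BM to 1 g, TL to 0.1 mm;
`round_measurements=False` gives the exact model values for estimator
round-trip checks). Defaults per period: 60 juveniles and 30 adults.

* **Birth weeks**: truncated discrete Gaussian mixtures — period 1
  equal-weight components at ISO weeks 23 and 27 (sd 1.5, support 22-35),
  period 2 a single component at week 25 (sd 2, support 18-32). The real
  distributional family is unknown; only the peaks and ranges are documented.
* **Juvenile growth**: TL on the reference Gompertz curve at age-at-capture
  plus 0.3 mm noise; juveniles enter the capturable pool at 30 days (nest
  exit). Juvenile BM follows ln BM = −0.32 + 0.11·TL + 0.03·birth_week −
  0.23·[period 2] plus an individual intercept (sd 0.04) and residual
  (sd 0.05) on the log scale.
* **Adult BM**: a sex × month × period mean table anchored at the published
  September means (male 105.1/91.8 g, female 85.5/75.5 g) and the published
  May/July cells; unpublished cells are smooth seasonal interpolations with
  fattening starting in August. Individual TL ~ N(31.7, 0.9²) for females
  and N(32.8, 0.9²) for males, entering BM with a 1 g/mm slope centred at
  the sex mean; random-intercept sd 3 g, residual sd 4 g (free parameters —
  the study does not report within-individual correlation).
* **Diet**: per month × age-class Dirichlet compositions (total
  concentration 8) whose expected arthropod share tracks the field pattern
  (~25% for adults rising to 61% in September; ~50% for juveniles); residues
  below a 0.5 mm² detection floor go unrecorded, so categories can be
  genuinely absent from a sample.
* **Temperature**: a sinusoidal annual cycle of daily minima (mean 4 °C,
  amplitude 8 °C, warmest mid-July) with Gaussian noise (sd 3 °C).

Identical seeds give identical output; changing the seed changes draws but
not structure. What the generator does **not** emulate: survival and
mortality, dispersal, trap response, within-season temperature weather
systems, overdispersed litter-level birth clustering, and digestibility
biases in fecal residues. Passing tests on synthetic data therefore show
that the estimators recover the data-generating process they assume — not
that the field data satisfy those assumptions.

## Problem sizes and numerics

The test suite and the acceptance script run everything at modest sizes
chosen to keep the stochastic checks tight but fast: 200 replicate litters
for growth-parameter recovery, 50 cohorts of 60 juveniles for the birth-peak
pattern, 150 juveniles per period for mixed-model coefficient recovery, and
~300 fecal samples for composition summaries. REML uses a 57-point log grid
plus bounded scalar refinement (xatol 1e-10); the nonlinear growth fit uses
tolerance 1e-8 with at most 200 iterations; share rounding is half-up;
day-shift rounding is to the nearest day. Degenerate inputs (constant TL,
all-zero counts, single individuals, empty hibernation windows) raise typed
errors rather than returning numbers.
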