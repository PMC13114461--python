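# Methods

## The model

`motorprof` analyzes domain-specific motor competence in primary-school
children. Each child is assessed on three MABC-2 domains — manual dexterity,
aiming–catching and balance — yielding age-adjusted standard scores on a
1–19 scale (population mean 10, SD 3). Children are nested in classes, and
the scientific questions concern (a) domain differences and their
moderation by sex and age and (b) how much of the variability in scores is
contextual, i.e. attributable to the class a child attends.

The score of child *s* in class *c* on domain row *i* follows a two-level
random-slope linear mixed model

y_csi = x'_csi β + z'_i b_c + z'_i b_s + ε_csi,

where z_i = (1, 1[aiming–catching], 1[balance]) with manual dexterity as
the reference domain, b_c ~ N(0, Σ_class) and b_s ~ N(0, Σ_student) are
3×3 general positive-definite covariances (overall level plus
domain-profile slopes at each grouping level), and ε ~ N(0, σ²) iid. The
random-effect reference level is arbitrary: any re-coding of z yields the
same marginal covariance. An optional school-level random intercept extends
the model to three levels for the school test in the selection chain.

The fixed design uses sum coding for domain and sex (so Type III tests are
meaningful), with the convention that the last factor level (balance;
girl) carries the −1 row. Age enters either grand-mean centered
(`age_c`) or decomposed into a between-class part (the class mean age,
grand-mean centered) and a within-class part (each child's deviation from
the class mean, computed over unique children, not domain rows). The
decomposition separates the individual-level age gradient from the
contextual one; pooling the two can mask a within-class association when
the between-class association has opposite sign (a suppression effect).

## Estimation

The likelihood is marginal Gaussian and factorizes over classes (schools,
when a school intercept is present). Covariances are parametrized relative
to σ² through the Log-Cholesky scheme — the lower Cholesky factor with its
diagonal stored on the log scale — which makes the optimization
unconstrained; β and σ² are profiled out, leaving at most 13 free
parameters. Every class of the same size shares the same marginal
covariance block, so one likelihood evaluation needs one Cholesky
factorization per distinct class size (two, in the study layout).

REML uses the Harville error-contrast form, which includes the
+½log|XᵀX| term and is therefore exactly invariant under invertible
reparametrization of the fixed design. Mixed-model software that omits the
term differs by a data-independent additive constant; likelihood-ratio
statistics and information-criterion differences are unaffected, but
absolute log-likelihood values are comparable only within one convention.

Optimization is quasi-Newton (L-BFGS-B) with box bounds of ±8 on the log
diagonals, a relative function tolerance of 1e-12, and three documented
starting points: a moment-based guess from OLS residual variance at each
grouping level, zeros (unit relative covariances), and the moment guess
perturbed. Simulation loops (parametric bootstrap, calibration studies)
refit with a single start — the moment start for fresh cohorts, or a warm
start at the generating covariance parameters when simulating from a fit —
since the REML surface for this block structure is well-behaved and the
extra starts only guard against rare pathologies. Non-convergence is
flagged on the result and simulation refits that fail are excluded with a
logged count.

### A non-identifiability inherent to the design

Each child contributes each domain exactly once, so the 3×3 random-effect
design Z per student is an invertible matrix. Consequently
(Σ_student + δ·M, σ² − δ) with M = Z⁻¹Z⁻ᵀ produces an *identical* marginal
covariance for every admissible δ: the likelihood has an exactly flat
one-dimensional ridge. Identified quantities are β, its covariance, all
Wald tests, Σ_class, and the per-student marginal covariance
ZΣ_studentZᵀ + σ²I; the split of the latter into student-level components
and a residual — and hence σ itself, and the individual student-level and
residual variance *shares* — is resolved only by where the optimizer stops
on the ridge. The reported decomposition table should be read with this in
mind: class-level shares and the class-vs-rest split are meaningful, the
fine split within the student+residual block is conventional. The same
caveat applies to any software fitting this structure to one-observation-
per-domain data. Parameter-recovery tests accordingly assess bias on the
identified functionals only.

## Inference

* **Type III Wald F** per term, F = (Lβ̂)ᵀ(L Ĉ Lᵀ)⁻¹(Lβ̂)/q with L selecting
  the term's sum-coded columns. Denominator df follow the containment
  (inner–outer) rule: terms varying within students (anything involving
  domain) get n_obs − n_students − p_obs; student-level terms (sex,
  within-class or combined age) get n_students − n_classes − p_stu;
  class-level terms (between-class age) get n_classes − 1 − p_class, where
  p_• counts the non-intercept fixed columns at that level. On the study
  layout (936/312/31, final model) this yields 620, 279 and 29.
* **Partial η²** = F·q/(F·q + df_den), with a 95% two-sided confidence
  interval from noncentral-F inversion mapped through
  λ/(λ + df_num + df_den + 1).
* **Cohen's d** for model contrasts is 2t/√df — a standardization against
  the total multilevel variance pooled across levels.
* **Marginal means and contrasts** are linear combinations of β̂ at factor
  cells with covariates at their (centered) means, averaging with equal
  weights over unspecified factors. Families of contrasts are adjusted by
  single-step max-|t| under the joint multivariate t (Monte Carlo, 10⁵
  seeded draws, df = the family minimum) refined by free step-down;
  monotonicity and p_adj ≥ p_raw are enforced. This approximates the exact
  truncated closed-testing scheme, which is a non-goal; at 10⁵ draws the
  Monte-Carlo error on adjusted p values is ~10⁻³.
* **R²** (marginal/conditional) uses the variance-partition form with the
  random-slope extension: the random-effect contribution is the mean over
  observations of zᵀΣ̂z at each level.
* **Pseudo-R²** for the fixed effects against an intercept-only null with
  the same random structure (both ML): Cox–Snell 1 − exp(−LRT/n) as the
  primary form, with the Nagelkerke normalization also reported.
* **Variance decomposition**: shares of each of the six random-effect
  variances and σ² in their total; the variance partition coefficient at
  the grand mean uses intercept variances only,
  VPC = σ²_class,int /(σ²_class,int + σ²_student,int + σ²). Shares and VPC
  are invariant to rescaling the response.
* **Empirical-Bayes class profiles**: BLUPs b̂_c = Σ̂_class Z_cᵀ V_c⁻¹
  (y_c − X_c β̂) with conditional covariance Σ̂ − Σ̂ZᵀV⁻¹ZΣ̂; a class is
  flagged when |b̂| > 1.96 × posterior SD, and the caterpillar table carries
  95% prediction intervals sorted by intercept.
* **Diagnostics**: the Breusch–Pagan statistic is computed on *studentized
  conditional* residuals (ε̂ = σ̂²V̂⁻¹r scaled by their model-implied SDs)
  regressed on the fixed design. Marginal residuals are heteroscedastic by
  construction under random slopes, so a homoscedasticity check must remove
  the random-effect variance first; with studentization the test is
  calibrated (rejection at the nominal rate on model-generated cohorts,
  checked by simulation in the test suite). Generalized VIFs per term come
  from determinant ratios of the
  fixed-design correlation matrix, reported raw and as gVIF^(1/2df).

## Model selection chain

Sequential ML likelihood-ratio tests at α = 0.05, mirroring the study
workflow: (1) class random intercept over student-only structure; (2) full
class-level domain slopes over the intercept; (3) a school-level random
intercept (dropped if not supported); (4) pruning of the three-way
domain × age × sex and age × sex interactions, then domain × age; (5) the
within/between decomposition of age against combined age — a one-df test,
since the combined model is the constraint β_within = β_between. The
random-structure comparisons use the pruned seven-column fixed set
(intercept, domain, sex, domain × sex, combined age), which keeps the
comparison-table parameter counts at 14/15/20 with the final decomposed
model at 21. The final model is refit by REML before inference.

## Parametric-bootstrap power and MDES

For a fixed term and a grid of coefficient values, each iteration simulates
a response from the fitted model — class- and student-level effects drawn
from their estimated 3×3 normals, residual noise added, the term's
coefficient replaced by the grid value (multi-column terms scale along the
fitted coefficient direction) — refits by REML from a warm start, and
records the Type III p value and partial η². Rejection proportions trace
the power curve; the minimum detectable effect size at 80% power is
linearly interpolated between the bracketing grid points, both on the
coefficient scale and on the η² scale (per-point medians over significant
iterations, interpolated at the same abscissa; both raw series are exported
so alternative readings can be recomputed). A significant observed effect
whose η² falls below its MDES is flagged as a Type-M (exaggeration) risk
with the ratio MDES/observed. Default grid: 12 points from 0 to 3× the
observed coefficient magnitude (or 4 SE when the observed coefficient is
negligible). Grid points with more than 10% refit failures are visible in
the exported failure counts.

## Synthetic cohorts

The generator emulates the study conditions: 31 classes (23 of size 8, 8 of
size 16; 312 children, 936 scores) distributed over 14 schools, sexes
alternating within class (balanced to within one child), class mean ages
drawn with SD 1.71 y around age 9 and child ages around their class mean
with SD 0.5 y, both truncated to the eligible 6–12-y range (the within-class
age spread is not published; 0.5 y reflects single-grade classrooms with
mixed birth months). Variance magnitudes derive from the published
decomposition: σ = 0.95 at a residual share of 7.8% fixes the total
T = σ²/0.078 ≈ 11.57; class-level variances are T × (0.089, 0.079, 0.063)
and student-level T × (0.254, 0.212, 0.224), with class-level correlations
(0.49, 0.35, −0.26), student AC–balance correlation −0.58 and unpublished
student intercept–slope correlations set to 0 (configurable). Fixed-effect
defaults are chosen once from the descriptive table (grand intercept 9.8;
domain offsets −2.2/+0.8/+1.4; small sex and domain × sex offsets) and the
reported age slopes (−0.495 within, +0.132 between). Scores are continuous
by default (`round_scores` mimics integer standard scores at the cost of an
exact likelihood).

What the generator does *not* emulate: the discreteness and skew of real
standard scores, norm-table percentile granularity, school-level effects
(the study found none), missingness (the study had none), and any
dependence of class composition on unmeasured context. Passing tests
therefore demonstrate correctness of the machinery under the model, not
robustness to real-data deviations from it.

## Simulation sizes and test calibration

The heavier checks use sizes chosen to balance Monte-Carlo resolution
against a desk-scale run: 200 cohorts for parameter recovery (bias bands at
z = 2.81 per quantity, ~20 simultaneous quantities; Wald coverage pooled
over the 8 fixed effects against 92–98%), 1,000 fresh cohorts for the
null calibration of the Type III test (binomial 95% band around 0.05),
150 cohorts for the homoscedasticity-diagnostic calibration, 150
iterations per grid point for the shared power curve and 200 at the
interpolated MDES coefficient (self-consistency band ±7 points around
80%). All simulations are seeded and reproducible.

## Numerical choices

* Convergence: L-BFGS-B `ftol` 1e-12 (relative), `gtol` 1e-6; the RSS is
  floored at 1e-300 to keep degenerate zero-variance data finite.
* Covariances at the PSD boundary are representable (log-diagonals bounded
  at −8, i.e. relative SDs ~3×10⁻⁴).
* Zone boundaries: red ≤ 5th percentile < amber ≤ 15th percentile < green;
  ties at the cut-points go to the more severe zone.
* When the percentile column is absent, percentiles use the normal
  approximation 100·Φ((ss − 10)/3); MABC-2 norm tables are proprietary, and
  the approximation preserves ordering and the approximate cut-points.
* Median confidence intervals in the descriptive table use a seeded
  percentile bootstrap (1,000 resamples, 95%).
* Singleton-child classes are allowed (age_within = 0); singleton cells in
  descriptives report an undefined SD rather than an error.

## Known limitations

* Containment df are the only denominator-df method (Satterthwaite and
  Kenward–Roger are out of scope), matching the study's software.
* The Westfall adjustment is the max-t + free step-down approximation, not
  exact truncated closed testing.
* The student/residual variance split is non-identified (see above).
* Crossed random effects, more than three grouping levels and
  non-Gaussian responses are out of scope, as are raw MABC-2 item scoring
  and norm-table reproduction.
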