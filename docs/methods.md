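# Methods

## The inferential model

The pipeline tests, for each outcome variable *y* in a panel of epigenetic
markers, the null hypothesis that a binary exposure carries no information
about *y* beyond a block of covariates.  Rather than a parametric
(M)ANCOVA — untenable here because the outcomes are heavily right-skewed
with heterogeneous variances, several covariates differ between groups, the
covariate block is collinear, relationships may be nonlinear, and *n* (98)
is small relative to the number of covariates — the evidence is the
*incremental out-of-sample predictive value* of the exposure:

* For a regressor family *f*, compute the leave-one-out cross-validated
  R² of the covariates-only model and of the covariates-plus-exposure
  model.  R² uses the full-sample mean in its denominator,
  R² = 1 − Σ(yᵢ − ŷ₍₋ᵢ₎)²/Σ(yᵢ − ȳ)², and is therefore negative whenever
  the model predicts worse than the mean — the expected outcome for a
  useless model evaluated out of sample, and the honest baseline for an
  overparameterized fit at small *n*.
* The statistic is ΔR² = R²(full) − R²(baseline).  Its null distribution is
  generated by refitting the full model under uniform random permutations of
  the exposure vector, which preserves both group sizes and the entire
  covariate structure and requires only exchangeability of labels under the
  null.
* The empirical p-value uses the add-one rule, p = (#{Δᵦ ≥ Δobs} + 1)/(B+1).
  It can never be zero; its floor at B = 999 is 1/1000, consistent with
  "<0.001" reporting at B = 10⁴.  Ties count toward the numerator
  (conservative), with a 10⁻¹² tolerance absorbing float jitter so that
  exact relabel symmetries hold.
* Family-wise adjustment across the m outcome variables is plain Bonferroni,
  min(1, p·m), applied within each regressor family.  Although step-down
  Holm is the more powerful standard, the published base/adjusted pairs this
  package anchors to (e.g. 0.016 → 0.128 with m = 8) are exact ×m products,
  so Bonferroni is the default and Holm is available behind
  `adjust_pvalues(..., method="holm")` and the CLI `--adjust holm` switch.

Since the baseline R² is a constant offset within one outcome, counting
Δᵦ ≥ Δobs is equivalent to counting permuted full-model R² ≥ observed
full-model R²; the baseline is still computed and reported because the
observed ΔR² is itself a quantity of interest.  Result objects carry both
ΔR² against the covariates-only baseline (the test statistic) and the
full-model R² minus the mean permuted R² (the increment conventionally
printed in summary tables); the two differ, and reporting both removes the
ambiguity.

### Regressors

Four families are supported: ordinary least squares as a reference and
three ensemble tree regressors (random forest, extremely randomized trees,
gradient boosting) chosen for robustness to collinearity and nonlinearity.
Defaults: 100 trees for each ensemble, unconstrained depth for the two
forests, depth 3 with learning rate 0.1 for gradient boosting, and a fixed
fit seed.  Tree regressors see the covariates untransformed (they are
scale-free); the linear pipeline standardizes columns on each training fold
only — a transformation that provably does not change OLS predictions, kept
so that the fitted pipeline matches what it claims to be.

For the linear family, LOOCV predictions come from the exact leave-one-out
identity ŷ₍₋ᵢ₎ = yᵢ − eᵢ/(1 − hᵢᵢ), with leverages and residuals obtained
from a rank-truncated SVD of the design matrix so that collinear
(rank-deficient) designs behave exactly like scikit-learn's least-squares
solution; the identity is verified against explicit per-fold refits in the
tests, including a duplicated-column design.  If any leverage reaches 1 the
code falls back to the explicit loop.  This closed form is what makes
thousand-permutation × LOOCV runs interactive.  Tree families use an
explicit `LeaveOneOut` loop.

Permutation draws are generated once per outcome and shared across
regressor families, so every family is evaluated against the identical set
of null labelings.  An exhaustive mode enumerates all C(n, k) distinct
label arrangements (feasible for n ≲ 15) and returns the exact permutation
p-value with the observed arrangement included.

## The descriptive battery

Normality is assessed per group by Shapiro–Wilk; a variable is compared
with Welch's unequal-variance t-test only when normality is rejected in
*neither* group at 0.05, otherwise with the two-sided Mann–Whitney U test.
The Mann–Whitney implementation is the asymptotic normal approximation with
midranks over ties, tie-corrected variance and a 0.5 continuity correction
— the combination that reproduces published questionnaire p-values from
reconstructed counts; the exact distribution is deliberately not used
(tests verify the asymptotic p is within 0.02 of full enumeration on small
cases).  Ordinal questionnaire variables are ranks by construction and
always use Mann–Whitney regardless of their normality verdict.  Degenerate
ordinal data with every observation in one shared category yield p = 1 with
a warning.  Summaries report mean, median, SD (ddof = 1) and IQR = Q3 − Q1
with linear-interpolation quantiles (the printed tables do not state their
quantile convention; this is the numpy default).

Spearman matrices are computed per group over all covariates and outcomes
(group-restricted columns only within their group), with three significance
tiers (0.05, 0.01, 0.001) from the t-approximation p-values and no
within-matrix multiplicity adjustment, matching how such matrices are
conventionally flagged.  Constant columns produce undefined correlations,
reported as missing.

`reconstruct_counts` inverts printed percentage rows to integer counts by
half-up rounding of p·n/100 and warns when the counts cannot re-produce the
printed row — which happens for rows whose printed percentages do not sum
to 100.

## The synthetic cohort generator

The generator emulates the data structure of a 48 + 50 case–control study:

* **Marginals.** Each covariate/outcome has per-group parameters.
  Continuous variables are normal or lognormal; lognormal parameters are
  moment-matched (σ² = ln(1 + (s/m)²), μ = ln m − σ²/2) so the configured
  mean and SD are the *distribution's* mean and SD.  Ordinal variables are
  drawn from per-group category probabilities on their stated coding.
  Variables whose published normality tests fail decisively (triglycerides,
  CRP, the smoking quantities, and all eight epigenetic outcomes) default
  to lognormal; symmetric laboratory values default to normal.
* **Correlation blocks.** Covariates sharing a block id are drawn through an
  exchangeable Gaussian copula.  The block parameter is the target
  *Spearman* correlation (default 0.8); the latent Gaussian correlation is
  2 sin(πρ/6), so continuous block members reach the target rank correlation
  up to Monte-Carlo error (ordinal members attenuate it through
  discretization).  Two default blocks reproduce the observed clusters:
  height/weight/BMI and the four smoking variables.
* **Group-restricted columns.** CD3/CD4/CD8 lymphocyte counts exist only in
  the exposed group and carry NA elsewhere; they are summarized per group
  and excluded from the association covariate block by default.
* **Outcomes.** Drawn independently of the covariates given the group
  label.  The default outcome panel uses the published per-group means and
  SDs for all eight markers.
* **Roster size.** The default roster is 10 ordinal + 18 continuous
  covariates (the published enumeration); inert standard-normal covariates
  can pad the roster (e.g. to 32) since the full covariate list of the
  original analysis is not enumerated anywhere.
* **Ct-level simulation.** `simulate_medip_ct` and `simulate_expression_ct`
  invert the quantification formulas, adding zero-mean Gaussian Ct noise to
  the measured aliquot.  At zero noise the round trip through the
  quantification stage is exact to 10⁻⁹ relative; with noise, the mean
  quantified recovery is inflated by the lognormal factor E[2^−ε], which
  the tests pin against a direct Monte-Carlo oracle.

What the generator does **not** emulate: the real participants' joint
distribution beyond marginals and block structure, covariate–outcome
dependence (unless a study effect links outcome to group), missingness
beyond the restricted columns, viral-load dynamics or treatment history,
and the arithmetic inconsistencies of some printed percentage rows (rows
are renormalized to sum to 1).  Consequently, passing tests demonstrate the
*procedure's* statistical behaviour — calibration, power at published
effect sizes, invariances — not recovery of the original study's exact R²
values, which additionally depend on unpublished participant data and
hyperparameters.

## Numerical and design choices

* Determinism: every stochastic step flows from `numpy.random.default_rng`
  seeded from explicit arguments; identical (config, seed) reproduces
  byte-identical cohort CSVs and identical analysis results.
* Permutations are uniform over orderings of the observed exposure vector,
  equivalently uniform over label assignments with fixed group sizes.
* Percent recovery is not capped at 100: enrichment assays legitimately
  exceed the input aliquot (one published locus has a group mean near 60%
  of input with a long right tail), so values > 100 pass through with a
  warning at the plate-quantification stage.
* Technical replicate wells sharing (sample, assay, role) are averaged on
  Ct scale by the plate reader; downstream, duplicate (sample, gene)
  records are an error.
* Report TSVs round to 3 decimals for display; cohort CSVs and manifests
  keep full precision.
* Problem sizes in the test suite are scaled to what the checks need:
  calibration suites use 150–200 replicates at B = 99–199 with the linear
  family (whose closed-form LOOCV makes them cheap), tree-family checks use
  small n with reduced tree counts, and the headline power check runs 50
  replicates at B = 999.

## Known limitations

* The ensemble families' published hyperparameters are unknown; with
  defaults the original R² values are not reproducible, only the
  procedure's behaviour.
* The asymptotic Mann–Whitney approximation is used at all sample sizes; at
  very small n the exact test would differ (bounded at 0.02 in tests for
  3+3 cases).
* The Gaussian copula fixes a single within-block correlation; real blocks
  (e.g. BMI vs weight) are heterogeneous.
* LOOCV at n near 100 with 10⁴ permutations under the tree families is
  computationally heavy (≈10⁶ model fits per outcome × family); the linear
  family is the practical screening tool at that scale.
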