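# Methods

This note documents the simulation model behind `phacksim`: what the
synthetic data represent, how each p-hacking strategy is operationalized,
the numerical conventions, and the design choices made where the underlying
procedures are genuinely under-specified in the literature.

## The simulation model

All severity estimates are Monte-Carlo estimates of

P(at least one candidate test significant at level α | no true effect),

the family-wise false-positive rate of a researcher who computes a batch of
undisclosed analyses and needs only one of them to cross the threshold.
Data are always generated under the global null — equal group means, zero
regression slope — so every significant result is a false positive by
construction, and the estimate is a binomial proportion with standard
error √(p̂(1−p̂)/iterations), which the package reports alongside every
rate.

Two design families cover the strategies: a two-group design (N per group,
k standardized outcomes, optional covariates and incidental binary
grouping variables) analyzed by independent-samples t tests, and a
univariate regression design (total n, predictor x, outcome y, optionally
a k-item scale whose row mean forms one of the variables). Defaults follow
the conventions of the p-hacking simulation literature: α = 0.05,
two-sided tests, N ∈ {30, 50, 100, 300}, 10,000 iterations per reporting
strategy per condition.

### Synthetic data

All correlated blocks (multiple DVs, candidate predictors, covariates,
scale items) are drawn multivariate normal with **compound-symmetric**
correlation (a single r per block) and standard-normal margins, realised
through the one-factor representation X_j = √r·Z₀ + √(1−r)·Z_j, or through
an eigenvalue factor of the joint (DV, covariate) correlation matrix when
cross-block correlations (r_ZY) are requested; non-positive-semi-definite
requests are rejected up front. Missingness is MCAR: each entry of x and y
is masked independently with probability ρ (which variables receive
missingness is configurable; both by default). Incidental grouping
variables are fair Bernoulli draws per participant, so subgroup sizes vary
as they would in practice.

What the generator deliberately does **not** emulate: non-normal or
heteroscedastic populations, unequal experimental group sizes, MAR/MNAR
missingness, and measurement error beyond the item model. Passing tests
therefore certify the behaviour of the *procedures* under ideal
assumptions — the inflation measured here is attributable to multiplicity
alone, not to assumption violations in the data. Real-data severity can be
higher (e.g. skewed populations interact with outlier rules).

### Randomness and reproducibility

Every source of randomness flows from one integer seed through
hierarchical streams `(seed, path)` implemented with numpy `SeedSequence`
spawn keys. A stream is a pure function of its path — generating cell 3,
iteration 400 never depends on what else was computed — which gives
bit-identical reruns, embarrassingly parallel semantics, and **common
random numbers** where they matter: `compare_alpha` replays the identical
stream at every significance level, so "FP(0.005) < FP(0.05)" is observed
as an exact, per-dataset dominance rather than a noisy contrast, and the
invariance of the success rate to the reporting rule is exact by
construction.

## Strategy-specific conventions

**Candidate order.** "First significant" is defined by a deterministic
trying order (column order for DVs/IVs, ladder order for thresholds,
registry order for tests). Order affects the reported-p distribution,
never the success rate.

**Degenerate tests** (zero variance, undersized cells, rank deficiency)
are skipped and counted, never treated as significant.

**Optional stopping (s3)** peeks at N_min, then every `step` added
observations per group, and finally at N_max (exactly two peeks when the
step exceeds the range); the candidate list ends at the first significant
peek, since later looks never happen.

**Outlier exclusion (s4).** The roster of 12 detection techniques is a
declared registry (the simulation literature enumerates dozens; this set
spans the families relevant to a univariate regression): SD-from-mean,
boxplot/IQR fences, MAD robust z, percentile cut (univariate, applied per
variable); standardized and externally studentized residuals, leverage,
Cook's distance, DFFITS, DFBETAS of the slope, covariance ratio
(regression influence); and Mahalanobis distance on (x, y). Cut-offs are
textbook defaults (e.g. Cook's D > 4/n then 1.0, |DFFITS| > 2√(k/n),
hat values > 2k/n then 3k/n, χ²₂ quantiles 0.975/0.99/0.999). "Subjective
threshold setting" is an escalation ladder: start lenient (e.g. 2.0 SD)
and tighten stepwise (+0.5 SD, or ×1.25 for the size-adjusted measures)
until nothing is flagged; each non-empty rung yields candidate exclusions
(drop x-flagged rows, y-flagged rows, or rows flagged in either variable;
one candidate per rung for joint measures). Exclusion is single-step —
flags always come from the original data, never re-detected on reduced
data — duplicated exclusion sets are tested once, and candidates leaving
fewer than 4 observations are dropped. IQR quartiles use linear (type-7)
interpolation; quartile dialects change flags, so the convention is fixed
and stated.

**Covariates (s5).** After the planned t test, each covariate enters
singly, then sequentially in decreasing order of sample |corr(Z, DV)|
(the one-covariate sequential model duplicates the best single model and
is dropped): k covariates produce 2k − 1 additional tests — five for
k = 3. The group effect is tested on its coefficient in the full linear
model (equivalent to a type-III test in this design). Exhaustive covariate
subsets are deliberately out of scope: the simulated researcher does not
automate a combinatorial search.

**Scale redefinition (s6)** deletes greedily the item whose removal
maximizes Cronbach's alpha (ties broken at the lowest index), re-testing
after each deletion with both the reduced-scale mean and the deleted item
alone as predictor, stopping at two remaining items.

**Transformation (s7).** Candidates are log, reciprocal and square root
applied to x, y, or both. Standard-normal variables are not positive, and
the convention for meeting that problem drives the severity of this
strategy, so it is an explicit parameter. Default (`positivity="drop"`):
values where the transform is undefined (log/√ of non-positives) become
missing and the candidate analysis runs on the subset where it exists —
the candidates then differ from the planned analysis in both scale and
analyzed subset, residual normality is genuinely violated, and the
strategy is severe (~30% at n = 30, declining with n). Alternative
(`positivity="shift"`): translate the variable so its minimum maps to 1
first; the transforms are then nearly affine over the observed range, the
candidates nearly duplicate the planned test, and severity stays near
10–15%. The optional normality gate transforms only when a Shapiro–Wilk
test on the planned fit's residuals is significant at 0.05; on normal data
this closes the door in 95% of samples and removes most of the inflation.

**Alternative tests (s9)** runs Student, Welch, Wilcoxon rank-sum (normal
approximation with continuity and tie correction — group sizes in all
simulated grids make the exact distribution unnecessary) and Yuen's
trimmed-means test at trims {0.1, 0.15, 0.2, 0.25} (trimmed means,
winsorized variances, Welch-type df; ⌊trim·n⌋ removed per tail; trim = 0
reduces exactly to Welch).

**Imputation (s10).** A declared registry of 10 methods spanning the usual
families: listwise deletion, mean, median, hot deck, deterministic and
stochastic regression imputation, predictive mean matching, 5-NN mean on
the companion variable, EM under bivariate normality (tolerance 10⁻⁶, max
200 iterations, conditional-mean completion), and multiple imputation
collapsed to the mean of m = 5 stochastic-regression completions — the
strategy needs one p-value per candidate, so Rubin's-rules pooling is
intentionally not performed. The planned analysis is the listwise-deletion
regression; each sampled method contributes one re-analysis. Observed
values are never modified.

**Subgroup analyses (s11)** re-runs the t test within each level of every
binary grouping variable; a subgroup test with any cell below 3
observations is skipped (a t test needs 2 per cell; the guard avoids
counting noise from 2-observation cells).

**Incorrect rounding (s12)** is analytic: reporting any α ≤ p < level as
significant makes the effective type I rate equal the level exactly
(0.051, 0.06 for the two conventional levels); within workflows it is
applied at every stage and the share of successes that required rounding
is tracked.

**Method subsampling** (s4, s10) models limited researcher knowledge:
k methods drawn uniformly without replacement, fresh per iteration.

## Reporting strategies and diagnostics

`select_report` implements first-significant, smallest, and
smallest-significant (reverting to the planned test when nothing is
significant). The p-curve uses ten 0.01-wide bins over (0, 0.1] with the
*full* set of reported p-values as denominator, so bins sum to
P(p ≤ 0.1). Effect sizes are Cohen's d with the pooled SD (no small-sample
correction, matching how these distributions are usually displayed) and
R²; the reported effect belongs to the *selected* candidate, which may
have a reduced n after exclusions.

The JZS Bayes factor for the two-sample t test places a Cauchy(0, r) prior
on the standardized effect (default r = √2/2, the "medium" default of
standard Bayes-factor software, exposed as a parameter) and a Jeffreys
prior on the variance; BF₁₀ is evaluated by adaptive quadrature of the
scaled-likelihood mixture over the inverse-gamma(½, r²/2) representation
of the Cauchy, relative tolerance 10⁻⁶, with effective N = n₁n₂/(n₁+n₂)
and ν = n₁+n₂−2. The test suite verifies it against two independent
routes: a dense-grid trapezoid of the same integrand under a tangent
substitution, and a mathematically distinct mixture of the noncentral-t
likelihood over the Cauchy prior.

## Built-in workflow scenarios

Both scenarios run at N = 100 with incorrect rounding at p < 0.051 at
every stage, medium aggressiveness throughout. The t-test scenario chains
three alternative tests (Welch, Wilcoxon, Yuen 0.2 — the specific trio is
configurable), five DVs at r = 0.6, three covariates at r_Z = r_ZY = 0.3,
and three grouping variables. The regression scenario chains five random
imputation methods on 10% MCAR data, then (after listwise deletion)
unconditional transformations, up to three deletions from a five-item
scale, and three random outlier techniques. The scale's item correlation
is fixed at r = 0.3 (the lower of the two values used in the solo
scale-redefinition grids — a deliberately modest choice). In this scenario
the scale is the *outcome*; the slope test's p-value is symmetric in
(predictor, outcome), so the scale-redefinition op is reused with the
roles swapped without changing any p-value. Workflows stop at the first
successful stage; cumulative rates are non-decreasing by construction and
each stage's increment is smaller than that strategy's solo severity,
because earlier stages have already harvested the easy successes.

## Problem sizes

Default grids use 10,000 iterations per reporting rule per cell, the
convention of this simulation literature; the test suite uses 10,000
iterations for its headline severity checks and 1,500–4,000 for ordering
and flatness checks, with binomial 3-SE tolerances computed at the
iteration count actually used. The acceptance script runs every condition
at 10,000 iterations.

## Known limitations

- Severity figures are conditional on the declared rosters and cut-offs
  (outlier techniques, imputation methods); both are registries, so
  swapping in a different roster is a configuration change, not a rewrite.
- The normal-approximation Wilcoxon differs from the exact test below
  n ≈ 10 per group; the simulated grids never go there.
- Bayes factors are computed only for two-group t statistics; regression
  candidates report R² instead.
- ANCOVA candidates report no standardized effect size (partial η² is out
  of scope).
- The p-curve is descriptive; no p-hacking *detection* inference (right-
  skew tests, Caliper test, Fisher's method) is implemented.
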