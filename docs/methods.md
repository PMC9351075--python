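# Methods

## The model

`profilemix` fits latent profile models: finite mixtures of multivariate
normals over J continuous indicators with conditional independence
within class and **pooled variances** (one residual variance per
indicator, shared by all classes),

    f(y_i) = Σ_c π_c Π_j N(y_ij; μ_cj, σ_j²),   Σ_c π_c = 1.

Subjects are assumed exchangeable complete cases; indicators are
typically z-scored within sample before fitting, so μ_cj reads as a
class's position in within-sample SD units. The package targets small
samples (n ≲ 150), where the central difficulties are multimodal
likelihoods, boundary solutions, and too many free parameters; its
three levers are mean restrictions, multistart mode diagnostics, and
multi-criteria evaluation.

### Mean restrictions

Two restriction types reduce the free-parameter count:

* **Fixed (reference) classes.** A class's entire mean vector is pinned
  to constants — canonically a "low average" class at −0.5 on every
  indicator and a "high average" class at +0.5. A two-class model with
  both classes fixed estimates only one proportion and the J pooled
  variances.
* **Equality groups.** One indicator's mean is tied to be equal across
  a set of classes. Ties are always *within an indicator, across
  classes* — never across indicators — and a cell may not be both
  fixed and tied (enforced by `ModelSpec` validation).

Restrictions act only in the M-step; the likelihood and E-step are
those of the unrestricted mixture. The free-parameter count is
k = (free mean cells) + J + (C − 1), where a fixed class contributes 0
free mean cells and an equality group of size g contributes 1 instead
of g.

## Estimation

### EM

The E-step computes posterior membership probabilities
τ_ic ∝ π_c f_c(y_i) in the log domain (log-sum-exp). The M-step uses
posterior-weighted moments: π_c = Σ_i τ_ic / n; free means are weighted
averages; a tied group's shared value pools weighted sums over its
classes; pooled variances average squared deviations over all classes
with denominator n. Fixed cells are overwritten with their constants
every iteration, so restrictions hold exactly in the result.

Numerical choices:

* **Variance floor**: σ_j² ≥ 1e−4 × sample variance of indicator j.
  Gaussian mixtures otherwise have unbounded likelihood spikes when a
  class collapses onto a few points; hitting the floor (or a class
  proportion below 1e−4) sets `boundary_flag`.
* **Empty classes**: a class whose posterior mass falls below 1e−10
  keeps its previous mean row rather than producing 0/0.
* **Monotonicity**: the observed-data loglikelihood must be
  non-decreasing across iterations; a decrease beyond 1e−9 raises
  `EMError`, since it indicates a numerical fault rather than a
  modelling outcome.
* **Stopping rule**: Aitken-projected convergence. Let δ_t be the LL
  gain at iteration t and r_t = δ_t/δ_{t−1} the contraction estimate.
  EM stops when two consecutive gains fall below tol·max(|LL|, 1)
  (tol = 1e−8, max_iter = 2000) *and* the projected asymptotic
  remaining gain δ_t·r_t/(1−r_t) is also below that threshold. A plain
  change-based rule is unreliable here: starts whose class means
  initialize close together crawl along the "collapsed classes" ridge
  (all classes equal to a common mean — a stationary set of the EM map)
  with per-iteration gains far below any reasonable tolerance, yet EM
  eventually escapes to a genuine maximum. The Aitken projection
  refuses to stop while gains are not contracting (r ≥ 0.999), which is
  exactly the ridge signature. `fit_em` reports `converged=False` if
  max_iter is exhausted first; multistart counts such runs as failures.
* **C = 1** is solved in closed form (sample mean, denominator-n
  variance).

### Multistart and modes

Small-sample mixture likelihoods are multimodal, and the dispersion of
solutions across local maxima ("modes") is itself a diagnostic: many
modes with similar loglikelihoods but different parameters signal an
unstable model. `run_multistart` fits `n_starts` (default 1000) random
starts and groups converged solutions into modes.

* **Start scheme** (`seeded-partition+dirichlet`): each start draws C
  distinct subjects as seeds, partitions all subjects to the nearest
  seed, and initializes free class means at the partition's group means
  with variances at the pooled within-group column variances — one
  k-means-style classification step — plus flat-Dirichlet proportions.
  Starting from raw seed rows with total-column variances was tried
  first and rejected: with initial variances at the marginal spread the
  first E-step returns near-uniform posteriors, and any start whose
  seeds land in one cluster slides onto the collapsed ridge. With the
  classification step, the well-separated two-class benchmark sends
  97–98% of starts to the dominant mode.
* **Mode equality**: two solutions share a mode iff |ΔLL| ≤ `ll_tol`
  (default 0.01) *and* the max-abs parameter difference after optimal
  class relabelling is ≤ `param_tol` (default 0.05 on the standardized
  scale); grouping is the transitive closure. Relabelling solves the
  assignment problem on squared mean-profile distances exactly
  (`scipy.optimize.linear_sum_assignment`), with fixed classes mapped
  to themselves. Both tolerances are exposed as CLI flags; the
  conjunctive rule was chosen over LL-only because distinct parameter
  patterns at nearly equal LL are precisely the instability one wants
  to see counted.

## Evaluation

No single fit statistic is trusted. `fit_report`/`compare_models`
report, per model: k; LL; AIC = 2k − 2LL; BIC = k·ln n − 2LL; relative
entropy E = 1 − Σ_ic(−τ_ic ln τ_ic)/(n ln C) (1 = crisp, 0 =
uninformative; undefined at C = 1 and reported as NaN); the fraction of
subjects with max posterior above 0.8; per-indicator residual variance
fractions σ̂_j²/s_j² (σ̂² uses denominator n, the sample variance
n − 1 — both conventions are stated to avoid ambiguity); class
proportions; and convergence summaries (number of modes, share of
starts at the top mode). The comparison table never declares a winner;
the pipeline's selection report names each criterion's favourite and
flags disagreement. The entropy formula is printed in output metadata
because software packages differ in which variant they report.

Stability diagnostics: `sensitivity_grid` refits the
two-reference-class model over a grid of reference means (default
(−0.5, +0.5), (0, 1), (−1, +1), (−2, +2), (−2, −1)), reporting fit
statistics per level and a no-convergence marker when every start
fails — well-chosen references should dominate grossly misspecified
ones on AIC and BIC. `track_class_evolution` matches classes across
models of increasing C by profile distance and traces proportion
trajectories, exposing the characteristic pattern of subjects peeling
out of a broad class into newly added ones. `back_transform` maps
standardized class means to the raw metric with normal-CDF percentiles;
the percentiles assume norm-referenced scores and are interpretive, not
inferential.

## Multiple-imputation extension

To profile secondary indicators (e.g. EEG band powers) on an
established class structure without refitting a joint mixture — which
in small samples lets the noisier indicators overpower the structure —
`extend_model` draws D = 20 class assignments per subject from the
posterior probabilities, computes per-class means and squared standard
errors per draw, and pools with Rubin's rules: T = W̄ + (1 + 1/D)·B.
Intervals use a t reference with Barnard–Rubin small-sample degrees of
freedom, taking the complete-data dof as the average class size minus
one; when λ = (1+1/D)B/T reaches 1 the observed-data dof degenerates to
0 and the classical MI dof (D−1)/λ² is used instead. Draws in which a
class is empty (or a singleton, for indicator means) are dropped for
that class and the usable-draw count reported — plausible at 5–6%
class prevalence and n = 120. With one-hot posteriors the machinery
reduces exactly to subgroup means with B = 0. `theta_beta_ratios`
computes per-subject log ratios of raw theta to low-beta and high-beta
power; the band pairing is configurable because labelling conventions
differ.

## External variables

`fit_concomitant` implements one-step latent class regression: class
proportions become multinomial-logit functions of covariates,
π_c(x_i) = exp(γ_c0 + γ_c'x_i)/Σ_k exp(·), estimated jointly with the
mixture by EM (measurement M-step unchanged under all restrictions;
γ updated by damped Newton on the posterior-weighted multinomial
likelihood, which is concave). The one-step route was chosen over
classify-then-regress because hard classification attenuates covariate
effects; the MI route (`external_binary_by_class`) is the documented
fallback when regression degenerates — e.g. when an outcome perfectly
predicts a class, which raises a separation error (|γ| > 50). Standard
errors for γ come from the numerically differentiated observed
information at the MLE (measurement parameters held fixed), with Wald
z, p, and ±1.96·SE intervals; the reference class defaults to the
first fixed class. `external_binary_by_class` pools class-wise
proportions of a binary variable over assignment draws with binomial
within-draw variance p(1−p)/m. `stability_under_covariates` aligns the
with- and without-covariate fits and flags any class whose mean profile
moved by more than 0.25 — proportion shifts are expected, profile
shifts are the warning sign.

## Synthetic data

The generator mirrors the model: categorical class labels (optionally
covariate-dependent through the same multinomial logit), conditionally
independent Gaussian indicators given class with pooled variances,
Bernoulli external binary with class-dependent probabilities, and
log-normal secondary band powers (the standardized-log-power matrix and
the raw powers are both returned). The default scenario encodes a small
neurodevelopmental study: n = 120; five classes at proportions
(0.42, 0.34, 0.09, 0.06, 0.09); two reference classes at constant
∓0.5; three free classes shaped as "low control/high memory" (weak
response control, strong memory span), "high IQ" (FSIQ peak at +2.05
with good coding), and "below average" (−1 throughout except average
SSRT); pooled variances 0.44–0.86 (modestly informative indicators);
diagnosis probabilities (0.88, 0.65, 0.70, 0.34, 0.97) by class; and a
0.48 age logit slope for the high-average vs low-average contrast. The
free-class profiles are plausible encodings of the qualitative shapes
the framework is meant to find — generator truth for recovery testing,
not estimates from any dataset. Real EEG bands are cross-correlated;
the generator's bands are conditionally independent by default, with an
optional common-factor loading (`secondary_common_factor`) off by
default. Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not
robustness to the dependence structure of real data.

`parameter_recovery_suite` simulates replicates, fits the correctly
specified restricted model by multistart, aligns the best solution to
truth, and reports mean-profile RMSE, proportion RMSE, and the adjusted
Rand index of the modal partition against true labels. At the default
study scale (n = 120, 20 replicates, 200 starts) median profile RMSE is
≈ 0.35 and median ARI ≈ 0.6; both improve strictly when between-class
separation doubles (median RMSE ≈ 0.24) or n grows to 1000 (≈ 0.10).
The easier regimes are benchmarked at 10 replicates × 50 starts — their
error distributions concentrate far below the n = 120 level, so smaller
replications resolve the comparison. The test suite runs these same
sizes; the acceptance script reports the default-scenario suite at 10
replicates × 100 starts.

## Known limitations

* Pooled (not class-specific) variances and diagonal within-class
  covariance only; no FIML for missing data (complete cases are
  required, explicitly).
* The entropy variant reported by other software has not been verified
  against this implementation's formula; comparisons across packages
  should recompute entropy from exported posteriors.
* Mode counts depend on `ll_tol`/`param_tol`; the defaults were chosen
  for stability on synthetic replicas of the target study size and are
  deliberately exposed rather than hidden.
* Wald inference for γ uses the normal approximation; no profile
  likelihood or resampling intervals.
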