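# Methods

## The model and what makes the direction identifiable

For a pair of observed scores per participant the package assumes one of
two linear structural models: `y = b·x + e` (x causes y) or
`x = b·y + e'` (y causes x), with the residual independent of the
predictor and **non-Gaussian**. With Gaussian data the two orientations
are observationally equivalent; with non-Gaussian data only the true
orientation yields a residual independent of its predictor, and the
direction becomes an estimable quantity. The estimated cause is the
*exogenous* variable — the one that is not a function of the other.

Three signed statistics decide the orientation; for each, positive
means the first argument is the estimated cause, negative the opposite,
and exactly zero is reported as a tie (never silently broken — in
bootstrap summaries ties appear in their own column, so the two
direction percentages need not sum to 100).

### Kernel-MI statistic

`stat_lingam` compares the dependence of each candidate cause on the
residual it would leave behind: `MI(y, e_x|y) − MI(x, e_y|x)` with
`e_a|b` the OLS residual of `a` on `b`. MI is a kernel
generalized-variance estimate: Gaussian-kernel Gram matrices of each
variable are factorized by pivoted Cholesky (truncation tolerance 1e-6
relative to the unit diagonal), centered, and their regularized kernel
canonical correlations `ρ_k` combined as `−½·Σ log(1 − ρ_k²)`. This
smoothed mutual information is zero at the population level exactly
under independence. Defaults:

* kernel width — median pairwise distance of the input (computed on a
  deterministic subsample beyond n = 1000); a scale-based fallback
  handles heavily tied inputs;
* spectral regularization κ = 2e-3, entering as `λ/(λ + nκ/2)`;
* arguments are ordered canonically (by byte representation) before
  factorization so the estimate is *bit-exactly* symmetric.

Both a standardized variant (default) and a raw variant that centers
but does not rescale are provided; the latter matters because the
kernel width then reflects the original scales.

### Skew- and tanh-based statistics

Closed-form approximations to the log likelihood ratio between the two
orderings. Both standardize the inputs first (they are undefined on raw
scales). The skew statistic multiplies each standardized variable by
the sign of its sample skewness before forming
`ρ̂·(Ê[x̃²ỹ] − Ê[x̃ỹ²])`; without this correction the sign is not
identifiable for left-skewed inputs. The tanh statistic is
`ρ̂·Ê[x̃·tanh(ỹ) − tanh(x̃)·ỹ]`. Expectations are plain sample means
(divide by n); correlations and standard deviations use n−1. Both are
exactly antisymmetric under argument exchange and invariant to affine
rescaling of either raw input. The magnitudes are implementation-
defined (normalization constants differ across formulations in the
literature); the sign convention and antisymmetry are the contract.

## Bootstrap direction inference

Participants (rows) are resampled with replacement, keeping the two
scores of a row together, B = 2000 by default. Reported per method:
percentage of replicates choosing each direction, the median replicate
statistic, and a 95% BCa interval. The BCa bias correction `z₀` comes
from the fraction of replicates below the original-sample statistic
(the original-sample statistic anchors the interval; the median is
reported alongside as a descriptive summary), and the acceleration `â`
from the jackknife skewness coefficient. Leave-one-out re-estimation of
an expensive statistic at n = 1699 is costly, so `â` may be estimated
on a seeded subsample of leave-one-out points (default 200; exact mode
available) — a documented approximation that empirically preserves the
interval's coverage. Degenerate resamples (a constant column) are
redrawn and counted; endpoints are clipped to the replicate range; if
every replicate falls on one side of the anchor the plain percentile
interval is returned with a warning.

## Assumption diagnostics

For an estimated orientation (cause, effect) the battery reports:

1. **linearity** — two-sided t-test of the quadratic coefficient in
   `effect ~ 1 + cause + cause²`;
2. **residual non-Gaussianity** — Lilliefors (KS distance to a Gaussian
   with estimated mean/s.d.), p-value from a seeded Monte-Carlo null
   table (default 10⁴ replicates; the null law is parameter-free given
   n, so the table is cached per n). The raw KS distance is also
   reported for effect size. Note the logic: *rejecting* normality
   supports the identifying assumption;
3. **cause–residual independence** — two tests, always between the
   estimated *cause* and the residual (the effect–residual pairing is
   dependent by construction):
   * a distribution-free L¹ test on a 4×4 equiprobable quantile grid:
     statistic `Σ |p̂_joint − p̂_x·p̂_y|` over cells, converted to a
     p-value by scalar inversion (quadratic-loss minimization) of the
     monotone threshold `t(α) = √(m²/n) + √(8·ln(1/α)/n)` — an
     expectation bound plus a bounded-difference tail. This p-value is
     an upper bound, hence conservative; a permutation-calibrated mode
     is provided and is the one whose size is asserted in tests;
   * Hoeffding's D from the classical joint-rank count formula
     (midranks and half-counts for ties; 30-scaled, range [−0.5, 1]),
     with a seeded permutation Monte-Carlo p-value (default 2000
     permutations) rather than asymptotic tables — exact smalln
     behaviour and determinism.

An optional jitter switch (additive Gaussian noise, variance 0.1)
reproduces the robustness check for heavily ordinal inputs whose atoms
formally violate the continuity assumptions of both independence tests.

## The perturbation study

`fit_data_model` estimates a tractable generative model from a pair:
OLS slope and intercept; a location-shifted exponential for the cause
(shift = sample minimum minus the small-sample correction
(mean−min)/n, rate chosen so the fitted mean is exact); and a
four-component Gaussian mixture for the residual via multi-start EM (10
seeded restarts, variance floor 1e-6×var, components sorted by mean),
translated to zero mean. Perturbations:

* **discretization** — both margins snapped to a k-interval equal-width
  lattice of lower bin edges (k = 2..15), emulating ordinal sum scores;
* **latent confounding** — an unobserved `z` distributed like the cause
  and a second residual `e_z`; *linear* mixing
  `y* = (1−λ)βx + λβz + e`, `x* = (1−λ)x + λ(βz + e_z)`, or
  *proportional* contamination where a Bernoulli(λ) mask per row draws
  from the fully confounded generator. Four distributional settings
  permute which of x/z and e/e_z are exponential vs Gaussian-mixture
  (residual-role draws always translated to zero mean). λ = 0
  reproduces the unconfounded draw bit for bit; at λ = 1 both variables
  are functions of z only and one direction is scored "correct" by
  convention, so success ≈ ½;
* **measurement error** — Gaussian noise added to x *after* y is
  computed, 15 s.d. levels on an even grid from 0 to 3·s.d.(x). The
  grid is defined relative to the cause's s.d. because that is the
  scale on which the noise acts.

Estimation success is the fraction of simulated studies (default 1000,
each at the model's n) in which a statistic returns the generating
direction; ties count as incorrect (conservative; only the tanh
statistic on coarse lattices is affected). Every replicate uses an
independent seeded substream (`SeedSequence.spawn`), so results are
invariant to execution order and worker count. The full grid is
14 + 2·4·15 + 15 = 149 conditions per method.

## The synthetic cohorts

Real sleep/depression cohort data is access-restricted; the generator
rebuilds study-like pairs from published summary moments: cause mean
and s.d., effect mean and s.d., cross-correlation r, and n, per study
arm. The implied structural parameters are `b = r·sd_y/sd_x`, an
exponential cause matched to (mean, s.d.), and a zero-mean right-skewed
4-component residual mixture scaled to `sd_y·√(1−r²)` — so the
synthetic margins, correlation and slope reproduce the printed values.
The residual-mixture *shape* (weights 0.45/0.30/0.17/0.08, ascending
means) is a package default chosen to give a positive-skew residual
like the observed ones; the originally fitted mixture parameters are
not published, so any result that depends on the mixture's fine
structure (notably the tanh error counts on coarse lattices) should be
read as conditional on this default. What the generator deliberately
does not emulate: item-level questionnaire structure, zero-inflation of
the Wisconsin sleep score (its printed s.d. exceeds its mean; the
profile reproduces moments only), attrition mechanisms, and any
dependence beyond the single linear link. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not validity of causal conclusions on real cohorts.

## Numerical choices and edge cases

* Ties at exactly 0 in a direction statistic are reported as ties.
* Constant vectors raise degenerate-input errors everywhere; a constant
  bootstrap column triggers a redraw (warned past 1% of B).
* Kernel-MI values have tiny negatives clipped to zero; canonical
  correlations are clipped below 1 to keep the log finite.
* The single-component mixture fit bypasses EM and returns the exact
  sample MLE.
* Monte-Carlo p-values use the add-one estimator (1+#exceed)/(1+B),
  which is valid at any replicate count.
* Small p-values are kept as raw numbers in all machine outputs;
  "<.001"-style flooring is applied only in human-readable displays.

## Problem sizes used in the shipped analyses and tests

Simulation-heavy checks in the test suite run at the study's n = 1699
where the claim depends on it (discretization and confounding success
rates, bootstrap coverage) and at reduced n (400–600) for
assumption-battery calibration and kernel-MI bootstrap checks, whose
per-call cost is quadratic-to-cubic in n; the analysis drivers note in
their docstrings where the kernel-MI statistic runs on a coarse
sub-grid for the same reason. The acceptance script always runs 1000
replicates at n = 1699.

## Known limitations

* Two variables only; no multivariate ordering, no cyclic models —
  under reciprocal causation the statistics estimate the *dominant*
  direction at best.
* The distribution-free L¹ p-value is a bound, not an exact level.
* The kernel-MI statistic's magnitude depends on kernel width and
  regularization; only its sign and bootstrap stability are
  interpreted.
* BCa intervals for strongly skewed statistics undercover slightly at
  moderate n (observed ≈ 90% empirical coverage for nominal 95% at
  n = 1699 in the shipped coverage check).
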