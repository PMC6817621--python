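# Methods

This note documents the statistical procedures, defaults, and design
decisions behind `hybridscreen`, and what its synthetic-data checks do and
do not establish.

## Latent trait model and estimation

Item responses follow the unidimensional 2PL on the logit scale with no
`D = 1.7` scaling constant; the Rasch path fixes every discrimination at 1
and is implemented as exactly that substitution (`ItemBank.as_rasch`), so
the two share all downstream code. Item parameters are consumed as fixed
inputs (the shipped bank is an external large-sample calibration); the
package deliberately contains no item-calibration code.

Person estimation is expected a posteriori (EAP): the posterior mean and SD
of `θ` under a normal prior, computed by normalized rectangle quadrature on
an equally spaced grid. The default grid has 121 points spanning prior mean
± 6 prior SDs — identical to the conventional `[−6, 6]` grid for the
standard normal prior, and automatically wide enough for text-informed
priors whose means are shifted or whose variance is 3.57. A user-supplied
grid must cover ≥ 99.999% of the prior mass or estimation refuses to run;
silently truncated tails would bias the posterior mean toward the grid
center. Probabilities are clamped to `[1e−12, 1 − 1e−12]` inside the
log-likelihood; missing responses are skipped (complete-response surveys
never hit this path, but routed subsets do). Against a 10×-finer
Riemann-sum oracle the default grid agrees to better than `1e−4` in both
posterior mean and SD, which is far below any decision-relevant scale here.

## Product score model

Preprocessing lowercases, expands common English contractions (the
expansions are stop words and vanish at the next step), drops tokens
containing digits, removes stop words (default list: scikit-learn's
English stop-word set, applied before stemming), and Porter-stems the
remainder with an in-house implementation of the original algorithm
validated against the reference vocabulary pairs.

Scoring is done entirely in the log domain:
`log(S1/S2) = log(P1/P2) + Σ_tokens [log((u_w+a)/len1) − log((v_w+a)/len2)]`.
Choices the original formulation leaves open, fixed here:

- **Natural logarithm.** The base only rescales the `b = 0` threshold.
- **Token multiplicity.** Occurrences count multinomially ("number of
  occurrences of keyword w"); each repeated token contributes one factor.
- **Out-of-vocabulary tokens are skipped** — only extracted keywords are
  scored.
- **Ties classify as non-PTSD**: the decision rule is strictly
  `log(S1/S2) > b` for the positive class.
- **Class priors** default to training document proportions and can be
  pinned (e.g. to an assumed population prevalence).
- **Standardization** z-scores over the cohort being analyzed with the
  `n − 1` SD. Which reference population the original system standardized
  against is unknowable; the cohort convention is self-contained and is
  what the synthetic generator assumes.
- The original 1,000-unigram keyword list is not public, so the vocabulary
  is an input; by default training uses the union of observed stems.

## Bayesian combination

The latent regression `θ_n = b0 + b1 y_n + ε_n`, `ε_n ~ N(0, σ²)` is
equivalent to the informative prior `θ_n | y_n ~ N(b0 + b1 y_n, σ²)`.
Two modes:

- **Two-stage** (`hybrid_eap`): coefficients fixed, per-person quadrature.
  With `(b0, b1, σ²) = (0, 0, 1)` this reduces exactly — same grid, same
  arithmetic — to the standard estimate, which is asserted as a test.
- **Joint** (`fit_latent_regression`): Metropolis-within-Gibbs over
  `{θ_1..N, b0, b1, σ²}`. The θ updates are random-walk Metropolis with
  per-person step sizes adapted every 100 burn-in iterations toward a
  30–50% acceptance window; `(b0, b1)` and `σ²` have conjugate conditionals
  (normal and inverse-gamma). Block priors are weakly informative
  conventional defaults — `b0, b1 ~ N(0, 100)`, `σ² ~ InvGamma(0.01, 0.01)`
  — and configurable. Defaults are 5,000 iterations with 1,000 burn-in and
  2 chains; a split-chain R̂ is reported per coefficient. Runs are
  bit-reproducible given the config seed (chain streams are spawned from
  one `SeedSequence`). `fix_reg` freezes the coefficient block, which is
  how the sampler is cross-checked against the quadrature engine (θ
  posterior means agree within 3 batch-means MCSEs).

## Routing and the SE curve

Items are ranked once by Fisher information `α²P(1−P)` at the diagnostic
cutoff `θ = −0.15` (ties keep bank order); the cutoff itself comes from an
external large-sample standard-setting exercise and is consumed as
configuration. The SE curve reports, for each test length m, the cohort
mean of the per-person posterior SD using the first m ranked items —
posterior SD rather than information-based SE, because estimation here is
per-respondent and Bayesian.

One consequence deserves emphasis: a text prior with variance 3.57 is
*less* concentrated than the standard normal prior, so against an N(0, 1)
reference the with-prior curve lies **above** the reference at short test
lengths and the crossing rule yields a saving of 0. The informative prior
only beats a reference that is itself weaker — which is how the original
two-curve comparison must be read, since its reference curve starts near
1.6, above the ceiling of 1 that any N(0, 1)-prior posterior SD obeys. The
pipeline therefore reports both comparisons: the N(0, 1) reference (the
default `se_curve` contract) and a near-flat `N(0, 25)` reference
(`prior_var=25`), which behaves like prior-free estimation and reproduces
the qualitative two-curve picture — with-prior below, gap largest at one
item and shrinking as the test lengthens, positive item saving. The
crossing rule is discrete (`≤` at integer m, no interpolation).

## Standard setting

Three cutoffs on the latent scale, then their mean: midpoint of group
medians; contrasting groups (logistic regression of diagnosis on score,
cutoff at fitted probability 0.5, i.e. `−intercept/slope` — the "linear
predictor equals zero" reading of the 50% rule); and the Gaussian
discriminant under zero-one loss (normal densities by sample moments,
priors defaulting to group proportions). With unequal variances the
boundary equation is quadratic; the root between the group means is
returned, else the root nearest that interval — the operating boundary in
the overlap region is the one a screening rule would use. All three
methods are translation-equivariant and return 0 for symmetric
equal-prevalence groups, which the tests exercise at n = 20,000.

## Screening evaluation

`classify` calls `θ̂ ≥ cutoff` positive (boundary inclusive; configurable).
Metrics with zero denominators are reported as NaN rather than silently
dropped. Reported tables round to 2 decimals. Validity coefficients are
point-biserial correlations between item responses and a criterion score —
by default the estimated latent trait; a sum-score criterion is just a
different array passed to the same function.

## Synthetic cohorts

The generator emulates the study's *statistical* structure, not its
language: diagnoses are Bernoulli at prevalence 34/99; narratives are bags
of Porter stems from class-conditional unigram multinomials over 10
PTSD-marker stems, 10 non-PTSD-marker stems and 30 neutral fillers;
document lengths are 150 + Poisson(30), echoing the recommended minimum of
150 words. Defaults:

- `text_effect = 0.12` — the log-rate tilt on marker stems. Calibrated once
  so that a PSM trained and evaluated on held-out synthetic narratives
  scores ≈ 0.84, the accuracy regime reported for real narratives; it is a
  similarity calibration, not a reproduction.
- `y_class_gap = 2.0` — the separation of class-conditional text-score
  distributions in `gen_cohort` (direct-`y` mode), chosen a priori to give
  roughly the same two-class separability at that prevalence.
- `(b0, b1, σ²) = (−0.41, 1.44, 3.57)` — the latent-regression defaults.

`gen_study` chains the full design: labels → narratives → in-sample PSM →
standardized scores → `θ = b0 + b1 y + ε` → 2PL responses. Because θ is
generated from the PSM-derived scores, fitting the latent regression to a
generated study is a genuine parameter-recovery exercise, and that recovery
(within 3 posterior SDs at n = 200) is the headline property standing in
for the non-deposited respondent data. What passing these checks does
*not* show: anything about real narrative language (the bag-of-stems model
has no syntax, discourse or topic structure), about the true
diagnosis→severity pathway (here diagnosis affects θ only through the text
score, which caps questionnaire-side classification accuracy on synthetic
cohorts well below the real study's 0.94), or about transfer of the
calibrated accuracies to other populations.

## Known limitations

- Joint MCMC treats item parameters as known constants; calibration error
  in the bank is not propagated.
- The contrasting-groups method inherits maximum-likelihood logistic
  regression's failure under complete separation; the package raises
  rather than penalizing the fit.
- Routing ranks items once at the fixed cutoff; fully adaptive per-person
  selection with interim θ updates is out of scope.
- The SE-curve loop recomputes each person×length posterior independently;
  it is O(N·M²) quadrature calls and intended for cohort-scale (hundreds),
  not population-scale, inputs.
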