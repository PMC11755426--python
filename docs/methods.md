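# Methods

## The model

`mnrm` implements the multidimensional nominal response model (MNRM) for
rating-scale items. Person *n*'s response to item *i* falls in category
*k* ∈ {0, …, K} with probability

```
p(Y_ni = k | θ_n) = exp( Σ_d α_id s_idk θ_nd + γ_ik )
                    / Σ_m exp( Σ_d α_id s_idm θ_nd + γ_im )
```

where θ_n ~ MVN(0, Σ) collects the person's levels on D latent
dimensions, α_id are estimated item slopes, γ_ik estimated item-category
intercepts, and s_idk *fixed* scoring weights that encode how dimension
d expresses itself across the categories of item i. Identification uses
the usual constraints: latent means 0, latent variances 1 (Σ is a
correlation matrix), and γ_i0 = 0 for every item.

The dimensions are, in fixed order: substantive traits (weights
0, 1, …, K on the item's own trait, zeros on the others), extreme
response style (ERS; endpoint indicators 1, 0, …, 0, 1), midscale
response style (MRS; midpoint indicator), and faking. The faking
dimension has *item-specific* weights: mean social-desirability ratings
of each response category, linearly rescaled to [0, 1] with the rating
instrument's global bounds (per-item rescaling is available behind a
flag but discouraged, since it erases between-item desirability level
differences). Because desirability trajectories vary by item — some
rise monotonically with the category, some peak mid-scale — faking is
neither redundant with the trait ramps nor with the style indicators.

## Estimation

`fit_mnrm` maximizes the marginal likelihood by a
Metropolis–Hastings Robbins–Monro (MH-RM) scheme:

* **Imputation.** A persistent component-wise random-walk Metropolis
  chain updates all persons' θ in one compiled sweep per cycle. A
  proposal on a trait dimension only touches that trait's items (the
  other items' logits do not involve it), which keeps a sweep at
  roughly `n_styles + 1` full likelihood evaluations. Proposal scales
  adapt per dimension toward an acceptance band of 0.23–0.45 during
  burn-in and are frozen afterwards.
* **Approximation.** Given the imputed θ, item parameters move along a
  Newton direction of the complete-data log-likelihood. The
  complete-data Fisher information is accumulated across cycles with
  the same Robbins–Monro gain as the parameter updates (stage 1:
  constant gain 1 for `burnin` cycles; stage 2: gain t^−0.75). Steps
  are clipped at ±1 per parameter per cycle.
* **Latent correlations.** Σ is updated by gain-weighted averaging of
  the imputed second moments θᵀθ/N and renormalized to a correlation
  matrix each cycle — the same fixed point as a constrained M-step,
  and always a valid correlation matrix.
* **Averaging and convergence.** After `min_stage2` decay cycles the
  stage-2 parameter trajectory is Polyak–Ruppert averaged; the fit
  returns the averaged estimates. Convergence is declared when the
  largest absolute change of the running averages stays below `tol`
  (default 1e-3) over a window of 3 cycles, with at least `min_avg`
  averaged cycles. The raw per-cycle change is not a usable criterion
  here: intercepts of rarely observed categories wobble at the order of
  the gain indefinitely, while their averages settle.
* **Degenerate categories.** A category never observed for an item has
  no finite intercept MLE; its intercept is pinned at −30 (probability
  ≈ 0) with a warning and excluded from updates.
* **Equality-constrained slopes.** With `constraint_mode="equal"` all
  items share one slope per dimension; the shared slope vector and the
  per-item intercepts are updated by alternating conditional Newton
  steps.

Randomness is organized as spawned seed streams (master seed → chain
stream, log-likelihood stream), so identical seeds give bit-identical
fits.

Defaults: burn-in 200 cycles, hard cap 2000, tol 1e-3. The Monte Carlo
study and the acceptance script use a documented lighter schedule
(burn-in 80, cap 1000, minimum 80 averaged cycles, tol 1.5e-3); at the
study's problem sizes the two schedules agree to well within Monte
Carlo error, and the lighter one keeps a full study at desk scale.

## Marginal log-likelihoods

Model fit is summarized by an approximate marginal log-likelihood
∑_n log ∫ p(Y_n|θ) φ(θ; 0, Σ) dθ, with four interchangeable,
method-tagged evaluators:

* `laplace` (default): Laplace approximation at the per-person
  posterior mode. The log posterior is strictly concave, so damped
  Newton ascent from 0 finds the unique mode; deterministic and usable
  at D = 8.
* `quadrature`: adaptive Gauss–Hermite product rule centred and scaled
  at the posterior mode, D ≤ 3. Agrees with `laplace` to ~0.01% on
  one- and two-dimensional test beds.
* `importance`: importance sampling from a normal proposal matched to
  the mode and curvature, antithetic draws, seeded.
* `montecarlo`: plain Monte Carlo with antithetic draws from the latent
  prior, shared across persons — the estimator general-purpose IRT
  software typically reports for stochastically estimated models. It is
  noisy and biased low when posteriors are sharp (Jensen), more so for
  higher-dimensional models; it is provided for comparability, not as
  the default.

A likelihood-ratio comparison requires both fits to carry the same
method (and seed, for the stochastic methods); `lr_test` enforces this.
The choice of evaluator materially affects nested-model LR statistics
for high-dimensional models — see "Known limitations".

## Person scores

`map_scores` returns maximum a-posteriori estimates: the maximizer of
log p(Y_n|θ) + log φ(θ; 0, Σ̂), by the same damped Newton ascent
(global convergence follows from strict concavity; non-converged
persons are flagged, never fatal). Scoring a *new* sample with the item
parameters and correlations of an existing fit is first-class: pass the
`FitResult`, which carries its weight set (hash-checked), to score, for
example, a low-stakes sample on a high-stakes calibration.

## The synthetic-data generator

`generate_dataset` emulates a personality questionnaire under response
styles and (optionally) faking. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_traits × items_per_trait | 5 × 10 | questionnaire layout |
| n_categories | 7 | Likert categories 0..6 |
| sample_sizes | 250/500/1000/3000 | persons per dataset |
| slope bounds | U(0.25, 0.75) | all loading slopes |
| faking_slope_scale | K = 6 | see below |
| threshold means | (−1.5, −0.9, −0.3, 0.3, 0.9, 1.5) | category thresholds τ̄ |
| threshold variance | 0.7 | τ_ik ~ MVN(τ̄, 0.7·I) |
| trait correlations | fixed matrix, .10–.30 | documented stand-in for meta-analytic Big-Five values |
| faking–trait correlations | (.00, .10, −.10, .30, −.30) | |
| ERS, MRS | orthogonal to everything | |
| replications | 50 | reduced from 1000; Monte Carlo SEs are reported so scaled runs stay interpretable |

Intercepts are built as γ_ik = −Σ_{m≤k} τ_im with γ_i0 = 0. Faking
weight vectors are deterministic templates on [0, 1] assigned within
each trait block by a 40/30/30 census: monotone (linear ramp),
non-monotone increasing (ramp with one interior dip), inverted-U
(quadratic peak at the midpoint); optional uniform jitter, clipped back
to [0, 1], roughens the templates without changing their class.

**Faking impact scale.** Trait weights step by 1 per category while the
faking templates span [0, 1], so identical slope ranges would give the
faking dimension ~1/K of a trait's per-category impact — far too weak
for the faking signal the study design intends ("equivalent impact" of
all dimensions), and too weak for any selection criterion to detect at
N = 250. The generator therefore scales the faking slope column by
`faking_slope_scale` (default K), which gives faking trait-equivalent
category steps while keeping every weight on the [0, 1] metric; only
the product α·s enters the model, and true and estimated faking slopes
share one metric. With this default, faking-present selection power is
100% for LR, AIC and BIC at N = 250, and ignoring faking biases
trait–trait correlations upward by ≈ +0.3 — both study headline
behaviors.

What the generator does *not* emulate: acquiescence, item-content
effects beyond the single own-trait loading, person-specific
desirability perceptions (all persons share each item's faking
weights), missing data, and local item dependence. Passing tests
therefore show internal validity of the estimator and study pipeline,
not robustness of the model on real questionnaires.

## The study runner

`run_study` repeats generate → fit roster → select → measure over
replications and sample sizes, from one master seed (spawned
sub-streams per replication and model; the two fits in a comparison
share one log-likelihood seed). The default roster is the nested chain
traits → +ERS → +MRS → +faking with free slopes. Selection criteria:
LR step-up chain at α (adjacent-pair test when the roster has two
models), AIC, and BIC. Recovery metrics per fitted model: bias and RMSE
of trait–trait and faking–trait correlations and of slopes, and mean
correlations between MAP and generating person parameters averaged
through Fisher's z, aggregated across traits and reported separately
for faking. Replication-level convergence failures are recorded and
excluded, never silently dropped. Proportions carry binomial Monte
Carlo standard errors, biases the replication-level standard error of
the mean.

## Numerical choices

* Softmax logits are max-shifted before exponentiation.
* Newton systems add a ridge of 1e-8·N to the accumulated information.
* Fisher-z averaging clips correlations to ±(1 − 1e-12) before atanh.
* LR statistics are floored at 0; identical log-likelihoods give p = 1.
* CSV floats are written with 17 significant digits and parsed with
  round-trip precision, so file round trips are lossless.

## Known limitations

* **Null distribution of the +faking LR test.** When the generating
  faking slopes are all zero, the faking–trait correlations are
  unidentified, a boundary setting in which the LR statistic is not
  chi-square distributed: its mean exceeds the nominal df by roughly a
  third at these designs, and the excess does not vanish with sample
  size. With accurate log-likelihoods the α = .05 LR test therefore
  over-rejects the no-faking null (type-I rates of ~0.3–0.6 instead of
  .05 at N = 250), while AIC and BIC remain well behaved (faking
  selected in ~5% and ~0% of null replications). The `montecarlo`
  evaluator, whose downward bias grows with model dimension, pulls the
  LR back toward nominal but not reliably. Practical guidance follows
  the information criteria — BIC in particular — rather than the raw
  LR p-value when testing for faking.
* Standard errors of item parameters and latent correlations are not
  produced; the convergence trace and seed-level replication are the
  current substitutes.
* Missing responses are rejected rather than skipped, keeping the
  likelihood semantics unambiguous.
* Product quadrature is limited to D ≤ 3; higher dimensions rely on
  the Laplace or importance evaluators.
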