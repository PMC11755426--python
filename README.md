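# mnrm — modeling faking and response styles in rating-scale data

Self-report personality tests used in high-stakes settings (personnel
selection, admissions) are vulnerable to *faking*: deliberate response
distortion toward whatever is socially desirable in that context.
Faking inflates scale means and intercorrelations and reorders
test-takers. `mnrm` implements a multidimensional nominal response
model (MNRM) that measures substantive traits jointly with extreme
response style (ERS), midscale response style (MRS), and a faking
dimension whose *item-specific* effect pattern comes from desirability
ratings of each response category — so an item whose mid-scale answer
is the most desirable one is modeled as such, not forced into a
"higher is more desirable" straitjacket.

The model: person *n* answers item *i* in category *k* ∈ {0, …, K} with

    p(Y_ni = k | θ_n) ∝ exp( Σ_d α_id · s_idk · θ_nd + γ_ik ),

with latent vector θ_n ~ MVN(0, Σ) (unit variances), item slopes α_id,
item-category intercepts γ_ik (γ_i0 = 0), and fixed scoring weights
s_idk: the ramp (0, 1, …, K) on the item's own trait, (1, 0, …, 0, 1)
for ERS, a midpoint indicator for MRS, and rescaled desirability
ratings in [0, 1] for faking. Estimation is marginal maximum
likelihood by the Metropolis–Hastings Robbins–Monro algorithm; person
scores are MAP estimates; nested models are compared by LR test, AIC,
and BIC. A simulation module generates data under the full design
(slopes U(0.25, 0.75), thresholds MVN around (−1.5 … 1.5) with
variance 0.7, faking–trait correlations .00/.10/−.10/.30/−.30) and
runs complete recovery-and-selection studies.

The package is aimed at psychometricians and applied researchers who
want faking-adjusted trait estimates, a per-person faking score, or a
testbed for studying how response biases distort rating-scale data.

## Worked example

Simulate a faking-contaminated questionnaire (5 traits × 5 items,
7 categories, N = 500), fit the model with and without the faking
dimension, and compare:

```python
import numpy as np
from mnrm import (SimulationDesign, generate_dataset, FitOptions,
                  fit_mnrm, compare_models, map_scores)

design = SimulationDesign(n_traits=5, items_per_trait=5,
                          sample_sizes=(500,), faking_present=True)
responses, weights, truth = generate_dataset(design, 7, n=500)

opts = FitOptions(burnin=80, min_stage2=60, min_avg=80, tol=1.5e-3,
                  max_cycles=1000, info_every=2, require_convergence=False)
restricted = fit_mnrm(responses, weights.subset(
    [f"trait{t}" for t in range(1, 6)] + ["ers", "mrs"]), "free", opts, seed=1)
full = fit_mnrm(responses, weights, "free", opts, seed=2)

print(compare_models([restricted, full],
                     names=["traits/ERS/MRS", "+faking"]).to_frame().round(1))

fk = full.latent.roles.index("faking")
print("estimated faking-trait correlations:",
      np.round(full.latent.corr[fk, :5], 2))
scores = map_scores(responses, full)
```

Output:

```
         model   loglik  n_params     AIC     BIC  LR_stat  LR_df  LR_p
traits/ERS/MRS -19630.1       246 39752.3 40789.1      NaN    NaN   NaN
       +faking -19343.4       278 39242.7 40414.4    573.6   32.0   0.0

estimated faking-trait correlations: [-0.09  0.07 -0.05  0.18 -0.33]
generating values:                   [ 0.   0.1 -0.1  0.3 -0.3]
MAP faking scores vs generating faking levels: r = 0.92
```

Adding the faking dimension raises the marginal log-likelihood by
~287 points for 32 extra parameters — every criterion (LR χ²(32) =
573.6, AIC, BIC) selects the faking model. The estimated faking–trait
correlations track the generating ones to within sampling error, and
the per-person MAP faking scores correlate .92 with the latent faking
levels that generated the data. `map_scores(new_responses, full)`
scores a fresh sample (say, a low-stakes group) on the same
calibration, which is how high- vs. low-stakes mean comparisons are
made.

The same workflow is available from the shell: `mnrm simulate`,
`mnrm weights` (desirability CSV → scoring-weight set), `mnrm fit`,
`mnrm score`, `mnrm compare`, `mnrm study`. See `docs/methods.md` for
the model, estimator, and generator details.

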