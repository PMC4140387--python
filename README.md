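# lcasim

A Monte-Carlo laboratory for **latent class analysis (LCA)**: how do sample
size, the number and quality of binary indicators, and a covariate of class
membership affect whether an LCA fit converges, recovers the labels of the
generating classes, avoids boundary estimates, and returns unbiased
parameters? `lcasim` generates data from known latent class populations, fits
correctly specified models by maximum likelihood (EM), applies the
replication-exclusion and label-alignment rules such simulation designs
require, and summarizes parameter recovery over a factorial design.

It is aimed at methodologists planning or auditing LCA simulation studies,
and at applied researchers who want a quick, reproducible answer to "would
LCA work at my N, with my indicators?".

## The model

The unconditional latent class model for a binary response pattern
**y** = (y₁, …, y_J) is

P(**Y** = **y**) = Σ_c γ_c ∏_j ρ_{cj}^{y_j} (1 − ρ_{cj})^{1−y_j}

with class proportions γ_c and conditional response probabilities (CRPs)
ρ_{cj} = P(Y_j = 1 | L = c); items are locally independent given the class.
With a covariate X, class membership becomes multinomial-logistic,

P(L = c | X = x) = exp(β₀c + β₁c x) / Σ_d exp(β₀d + β₁d x),

with the last class as reference (β₀C = β₁C = 0), so exp(β₁c) is the odds
ratio of membership per unit of X. Estimation is one-step maximum likelihood
via EM: the E-step computes posterior class memberships, the M-step updates
CRPs and class proportions in closed form and solves the posterior-weighted
multinomial logistic regression by Newton iterations.

The simulation design crosses sample size (70–2000), 2 or 3 classes, 4–12
indicators, CRP quality levels (0.9/0.1, 0.8/0.2, 0.7/0.3), and covariate
effect size (odds ratio 1, 1.5, 2.5, 4): 1428 conditions. Each fitted
replication is classified as usable, non-converged (500 EM iterations,
log-likelihood tolerance 1e-7), label-switched, incorrigible (class
assignment too inaccurate to determine any labeling), or zero-variance;
unusable replications are replaced by refill batches three times the
shortfall, and a cell whose initial batch is mostly unusable is excluded.
Outcomes per cell are the non-convergence and incorrigibility rates, the
prevalence of boundary CRP estimates (exactly 0/1), and absolute relative
parameter bias; factor effects are summarized by η² (balanced ANOVA
decomposition) and logistic-regression odds ratios.

## Worked example

```bash
python examples/fit_single_dataset.py
```

```
converged: True after 11 iterations
log-likelihood: -1535.03
true class proportions: [0.67 0.33]
estimated proportions:  [0.6643 0.3357]
estimated CRPs (rows = classes):
[[0.913 0.896 0.93  0.892 0.888 0.913 0.899 0.909]
 [0.893 0.885 0.042 0.07  0.919 0.083 0.873 0.085]]
boundary CRP estimates: 0 of 16
```

One sample of N = 500 from the 2-class, high-quality, 8-indicator population:
the EM fit recovers the 0.67/0.33 class split to within sampling error, the
Class-1 row of CRPs sits near the generating 0.9 for every item, the Class-2
row near 0.9 for its high items and 0.1 for its low items, and no estimate
hit the 0/1 boundary.

Other examples: `covariate_effect_recovery.py` (recovering an odds-ratio-4
covariate effect), `run_small_grid.py` (the replication/refill/exclusion
policy on a small grid), `effect_size_analysis.py` (η² and odds-ratio factor
summaries).

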