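# Methods

## Generating model

Data are drawn from a finite mixture of Bernoulli products. A design cell
fixes the number of classes C ∈ {2, 3}, sample size N ∈ {70, 100, 200, 300,
500, 1000, 2000}, number of binary indicators J ∈ {4, …, 12} (J = 4 is
disallowed for C = 3, where it is generally underidentified), indicator
quality, and covariate effect size. The population for a cell is:

- **Class proportions.** γ = (0.67, 0.33) for 2 classes, (0.4, 0.4, 0.2) for
  3 classes — unequal on purpose, mirroring the class splits common in
  applied work.
- **Class profiles.** Class 1 endorses every item at the high CRP; Class 2
  endorses items 1, 2, 5, 7, 9, 11 (1-based, truncated to J) at the high CRP
  and the rest at the low one; Class 3 endorses everything at the low CRP.
  Quality sets the high/low pair: (0.9, 0.1) high, (0.8, 0.2) moderate,
  (0.7, 0.3) low. For odd J the fixed 12-item template decides which class-2
  items are high (e.g. J = 5 gives three high, two low).
- **Covariate.** X ~ N(0, 1); membership follows a multinomial logistic
  model with slopes β₁c = log(OR) for OR ∈ {1.5, 2.5, 4} (small / moderate /
  large; all non-reference classes share the slope) and intercepts
  β₀c = log(γ_c/γ_C), so that class proportions at the covariate mean equal
  the unconditional γ. The covariate is generated, never re-standardized per
  sample — sample standardization would change the meaning of β.

The full cross minus the 3-class/4-indicator cells gives 756 + 672 = 1428
conditions.

## Estimation

Models are correctly specified and fitted by EM from **true-parameter
starting values** (the design's device for cutting label switching and local
maxima; user-supplied starts are accepted for other uses). The E-step is
computed in log space (log-sum-exp); boundary CRPs are handled exactly, an
impossible response contributing −inf. M-step updates are closed-form
posterior-weighted means for CRPs and class proportions; with a covariate,
the structural parameters solve the posterior-weighted multinomial logistic
likelihood by Newton–Raphson (gradient tolerance 1e-10, ≤ 50 inner
iterations, warm-started from the previous EM iteration — the inner problem
is concave and typically finishes in 2–4 steps).

Convergence follows the stated study rule: at most **500 iterations**, stop
when the absolute log-likelihood change falls below **1e-7**. A class whose
total posterior mass drops below 1e-6·N marks the fit non-converged
(estimation has effectively degenerated). EM monotonicity is asserted in the
tests to 1e-10 relative tolerance.

Plain EM is deliberately the optimizer: it is the standard, stable choice
for LCA and makes the monotonicity contract testable. One consequence is
that in poorly separated low-quality conditions EM can need more than 500
iterations (it converges, but slowly), so those cells show more
non-convergence than an accelerated ML implementation would produce under
the same nominal rule. Outcomes tied to the convergence rule should be read
as properties of "EM with this rule", not of the likelihood itself.

**Boundary estimates.** A CRP is flagged at the boundary when it lies within
eps = 1e-4 of 0 or 1 — below measurement relevance, above round-off.
Boundary prevalence for a replication is the flagged fraction of the C·J
CRPs; cell-level prevalence averages over usable replications.

## Replication statuses and label alignment

Each replication receives exactly one status, in order of precedence:

1. **zero_variance** — some item is constant in the sample (its CRP is not
   estimable). Checked before fitting.
2. **nonconverged** — the EM rule above failed.
3. Label classification from the **class assignment matrix** A, where
   A[t, e] is the fraction of observations with true class t whose modal
   posterior class is e (ties toward the lower index). The permutation
   maximizing the matched-assignment trace is found by brute force (C ≤ 3).
   If the best permutation is tied, or some class's matched accuracy falls
   below the **accuracy floor of 0.7**, the replication is **incorrigible**;
   otherwise it is **ok** (identity) or **label_switched**. Switched
   replications are excluded, not relabeled. The floor is a package choice
   (the rule's published source does not fix one) and is exposed as a
   parameter; the per-class minimum (rather than average accuracy) is the
   stricter reading and the one implemented.

## Harness policies

Per cell: run `target_reps` initial replications (default 1000; desk-scale
runs use 40–200 through the same code path). If fewer than half of the
initial batch is usable the cell is **excluded** and never refilled; the 50%
rule looks at the initial batch only. Otherwise refill batches of **3× the
current shortfall** are generated (new replication indices, hence new seeds)
until `target_reps` usable replications exist, capped at 10 refill rounds
(recorded as `refill_exhausted`, distinct from the 50% exclusion — the cap
guarantees termination; the source design leaves recursion depth unstated).
Exactly the first `target_reps` usable replications feed the cell metrics,
keeping the design balanced.

Seeds derive from `SeedSequence([root_seed, cell_key, replication_index])`
where `cell_key` encodes the cell's factor levels, so outputs are invariant
to cell ordering and worker count (asserted byte-for-byte in the tests).
Grid execution parallelizes over cells with joblib; a cell that errors is
recorded as excluded with the message, never aborting the grid.

## Outcome metrics

- **Relative bias** |est − truth| / |truth| (undefined at truth 0, rejected).
  Reported per class for proportions; in covariate cells the intercepts β₀c
  play the class-proportion role (they are the conditional proportions at
  X = 0) and the slope biases of the two β₁c are averaged in 3-class models.
- **CRP bias** averages exactly two high-value and two low-value CRPs per
  replication — the first two of each in class-major order — so cells with
  different J are compared on equal footing; boundary estimates are
  included.
- **η²** = SS_effect/SS_total from the balanced fixed-effects decomposition,
  computed from marginal cell means by inclusion–exclusion; unbalanced input
  is rejected rather than approximated. Replication-level observations are
  the default unit of analysis (cell means can be passed instead; the two
  can differ). Cross-checked against statsmodels ANOVA in the tests.
- **Odds ratios** for binary outcomes come from a maximum-likelihood
  logistic fit with each factor entered as one ordinal predictor rescaled to
  [0, 1] (one coefficient per factor); complete separation is reported as an
  infinite OR with a flag.

## Problem sizes in the shipped checks

The full design (1428 cells × 1000 replications) is cluster-scale. The test
suite and `scripts/acceptance.py` exercise the identical code paths at sizes
chosen to keep a single-CPU run in minutes: single fits at n = 100,000 for
large-sample recovery (class proportions, CRPs, covariate odds ratio),
100–200 replications for per-cell outcome rates, and 40–100 replications for
directional comparisons (incorrigibility ordered by indicator quality; bias
decreasing in N). Monte-Carlo tolerances are 3 standard errors, analytic
where near-complete-data information makes them essentially exact, and
estimated by repeated simulation (rescaled by √n) for the covariate slope.

## What the generator does and does not emulate

The generator reproduces the study populations exactly: two CRP values per
model, locally independent binary items, a single standard-normal covariate,
equal slopes across non-reference classes. Real data rarely look like this —
mixed item quality, violations of local independence, multiple correlated
covariates, more or smaller classes are all out of scope — so passing tests
certify the estimator and pipeline under the stated conditions, not LCA
performance on arbitrary data.

## Known limitations

- Standard errors and confidence intervals are not computed (they are
  unavailable at boundary estimates in any case); no model selection — the
  number of classes is always the generating one.
- No multi-start optimization: simulation runs start at the truth by design,
  so local-maximum behaviour from bad starts is not measured.
- The incorrigibility rule approximates a third-party algorithm whose
  thresholds are unpublished; rates depend on the accuracy floor and should
  be compared across conditions, not read as absolute.
- Non-convergence rates in low-quality conditions reflect plain EM's slow
  tail under the 500-iteration cap (see Estimation).
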