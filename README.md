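# regmixsim

Monte Carlo evaluation of **regression mixture models** (RMMs) with free
versus equality-constrained residual variances.

RMMs capture unobserved population heterogeneity in the relationship
between predictors and an outcome: latent class *k* (mixing proportion πₖ)
has its own linear model

    yᵢ = β₀ₖ + Σₚ βₚₖ xᵢₚ + εᵢ,   εᵢ ~ N(0, σₖ²).

Applied users often constrain the class-specific residual variances to be
equal (σₖ² ≡ σ²) for parsimony or to rescue a non-converging fit. This
package implements the machinery to study what that constraint does to
estimation accuracy: a synthetic-data generator for a 96-cell factorial
design (model family × class separation × sample size × class proportion),
a multi-start EM estimator for K-class mixtures of linear regressions with
free or pooled residual variances, sandwich ("MLR"-style) robust standard
errors, label alignment to the generating classes, enumeration fit indices
(AIC/BIC/ABIC, entropy), and per-condition accuracy summaries (convergence
rate, relative bias, MSE, 95%-CI coverage).

It is aimed at methodologists studying finite-mixture estimation behaviour
and at applied researchers who want to gauge, by simulation, whether an
equality constraint is safe for data like theirs.

## Worked example

Fit both variants to one replication of the two-predictor,
large-separation, balanced condition at n = 2,000 (`examples/02_fit_mixture.py`):

```python
import regmixsim as rm

cond = rm.get_condition("two_no_intdiff-large-n2000-balanced")
data = rm.generate_dataset(cond, seed=7)
fits = rm.fit_both_variants(data, K=2)
free = rm.align_labels(fits["free"], cond)
```

prints

```
free model  (loglik -1600.97, 24 EM iterations, 37 starts converged)
  class 1: intercept +0.001 (SE 0.005), slopes +0.629 (SE 0.006), +0.633 (SE 0.006), sigma^2 0.018, pi 0.508
  class 2: intercept -0.037 (SE 0.032), slopes +0.211 (SE 0.038), +0.179 (SE 0.035), sigma^2 0.902, pi 0.492

constrained model  (loglik -2170.39, 39 EM iterations, 36 starts converged)
  class 1: intercept +0.001 (SE 0.017), slopes +0.569 (SE 0.018), +0.577 (SE 0.020), sigma^2 0.346, pi 0.794
  class 2: intercept -0.066 (SE 0.081), slopes -0.115 (SE 0.078), -0.148 (SE 0.063), sigma^2 0.346, pi 0.206
```

The free model recovers the generating values (slopes 0.6261/0.17889,
variances 0.02/0.92, proportions 0.5/0.5) almost exactly. The constrained
model, forced to a single pooled variance on data whose true class
variances differ by a factor of 46, distorts everything: slopes shrink,
the class proportions drift to 0.79/0.21, and its log-likelihood is far
below the free model's (which is guaranteed — the models are nested, and
the free fit is warm-started from the constrained solution).

Other examples: `examples/01_generate_data.py` (design and generator
moments), `examples/03_class_enumeration.py` (AIC/BIC/ABIC/entropy across
K = 1..3), `examples/04_run_study.py` (a small study slice with bias, MSE
and coverage summaries).

## Command line

```bash
# one design cell, 10 replications, both variants, results to ./out
regmixsim simulate --conditions family=two_no_intdiff,separation=large,n=500,proportion=balanced \
                   --reps 10 --seed 1 --out out

# recompute tidy summaries from stored replication-level results
regmixsim summarize --replications out/replications.csv --out out/summaries2.csv --reps 10

# fit one CSV dataset (columns x1[,x2],y[,true_class])
regmixsim fit data.csv --classes 2 --constrain-rv --out fit.json
```

`simulate` writes `replications.csv` (per-replication estimates, SEs,
convergence), `summaries.csv` (tidy metrics) and `manifest.json`; output is
byte-identical for a given master seed regardless of worker count, and
interrupted runs can be completed with `regmixsim.resume_study`.

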