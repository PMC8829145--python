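"""Fit the free and the equality-constrained mixture to one dataset.

The free model estimates a residual variance per latent class; the
constrained model pools them (one fewer parameter).  Multi-start EM picks
the best converged admissible start; sandwich (robust) standard errors are
reported.  The free log-likelihood always dominates the constrained one
because the models are nested.
"""

import numpy as np

import regmixsim as rm

cond = rm.get_condition("two_no_intdiff-large-n2000-balanced")
data = rm.generate_dataset(cond, seed=7)

fits = rm.fit_both_variants(data, K=2)
for variant in ("free", "constrained"):
    fit = rm.align_labels(fits[variant], cond)
    p = fit.params
    print(f"\n{variant} model  (loglik {fit.loglik:.2f}, "
          f"{fit.n_iterations} EM iterations, "
          f"{fit.n_starts_converged} starts converged)")
    for k in range(2):
        se = fit.standard_errors["coefficients"][k]
        print(f"  class {k + 1}: intercept {p.coefficients[k, 0]:+.3f} "
              f"(SE {se[0]:.3f}), slopes "
              + ", ".join(f"{b:+.3f} (SE {s:.3f})"
                          for b, s in zip(p.coefficients[k, 1:], se[1:]))
              + f", sigma^2 {p.residual_variances[k]:.3f}, "
              f"pi {p.proportions[k]:.3f}")

print("\nnesting check: constrained loglik <= free loglik:",
      fits["constrained"].loglik <= fits["free"].loglik)
# With this well-separated cell the free fit recovers the generating values
# (slopes ~0.63/0.18, variances ~0.02/0.92); the constrained fit must distort
# them because no single pooled variance matches both classes.
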