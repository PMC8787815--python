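"""Fit the model to a noisy synthetic titration and profile one parameter.

Generates a triplicate DNA titration at 2% proportional noise from known
parameters, refits the full model by multistart maximum likelihood, then
computes the profile likelihood of the transcription rate k_r and its
likelihood-based 95% confidence interval (chi-squared threshold with
df = number of free parameters). The interval should bracket the
generating value of 2894 nM/h.
"""

from cfekit import (
    BULK_MLE, PHYSICAL_BOUNDS, GeneratorConfig, fit_mle,
    generate_bulk_titration, likelihood_ci, profile_likelihood,
)
from cfekit.studies import FIT_H, RECOVERY_FREE

data = generate_bulk_titration(GeneratorConfig(
    dna_levels_nM=(0.94, 1.875, 3.75), replicates=3, noise_cv=0.02, seed=42,
))
fixed = {"k_mat": BULK_MLE.k_mat, "K_l": BULK_MLE.K_l,
         "tau_d": BULK_MLE.tau_d, "tau_l": 0.0}
fit = fit_mle(data, "V1", bounds=PHYSICAL_BOUNDS, n_starts=4, seed=1,
              fixed=fixed, free=RECOVERY_FREE, h_target=FIT_H)

print(f"NLL at the optimum: {fit.nll_hat:.1f}  (AIC {fit.aic:.1f}, "
      f"k={fit.k} free parameters)")
for name in ("k_r", "delta_r", "k_p"):
    true = getattr(BULK_MLE, name)
    est = getattr(fit.theta_hat, name)
    print(f"  {name:8s} true {true:10.4g}   estimate {est:10.4g}   "
          f"rel. err {abs(est - true) / true:6.1%}")

prof = profile_likelihood(fit, data, "k_r", n_grid=21)
lo, hi = likelihood_ci(prof, df=fit.k)
print(f"\nprofile 95% CI for k_r (df={fit.k}): [{lo:.0f}, {hi:.0f}] nM/h")
print("a finite interval on both sides means k_r is practically")
print("identifiable within one decade of the estimate")
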