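"""Misspecification bias: ML-under-normality vs the threshold model.

Simulates one ordinal dataset (true h^2 = 0.6) and fits it twice:
treating the 0-9 codes as a normal trait (maximum likelihood), and with
the Bayesian ordered-probit animal model that respects the ordinal
scale.  The normality fit underestimates heritability severely; the
threshold model recovers it.
"""

import dataclasses

import numpy as np

from pedherit import (
    MCMCConfig,
    PriorSpec,
    fit_ml,
    generate_dataset,
    kinship_matrix,
    recode_contiguous,
    run_mcmc,
    scenario_preset,
)

cfg = scenario_preset("three_gen_ordinal10", h2=0.6, n_families=40, seed=2)
k = kinship_matrix(cfg.pedigree)
data, _ = generate_dataset(cfg, kinship=k)

naive = dataclasses.replace(data, shape="normal", n_categories=None, thresholds=None)
ml = fit_ml(naive, k, ("age",))
print(f"ML assuming normality:  h2_hat = {ml.h2_hat:.3f} "
      f"(95% CI {ml.ci95[0]:.3f}, {ml.ci95[1]:.3f})")

mc = MCMCConfig(n_iter=20_000, burn_in=5_000, thin=10, seed=3)
samples = run_mcmc(recode_contiguous(data), k, PriorSpec(), mc, ("age",))
h2 = samples.h2[~np.isnan(samples.h2)]
print(f"Bayesian ordered probit: posterior median h2 = {np.median(h2):.3f}, "
      f"mean = {h2.mean():.3f}")
print("\nTruth is 0.6: the normality fit is biased toward zero because two")
print("thirds of the codes sit in one category; the threshold model, which")
print("models exactly that censoring, stays near the truth.")
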