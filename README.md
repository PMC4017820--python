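# pedherit

Pedigree-based heritability estimation for ordinal traits.

Many clinically scored traits — radiographic osteophytosis grades in a
primate colony being the motivating case — are recorded on an ordinal
scale with a large excess of unaffected individuals.  Treating such
scores as a normal trait and fitting the classical animal model can bias
heritability estimates severely.  `pedherit` implements both sides of
that comparison, plus the machinery around it, for quantitative
geneticists planning or analysing pedigree studies of ordinal traits:

* **Pedigrees and kinship** — parsing/validation of `id sire dam [sex]`
  tables, kinship matrices Φ by the recursive tabular method, the
  additive covariance 2σ²_A Φ + σ²_E I, a replicated three-generation
  family builder, and a greedy cumulative-kinship subset ordering for
  study design.
* **Liability simulation** — traits simulated under the polygenic
  threshold model U = Xβ + a + ε with a ~ N(0, 2σ²_A Φ), discretized at
  quantile cutpoints into configurable category distributions
  (zero-inflated 10-category, binary, age-shifted, non-zero-inflated,
  or left continuous); plus a fully synthetic 542-member colony study
  emulating the motivating dataset's structure.
* **Maximum likelihood under normality** — variance components and h²
  with GLS-profiled fixed effects and delta-method intervals.
* **Bayesian threshold model (ordered probit)** — a
  Metropolis-within-Gibbs animal-model sampler with liability data
  augmentation, joint cutpoint–liability updates, inverse-gamma variance
  priors (inducing a Beta prior on h²), and both identifiability
  schemes: fixed residual variance, or the auxiliary approach that
  samples the unidentified model and draws inference on h² only.
* **Diagnostics and pipelines** — effective sample size, the ten-bin
  estimability criterion for h² posteriors, posterior summaries, and
  drivers for method comparison, sample-size search, prior sensitivity
  and full-dataset analysis, with a thin `pedherit` CLI on top.

The model: heritability is h² = σ²_A / (σ²_A + σ²_E), where the additive
genetic covariance between individuals i and j is 2σ²_A Φ_ij and an
ordinal category j is observed when the latent liability falls in
(t_{j-1}, t_j].  See `docs/methods.md` for the estimation details and
every numerical convention.

## Worked example

```python
import dataclasses, numpy as np
from pedherit import (MCMCConfig, PriorSpec, fit_ml, generate_dataset,
                      kinship_matrix, recode_contiguous, run_mcmc,
                      scenario_preset)

# 40 three-generation families (n = 320), zero-inflated 10-category
# trait driven by a liability with true h2 = 0.6 and age slope 1.5/year
cfg = scenario_preset("three_gen_ordinal10", h2=0.6, n_families=40, seed=2)
k = kinship_matrix(cfg.pedigree)
data, _ = generate_dataset(cfg, kinship=k)

# naive: pretend the 0-9 codes are a normal trait
naive = dataclasses.replace(data, shape="normal", n_categories=None, thresholds=None)
ml = fit_ml(naive, k, ("age",))
print(f"ML assuming normality:   h2_hat = {ml.h2_hat:.3f}")

# threshold model: Bayesian ordered probit
mc = MCMCConfig(n_iter=20_000, burn_in=5_000, thin=10, seed=3)
samples = run_mcmc(recode_contiguous(data), k, PriorSpec(), mc, ("age",))
print(f"Bayesian ordered probit: posterior median h2 = {np.nanmedian(samples.h2):.3f}")
```

prints (exact values depend on the seed):

```
ML assuming normality:   h2_hat = 0.214
Bayesian ordered probit: posterior median h2 = 0.619
```

The normality fit is biased far below the simulation truth of 0.6 —
two thirds of the cohort share the single "unaffected" category, which
destroys the linear-scale covariance signal — while the threshold model,
which models exactly that censoring, stays near the truth.  The
`examples/` directory has one short script per capability (kinship,
simulation, model comparison, identifiability schemes, estimability and
sample size, and the synthetic colony analysis).

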