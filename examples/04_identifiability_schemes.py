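"""Auxiliary-variable vs fixed-residual identifiability schemes.

Individual variance components are not identifiable in an ordinal
threshold model (the latent scale is free).  Two remedies: fix
sigma_E^2 = 1 and sample only sigma_A^2, or sample the unidentified
joint posterior and read off only the ratio h^2 (the 'auxiliary' scheme).
This script shows the auxiliary h^2 chain mixing far better, while its
individual variance chains wander without converging.
"""

import numpy as np

from pedherit import (
    MCMCConfig,
    PriorSpec,
    effective_sample_size,
    generate_dataset,
    kinship_matrix,
    recode_contiguous,
    run_mcmc,
    scenario_preset,
)

cfg = scenario_preset("three_gen_ordinal10", h2=0.6, n_families=40, seed=2)
k = kinship_matrix(cfg.pedigree)
data, _ = generate_dataset(cfg, kinship=k)
data = recode_contiguous(data)

for scheme in ("auxiliary", "fixed_residual"):
    mc = MCMCConfig(n_iter=20_000, burn_in=5_000, thin=10, scheme=scheme, seed=3)
    s = run_mcmc(data, k, PriorSpec(), mc, ("age",))
    h2 = s.h2[~np.isnan(s.h2)]
    print(f"{scheme:>14s}: ESS(h2) = {effective_sample_size(h2):6.0f} of {h2.size}, "
          f"posterior median h2 = {np.median(h2):.3f}, "
          f"sigma_A2 chain spans [{s.sigma_A2.min():.2g}, {s.sigma_A2.max():.2g}]")
print("\nUnder 'auxiliary' the sigma chains drift over orders of magnitude")
print("(the scale is unidentified) while their ratio h2 is the inferential")
print("target; the fixed-residual chain pins the scale but mixes far worse.")
print("Posteriors of h2 from a single zero-inflated dataset of this size are")
print("wide and can lean toward a boundary; study-level conclusions rest on")
print("many replicate datasets (see scripts/acceptance.py).")
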