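"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately implemented by a different route than the
library code it checks (Monte Carlo gene dropping for kinship, dense
matrix algebra for Gaussian densities and conditionals).
"""

import numpy as np

from pedherit.pedigree import Pedigree, topological_order


def gene_dropping_kinship(ped: Pedigree, n_reps: int, rng) -> np.ndarray:
    """Monte Carlo kinship matrix by dropping two alleles per founder.

    Each founder receives two unique allele labels; every offspring
    inherits one random allele from each parent, independently per
    replicate.  The kinship estimate for (i, j) is the probability that
    one allele drawn from i and one drawn from j carry the same label,
    averaged over the four allele pairings.
    """
    order = topological_order(ped)
    pos = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    alleles = np.empty((n, 2, n_reps), dtype=np.int32)
    next_label = 0
    for ind in order:
        i = pos[ind]
        s, d = ped.sire[ind], ped.dam[ind]
        for slot, parent in enumerate((s, d)):
            if parent is None:
                alleles[i, slot, :] = next_label
                next_label += 1
            else:
                p = pos[parent]
                pick = rng.integers(0, 2, size=n_reps)
                alleles[i, slot, :] = alleles[p, pick, np.arange(n_reps)]
    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            same = np.zeros(n_reps)
            for si in range(2):
                for sj in range(2):
                    same += alleles[i, si, :] == alleles[j, sj, :]
            phi_ij = float(np.mean(same) / 4.0)
            phi[i, j] = phi[j, i] = phi_ij
    return phi, order


def dense_mvn_loglik(y, mean, cov) -> float:
    """Gaussian log density via explicit determinant and inverse."""
    r = y - mean
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    return float(
        -0.5 * (len(y) * np.log(2 * np.pi) + logdet + r @ np.linalg.inv(cov) @ r)
    )


def dense_breeding_conditional(A, sigma_A2, sigma_E2, resid):
    """Mean and covariance of a | resid from explicit dense precision:
    P = (A sA2)^-1 + I/sE2, mean = P^-1 resid / sE2 (all phenotyped)."""
    n = A.shape[0]
    P = np.linalg.inv(A * sigma_A2) + np.eye(n) / sigma_E2
    cov = np.linalg.inv(P)
    mean = cov @ resid / sigma_E2
    return mean, cov
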