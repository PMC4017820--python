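"""Chain diagnostics, posterior summaries and the estimability criterion.

The estimability rule classifies a posterior sample of heritability as
informative when, among the ten equal-width bins of [0, 1], the two end
bins [0, 0.1) and [0.9, 1.0] carry no more mass than any interior bin —
an uninformative posterior under the Beta(0.01, 0.01)-type induced prior
piles its mass at the ends, while an informative one is unimodal with
decreasing tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = [
    "EstimabilityReport",
    "effective_sample_size",
    "estimability",
    "posterior_summary",
    "thin_and_trace",
]


def effective_sample_size(chain) -> float:
    """Autocorrelation-time ESS with Geyer's initial-positive-sequence rule.

    ESS = n / (1 + 2 sum_k rho_k), with the autocorrelation sum truncated
    at the first non-positive consecutive pair sum.  A constant
    (degenerate) chain returns 1 with a warning.  Invariant under affine
    transformation of the chain.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 10:
        raise ConfigError("chain too short for ESS estimation (need >= 10)")
    if np.all(x == x[0]):
        warnings.warn("degenerate (constant) chain; ESS reported as 1", stacklevel=2)
        return 1.0
    x = x - x.mean()
    var0 = float(x @ x) / n
    if var0 == 0.0 or not np.isfinite(var0):
        warnings.warn("degenerate (constant) chain; ESS reported as 1", stacklevel=2)
        return 1.0
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sum consecutive pairs (rho_{2m} + rho_{2m+1}) while positive
    tau = 0.0
    m = 0
    while 2 * m + 1 < n:
        gamma = rho[2 * m] + rho[2 * m + 1]
        if gamma <= 0:
            break
        tau += gamma
        m += 1
    tau_int = max(2.0 * tau - 1.0, 1.0)  # rho_0 counted once
    return float(min(n / tau_int, n))


@dataclass(frozen=True)
class EstimabilityReport:
    """Bin masses of an h^2 posterior and the end-bin estimability verdict."""

    bin_masses: np.ndarray = field(repr=False)
    estimable: bool = False
    posterior_mode_bin: int = 0
    tie_degenerate: bool = False
    n_samples: int = 0


def estimability(h2_samples) -> EstimabilityReport:
    """Apply the ten-bin end-mass estimability criterion.

    Samples must lie in [0, 1].  Bin j covers (0.1 j, 0.1 (j+1)] except
    the first, which includes 0 (boundary samples go to the lower bin;
    1.0 belongs to the top bin).  ``estimable`` is true iff both end bins
    carry mass <= every interior bin; exact ties satisfy the criterion
    but are flagged ``tie_degenerate``.
    """
    x = np.asarray(h2_samples, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ConfigError("no valid h2 samples")
    if np.any((x < 0) | (x > 1)):
        raise ConfigError("h2 samples must lie in [0, 1]")
    if x.size < 1000:
        warnings.warn("fewer than 1000 h2 samples; bin masses are noisy", stacklevel=2)
    # right-closed bins: boundary values fall in the lower bin
    idx = np.clip(np.ceil(x * 10.0).astype(int) - 1, 0, 9)
    masses = np.bincount(idx, minlength=10) / x.size
    interior_min = masses[1:9].min()
    estimable = bool(masses[0] <= interior_min and masses[9] <= interior_min)
    tie = bool(estimable and (masses[0] == interior_min or masses[9] == interior_min))
    return EstimabilityReport(
        bin_masses=masses,
        estimable=estimable,
        posterior_mode_bin=int(np.argmax(masses)),
        tie_degenerate=tie,
        n_samples=int(x.size),
    )


def posterior_summary(samples, level: float = 0.95) -> dict:
    """Mean, median and equal-tail credible interval."""
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ConfigError("no samples to summarize")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "ci_lower": float(lo),
        "ci_upper": float(hi),
        "level": level,
        "n": int(x.size),
    }


def thin_and_trace(samples, thin: int) -> np.ndarray:
    """Every ``thin``-th value (first index retained); count = ceil(n/k)
    capped below by one value for k > n."""
    if thin < 1:
        raise ConfigError("thin must be >= 1")
    x = np.asarray(samples)
    return x[::thin]
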