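"""Core parameter containers for the polygenic liability model.

The trait model is the classical animal model: a phenotype (or an
unobserved liability underlying an ordinal phenotype) decomposes as

    U = X beta + a + eps,      a ~ N(0, 2 sigma_A^2 Phi),   eps ~ N(0, sigma_E^2 I),

where Phi is the pedigree kinship matrix, sigma_A^2 the additive genetic
variance and sigma_E^2 the environmental variance.  Narrow-sense
heritability is h^2 = sigma_A^2 / (sigma_A^2 + sigma_D^2 + sigma_E^2);
dominance variance sigma_D^2 is carried for completeness but fixed at 0
throughout this package.

An ordinal trait with C categories is linked to the liability through
ordered cutpoints t_0 = -inf < t_1 < ... < t_{C-1} < t_C = +inf, with
category j observed iff t_{j-1} < U <= t_j (right-closed convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, UnsupportedFeatureError

__all__ = ["VarianceComponents", "ThresholdSpec"]


@dataclass(frozen=True)
class VarianceComponents:
    """Additive, dominance and environmental variance components.

    Parameters
    ----------
    sigma_A2
        Additive genetic variance (trait units squared), >= 0.
    sigma_E2
        Environmental (residual) variance, >= 0.
    sigma_D2
        Dominance variance; must be 0 (dominance is out of scope).
    """

    sigma_A2: float
    sigma_E2: float
    sigma_D2: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_A2 < 0 or self.sigma_E2 < 0 or self.sigma_D2 < 0:
            raise ConfigError("variance components must be non-negative")
        if self.sigma_A2 + self.sigma_D2 + self.sigma_E2 <= 0:
            raise ConfigError("total variance must be positive")
        if self.sigma_D2 != 0:
            raise UnsupportedFeatureError(
                "dominance variance (sigma_D2 != 0) is not supported; "
                "the two-gene IBD coefficient matrix is not computed"
            )

    @property
    def sigma_Y2(self) -> float:
        """Total phenotypic variance sigma_A^2 + sigma_D^2 + sigma_E^2."""
        return self.sigma_A2 + self.sigma_D2 + self.sigma_E2

    @property
    def h2(self) -> float:
        """Narrow-sense heritability sigma_A^2 / sigma_Y^2."""
        return self.sigma_A2 / self.sigma_Y2

    @classmethod
    def from_h2(cls, h2: float, sigma_Y2: float = 1.0) -> "VarianceComponents":
        """Build components from heritability and total variance."""
        if not 0.0 <= h2 <= 1.0:
            raise ConfigError(f"h2 must lie in [0, 1], got {h2}")
        if sigma_Y2 <= 0:
            raise ConfigError("sigma_Y2 must be positive")
        return cls(sigma_A2=h2 * sigma_Y2, sigma_E2=(1.0 - h2) * sigma_Y2)


@dataclass(frozen=True)
class ThresholdSpec:
    """Ordered cutpoints delimiting C ordinal categories on the liability scale.

    ``cutpoints`` holds the full vector (t_0, ..., t_C) with t_0 = -inf and
    t_C = +inf; the C - 1 interior cutpoints are strictly increasing.
    """

    cutpoints: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.cutpoints, dtype=float)
        object.__setattr__(self, "cutpoints", c)
        if c.ndim != 1 or c.size < 3:
            raise ConfigError("cutpoints must be a 1-d vector (t_0, ..., t_C) with C >= 2")
        if not np.isneginf(c[0]) or not np.isposinf(c[-1]):
            raise ConfigError("cutpoints must start at -inf and end at +inf")
        interior = c[1:-1]
        if interior.size and not np.all(np.diff(interior) > 0):
            raise ConfigError("interior cutpoints must be strictly increasing")
        if interior.size and not np.all(np.isfinite(interior)):
            raise ConfigError("interior cutpoints must be finite")

    @property
    def n_categories(self) -> int:
        return self.cutpoints.size - 1

    @property
    def interior(self) -> np.ndarray:
        """The finite cutpoints t_1, ..., t_{C-1}."""
        return self.cutpoints[1:-1]

    @classmethod
    def from_interior(cls, interior) -> "ThresholdSpec":
        interior = np.atleast_1d(np.asarray(interior, dtype=float))
        return cls(np.concatenate(([-np.inf], interior, [np.inf])))
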