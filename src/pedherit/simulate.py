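"""Liability-trait simulation on pedigrees and ordinal discretization.

Traits are simulated under the polygenic liability model

    U = X beta + a + eps,   a ~ N(0, 2 sigma_A^2 Phi),   eps ~ N(0, sigma_E^2 I),

with breeding values drawn over the *entire* pedigree and then restricted
to phenotyped individuals, so relatedness propagates through unphenotyped
ancestors.  An ordinal phenotype is obtained by discretizing U at ordered
cutpoints placed at empirical quantiles of a calibration pool, which
reproduces a target category distribution (e.g. a zero-inflated
10-category trait) exactly up to integer rounding.

Scenario presets mirror the study designs this package is built around:
replicated three-generation families with a normal or zero-inflated
ordinal trait, an age-shifted variant, a non-zero-inflated ("Wisconsin
shaped") variant, a binary trait, and a 542-member multi-generation
colony emulation with 173 phenotyped individuals (see
:mod:`pedherit.macaque`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .errors import ConfigError, NumericalError
from .model import ThresholdSpec, VarianceComponents
from .pedigree import KinshipMatrix, Pedigree, build_three_generation_pedigree, kinship_matrix

__all__ = [
    "TraitDataset",
    "LiabilityState",
    "ScenarioConfig",
    "simulate_covariates",
    "simulate_liability",
    "choose_cutpoints",
    "discretize",
    "generate_dataset",
    "scenario_preset",
    "zero_inflated_proportions",
    "wisconsin_proportions",
    "SCENARIO_PRESETS",
    "DEFAULT_AGE_RANGE",
]

#: Observed age range (years) of the phenotyped colony females; unknown
#: ages are simulated uniformly over this interval.
DEFAULT_AGE_RANGE = (4.7, 29.2)

#: Zero-category mass of the motivating dataset: 115 of 173 individuals
#: were unaffected.
ZERO_CATEGORY_MASS = 115.0 / 173.0


@dataclass(frozen=True)
class TraitDataset:
    """Per-individual phenotype, covariates and missingness.

    ``y`` holds either a continuous trait or ordinal codes 0..C-1 (stored
    as float; entries flagged in ``missing`` are ignored by fitters).
    ``covariates`` is indexed by ``ids``; the intercept is added by
    :meth:`design_matrix`, not stored.
    """

    ids: tuple
    y: np.ndarray = field(repr=False)
    covariates: pd.DataFrame = field(repr=False)
    shape: str = "normal"  # 'normal' | 'ordinal'
    n_categories: int | None = None
    thresholds: ThresholdSpec | None = None
    missing: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        n = len(self.ids)
        if y.shape != (n,):
            raise ConfigError("y must be aligned with ids")
        if len(self.covariates) != n:
            raise ConfigError("covariates must be row-aligned with ids")
        if self.shape not in ("normal", "ordinal"):
            raise ConfigError("shape must be 'normal' or 'ordinal'")
        if self.missing is None:
            object.__setattr__(self, "missing", np.zeros(n, dtype=bool))
        if self.shape == "ordinal":
            obs = y[~self.missing]
            if self.n_categories is None:
                object.__setattr__(self, "n_categories", int(obs.max()) + 1 if obs.size else 0)
            if obs.size and (obs.min() < 0 or obs.max() > self.n_categories - 1):
                raise ConfigError("ordinal codes out of range 0..C-1")

    @property
    def n(self) -> int:
        return len(self.ids)

    def design_matrix(self, columns: Sequence[str]) -> np.ndarray:
        """n x (1 + p) design matrix: intercept column then ``columns``."""
        cols = [np.ones(self.n)]
        for c in columns:
            if c not in self.covariates.columns:
                raise ConfigError(f"covariate column {c!r} not present")
            cols.append(self.covariates[c].to_numpy(dtype=float))
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        df = self.covariates.copy()
        df.insert(0, "id", list(self.ids))
        df.insert(1, "y", self.y)
        return df


@dataclass(frozen=True)
class LiabilityState:
    """Realized liabilities and their decomposition (simulation mode)."""

    ids: tuple
    U: np.ndarray = field(repr=False)
    a: np.ndarray = field(repr=False)
    eps: np.ndarray = field(repr=False)
    a_full: np.ndarray | None = field(default=None, repr=False)
    mean: np.ndarray | None = field(default=None, repr=False)  # X beta


def simulate_covariates(
    n_or_ids,
    known: pd.DataFrame | None = None,
    *,
    age_shift: float = 0.0,
    rng: np.random.Generator | None = None,
    age_range: tuple = DEFAULT_AGE_RANGE,
) -> pd.DataFrame:
    """Ages (and pass-through covariates), with an optional uniform shift.

    Known values are passed through (plus ``age_shift`` for the age
    column); unknown ages are drawn uniformly over ``age_range`` and then
    shifted.  Deterministic given ``rng``.
    """
    if age_shift < 0:
        raise ConfigError("age_shift must be >= 0")
    rng = np.random.default_rng(rng)
    if isinstance(n_or_ids, int):
        ids = [str(i) for i in range(n_or_ids)]
    else:
        ids = [str(i) for i in n_or_ids]
    n = len(ids)
    if known is not None:
        out = known.copy()
        out.index = ids
    else:
        out = pd.DataFrame(index=ids)
    if "age" not in out.columns:
        out["age"] = np.full(n, np.nan)
    age = out["age"].to_numpy(dtype=float)
    unknown = np.isnan(age)
    age[unknown] = rng.uniform(age_range[0], age_range[1], size=int(unknown.sum()))
    out["age"] = age + age_shift
    return out


def simulate_liability(
    k: KinshipMatrix,
    phenotyped_ids: Sequence,
    X: np.ndarray,
    beta: np.ndarray,
    vc: VarianceComponents,
    rng: np.random.Generator | None = None,
    *,
    chol_2phi: np.ndarray | None = None,
) -> LiabilityState:
    """Draw U = X beta + a + eps for the phenotyped individuals.

    Breeding values are generated over the whole pedigree behind ``k``
    (covariance 2 sigma_A^2 Phi) and then restricted to
    ``phenotyped_ids``; residuals are iid N(0, sigma_E^2).  A precomputed
    Cholesky factor of 2 Phi (lower triangular) can be supplied to avoid
    refactorizing across replicates.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    idx = k.index(phenotyped_ids)
    n_obs = idx.size
    if X.shape[0] != n_obs:
        raise ConfigError("X must be row-aligned with phenotyped_ids")
    if vc.sigma_A2 > 0:
        if chol_2phi is None:
            try:
                chol_2phi = cholesky(2.0 * k.phi, lower=True)
            except np.linalg.LinAlgError as exc:
                raise NumericalError(
                    "2*Phi is not positive definite; the pedigree may contain "
                    "duplicate individuals or invalid parentage"
                ) from exc
        a_full = np.sqrt(vc.sigma_A2) * (chol_2phi @ rng.standard_normal(k.n))
    else:
        a_full = np.zeros(k.n)
    a = a_full[idx]
    eps = np.sqrt(vc.sigma_E2) * rng.standard_normal(n_obs)
    mean = X @ beta
    return LiabilityState(
        ids=tuple(phenotyped_ids), U=mean + a + eps, a=a, eps=eps, a_full=a_full, mean=mean
    )


def choose_cutpoints(U_pool: np.ndarray, target_proportions: Sequence[float]) -> ThresholdSpec:
    """Place interior cutpoints at empirical quantiles of a liability pool.

    The cutpoint between categories j and j+1 is the m-th order statistic
    of the pool, m = round(n * cumulative proportion), so that under the
    right-closed discretization convention the realized category counts on
    the pool itself match the targets up to integer rounding (exactly, for
    pools without ties).
    """
    p = np.asarray(target_proportions, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ConfigError("need at least two category proportions")
    if np.any(p <= 0):
        raise ConfigError("target proportions must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ConfigError("target proportions must sum to 1")
    u = np.sort(np.asarray(U_pool, dtype=float))
    n = u.size
    if np.unique(u).size < p.size:
        raise ConfigError("fewer distinct liability values than categories")
    cum = np.cumsum(p)[:-1]
    m = np.clip(np.rint(cum * n).astype(int), 1, n - 1)
    interior = u[m - 1].copy()
    bumped = False
    for j in range(1, interior.size):
        if interior[j] <= interior[j - 1]:
            interior[j] = np.nextafter(interior[j - 1], np.inf)
            bumped = True
    if bumped:
        warnings.warn("tied/colliding cutpoints perturbed by machine epsilon", stacklevel=2)
    return ThresholdSpec.from_interior(interior)


def discretize(U: np.ndarray, t: ThresholdSpec) -> np.ndarray:
    """Ordinal codes: j iff t_{j-1} < U <= t_j (right-closed intervals)."""
    return np.searchsorted(t.interior, np.asarray(U, dtype=float), side="left")


def zero_inflated_proportions(
    n_categories: int = 10,
    p_zero: float = ZERO_CATEGORY_MASS,
    decay: float = 0.7,
) -> np.ndarray:
    """Zero-inflated category targets: mass ``p_zero`` in category 0, the
    remainder spread over categories 1..C-1 with geometrically decaying
    weights (ratio ``decay``).  An emulation of the motivating trait's
    shape, not ground truth; fully configurable."""
    if n_categories < 2:
        raise ConfigError("need at least 2 categories")
    w = decay ** np.arange(n_categories - 1)
    p = np.concatenate(([p_zero], (1.0 - p_zero) * w / w.sum()))
    return p


def wisconsin_proportions(n_categories: int = 10) -> np.ndarray:
    """Non-zero-inflated unimodal category targets (older-cohort shape),
    emulated as a Binomial(C-1, 0.4) profile with a small floor."""
    from scipy.stats import binom

    p = binom.pmf(np.arange(n_categories), n_categories - 1, 0.4)
    p = np.maximum(p, 1e-3)
    return p / p.sum()


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of a simulation scenario.

    ``beta`` maps covariate names (plus ``"intercept"``) to fixed-effect
    sizes; covariates named there but absent from the simulated covariate
    table raise at generation time.  With ``age_shift`` > 0, cutpoints are
    calibrated on the *unshifted* liabilities and applied to the shifted
    ones, so the shift changes the realized category distribution (an
    older cohort shows a less zero-inflated trait).
    """

    pedigree: Pedigree
    phenotyped_ids: tuple
    vc: VarianceComponents
    beta: dict = field(default_factory=lambda: {"intercept": 0.0, "age": 1.5})
    shape: str = "ordinal"
    proportions: np.ndarray | None = None
    age_shift: float = 0.0
    seed: int = 0
    covariates: pd.DataFrame | None = None  # known covariate values, optional
    fix_covariates_across_replicates: bool = True
    age_range: tuple = DEFAULT_AGE_RANGE
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.shape not in ("normal", "ordinal"):
            raise ConfigError("shape must be 'normal' or 'ordinal'")
        if self.shape == "ordinal":
            if self.proportions is None:
                object.__setattr__(self, "proportions", zero_inflated_proportions())
            p = np.asarray(self.proportions, dtype=float)
            if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ConfigError("category proportions must be > 0 and sum to 1")
            object.__setattr__(self, "proportions", p)

    @property
    def covariate_names(self) -> tuple:
        return tuple(k for k in self.beta if k != "intercept")

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta.get("intercept", 0.0)] + [self.beta[c] for c in self.covariate_names])


def _scenario_rngs(cfg: ScenarioConfig, replicate: int):
    """Independent covariate / liability streams, per-replicate reproducible."""
    cov_key = [cfg.seed, 0, 0] if cfg.fix_covariates_across_replicates else [cfg.seed, replicate + 1, 0]
    cov_rng = np.random.default_rng(np.random.SeedSequence(cov_key))
    liab_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, replicate + 1, 1]))
    return cov_rng, liab_rng


def generate_dataset(
    cfg: ScenarioConfig,
    replicate: int = 0,
    *,
    kinship: KinshipMatrix | None = None,
    chol_2phi: np.ndarray | None = None,
):
    """Simulate one dataset under a scenario.

    Returns ``(TraitDataset, LiabilityState)``; the liability state is
    exposed for test introspection.  Identical config + seed + replicate
    index reproduce identical output.  ``kinship`` / ``chol_2phi`` may be
    supplied to reuse factorizations across replicates.
    """
    k = kinship if kinship is not None else kinship_matrix(cfg.pedigree)
    cov_rng, liab_rng = _scenario_rngs(cfg, replicate)
    cov = simulate_covariates(
        cfg.phenotyped_ids,
        cfg.covariates,
        age_shift=cfg.age_shift,
        rng=cov_rng,
        age_range=cfg.age_range,
    )
    X = np.column_stack(
        [np.ones(len(cfg.phenotyped_ids))]
        + [cov[c].to_numpy(dtype=float) for c in cfg.covariate_names]
    )
    beta = cfg.beta_vector()
    state = simulate_liability(
        k, cfg.phenotyped_ids, X, beta, cfg.vc, liab_rng, chol_2phi=chol_2phi
    )
    if cfg.shape == "normal":
        data = TraitDataset(
            ids=tuple(cfg.phenotyped_ids), y=state.U, covariates=cov, shape="normal"
        )
        return data, state
    # calibrate cutpoints on unshifted liabilities so an age shift changes
    # the realized trait distribution rather than being absorbed
    beta_age = cfg.beta.get("age", 0.0)
    u_cal = state.U - cfg.age_shift * beta_age
    t = choose_cutpoints(u_cal, cfg.proportions)
    y = discretize(state.U, t)
    data = TraitDataset(
        ids=tuple(cfg.phenotyped_ids),
        y=y.astype(float),
        covariates=cov,
        shape="ordinal",
        n_categories=len(cfg.proportions),
        thresholds=t,
    )
    return data, state


def scenario_preset(
    name: str,
    *,
    h2: float = 0.6,
    sigma_Y2: float = 100.0,
    n_families: int = 40,
    seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """Named scenario presets.

    ``three_gen_normal`` / ``three_gen_ordinal10`` / ``binary`` /
    ``age_shift_5`` / ``wisconsin_shape`` use the replicated
    three-generation pedigree (``n_families`` families of eight, all
    phenotyped); ``wanprc_ordinal10`` uses the synthetic 542-member colony
    emulation with its 173 complete-data phenotyped individuals.

    The default total liability variance (100) puts the cohort-wide age
    effect (slope 1.5 over ages 4.7-29.2, SD ~10.6) on a par with the
    polygenic + environmental SD (10): the liability is then genuinely
    bell-shaped rather than a deterministic function of age.  h^2 is
    scale-free, so only this ratio matters.
    """
    if name not in SCENARIO_PRESETS:
        raise ConfigError(f"unknown scenario preset {name!r}; known: {sorted(SCENARIO_PRESETS)}")
    vc = VarianceComponents.from_h2(h2, sigma_Y2)
    common = dict(vc=vc, seed=seed, name=name)
    if name == "wanprc_ordinal10":
        from .macaque import synthesize_macaque_study

        study = synthesize_macaque_study(seed=overrides.pop("study_seed", 0))
        cov = study.raw.set_index("id").loc[list(study.complete_ids), ["age", "mass", "parity"]]
        base = dict(
            pedigree=study.pedigree,
            phenotyped_ids=tuple(study.complete_ids),
            covariates=cov,
            shape="ordinal",
            proportions=zero_inflated_proportions(),
            **common,
        )
    else:
        ped = build_three_generation_pedigree(n_families)
        base = dict(pedigree=ped, phenotyped_ids=tuple(ped.ids), **common)
        if name == "three_gen_normal":
            base["shape"] = "normal"
        elif name == "three_gen_ordinal10":
            base.update(shape="ordinal", proportions=zero_inflated_proportions())
        elif name == "binary":
            base.update(
                shape="ordinal",
                proportions=np.array([ZERO_CATEGORY_MASS, 1.0 - ZERO_CATEGORY_MASS]),
            )
        elif name == "age_shift_5":
            base.update(shape="ordinal", proportions=zero_inflated_proportions(), age_shift=5.0)
        elif name == "wisconsin_shape":
            # older cohort: mean age 21.55 years, no zero inflation
            base.update(
                shape="ordinal",
                proportions=wisconsin_proportions(),
                age_range=(13.9, 29.2),
            )
    base.update(overrides)
    return ScenarioConfig(**base)


SCENARIO_PRESETS = (
    "three_gen_normal",
    "three_gen_ordinal10",
    "binary",
    "age_shift_5",
    "wisconsin_shape",
    "wanprc_ordinal10",
)
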