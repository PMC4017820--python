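"""Bayesian animal-model MCMC for ordinal and Gaussian traits.

The ordinal (ordered-probit / threshold) model augments the observed
categories Y with a latent liability vector U = X beta + a + eps and
ordered cutpoints t, targeting the joint posterior

    p(beta, U, t, sA2, sE2 | Y) ∝ p(beta) p(t) p(U | beta, sA2, sE2)
                                  p(sA2) p(sE2) p(Y | U, t),

with a ~ N(0, 2 Phi sA2) over the whole pedigree, inverse-gamma priors
on both variances (shape/scale parameterization, density ∝
x^{-(a+1)} e^{-g/x}, defaults a = g = 0.01 — which induces a
Beta(0.01, 0.01) prior on h^2 = sA2/(sA2+sE2)), a vague normal prior on
beta, and a flat improper prior on the cutpoints.

One sweep updates, in order: beta (conjugate multivariate normal),
breeding values (exact joint draw), the variances (conjugate inverse
gamma), and — in ordinal mode — the liabilities and cutpoints by a
joint Metropolis step: the free interior cutpoints move by a symmetric
random walk, accepted by the ratio of products of normal-CDF category
probabilities (the liabilities integrated out), after which every U_i
is refreshed from its truncated-normal full conditional.  With a free
intercept the cutpoint location is unidentified, so t_1 is pinned at 0
(standard ordered-probit anchoring).

Identifiability schemes: ``auxiliary`` (default) leaves both variances
free — the individual components are unidentified and their chains
wander, but the heritability ratio is inferred from the joint chain;
``fixed_residual`` holds sE2 at a constant c and samples only sA2.

The breeding-value draw is made O(n^2) per sweep by a one-time
factorization: with A = 2 Phi = L L' and M the phenotyped rows of L,
write a = L w; in the right-singular basis of M the full conditional of
w has diagonal precision, so the joint draw needs only two dense
matrix-vector products per sweep.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, svd
from scipy.special import log_ndtr, ndtr, ndtri

from .errors import ConfigError, NumericalError
from .model import ThresholdSpec
from .pedigree import KinshipMatrix
from .simulate import TraitDataset

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "ChainState",
    "PosteriorSamples",
    "ThresholdModelSampler",
    "run_mcmc",
    "heritability_chain",
    "induced_h2_prior_draws",
    "recode_contiguous",
]


@dataclass(frozen=True)
class PriorSpec:
    """Priors: IG(shape, scale) on each variance, N(0, v I) on beta.

    The inverse gamma is parameterized so that IG(0.01, 0.01) on both
    components induces Beta(0.01, 0.01) on h^2.
    """

    alpha_A: float = 0.01
    gamma_A: float = 0.01
    alpha_E: float = 0.01
    gamma_E: float = 0.01
    beta_prior_variance: float = 1e10

    def __post_init__(self) -> None:
        if min(self.alpha_A, self.gamma_A, self.alpha_E, self.gamma_E) <= 0:
            raise ConfigError("inverse-gamma shapes and scales must be > 0")
        if self.beta_prior_variance <= 0:
            raise ConfigError("beta_prior_variance must be > 0")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``scheme`` is ``"auxiliary"`` or ``"fixed_residual"`` (the latter
    holds sE2 at ``fixed_c``); ``response`` is ``"ordinal"`` or
    ``"gaussian"``.  The threshold random-walk SD is tuned toward a
    20-50% acceptance rate during burn-in only (never afterwards), unless
    ``adapt_proposal`` is off.  ``fixed_thresholds`` freezes the cutpoints
    at known values (no Metropolis step; liabilities still refreshed).
    """

    n_iter: int = 100_000
    burn_in: int = 10_000
    thin: int = 10
    scheme: str = "auxiliary"
    fixed_c: float = 1.0
    response: str = "ordinal"
    start_sigma_A2: float = 1.0
    start_sigma_E2: float = 1.0
    threshold_proposal_sd: float = 0.1
    adapt_proposal: bool = True
    collapsed_moves: int = 3
    collapsed_step_sd: float = 0.5
    seed: int = 0
    fixed_thresholds: ThresholdSpec | None = None
    debug_checks: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ConfigError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if self.scheme not in ("auxiliary", "fixed_residual"):
            raise ConfigError("scheme must be 'auxiliary' or 'fixed_residual'")
        if self.scheme == "fixed_residual" and self.fixed_c <= 0:
            raise ConfigError("fixed_c must be > 0")
        if self.response not in ("ordinal", "gaussian"):
            raise ConfigError("response must be 'ordinal' or 'gaussian'")


@dataclass
class ChainState:
    """Mutable sampler state (one point of the augmented posterior)."""

    beta: np.ndarray
    w: np.ndarray  # breeding values in the whitened/rotated basis
    a_obs: np.ndarray  # breeding values of phenotyped individuals
    U: np.ndarray  # liabilities (== y in gaussian mode)
    t_interior: np.ndarray | None  # finite cutpoints t_1..t_{C-1}
    sigma_A2: float
    sigma_E2: float


@dataclass(frozen=True)
class PosteriorSamples:
    """Stored MCMC output (post burn-in, thinned)."""

    iteration: np.ndarray = field(repr=False)
    sigma_A2: np.ndarray = field(repr=False)
    sigma_E2: np.ndarray = field(repr=False)
    h2: np.ndarray = field(repr=False)
    beta: np.ndarray = field(repr=False)  # n_stored x p
    t: np.ndarray | None = field(repr=False)  # n_stored x (C-1) interior cutpoints
    acceptance_rate: float | None
    threshold_sd_final: float | None
    covariate_names: tuple
    config: MCMCConfig
    prior: PriorSpec
    n_h2_undefined: int = 0

    def __len__(self) -> int:
        return self.h2.size

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"iter": self.iteration, "sigma_A2": self.sigma_A2,
             "sigma_E2": self.sigma_E2, "h2": self.h2}
        )
        names = ["intercept"] + list(self.covariate_names)
        for j, name in enumerate(names):
            df[f"beta_{name}"] = self.beta[:, j]
        if self.t is not None:
            for j in range(self.t.shape[1]):
                df[f"t_{j + 1}"] = self.t[:, j]
        return df

    def write(self, path) -> None:
        """CSV of the chains plus a JSON run-metadata sidecar."""
        path = str(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {
            "acceptance_rate": self.acceptance_rate,
            "threshold_sd_final": self.threshold_sd_final,
            "covariates": list(self.covariate_names),
            "n_h2_undefined": self.n_h2_undefined,
            "seed": self.config.seed,
            "config": {k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v))
                        for k, v in vars(self.config).items()},
            "prior": vars(self.prior),
        }
        with open(path + ".meta.json", "wt") as fh:
            json.dump(meta, fh, indent=1)


def _h2_ratio(sa, se, warn_counter=None):
    sa = np.asarray(sa, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = sa / (sa + se)
    # sE2 underflowing to exactly 0 with sA2 > 0 is a valid h2 = 1 sample
    h2 = np.where((se == 0) & (sa > 0), 1.0, h2)
    both_zero = (se == 0) & (sa == 0)
    h2 = np.where(both_zero, np.nan, h2)
    n_bad = int(np.sum(both_zero))
    if n_bad and warn_counter is None:
        warnings.warn(f"{n_bad} h2 sample(s) undefined (both variances zero)", stacklevel=2)
    return h2, n_bad


def heritability_chain(samples: PosteriorSamples) -> np.ndarray:
    """h^2 = sA2/(sA2+sE2) per stored iteration.

    A sE2 chain value of exactly 0 (floating-point underflow of the
    conjugate draw) with sA2 > 0 yields exactly 1; both zero yields NaN
    with a warning.
    """
    h2, _ = _h2_ratio(samples.sigma_A2, samples.sigma_E2)
    return h2


def induced_h2_prior_draws(prior: PriorSpec, size: int, rng=None) -> np.ndarray:
    """Draws from the prior h^2 induced by the two inverse-gamma priors
    (Beta(alpha, alpha) when both components share shape = scale)."""
    rng = np.random.default_rng(rng)
    ga = rng.gamma(prior.alpha_A, 1.0, size=size)
    ge = rng.gamma(prior.alpha_E, 1.0, size=size)
    # h2 = (gA/ga) / (gA/ga + gE/ge) rewritten to avoid overflow when a
    # tiny-shape gamma draw underflows to zero
    return prior.gamma_A * ge / (prior.gamma_A * ge + prior.gamma_E * ga)


def recode_contiguous(data: TraitDataset) -> TraitDataset:
    """Recode ordinal codes onto 0..C'-1 keeping order (drops empty categories)."""
    obs = data.y[~data.missing]
    cats = np.unique(obs)
    lookup = {c: j for j, c in enumerate(cats)}
    y = np.array([lookup.get(v, np.nan) for v in data.y], dtype=float)
    return replace(data, y=y, n_categories=len(cats), thresholds=None)


# --- numerics -------------------------------------------------------------


def log_norm_interval(a, b):
    """log(Phi(b) - Phi(a)) elementwise, robust in both tails."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    flip = (a + b) > 0
    lo = np.where(flip, -b, a)
    hi = np.where(flip, -a, b)
    la = log_ndtr(lo)
    lb = log_ndtr(hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = lb + np.log(-np.expm1(np.minimum(la - lb, -0.0)))
    out = np.where(la == lb, -np.inf, out)
    return out


def truncated_normal(rng, mu, sigma, lo, hi):
    """Vectorized draw from N(mu, sigma^2) truncated to (lo, hi].

    Inverse-CDF sampling with a reflection into the numerically stable
    half-line; intervals so deep in a tail that their probability
    underflows return the bound nearest the mean.
    """
    mu = np.asarray(mu, dtype=float)
    a = (np.asarray(lo, dtype=float) - mu) / sigma
    b = (np.asarray(hi, dtype=float) - mu) / sigma
    flip = (a + b) > 0
    aa = np.where(flip, -b, a)
    bb = np.where(flip, -a, b)
    pa = ndtr(aa)
    pb = ndtr(bb)
    u = rng.random(size=np.broadcast(aa, bb).shape)
    with np.errstate(invalid="ignore"):
        x = ndtri(pa + u * (pb - pa))
    # underflown interval: sit at the bound nearest the mean
    x = np.where(pb <= 0, bb, x)
    x = np.where(~np.isfinite(x), bb, x)
    x = np.clip(x, np.nextafter(aa, np.inf), bb)
    x = np.where(flip, -x, x)
    out = mu + sigma * x
    lo_arr = np.broadcast_to(np.asarray(lo, dtype=float), out.shape)
    hi_arr = np.broadcast_to(np.asarray(hi, dtype=float), out.shape)
    out = np.minimum(np.maximum(out, np.nextafter(lo_arr, np.inf)), hi_arr)
    return out


def _draw_inverse_gamma(rng, shape, scale):
    return scale / rng.gamma(shape, 1.0)


# --- sampler --------------------------------------------------------------


class ThresholdModelSampler:
    """Metropolis-within-Gibbs sampler for the pedigree threshold model.

    Holds the one-time factorizations (Cholesky of 2 Phi and the SVD of
    its phenotyped rows); the ``update_*`` methods draw from the exact
    full conditionals and may be called standalone for testing.
    """

    def __init__(
        self,
        data: TraitDataset,
        k: KinshipMatrix,
        prior: PriorSpec | None = None,
        config: MCMCConfig | None = None,
        covariates=("age",),
    ) -> None:
        self.prior = prior or PriorSpec()
        self.config = config or MCMCConfig()
        self.covariate_names = tuple(covariates)
        mask = ~data.missing
        self.y = data.y[mask]
        self.X = data.design_matrix(covariates)[mask]
        self.obs_ids = tuple(i for i, keep in zip(data.ids, mask) if keep)
        self.n_obs = self.y.size
        self.n_ped = k.n
        self.rng = np.random.default_rng(self.config.seed)

        if self.config.response == "ordinal":
            codes = self.y
            if np.any(codes != np.rint(codes)):
                raise ConfigError("ordinal response requires integer category codes")
            self.codes = codes.astype(int)
            cmax = int(self.codes.max())
            observed = set(np.unique(self.codes).tolist())
            if observed != set(range(cmax + 1)):
                raise ConfigError(
                    "ordinal codes must be contiguous from 0; recode the response "
                    "(see pedherit.mcmc.recode_contiguous)"
                )
            self.n_categories = (
                data.n_categories if data.n_categories and data.n_categories >= cmax + 1
                else cmax + 1
            )
            if self.config.fixed_thresholds is not None:
                if self.config.fixed_thresholds.n_categories != self.n_categories:
                    raise ConfigError("fixed_thresholds category count mismatch")
        else:
            self.codes = None
            self.n_categories = None

        try:
            self._L = cholesky(2.0 * k.phi, lower=True)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                "2*Phi is not positive definite; check the pedigree for "
                "duplicated individuals or invalid parentage"
            ) from exc
        M = self._L[k.index(self.obs_ids), :]
        # full SVD: M = Usvd diag(s) Vh; conditional precision of w is
        # diagonal in the rows-of-Vh basis
        self._Usvd, s, self._Vh = svd(M, full_matrices=True)
        self._s_pad = np.zeros(self.n_ped)
        self._s_pad[: s.size] = s
        self._s_pad2 = self._s_pad**2
        self._s_obs = s
        # eigenvalues of the phenotyped-restricted additive relationship
        # matrix M M' = 2 Phi_obs, for the collapsed variance move
        self._lam_obs = np.clip(s**2, 0.0, None)

    # -- conditional updates ------------------------------------------------

    def update_beta(self, state: ChainState) -> np.ndarray:
        """Joint conjugate normal draw of the fixed effects.

        The precision X'X/sE2 + I/tau2 shares the eigenvectors of X'X for
        every sE2, so the draw is diagonal in that (precomputed) basis.
        """
        r = state.U - state.a_obs
        tau2 = self.prior.beta_prior_variance
        if not hasattr(self, "_xtx_eig"):
            from scipy.linalg import eigh as _eigh

            self._xtx_eig = _eigh(self.X.T @ self.X)
        dvals, V = self._xtx_eig
        prec = dvals / state.sigma_E2 + 1.0 / tau2
        if np.any(prec <= 0) or not np.all(np.isfinite(prec)):
            raise NumericalError("singular precision in beta update")
        rhs = V.T @ (self.X.T @ r) / state.sigma_E2
        z = self.rng.standard_normal(prec.size)
        return V @ (rhs / prec + z / np.sqrt(prec))

    def update_breeding_values(self, state: ChainState):
        """Exact joint draw of breeding values; returns (w, a_obs).

        ``w`` are the breeding values in the basis where the full
        conditional is diagonal; a = L V' w recovers the pedigree-wide
        vector, and the quadratic form a' (2 Phi)^-1 a equals w'w.
        sigma_A2 = 0 degenerates to a = 0.
        """
        if state.sigma_A2 <= 0:
            return np.zeros(self.n_ped), np.zeros(self.n_obs)
        r = state.U - self.X @ state.beta
        c_pad = np.zeros(self.n_ped)
        c_pad[: self.n_obs] = self._Usvd.T @ r
        d = 1.0 / state.sigma_A2 + self._s_pad2 / state.sigma_E2
        w = (self._s_pad * c_pad / state.sigma_E2) / d
        w += self.rng.standard_normal(self.n_ped) / np.sqrt(d)
        a_obs = self._Usvd @ (self._s_obs * w[: self.n_obs])
        return w, a_obs

    def breeding_values_full(self, w: np.ndarray) -> np.ndarray:
        """Pedigree-wide breeding-value vector a = L V' w."""
        return self._L @ (self._Vh.T @ w)

    def update_variances(self, state: ChainState):
        """Conjugate inverse-gamma draws of (sigma_A2, sigma_E2).

        Under the fixed-residual scheme sigma_E2 is held at the constant
        c and only sigma_A2 is drawn.  The additive draw conditions on
        breeding values over the full pedigree (n_ped), the residual draw
        on the phenotyped individuals (n_obs).
        """
        quad_a = float(state.w @ state.w)
        sa = _draw_inverse_gamma(
            self.rng, self.prior.alpha_A + 0.5 * self.n_ped,
            self.prior.gamma_A + 0.5 * quad_a,
        )
        if self.config.scheme == "fixed_residual":
            se = self.config.fixed_c
        else:
            resid = state.U - self.X @ state.beta - state.a_obs
            se = _draw_inverse_gamma(
                self.rng, self.prior.alpha_E + 0.5 * self.n_obs,
                self.prior.gamma_E + 0.5 * float(resid @ resid),
            )
        return sa, se

    def _log_ig(self, x, alpha, gamma):
        return -(alpha + 1.0) * np.log(x) - gamma / x

    def update_variances_collapsed(self, state: ChainState, step_sd: float, n_steps: int):
        """Metropolis moves of (sigma_A2, sigma_E2) with breeding values
        integrated out.

        The marginal likelihood of the liabilities given the variances is
        N(U; X beta, 2 sigma_A2 Phi_obs + sigma_E2 I); in the eigenbasis
        of 2 Phi_obs each evaluation is O(n).  A joint Gaussian random
        walk on the log variances (with the log-scale Jacobian) is run
        ``n_steps`` times; under the fixed-residual scheme only
        log sigma_A2 moves.  Composing these moves with the conjugate
        full-conditional draws leaves the posterior invariant and breaks
        the slow mutual adaptation between breeding values and
        sigma_A2.  Returns (sigma_A2, sigma_E2, n_accepted).
        """
        pr = self.prior
        fixed_e = self.config.scheme == "fixed_residual"
        r = state.U - self.X @ state.beta
        rt2 = (self._Usvd.T @ r) ** 2
        lam = self._lam_obs

        def logpost(sa, se):
            d = sa * lam + se
            ll = -0.5 * float(np.sum(np.log(d) + rt2 / d))
            lp = self._log_ig(sa, pr.alpha_A, pr.gamma_A) + np.log(sa)
            if not fixed_e:
                lp += self._log_ig(se, pr.alpha_E, pr.gamma_E) + np.log(se)
            return ll + lp

        sa, se = max(state.sigma_A2, 1e-300), state.sigma_E2
        cur = logpost(sa, se)
        acc = 0
        for _ in range(n_steps):
            la = np.log(sa) + step_sd * self.rng.standard_normal()
            le = np.log(se) if fixed_e else np.log(se) + step_sd * self.rng.standard_normal()
            sa_p, se_p = float(np.exp(la)), float(np.exp(le))
            if not (1e-30 < sa_p < 1e30) or not (1e-30 < se_p < 1e30):
                continue
            prop = logpost(sa_p, se_p)
            if np.log(self.rng.random()) < prop - cur:
                sa, se, cur = sa_p, se_p, prop
                acc += 1
        return sa, se, acc

    def update_scale(self, state: ChainState, step_sd: float = 0.7) -> bool:
        """Metropolis move along the unidentified latent-scale orbit.

        In ordinal mode with free cutpoints and both variances free, the
        likelihood is invariant under (beta, t, U, a, sigma^2) ->
        (s beta, s t, s U, s a, s^2 sigma^2).  The posterior along this
        orbit is improper-looking but bounded by the beta prior and the
        inverse-gamma tails; left to a random walk it equilibrates only
        after very many sweeps, dragging h^2 mixing with it.  This move
        proposes log s ~ N(0, step_sd^2) and accepts by the exact prior
        ratio plus Jacobian (the likelihood and h^2 are exactly
        invariant), so the scale reaches its stationary regime quickly.
        Disabled under fixed residual variance or fixed cutpoints, where
        the orbit is pinned.
        """
        cfg = self.config
        if (
            cfg.response != "ordinal"
            or cfg.scheme == "fixed_residual"
            or cfg.fixed_thresholds is not None
            or state.sigma_A2 <= 0
        ):
            return False
        pr = self.prior
        log_s = step_sd * self.rng.standard_normal()
        s2 = float(np.exp(2.0 * log_s))
        p = state.beta.size
        n_free = max(state.t_interior.size - 1, 0)
        coeff = p + n_free + 4.0 - 2.0 * (pr.alpha_A + 1.0) - 2.0 * (pr.alpha_E + 1.0)
        log_a = (
            coeff * log_s
            - (s2 - 1.0) * float(state.beta @ state.beta) / (2.0 * pr.beta_prior_variance)
            - pr.gamma_A * (1.0 / s2 - 1.0) / state.sigma_A2
            - pr.gamma_E * (1.0 / s2 - 1.0) / state.sigma_E2
        )
        s2_new = max(state.sigma_A2, state.sigma_E2) * s2
        s2_low = min(state.sigma_A2, state.sigma_E2) * s2
        if s2_new > 1e30 or s2_low < 1e-30:  # numerical guard, far outside
            return False  # any posterior mass at the orbit equilibrium
        if np.log(self.rng.random()) >= log_a:
            return False
        s = float(np.exp(log_s))
        state.beta = state.beta * s
        state.t_interior = state.t_interior * s
        state.U = state.U * s
        state.w = state.w * s
        state.a_obs = state.a_obs * s
        state.sigma_A2 *= s2
        state.sigma_E2 *= s2
        return True

    def _full_cutpoints(self, t_interior: np.ndarray) -> np.ndarray:
        return np.concatenate(([-np.inf], t_interior, [np.inf]))

    def update_liabilities_thresholds(self, state: ChainState, proposal_sd: float):
        """Joint Metropolis move of (t, U); returns (U, t_interior, accepted).

        t_1 is pinned at 0.  The remaining interior cutpoints move by a
        joint Gaussian random walk on the *log gaps* between consecutive
        cutpoints — ordering then holds by construction, and the move
        mixes across cutpoint scales (a zero-inflated trait has gaps
        spanning orders of magnitude).  The acceptance ratio is the ratio
        of products of normal-CDF category probabilities (liabilities
        marginalized out) times the log-gap Jacobian of the flat cutpoint
        prior; a proposal that would violate ordering cannot arise, and a
        non-finite ratio is rejected rather than raised.  All liabilities
        are then refreshed from truncated normals, restoring the category
        consistency invariant exactly.
        """
        mu = self.X @ state.beta + state.a_obs
        sigma = float(np.sqrt(state.sigma_E2))
        t = state.t_interior
        accepted = None
        n_free = t.size - 1
        if n_free > 0 and self.config.fixed_thresholds is None:
            gaps = np.diff(np.concatenate(([0.0], t[1:])))
            log_gaps = np.log(gaps)
            prop_log = log_gaps + proposal_sd * self.rng.standard_normal(n_free)
            prop = t.copy()
            prop[1:] = np.cumsum(np.exp(prop_log))
            cur_full = self._full_cutpoints(t)
            prop_full = self._full_cutpoints(prop)
            lp_cur = log_norm_interval(
                (cur_full[self.codes] - mu) / sigma,
                (cur_full[self.codes + 1] - mu) / sigma,
            ).sum()
            lp_prop = log_norm_interval(
                (prop_full[self.codes] - mu) / sigma,
                (prop_full[self.codes + 1] - mu) / sigma,
            ).sum()
            ratio = lp_prop - lp_cur + (prop_log.sum() - log_gaps.sum())
            if np.isnan(ratio):
                accepted = False
            else:
                accepted = bool(np.log(self.rng.random()) < ratio)
            if accepted:
                t = prop
        full = self._full_cutpoints(t)
        U = truncated_normal(self.rng, mu, sigma, full[self.codes], full[self.codes + 1])
        return U, t, accepted

    # -- initialization and the main loop -----------------------------------

    def _initial_thresholds(self, resid: np.ndarray) -> np.ndarray:
        """Cutpoints from the category quantiles of covariate-adjusted
        normal scores, shifted to pin t_1 = 0 (heuristic start only)."""
        if self.config.fixed_thresholds is not None:
            return self.config.fixed_thresholds.interior.copy()
        if self.n_categories < 2:  # degenerate single-category data
            return np.empty(0)
        counts = np.bincount(self.codes, minlength=self.n_categories).astype(float)
        cum = np.cumsum(counts)[:-1] / counts.sum()
        r = np.sort(resid)
        m = np.clip(np.rint(cum * r.size).astype(int), 1, r.size - 1)
        t = r[m - 1].copy()
        for j in range(1, t.size):  # break ties in the residual quantiles
            if t[j] <= t[j - 1]:
                t[j] = t[j - 1] + 1e-6
        return t - t[0]  # pin t_1 = 0

    def initial_state(self) -> ChainState:
        cfg = self.config
        if cfg.response == "gaussian":
            U = self.y.copy()
            t = None
            beta, *_ = np.linalg.lstsq(self.X, U, rcond=None)
        else:
            # marginal normal scores give a latent response whose
            # covariate-adjusted residual quantiles shape the cutpoints
            ranks = np.argsort(np.argsort(self.y, kind="stable"), kind="stable")
            z = ndtri((ranks + 0.5) / self.n_obs)
            beta, *_ = np.linalg.lstsq(self.X, z, rcond=None)
            resid = z - self.X @ beta
            t = self._initial_thresholds(resid)
            full = self._full_cutpoints(t)
            U = truncated_normal(
                self.rng, self.X @ beta, 1.0, full[self.codes], full[self.codes + 1]
            )
        state = ChainState(
            beta=beta,
            w=np.zeros(self.n_ped),
            a_obs=np.zeros(self.n_obs),
            U=U,
            t_interior=t,
            sigma_A2=float(cfg.start_sigma_A2),
            sigma_E2=float(cfg.fixed_c if cfg.scheme == "fixed_residual" else cfg.start_sigma_E2),
        )
        return state

    def run(self) -> PosteriorSamples:
        cfg = self.config
        state = self.initial_state()
        n_store = (cfg.n_iter - cfg.burn_in) // cfg.thin
        p = self.X.shape[1]
        out_iter = np.empty(n_store, dtype=int)
        out_sa = np.empty(n_store)
        out_se = np.empty(n_store)
        out_beta = np.empty((n_store, p))
        ordinal = cfg.response == "ordinal"
        out_t = np.empty((n_store, state.t_interior.size)) if ordinal else None
        sd = float(cfg.threshold_proposal_sd)
        acc_n = acc_y = 0
        adapt_acc = adapt_n = 0
        c_sd = float(cfg.collapsed_step_sd)
        c_acc = c_n = 0
        stored = 0
        for it in range(cfg.n_iter):
            state.beta = self.update_beta(state)
            if cfg.collapsed_moves > 0:
                # blocked draw: sigma from its a-marginalized conditional,
                # then breeding values from their exact conditional
                sa, se, acc = self.update_variances_collapsed(
                    state, c_sd, cfg.collapsed_moves
                )
                state.sigma_A2, state.sigma_E2 = sa, se
                c_acc += acc
                c_n += cfg.collapsed_moves
                # adapt after the initial transient only, with clamped steps
                if (
                    cfg.adapt_proposal
                    and cfg.burn_in // 4 <= it < cfg.burn_in
                    and c_n >= 200
                ):
                    rate = c_acc / c_n
                    if rate < 0.15:
                        c_sd = max(0.7 * c_sd, 0.05)
                    elif rate > 0.45:
                        c_sd = min(1.3 * c_sd, 1.5)
                    c_acc = c_n = 0
                elif it < cfg.burn_in // 4 and c_n >= 200:
                    c_acc = c_n = 0
            state.w, state.a_obs = self.update_breeding_values(state)
            state.sigma_A2, state.sigma_E2 = self.update_variances(state)
            if ordinal:
                self.update_scale(state)
                U, t, accepted = self.update_liabilities_thresholds(state, sd)
                state.U, state.t_interior = U, t
                if accepted is not None:
                    acc_n += 1
                    acc_y += accepted
                    if cfg.adapt_proposal and cfg.burn_in // 4 <= it < cfg.burn_in:
                        adapt_n += 1
                        adapt_acc += accepted
                        if adapt_n == 100:
                            rate = adapt_acc / adapt_n
                            if rate < 0.20:
                                sd = max(0.8 * sd, 1e-3)
                            elif rate > 0.50:
                                sd = min(1.25 * sd, 2.0)
                            adapt_acc = adapt_n = 0
                if cfg.debug_checks:
                    full = self._full_cutpoints(state.t_interior)
                    assert np.all(state.U > full[self.codes]) and np.all(
                        state.U <= full[self.codes + 1]
                    ), "category consistency violated"
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and stored < n_store:
                out_iter[stored] = it
                out_sa[stored] = state.sigma_A2
                out_se[stored] = state.sigma_E2
                out_beta[stored] = state.beta
                if ordinal:
                    out_t[stored] = state.t_interior
                stored += 1
        h2, n_bad = _h2_ratio(out_sa, out_se, warn_counter=True)
        return PosteriorSamples(
            iteration=out_iter[:stored],
            sigma_A2=out_sa[:stored],
            sigma_E2=out_se[:stored],
            h2=h2[:stored],
            beta=out_beta[:stored],
            t=None if out_t is None else out_t[:stored],
            acceptance_rate=(acc_y / acc_n) if acc_n else None,
            threshold_sd_final=sd if ordinal else None,
            covariate_names=self.covariate_names,
            config=cfg,
            prior=self.prior,
            n_h2_undefined=n_bad,
        )


def run_mcmc(
    data: TraitDataset,
    k: KinshipMatrix,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    covariates=("age",),
) -> PosteriorSamples:
    """Run the threshold-model (or Gaussian) animal-model MCMC.

    Sweeps update beta, breeding values, variances and — for ordinal
    responses — the liability/cutpoint block; burn-in is discarded and
    the rest thinned per the config.  Deterministic given the config
    seed.
    """
    return ThresholdModelSampler(data, k, prior, config, covariates).run()
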