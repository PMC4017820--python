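# Methods

## The model

`pedherit` estimates narrow-sense heritability of a trait measured on a
pedigreed population.  The polygenic (animal) model writes the trait —
or, for an ordinal trait, an unobserved continuous *liability* U — as

    U = X beta + a + eps,
    a   ~ N(0, 2 sigma_A^2 Phi),
    eps ~ N(0, sigma_E^2 I),

where Phi is the kinship matrix of the pedigree (Phi_ij = probability
that two gene copies drawn at random from individuals i and j are
identical by descent), `a` are breeding values, and X holds fixed-effect
covariates (intercept, age, body mass, parity).  Heritability is
h^2 = sigma_A^2 / (sigma_A^2 + sigma_E^2).  Dominance variance is carried
in the interface for completeness but fixed at zero throughout: the
two-gene IBD coefficient matrix is not computed, and requesting
sigma_D^2 != 0 raises an explicit unsupported-feature error.

An ordinal trait with C categories is linked to the liability by ordered
cutpoints t_0 = -inf < t_1 < ... < t_{C-1} < t_C = +inf:

    P(Y_i = j) = P(t_{j-1} < U_i <= t_j),

the right-closed convention being used everywhere (a liability exactly on
a cutpoint belongs to the lower category).

## Kinship computation

Kinship is computed by the recursive tabular method over a topological
order of the pedigree: Phi_ii = (1 + Phi_sd)/2 and
Phi_ij = (Phi_sj + Phi_dj)/2 for j preceding i, with unknown parents
contributing zero.  Pedigrees here are at most a few thousand
individuals, so dense O(n^2) storage is used deliberately; no
sparse-inverse (Henderson) machinery.  Inbreeding is handled by the same
recursion (diagonals may exceed 1/2); the test suite checks the whole
matrix against an independent gene-dropping Monte Carlo oracle.

The greedy "most related" ordering used for sample-size exploration adds,
at each step, the individual with the greatest summed kinship to the
current set.  Seed-set members unrelated to every other seed member are
removed first; ties — and candidates with zero kinship once the related
pool is exhausted — are resolved by ascending id, so replays are
deterministic.  Zero-kinship appendices are flagged in the result rather
than silently mixed in.

## Trait simulation

Breeding values are simulated over the *entire* pedigree and then
restricted to phenotyped individuals, so genetic covariance propagates
through unphenotyped ancestors (this matters for designs where only a
third of a colony is phenotyped).  Unknown ages are drawn uniformly on
(4.7, 29.2) years — the observed range of the motivating colony — and the
default age slope on the liability is 1.5 per year with an intercept of
zero; body-mass and parity effects default to zero.

Ordinal discretization places the interior cutpoints at empirical order
statistics of a calibration pool of simulated liabilities, so the
realized category distribution matches the target proportions exactly up
to integer rounding.  The default zero-inflated 10-category target puts
mass 115/173 in category 0 and spreads the rest over categories 1-9 with
geometrically decaying weights (ratio 0.7); this emulates the *shape* of
the motivating dataset — the original cutpoint locations were never
published — and is fully configurable.  The "Wisconsin" preset (an older
cohort with no zero-inflation) uses a Binomial(9, 0.4) profile and ages
uniform on (13.9, 29.2) (mean 21.55 years).  An age shift of +5 years is
applied *after* cutpoint calibration on the unshifted liabilities, so the
shift changes the realized category distribution (an older cohort is
less zero-inflated) instead of being absorbed into the quantiles.

Each scenario has one integer seed; per-replicate substreams are derived
deterministically from (seed, replicate), so any replicate is
reproducible in isolation.  Covariates are fixed across replicates by
default (a switch regenerates them per replicate); whether the original
study redrew ages per replicate is not documented, and fixing them makes
replicate comparisons sharper.

### The synthetic colony study

`pedherit.macaque` builds a fully synthetic stand-in for the motivating
dataset: a six-generation pedigree of 542 individuals (cohort sizes 120,
100, 90, 80, 70, 54 plus 28 isolated founder females), 189 phenotyped
females of which 173 have complete scores on the seven focus
intervertebral spaces, exactly 28 of those 173 unrelated to every other
member of the set, 115 of the 173 scoring zero, and per-space scores in
{0..3} whose sum reproduces a category table that merges to 10 ordered
categories.  Covariates are shaped to the published summary statistics
(age mean ~9.8 on (4.7, 29.2), mass ~N(7.06, 1.40^2) kg, parity rising
with age).  The scores are driven by a genuinely heritable liability
(default h^2 = 0.6) simulated on the pedigree.  Everything about this
object is an emulation of *structure*: analyses of it exercise the
pipelines end to end but say nothing about real animals, and the real
dataset's published point estimates cannot be reproduced from it.

## Maximum likelihood under normality

For a continuous (or naively-treated) trait, Y ~ N(X beta, 2 sigma_A^2
Phi_obs + sigma_E^2 I) over the phenotyped subset.  beta is profiled out
by GLS at every variance evaluation.  A one-time symmetric
eigendecomposition 2 Phi_obs = Q L Q' reduces each profiled likelihood
evaluation to O(n p^2); for a fixed variance ratio rho =
sigma_A^2/sigma_E^2 the residual scale is closed-form, so the search is
one-dimensional in log rho: a 5-point dispersed grid, each point refined
by bounded scalar minimization (tolerance 1e-10), with the rho = 0
boundary always evaluated explicitly since the log parameterization
cannot reach it.  The 95% CI for h^2 is a delta-method Wald interval from
the numerically differentiated observed information of the profile
likelihood in (sigma_A^2, sigma_E^2); it is reported unclipped (such
intervals legitimately extend below 0 or above 1) together with a clipped
copy.  At a boundary optimum the quadratic approximation is one-sided and
the interval should be read qualitatively.

## The threshold-model MCMC

The sampler targets the joint posterior of (beta, U, t, sigma_A^2,
sigma_E^2) given the observed categories, with priors: inverse gamma
(shape/scale parameterization, density proportional to
x^{-(alpha+1)} e^{-gamma/x}) with alpha = gamma = 0.01 on each variance —
which induces a Beta(0.01, 0.01) prior on h^2 — a N(0, 1e10) prior per
fixed effect, and a flat improper prior on the cutpoints.  One sweep:

1. **beta** — conjugate multivariate-normal draw (diagonalized in the
   eigenbasis of X'X, which is shared by every residual variance).
2. **collapsed variance move** — a few (default 3) Metropolis steps on
   (log sigma_A^2, log sigma_E^2) targeting their conditional with the
   breeding values integrated out, i.e. the Gaussian likelihood
   N(U; X beta, 2 sigma_A^2 Phi_obs + sigma_E^2 I), evaluated in O(n)
   per proposal via a precomputed eigendecomposition.  The move is
   immediately followed by step 3, making the pair an exact blocked draw
   from p(sigma, a | U, beta) (partially collapsed Gibbs).  Without this
   move the mutual adaptation of sigma_A^2 and the breeding values gives
   the h^2 chain an autocorrelation time of thousands of sweeps — the
   same order as the original software, which compensated with
   million-iteration chains; the collapsed move cuts it by roughly 30-50x
   so desk-scale chains carry usable effective sample sizes.
3. **breeding values** — exact joint draw.  With A = 2 Phi = L L' and M
   the phenotyped rows of L, writing a = L w makes the full conditional
   of w diagonal in the right-singular basis of M (one-time SVD), so the
   draw costs two dense matrix-vector products per sweep, for any
   pattern of unphenotyped individuals.
4. **variances** — the classical conjugate inverse-gamma full
   conditionals: sigma_A^2 | a over the full pedigree (shape
   alpha_A + n_ped/2), sigma_E^2 | residuals over the phenotyped (shape
   alpha_E + n_obs/2).  Under the fixed-residual scheme sigma_E^2 is
   held at the constant c and only sigma_A^2 is drawn.
5. **liabilities and cutpoints** (ordinal mode) — a joint Metropolis
   move: the free interior cutpoints are proposed by a joint Gaussian
   random walk on the *log gaps* between consecutive cutpoints (ordering
   therefore holds by construction, and the move mixes across the
   orders-of-magnitude gap spread of a zero-inflated trait; the log-gap
   Jacobian of the flat prior enters the ratio), accepted by the ratio
   of products of normal-CDF category probabilities with the liabilities
   marginalized out; then every U_i is refreshed from its
   truncated-normal full conditional, restoring the category-consistency
   invariant t_{Y_i - 1} < U_i <= t_{Y_i} exactly (assertable every
   sweep in debug mode).

Location anchoring: with a free intercept the cutpoints are
location-unidentified, so t_1 is pinned at 0 (the standard ordered-probit
convention); the latent *scale* remains unidentified under the auxiliary
scheme, which is intentional — the individual variance chains wander
while their ratio h^2 is inferred.

6. **scale move** (auxiliary ordinal mode only) — the likelihood is
   invariant under jointly rescaling (beta, t, U, a) by s and both
   variances by s^2, and the flat cutpoint prior makes posterior volume
   grow along this orbit until the fixed-effect prior and inverse-gamma
   tails bound it (the equilibrium sits at very large absolute variance
   components — the hallmark wandering of the unidentified model).
   Left to the other updates, the scale performs a slow random walk
   that drags h^2 mixing with it; a dedicated Metropolis move proposes
   log s ~ N(0, 0.7^2) and accepts by the exact prior ratio plus
   Jacobian.  The move leaves h^2 exactly unchanged, so it cannot bias
   the estimand; proposals that would push a variance outside
   [1e-30, 1e30] are rejected as a floating-point guard (the orbit
   equilibrium lies far inside).  It is disabled whenever the orbit is
   pinned (fixed residual variance, fixed cutpoints, or a Gaussian
   response).  The proposal SDs (threshold walk and
collapsed move) are tuned toward a 20-50% acceptance rate during burn-in
only.  Binary traits have no free cutpoint, so the move reduces to the
truncated-normal liability refresh.

Numerical care: interval probabilities use a log-CDF formulation stable
in both tails (reflection into the stable half-line plus expm1);
truncated-normal draws use inverse-CDF sampling with the same reflection,
and an interval whose probability underflows returns the bound nearest
the mean.  A residual-variance draw that underflows to exactly zero is
recorded as h^2 = 1 when sigma_A^2 > 0 (this mirrors the near-boundary
behaviour seen at very high true heritability); both components zero is
recorded as missing with a warning count.

Initialization: cutpoints start at category quantiles of
covariate-adjusted normal scores of the data (pinned to t_1 = 0), beta at
the corresponding least-squares fit, liabilities at truncated-normal
draws; variance chains start at configurable values (default 1, 1).
Start-value sensitivity runs use the grid sigma_E^2 in {0.1, 1, 1e3,
1e5} x sigma_A^2 in {0.1, 1, 10}.

Correctness is established by three independent routes in the test
suite: closed-form conditional oracles (KS tests per update), a
1-d numeric-integration oracle for the stationary law of a free cutpoint,
and successive-conditional ("getting it right") simulation showing that
posterior sweeps composed with model redraws of the data leave the prior
of h^2 invariant, in both Gaussian and ordinal modes.  The
free-threshold flat prior cannot be covered by the getting-it-right
construction (it is improper); the grid oracle covers that move instead.

## Diagnostics and estimability

Effective sample size uses the autocovariance (FFT) with Geyer's
initial-positive-sequence truncation; it is checked against the AR(1)
closed form and cross-checked against an independent implementation.
Constant chains report ESS 1 with a degenerate-chain warning.

The estimability criterion bins an h^2 posterior sample into ten
equal-width bins; the posterior is called estimable when the two end
bins ([0, 0.1) and [0.9, 1.0]) each carry no more mass than any interior
bin.  Ties count as satisfying the criterion but are flagged; boundary
samples go to the lower bin (1.0 to the top bin).  The report includes
the mode bin for the unimodality reading, but unimodality is not part of
the pass/fail rule.  An uninformative posterior under the
Beta(0.01, 0.01)-type induced prior concentrates ~48% of its mass in
each end bin and fails the criterion by a wide margin.

## Pipelines

*Phenotype derivation*: individuals missing any of the seven focus
intervertebral spaces are dropped; the ordinal trait is the focus-score
sum with adjacent categories of fewer than 3 individuals merged by a
left-to-right sweep repeated until stable (the sweep direction is pinned
and hand-checked in tests), then recoded 0..C-1; the average trait is the
mean focus score; the binary trait is the indicator of a nonzero sum
(chosen so that "unaffected" is exactly the zero category; the rule is
configurable).

*Method comparison* simulates normal and ordinal traits at h^2 in
{0.4, 0.6, 0.75, 0.9} on the replicated three-generation design and fits
ML-under-normality to everything, the Bayesian Gaussian model to normal
traits and the ordered-probit model to ordinal traits.  The Bayesian
point estimate is the posterior median.

*Sample-size search* walks a grid of sample sizes (whole families for
the replicated design; prefixes of a cumulative-kinship ordering
otherwise), simulates a few replicate datasets per size, and applies the
estimability criterion to each posterior; a size passes on a replicate
majority.  The original study ran one long chain per size; the
replicate-majority rule trades chain length for replication and is
configurable.  Non-monotone estimability patterns across the grid
(possible under Monte Carlo noise) are recorded in the result rather
than hidden.

## Problem sizes and defaults

Default chain lengths are deliberately desk-scale: 2x10^4 sweeps for
simulation studies (the collapsed move makes this worth ~100-300
effective h^2 samples at n = 320) and 10^5 for single-dataset analyses,
versus the ~10^6 of the original workflow; full-length runs are a config
change.  Method-comparison and sample-size experiments default to 50 and
5 replicates respectively (down from 200 replicates and single long
chains).  At these scales the replicate-median of ordered-probit
estimates in the headline recovery scenario carries its own Monte Carlo
spread of a few percent; the acceptance script reports the deviation it
actually measures.

## Weak identification of the variance partition

A caution that shapes several results: with a heavily zero-inflated
ordinal trait, the split of latent variance into additive and residual
components is only weakly identified.  The individual-specific
(Mendelian-segregation) part of a breeding value is statistically
confounded with the residual at the single-measurement level, so the
partition is informed solely by between-relative covariances — and most
related pairs share the unaffected category, which carries little
signal.  When the likelihood is nearly flat in the partition, the
x^{-(1+0.01)} inverse-gamma prior densities dominate and the posterior
piles mass at h^2 = 0 or 1 for some replicates even when the truth is
interior; an independent general-purpose MCMC implementation of the same
model (via JAGS) reproduces this behaviour on the same data, confirming
it is a property of the model and prior, not of this sampler.  The
practical consequences: per-replicate point estimates of h^2 scatter
widely (their *median* across replicates remains close to the truth —
this is what the acceptance script measures); and the ten-bin
estimability criterion, which penalizes end-bin mass, is sensitive to
exactly how informative a design is per individual, so the sample size
at which a design crosses into estimability depends strongly on
simulation conditions (liability scale, covariate spread, cutpoint
placement) that real studies should pin down from pilot data.

## Known limitations

* Dominance variance, REML, multi-trait models, censored-Gaussian
  responses, and marker-based relatedness are out of scope.
* The real motivating dataset is not bundled; `real_data_analysis`
  accepts its file formats, and the synthetic colony study reproduces
  its structure only.
* The Wald CI for h^2 at a boundary optimum is a qualitative summary.
* The estimability verdict at a given sample size is a Monte Carlo
  quantity; near the threshold sample size, verdicts at adjacent grid
  points can disagree between runs with different seeds.
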