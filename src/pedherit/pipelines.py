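"""End-to-end analysis pipelines.

Four experiment drivers built on the library modules:

* :func:`derive_ost_phenotypes` — turn a raw per-space ordinal score
  table into the derived traits (10-category ordinal, average, binary);
* :func:`method_comparison` — simulate traits at several true
  heritabilities and compare ML-under-normality with the Bayesian fit
  (Gaussian for normal traits, ordered probit for ordinal traits);
* :func:`sample_size_search` — walk a relatedness-ordered subset grid
  and find the smallest sample with estimable heritability;
* :func:`real_data_analysis` — descriptive statistics plus the full set
  of heritability fits for a pedigree + phenotype file pair;
* :func:`prior_sensitivity` — posterior behaviour under increasingly
  informative variance priors at two sample sizes.

All drivers are deterministic given their seed and return plain
dataclasses / DataFrames; the CLI wraps them thinly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import EstimabilityReport, estimability, posterior_summary
from .errors import ConfigError
from .macaque import ALL_SPACES, FOCUS_SPACES
from .mcmc import (
    MCMCConfig,
    PosteriorSamples,
    PriorSpec,
    induced_h2_prior_draws,
    recode_contiguous,
    run_mcmc,
)
from .ml import fit_ml
from .model import VarianceComponents
from .pedigree import (
    KinshipMatrix,
    SubsetOrdering,
    build_three_generation_pedigree,
    kinship_matrix,
    read_pedigree,
)
from .simulate import (
    ScenarioConfig,
    TraitDataset,
    generate_dataset,
    scenario_preset,
    zero_inflated_proportions,
)

__all__ = [
    "OstPhenotypes",
    "SampleSizeResult",
    "read_raw_ost",
    "derive_ost_phenotypes",
    "method_comparison",
    "summarize_method_comparison",
    "sample_size_search",
    "three_generation_sample_size_search",
    "real_data_analysis",
    "prior_sensitivity",
]


# --- raw score tables -----------------------------------------------------


def read_raw_ost(path_or_frame, *, covariate_cols=("age", "mass", "parity")) -> pd.DataFrame:
    """Read a raw OST score table, wide or long, into wide form.

    Wide form: one row per individual, columns ``id``, covariates and one
    column per intervertebral space (scores 0-3 or empty).  Long form:
    columns ``id, space_label, score`` (covariates repeated per row).
    The format is auto-detected from the columns.
    """
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) else pd.read_csv(path_or_frame)
    df = df.copy()
    df.columns = [str(c) for c in df.columns]
    if "space_label" in df.columns:  # long format
        idx_cols = ["id"] + [c for c in covariate_cols if c in df.columns]
        wide = df.pivot_table(index=idx_cols, columns="space_label", values="score", aggfunc="first")
        wide = wide.reset_index()
        wide.columns.name = None
        df = wide
    if "id" not in df.columns:
        raise ConfigError("raw OST table needs an 'id' column")
    df["id"] = df["id"].astype(str)
    return df


@dataclass(frozen=True)
class OstPhenotypes:
    """Derived traits from raw per-space scores.

    ``table`` has one row per retained (complete-data) individual with
    columns ``id``, ``ordinal`` (codes 0..C-1), ``average``, ``binary``
    and any covariates carried over.  ``merge_map`` maps each raw summed
    score to its merged ordinal code.
    """

    table: pd.DataFrame = field(repr=False)
    n_input: int = 0
    n_complete: int = 0
    n_categories: int = 0
    category_counts: tuple = ()
    merge_map: dict = field(default_factory=dict)
    dropped_ids: tuple = ()
    spaces: tuple = FOCUS_SPACES


def _merge_small_categories(values: np.ndarray, min_count: int = 3):
    """Left-to-right sweep merging adjacent categories with < min_count
    members into their right neighbour (left for the last), repeated
    until stable.  Returns (codes 0..C-1 aligned with values, merge map,
    category counts)."""
    cats = sorted(np.unique(values).tolist())
    groups = [[c] for c in cats]
    counts = [int(np.sum(values == c)) for c in cats]
    stable = False
    while not stable:
        stable = True
        for i in range(len(groups)):
            if counts[i] < min_count and len(groups) > 1:
                j = i + 1 if i + 1 < len(groups) else i - 1
                lo, hi = sorted((i, j))
                groups[lo] = groups[lo] + groups[hi]
                counts[lo] = counts[lo] + counts[hi]
                del groups[hi], counts[hi]
                stable = False
                break
    merge_map = {}
    for code, members in enumerate(groups):
        for c in members:
            merge_map[c] = code
    codes = np.array([merge_map[v] for v in values], dtype=int)
    return codes, merge_map, tuple(counts)


def derive_ost_phenotypes(
    raw,
    *,
    spaces=FOCUS_SPACES,
    min_count: int = 3,
    covariate_cols=("age", "mass", "parity"),
) -> OstPhenotypes:
    """Derive the ordinal, average and binary OST traits.

    Individuals missing any score on the focus ``spaces`` are dropped.
    The ordinal trait is the sum of the focus scores with adjacent
    categories of fewer than ``min_count`` individuals merged
    (left-to-right, repeated until stable) and recoded 0..C-1; the
    average trait is the mean focus score; the binary trait indicates a
    nonzero sum.
    """
    df = read_raw_ost(raw, covariate_cols=covariate_cols)
    missing_cols = [s for s in spaces if s not in df.columns]
    if missing_cols:
        raise ConfigError(f"focus spaces absent from table: {missing_cols}")
    sub = df[list(spaces)].apply(pd.to_numeric, errors="coerce")
    complete = sub.notna().all(axis=1)
    kept = df.loc[complete].reset_index(drop=True)
    scores = sub.loc[complete].to_numpy(dtype=float)
    if np.any((scores < 0) | (scores > 3)):
        raise ConfigError("per-space scores must lie in {0, 1, 2, 3}")
    sums = scores.sum(axis=1).astype(int)
    codes, merge_map, counts = _merge_small_categories(sums, min_count)
    if len(counts) < 2:
        raise ConfigError("fewer than 2 ordinal categories after merging")
    out = pd.DataFrame({"id": kept["id"].astype(str)})
    out["ordinal"] = codes
    out["average"] = scores.mean(axis=1)
    out["binary"] = (sums > 0).astype(int)
    out["ost_sum"] = sums
    for c in covariate_cols:
        if c in kept.columns:
            out[c] = pd.to_numeric(kept[c], errors="coerce")
    return OstPhenotypes(
        table=out,
        n_input=int(len(df)),
        n_complete=int(complete.sum()),
        n_categories=len(counts),
        category_counts=counts,
        merge_map=merge_map,
        dropped_ids=tuple(df.loc[~complete, "id"].astype(str)),
        spaces=tuple(spaces),
    )


# --- method comparison ----------------------------------------------------


def _bayes_point_estimate(samples: PosteriorSamples) -> float:
    h2 = samples.h2
    return float(np.nanmedian(h2))


def method_comparison(
    *,
    h2_values=(0.4, 0.6, 0.75, 0.90),
    shapes=("normal", "ordinal"),
    n_families: int = 40,
    n_replicates: int = 50,
    mcmc: MCMCConfig | None = None,
    prior: PriorSpec | None = None,
    seed: int = 0,
    covariates=("age",),
) -> pd.DataFrame:
    """Simulate-and-refit comparison of ML-normal vs the Bayesian fit.

    For each true h^2 and trait shape, ``n_replicates`` datasets are
    simulated on the replicated three-generation pedigree; ML under
    normality is fit to every dataset, the Bayesian model matches the
    shape (Gaussian for normal traits, ordered probit for ordinal).
    Returns one row per (scenario, replicate, method) with the point
    estimate (posterior median for Bayes); failed replicates are recorded
    with a NaN estimate.
    """
    prior = prior or PriorSpec()
    base_mcmc = mcmc or MCMCConfig(n_iter=20_000, burn_in=5_000, thin=10)
    rows = []
    ped = build_three_generation_pedigree(n_families)
    k = kinship_matrix(ped)
    from scipy.linalg import cholesky

    chol = cholesky(2.0 * k.phi, lower=True)
    for shape in shapes:
        preset = "three_gen_normal" if shape == "normal" else "three_gen_ordinal10"
        for h2 in h2_values:
            cfg = scenario_preset(preset, h2=h2, n_families=n_families, seed=seed)
            for r in range(n_replicates):
                data, _ = generate_dataset(cfg, r, kinship=k, chol_2phi=chol)
                try:
                    ml_est = fit_ml(data, k, covariates).h2_hat
                except Exception:
                    ml_est = np.nan
                mc = dataclasses.replace(
                    base_mcmc,
                    response="gaussian" if shape == "normal" else "ordinal",
                    seed=int(np.random.SeedSequence([seed, int(h2 * 1000), r]).generate_state(1)[0] % (2**31)),
                )
                try:
                    fit_data = recode_contiguous(data) if shape == "ordinal" else data
                    samples = run_mcmc(fit_data, k, prior, mc, covariates)
                    bayes_est = _bayes_point_estimate(samples)
                except Exception:
                    bayes_est = np.nan
                rows.append((shape, h2, r, "ml_normal", ml_est))
                method = "bayes_normal" if shape == "normal" else "bayes_opr"
                rows.append((shape, h2, r, method, bayes_est))
    return pd.DataFrame(rows, columns=["shape", "h2_true", "replicate", "method", "h2_hat"])


def summarize_method_comparison(results: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of the estimates per scenario and method."""
    def q(p):
        return lambda x: np.nanquantile(x, p)

    g = results.groupby(["shape", "h2_true", "method"])["h2_hat"]
    out = g.agg(median="median", q25=q(0.25), q75=q(0.75), n_ok=lambda x: int(np.isfinite(x).sum()))
    return out.reset_index()


# --- sample size search ---------------------------------------------------


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of an estimability-driven sample-size grid search."""

    scenario: str
    n_grid: tuple
    estimable_fraction: tuple  # per grid point, over replicates
    estimable: tuple  # majority verdict per grid point
    min_estimable_n: int | None
    non_monotone: bool
    details: tuple = ()  # per (n, replicate) EstimabilityReport bin masses

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.n_grid, "estimable_fraction": self.estimable_fraction,
             "estimable": self.estimable}
        )


def _search_from_scenarios(scenarios, n_grid, n_replicates, mcmc, prior, covariates, seed, label):
    flags, fracs, details = [], [], []
    for gi, (n, cfg, k, chol) in enumerate(scenarios):
        reps = []
        for r in range(n_replicates):
            data, _ = generate_dataset(cfg, r, kinship=k, chol_2phi=chol)
            data = recode_contiguous(data)
            mc = dataclasses.replace(
                mcmc,
                response="ordinal",
                seed=int(np.random.SeedSequence([seed, gi, r]).generate_state(1)[0] % (2**31)),
            )
            samples = run_mcmc(data, k, prior, mc, covariates)
            rep = estimability(samples.h2[~np.isnan(samples.h2)])
            reps.append(rep.estimable)
            details.append((n, r, tuple(rep.bin_masses)))
        frac = float(np.mean(reps))
        fracs.append(frac)
        flags.append(frac > 0.5)
    min_n = None
    for n, ok in zip(n_grid, flags):
        if ok:
            min_n = int(n)
            break
    non_monotone = False
    if min_n is not None:
        after = [ok for n, ok in zip(n_grid, flags) if n >= min_n]
        non_monotone = not all(after)
    return SampleSizeResult(
        scenario=label,
        n_grid=tuple(int(n) for n in n_grid),
        estimable_fraction=tuple(fracs),
        estimable=tuple(bool(f) for f in flags),
        min_estimable_n=min_n,
        non_monotone=non_monotone,
        details=tuple(details),
    )


def sample_size_search(
    k: KinshipMatrix,
    ordering: SubsetOrdering,
    scenario: ScenarioConfig,
    n_grid,
    *,
    n_replicates: int = 5,
    mcmc: MCMCConfig | None = None,
    prior: PriorSpec | None = None,
    covariates=("age",),
    seed: int = 0,
) -> SampleSizeResult:
    """Estimability along a cumulative-kinship ordering.

    For each n in ``n_grid`` the first n individuals of ``ordering``
    become the phenotyped set; ``n_replicates`` ordinal datasets are
    simulated per n and fitted with the threshold-model MCMC, and the
    ten-bin estimability criterion is applied to each posterior.  A grid
    point is estimable when the majority of replicates are;
    ``min_estimable_n`` is the smallest such n, and any larger
    non-estimable n is reported as ``non_monotone`` rather than hidden.
    """
    n_grid = sorted(int(n) for n in n_grid)
    if n_grid[0] < 2:
        raise ConfigError("grid sample sizes must be >= 2")
    if n_grid[-1] > len(ordering.kept_ids):
        raise ConfigError("grid exceeds the ordering length")
    mcmc = mcmc or MCMCConfig(n_iter=20_000, burn_in=5_000, thin=10)
    prior = prior or PriorSpec()
    from scipy.linalg import cholesky

    chol = cholesky(2.0 * k.phi, lower=True)
    scenarios = []
    for n in n_grid:
        ids = tuple(ordering.kept_ids[:n])
        cfg = dataclasses.replace(scenario, phenotyped_ids=ids, covariates=None)
        scenarios.append((n, cfg, k, chol))
    return _search_from_scenarios(
        scenarios, n_grid, n_replicates, mcmc, prior, covariates, seed, scenario.name
    )


def three_generation_sample_size_search(
    family_grid,
    *,
    h2: float = 0.6,
    age_shift: float = 0.0,
    n_replicates: int = 5,
    mcmc: MCMCConfig | None = None,
    prior: PriorSpec | None = None,
    seed: int = 0,
) -> SampleSizeResult:
    """Sample-size search over whole three-generation families.

    The natural sampling unit of the replicated-family design is the
    eight-member family, so the grid is in family counts; the result's
    ``n_grid`` is reported in individuals (8 per family).
    """
    family_grid = sorted(int(f) for f in family_grid)
    mcmc = mcmc or MCMCConfig(n_iter=20_000, burn_in=5_000, thin=10)
    prior = prior or PriorSpec()
    from scipy.linalg import cholesky

    scenarios = []
    n_grid = []
    for f in family_grid:
        preset = "age_shift_5" if age_shift else "three_gen_ordinal10"
        cfg = scenario_preset(preset, h2=h2, n_families=f, seed=seed)
        if age_shift and age_shift != 5.0:
            cfg = dataclasses.replace(cfg, age_shift=age_shift)
        k = kinship_matrix(cfg.pedigree)
        chol = cholesky(2.0 * k.phi, lower=True)
        n_grid.append(8 * f)
        scenarios.append((8 * f, cfg, k, chol))
    label = f"three_generation{'_age_shift' if age_shift else ''}"
    return _search_from_scenarios(
        scenarios, n_grid, n_replicates, mcmc, prior, ("age",), seed, label
    )


# --- real data analysis ---------------------------------------------------


def real_data_analysis(
    pedigree_file,
    phenotype_file,
    *,
    covariates=("age", "mass", "parity"),
    spaces=FOCUS_SPACES,
    mcmc: MCMCConfig | None = None,
    prior: PriorSpec | None = None,
    seed: int = 0,
) -> dict:
    """Descriptive statistics and all heritability fits for a study.

    Expects a pedigree file (``id sire dam [sex]``) and a raw per-space
    phenotype table (wide or long).  Produces the descriptive table
    (mean, median, min, max, SD for the summed trait and covariates), an
    ML-normal and a Bayesian-Gaussian fit of the average score, and
    Bayesian ordered-probit fits of the binary and merged-ordinal scores,
    all adjusted for the requested covariates.
    """
    ped = read_pedigree(pedigree_file)
    k = kinship_matrix(ped)
    phen = derive_ost_phenotypes(read_raw_ost(phenotype_file), spaces=spaces)
    tab = phen.table
    if not covariates:
        covariates = ()
    missing_cov = [c for c in covariates if c not in tab.columns]
    if missing_cov:
        raise ConfigError(f"covariates absent from phenotype table: {missing_cov}")

    def describe(col):
        x = tab[col].to_numpy(dtype=float)
        return {
            "mean": float(np.mean(x)), "median": float(np.median(x)),
            "min": float(np.min(x)), "max": float(np.max(x)),
            "sd": float(np.std(x, ddof=1)),
        }

    table1 = {"ost_sum": describe("ost_sum")}
    for c in covariates:
        table1[c] = describe(c)

    cov_df = tab.set_index("id")[list(covariates)] if covariates else pd.DataFrame(index=tab["id"])
    ids = tuple(tab["id"])

    def dataset(col, shape, n_categories=None):
        return TraitDataset(
            ids=ids, y=tab[col].to_numpy(dtype=float), covariates=cov_df,
            shape=shape, n_categories=n_categories,
        )

    mcmc = mcmc or MCMCConfig(n_iter=100_000, burn_in=10_000, thin=10)
    prior = prior or PriorSpec()
    seeds = np.random.SeedSequence(seed).generate_state(3) % (2**31)

    avg = dataset("average", "normal")
    ml = fit_ml(avg, k, covariates)
    bayes_normal = run_mcmc(
        avg, k, prior, dataclasses.replace(mcmc, response="gaussian", seed=int(seeds[0])), covariates
    )
    bayes_binary = run_mcmc(
        dataset("binary", "ordinal", 2), k, prior,
        dataclasses.replace(mcmc, response="ordinal", seed=int(seeds[1])), covariates,
    )
    bayes_ordinal = run_mcmc(
        dataset("ordinal", "ordinal", phen.n_categories), k, prior,
        dataclasses.replace(mcmc, response="ordinal", seed=int(seeds[2])), covariates,
    )

    def bayes_report(samples):
        h2 = samples.h2[~np.isnan(samples.h2)]
        rep = posterior_summary(h2)
        rep["sigma_A2_mean"] = float(np.mean(samples.sigma_A2))
        rep["sigma_E2_mean"] = float(np.mean(samples.sigma_E2))
        rep["estimability"] = dataclasses.asdict(estimability(h2)) | {
            "bin_masses": [float(m) for m in estimability(h2).bin_masses]
        }
        return rep

    return {
        "n_input": phen.n_input,
        "n_complete": phen.n_complete,
        "n_categories": phen.n_categories,
        "category_counts": list(phen.category_counts),
        "covariates": list(covariates),
        "intercept_only": not covariates,
        "table1": table1,
        "ml_normal_average": ml.to_dict(),
        "bayes_normal_average": bayes_report(bayes_normal),
        "bayes_opr_binary": bayes_report(bayes_binary),
        "bayes_opr_ordinal": bayes_report(bayes_ordinal),
    }


# --- prior sensitivity ----------------------------------------------------


def prior_sensitivity(
    *,
    shapes=(0.01, 0.1, 0.2),
    h2: float = 0.6,
    sigma_Y2: float = 100.0,
    n_values=(173, 542),
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    n_prior_draws: int = 100_000,
    study_seed: int = 0,
) -> dict:
    """Posterior behaviour under matched inverse-gamma prior shapes.

    For each shape s (equal shape and scale), variance priors
    IG(s, s) induce a Beta(s, s) prior on h^2.  Ordinal data are
    simulated at the requested sample sizes on the synthetic colony
    pedigree (h^2 = ``h2``) and refit under each prior; the report holds
    induced-prior draws, posterior h^2 samples, summaries and the
    estimability verdicts.
    """
    from .macaque import synthesize_macaque_study

    study = synthesize_macaque_study(seed=study_seed)
    ped = study.pedigree
    k = kinship_matrix(ped)
    from scipy.linalg import cholesky

    chol = cholesky(2.0 * k.phi, lower=True)
    mcmc = mcmc or MCMCConfig(n_iter=40_000, burn_in=10_000, thin=10)
    out = {}
    rng = np.random.default_rng(seed)
    for si, s in enumerate(shapes):
        prior = PriorSpec(alpha_A=s, gamma_A=s, alpha_E=s, gamma_E=s)
        entry = {
            "prior_shape": s,
            "prior_draws": induced_h2_prior_draws(prior, n_prior_draws, rng),
            "posteriors": {},
        }
        for ni, n in enumerate(n_values):
            if n == len(study.complete_ids):
                ids = tuple(study.complete_ids)
            elif n == ped.n:
                ids = tuple(ped.ids)
            else:
                ids = tuple(list(ped.ids)[:n])
            cov = None
            cfg = ScenarioConfig(
                pedigree=ped, phenotyped_ids=ids,
                vc=VarianceComponents.from_h2(h2, sigma_Y2),
                proportions=zero_inflated_proportions(),
                seed=seed, covariates=cov, name=f"prior_sens_n{n}",
            )
            data, _ = generate_dataset(cfg, 0, kinship=k, chol_2phi=chol)
            data = recode_contiguous(data)
            mc = dataclasses.replace(
                mcmc, response="ordinal",
                seed=int(np.random.SeedSequence([seed, si, ni]).generate_state(1)[0] % (2**31)),
            )
            samples = run_mcmc(data, k, prior, mc, ("age",))
            h2s = samples.h2[~np.isnan(samples.h2)]
            entry["posteriors"][int(n)] = {
                "h2_samples": h2s,
                "summary": posterior_summary(h2s),
                "estimability": estimability(h2s),
            }
        out[float(s)] = entry
    return out
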