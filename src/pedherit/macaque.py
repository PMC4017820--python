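"""Synthetic emulation of a captive macaque colony study.

Everything in this module is SYNTHETIC.  It emulates the *structure* of a
radiographic osteophytosis (OST) study in a captive pig-tailed macaque
colony — it is not the real dataset, and quantities estimated from it say
nothing about real monkeys.  The emulated features are:

* a six-generation pedigree of 542 individuals;
* 189 phenotyped females, 173 of which have complete scores on the seven
  focus intervertebral spaces (L5 up to T10), the other 16 having at
  least one of those scores missing;
* among the 173 complete-data females, exactly 28 unrelated to every
  other member of that set;
* per-space OST scores in {0, 1, 2, 3} (unaffected / slight / moderate /
  severe) at up to 16 intervertebral spaces, with a zero-inflated total:
  115 of the 173 complete females score 0 on all seven focus spaces, and
  the summed focus score, after merging adjacent categories with fewer
  than three individuals, yields 10 ordered categories;
* covariates shaped like the published descriptive statistics: age with
  mean near 9.8 years on (4.7, 29.2), body mass near N(7.06, 1.40^2) kg,
  and parity increasing with age (about half the females nulliparous).

The per-space scores are driven by a heritable liability simulated on the
pedigree, so the emulated trait carries a genuine genetic signal
(default h^2 = 0.6) through the documented polygenic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import VarianceComponents
from .pedigree import Pedigree, kinship_matrix, _make_pedigree
from .simulate import simulate_liability

__all__ = [
    "SyntheticColonyStudy",
    "build_wanprc_like_pedigree",
    "synthesize_macaque_study",
    "FOCUS_SPACES",
    "ALL_SPACES",
]

#: The seven focus intervertebral spaces (L5 up to T10) used for the
#: derived phenotype, and the full set of 16 scored spaces.
FOCUS_SPACES = ("T10T11", "T11T12", "T12L1", "L1L2", "L2L3", "L3L4", "L4L5")
ALL_SPACES = (
    "C7T1", "T1T2", "T2T3", "T3T4", "T4T5", "T5T6", "T6T7", "T7T8", "T8T9",
) + FOCUS_SPACES

#: Target counts of the summed focus score over the 173 complete females.
#: 115 zeros; sparse high categories so that merging adjacent categories
#: with < 3 individuals yields 10 ordered categories.
_SUM_COUNTS = (115, 14, 10, 8, 6, 5, 4, 3, 3, 2, 1, 1, 1)

_GEN_SIZES = (120, 100, 90, 80, 70, 54)  # six cohorts, 514 related individuals
_N_ISOLATED = 28


@dataclass(frozen=True)
class SyntheticColonyStudy:
    """A synthetic colony pedigree with raw OST scores and covariates."""

    pedigree: Pedigree
    raw: pd.DataFrame = field(repr=False)  # one row per phenotyped female
    phenotyped_ids: tuple  # all 189 phenotyped
    complete_ids: tuple  # the 173 with complete focus-space scores
    generation: dict = field(repr=False, default_factory=dict)


def build_wanprc_like_pedigree(seed: int = 0):
    """Six-generation synthetic colony pedigree of 542 individuals.

    Returns ``(pedigree, generation)`` where ``generation`` maps id ->
    cohort index (isolated late-introduction females get the last cohort).
    Cohorts 1+ mix within-cohort matings with immigrant founders; exactly
    28 individuals are founders without descendants, unrelated to everyone.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 542]))
    records = []
    generation = {}
    counter = [0]

    def new_id(prefix):
        counter[0] += 1
        return f"{prefix}{counter[0]:04d}"

    cohorts: list[list] = []
    males: dict[int, list] = {}
    females: dict[int, list] = {}
    for g, size in enumerate(_GEN_SIZES):
        cohort = []
        if g == 0:
            for _ in range(size):
                ind = new_id("M")
                sex = "M" if len(cohort) % 2 == 0 else "F"
                records.append((ind, None, None, sex))
                cohort.append((ind, sex))
        else:
            # immigrant founders join each cohort; the rest are offspring
            n_imm = max(2, int(round(0.15 * size)))
            n_children = size - n_imm
            imm = []
            for j in range(n_imm):
                ind = new_id("M")
                sex = "M" if j % 2 == 0 else "F"
                records.append((ind, None, None, sex))
                imm.append((ind, sex))
            prev_m = males[g - 1][:]
            prev_f = females[g - 1][:]
            rng.shuffle(prev_m)
            rng.shuffle(prev_f)
            imm_m = [i for i, s in imm if s == "M"]
            imm_f = [i for i, s in imm if s == "F"]
            couples = []
            # pair within the previous cohort, then marry leftovers to immigrants
            n_within = min(len(prev_m), len(prev_f))
            n_within = int(round(0.7 * n_within))
            couples += list(zip(prev_m[:n_within], prev_f[:n_within]))
            couples += list(zip(prev_m[n_within:], imm_f))
            couples += list(zip(imm_m, prev_f[n_within:]))
            if not couples:
                raise RuntimeError("no couples available for cohort construction")
            assign = rng.choice(len(couples), size=n_children)
            for ci in assign:
                sire, dam = couples[ci]
                ind = new_id("M")
                sex = "M" if rng.random() < 0.5 else "F"
                records.append((ind, sire, dam, sex))
                cohort.append((ind, sex))
            cohort += imm
        for ind, sex in cohort:
            generation[ind] = g
        males[g] = [i for i, s in cohort if s == "M"]
        females[g] = [i for i, s in cohort if s == "F"]
        cohorts.append([i for i, _ in cohort])

    # 28 isolated founder females: phenotyped but unrelated to everyone
    for _ in range(_N_ISOLATED):
        ind = new_id("U")
        records.append((ind, None, None, "F"))
        generation[ind] = len(_GEN_SIZES) - 1
    ped = _make_pedigree(records)
    assert ped.n == sum(_GEN_SIZES) + _N_ISOLATED
    return ped, generation


def _connect(k, core, pool):
    """Swap members of ``core`` with zero kinship to the rest of ``core``
    for pool members most related to the current set (greedy)."""
    core = [str(i) for i in core]
    pool = [str(i) for i in pool]
    for _ in range(200):
        idx = k.index(core)
        sub = k.phi[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, 0.0)
        lonely = [core[j] for j in range(len(core)) if sub[j].sum() == 0.0]
        if not lonely:
            return core, pool
        for lone in lonely:
            core.remove(lone)
        cur = k.index(core)
        cum = k.phi[:, cur].sum(axis=1)
        repl = sorted(pool, key=lambda f: -cum[k.index([f])[0]])[: len(lonely)]
        for r in repl:
            pool.remove(r)
            core.append(r)
    raise RuntimeError("could not build a fully connected phenotyped set")  # pragma: no cover


def _pick_phenotyped(ped, generation, rng):
    """189 phenotyped females: 28 isolated + 145 related complete-data +
    16 related incomplete, with every complete related female sharing
    ancestry with at least one other complete phenotyped female."""
    isolated = [str(i) for i in ped.ids if str(i).startswith("U")]
    k = kinship_matrix(ped)
    females = [
        str(i)
        for i in ped.ids
        if ped.sex.get(i) == "F" and not str(i).startswith("U") and generation[i] >= 1
    ]
    # younger cohorts over-represented, as in the described colony sample
    w = np.array([1.0 + 1.2 * generation[i] for i in females])
    chosen = [str(x) for x in rng.choice(females, size=161, replace=False, p=w / w.sum())]
    incomplete = [str(x) for x in rng.choice(chosen, size=16, replace=False)]
    complete_related = [f for f in chosen if f not in set(incomplete)]
    pool = [f for f in females if f not in set(chosen)]
    complete_related, pool = _connect(k, complete_related, pool)
    return isolated, complete_related, incomplete, k


def synthesize_macaque_study(
    seed: int = 0,
    h2: float = 0.6,
    beta_age: float = 0.12,
) -> SyntheticColonyStudy:
    """Generate the full synthetic study (pedigree + raw score table).

    ``beta_age`` is the liability age slope per year on a unit-variance
    liability; the default gives the strong age-OST association the study
    describes while keeping genetic signal visible.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1009]))
    ped, generation = build_wanprc_like_pedigree(seed)
    isolated, complete_related, incomplete, k = _pick_phenotyped(ped, generation, rng)
    phenotyped = isolated + complete_related + incomplete

    # covariates: age by cohort (younger cohorts younger), deterministic
    # Beta-shaped quantile spread matching the published summary shape
    n = len(phenotyped)
    from scipy.stats import beta as beta_dist

    q = (np.arange(n) + 0.5) / n
    ages_sorted = 4.7 + 24.5 * beta_dist.ppf(q, 0.62, 2.3)
    gen_arr = np.array([generation[i] for i in phenotyped], dtype=float)
    age_rank_score = -gen_arr + rng.normal(0, 0.9, size=n)  # older cohorts -> older ages
    order = np.argsort(np.argsort(age_rank_score))
    age = ages_sorted[order]
    mass = np.clip(rng.normal(7.06, 1.40, size=n), 4.53, 12.35)
    parity = np.minimum(rng.poisson(np.maximum(0.0, 0.42 * (age - 4.7))), 15)

    # heritable liability driving the scores
    vc = VarianceComponents.from_h2(h2, 1.0)
    X = np.column_stack([np.ones(n), age])
    state = simulate_liability(k, phenotyped, X, np.array([0.0, beta_age]), vc, rng)
    u = state.U

    # complete set: the 28 isolated plus 145 related females
    complete = [i for i in phenotyped if i not in set(incomplete)]

    # summed focus score by liability rank within the complete set (a
    # quantile discretization with the target zero-inflated counts)
    pos = {ind: j for j, ind in enumerate(phenotyped)}
    u_complete = np.array([u[pos[i]] for i in complete])
    ranks = np.argsort(np.argsort(u_complete))
    bounds = np.cumsum(_SUM_COUNTS)
    sum_complete = np.searchsorted(bounds, ranks, side="right")
    sums = {}
    for ind, s in zip(complete, sum_complete):
        sums[ind] = int(s)
    # incomplete females: threshold their liabilities with the same cuts
    cut_values = np.sort(u_complete)[bounds[:-1] - 1]
    for ind in incomplete:
        sums[ind] = int(np.searchsorted(cut_values, u[pos[ind]], side="left"))

    rows = []
    for ind in phenotyped:
        s = sums[ind]
        scores = np.zeros(len(FOCUS_SPACES), dtype=float)
        remaining = s
        while remaining > 0:
            open_spaces = np.flatnonzero(scores < 3)
            scores[rng.choice(open_spaces)] += 1
            remaining -= 1
        row = {"id": ind, "age": age[pos[ind]], "mass": mass[pos[ind]], "parity": int(parity[pos[ind]])}
        for sp, sc in zip(FOCUS_SPACES, scores):
            row[sp] = sc
        # the other nine spaces: correlated scores, heavy missingness
        for sp in ALL_SPACES:
            if sp in FOCUS_SPACES:
                continue
            if rng.random() < 0.45:
                row[sp] = np.nan
            else:
                row[sp] = float(rng.binomial(3, min(0.85, s / 14.0 + 0.03)))
        rows.append(row)
    raw = pd.DataFrame(rows)
    # blank 1-2 focus spaces for the incomplete females
    for ind in incomplete:
        n_blank = 1 + int(rng.random() < 0.4)
        for sp in rng.choice(FOCUS_SPACES, size=n_blank, replace=False):
            raw.loc[raw["id"] == ind, sp] = np.nan

    return SyntheticColonyStudy(
        pedigree=ped,
        raw=raw,
        phenotyped_ids=tuple(phenotyped),
        complete_ids=tuple(complete),
        generation=generation,
    )
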