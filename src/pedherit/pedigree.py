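"""Pedigrees and kinship matrices.

A pedigree is a directed acyclic parentage structure.  From it we compute
the kinship matrix Phi, whose entry Phi_ij is the probability that two
gene copies drawn at random, one from individual i and one from j, are
identical by descent.  Twice the kinship matrix (the additive
relationship matrix A = 2 Phi) is the covariance multiplier of breeding
values in the animal model.

Kinship is computed by the recursive tabular method over a topological
order: for individual i with parents s and d,

    Phi_ii = 1/2 (1 + Phi_sd),
    Phi_ij = 1/2 (Phi_sj + Phi_dj)   for j preceding i,

with unknown parents contributing 0.  Pedigrees of the sizes handled here
(hundreds to a few thousand individuals) make dense O(n^2) storage
trivial, so no sparse-inverse machinery is used.  Inbreeding is permitted
(diagonal entries may exceed 0.5).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import NumericalError, PedigreeValidationError, UnsupportedFeatureError
from .model import VarianceComponents

__all__ = [
    "Pedigree",
    "KinshipMatrix",
    "SubsetOrdering",
    "START_FROM_MOST_RELATED",
    "read_pedigree",
    "write_pedigree",
    "topological_order",
    "kinship_matrix",
    "additive_covariance",
    "build_three_generation_pedigree",
    "cumulative_kinship_ordering",
]

#: Sentinel for :func:`cumulative_kinship_ordering`: seed the greedy search
#: with the single individual most related to all others.
START_FROM_MOST_RELATED = "__START_FROM_MOST_RELATED__"


@dataclass(frozen=True)
class Pedigree:
    """Validated parentage records.

    ``sire`` / ``dam`` map each individual id to its parent id or ``None``
    for an unknown parent; founders have both parents unknown.  ``sex`` is
    carried for round-tripping only and never used in computation.
    """

    ids: tuple
    sire: dict
    dam: dict
    sex: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate(self)

    @property
    def n(self) -> int:
        return len(self.ids)

    def parents(self, ind) -> tuple:
        return self.sire[ind], self.dam[ind]

    def founders(self) -> list:
        return [i for i in self.ids if self.sire[i] is None and self.dam[i] is None]

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "id": list(self.ids),
            "sire": [self.sire[i] for i in self.ids],
            "dam": [self.dam[i] for i in self.ids],
        }
        if self.sex:
            rows["sex"] = [self.sex.get(i) for i in self.ids]
        return pd.DataFrame(rows)


def _validate(ped: Pedigree) -> None:
    seen = set()
    for ind in ped.ids:
        if ind in seen:
            raise PedigreeValidationError(f"duplicate individual id: {ind!r}")
        seen.add(ind)
    for ind in ped.ids:
        for parent in (ped.sire[ind], ped.dam[ind]):
            if parent is not None and parent not in seen:
                raise PedigreeValidationError(
                    f"parent id {parent!r} of individual {ind!r} has no pedigree record"
                )
    # acyclicity is established by the topological sort
    topological_order(ped)


def _make_pedigree(records: Iterable[tuple]) -> Pedigree:
    """Build a Pedigree from (id, sire-or-None, dam-or-None[, sex]) tuples."""
    ids, sire, dam, sex = [], {}, {}, {}
    for rec in records:
        ind, s, d = rec[0], rec[1], rec[2]
        ids.append(ind)
        sire[ind] = s
        dam[ind] = d
        if len(rec) > 3 and rec[3] is not None:
            sex[ind] = rec[3]
    return Pedigree(ids=tuple(ids), sire=sire, dam=dam, sex=sex)


def read_pedigree(
    path,
    *,
    unknown: str = "0",
    delimiter: str | None = None,
    on_missing_parent: str = "error",
) -> Pedigree:
    """Read a delimited pedigree file ``id sire dam [sex]``.

    The delimiter is auto-detected (comma if the first line contains one,
    otherwise any whitespace); a header line is detected when the first
    field equals ``id`` case-insensitively.  ``unknown`` is the token
    denoting an unknown parent.

    ``on_missing_parent`` controls file hygiene for ids that appear only
    as parents: ``"error"`` (default) raises a validation error naming the
    id; ``"promote"`` inserts them as founder records with a warning.
    """
    if on_missing_parent not in ("error", "promote"):
        raise ValueError("on_missing_parent must be 'error' or 'promote'")
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "rt") as fh:
            text = fh.read()
    rows = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(",") if (delimiter or ("," if "," in line else " ")) == "," else line.split(delimiter)
        fields = [f.strip() for f in fields if f.strip() != ""]
        if len(fields) < 3:
            raise PedigreeValidationError(f"pedigree line has fewer than 3 columns: {line!r}")
        rows.append(fields)
    if rows and rows[0][0].lower() == "id":
        rows = rows[1:]
    records = []
    present = {r[0] for r in rows}
    promoted = []
    for r in rows:
        ind = r[0]
        s = None if r[1] == unknown else r[1]
        d = None if r[2] == unknown else r[2]
        sx = r[3] if len(r) > 3 else None
        for parent in (s, d):
            if parent is not None and parent not in present:
                if on_missing_parent == "promote":
                    promoted.append(parent)
                    present.add(parent)
                else:
                    raise PedigreeValidationError(
                        f"parent id {parent!r} of individual {ind!r} has no pedigree record"
                    )
        records.append((ind, s, d, sx))
    if promoted:
        warnings.warn(
            f"promoted {len(promoted)} parent-only id(s) to founder records: "
            + ", ".join(map(repr, promoted[:10])),
            stacklevel=2,
        )
        records = [(p, None, None, None) for p in promoted] + records
    return _make_pedigree(records)


def write_pedigree(ped: Pedigree, path, *, unknown: str = "0", delimiter: str = " ") -> None:
    """Write a pedigree in the same ``id sire dam [sex]`` dialect."""
    lines = []
    for ind in ped.ids:
        s = ped.sire[ind] or unknown
        d = ped.dam[ind] or unknown
        fields = [str(ind), str(s), str(d)]
        if ped.sex:
            fields.append(str(ped.sex.get(ind, unknown)))
        lines.append(delimiter.join(fields))
    out = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(out)
    else:
        with open(path, "wt") as fh:
            fh.write(out)


def topological_order(ped: Pedigree) -> list:
    """Order ids so every parent precedes each of its offspring.

    Kahn's algorithm with ties broken by input order, so the output is
    deterministic; a founders-only pedigree is returned in input order.
    """
    pos = {ind: k for k, ind in enumerate(ped.ids)}
    children: dict = {ind: [] for ind in ped.ids}
    indeg = {ind: 0 for ind in ped.ids}
    for ind in ped.ids:
        for parent in (ped.sire[ind], ped.dam[ind]):
            if parent is not None:
                children[parent].append(ind)
                indeg[ind] += 1
    import heapq

    ready = [pos[i] for i in ped.ids if indeg[i] == 0]
    heapq.heapify(ready)
    order = []
    ids = list(ped.ids)
    while ready:
        k = heapq.heappop(ready)
        ind = ids[k]
        order.append(ind)
        for child in children[ind]:
            indeg[child] -= 1
            if indeg[child] == 0:
                heapq.heappush(ready, pos[child])
    if len(order) < len(ids):
        cycle = sorted(i for i in ids if indeg[i] > 0)
        raise PedigreeValidationError(
            f"pedigree contains a cycle involving (a subset of): {cycle[:10]}"
        )
    return order


@dataclass(frozen=True)
class KinshipMatrix:
    """Kinship coefficients Phi over an ordered id list."""

    ids: tuple
    phi: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        object.__setattr__(self, "phi", phi)
        n = len(self.ids)
        if phi.shape != (n, n):
            raise ValueError("phi must be n x n with n = len(ids)")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, ids: Sequence) -> np.ndarray:
        lookup = {ind: k for k, ind in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not present in kinship matrix") from exc

    def subset(self, ids: Sequence) -> "KinshipMatrix":
        idx = self.index(ids)
        return KinshipMatrix(ids=tuple(ids), phi=self.phi[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=list(self.ids), columns=list(self.ids))

    def write(self, path, *, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index_label="id")

    @classmethod
    def read(cls, path, *, sep: str = ",") -> "KinshipMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(ids=tuple(df.index), phi=df.to_numpy(dtype=float))


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix over all individuals, in topological order."""
    order = topological_order(ped)
    pos = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for k, ind in enumerate(order):
        s, d = ped.sire[ind], ped.dam[ind]
        si = pos[s] if s is not None else None
        di = pos[d] if d is not None else None
        if k:
            row = np.zeros(k)
            if si is not None:
                row += phi[si, :k]
            if di is not None:
                row += phi[di, :k]
            row *= 0.5
            phi[k, :k] = row
            phi[:k, k] = row
        phi_sd = phi[si, di] if (si is not None and di is not None) else 0.0
        phi[k, k] = 0.5 * (1.0 + phi_sd)
    return KinshipMatrix(ids=tuple(order), phi=phi)


def additive_covariance(k: KinshipMatrix, vc: VarianceComponents) -> np.ndarray:
    """Trait covariance 2 sigma_A^2 Phi + sigma_E^2 I.

    Requires sigma_D2 = 0 (enforced by :class:`VarianceComponents`) and
    sigma_E2 > 0 so the result is positive definite.
    """
    if vc.sigma_D2 != 0:  # unreachable through VarianceComponents; guard raw use
        raise UnsupportedFeatureError("dominance covariance is out of scope")
    if vc.sigma_E2 <= 0:
        raise NumericalError("sigma_E2 must be > 0 for a positive-definite covariance")
    n = k.n
    return 2.0 * vc.sigma_A2 * k.phi + vc.sigma_E2 * np.eye(n)


def build_three_generation_pedigree(n_families: int) -> Pedigree:
    """Replicated three-generation families.

    Each family has eight members: two unrelated founder grandparents with
    two children, each child married to an unrelated founder spouse, and
    one grandchild per couple.  The two grandchildren are first cousins
    (kinship 1/16); distinct families are mutually unrelated.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    records = []
    for f in range(1, n_families + 1):
        p = f"F{f:03d}"
        gp1, gp2 = f"{p}_GP1", f"{p}_GP2"
        c1, c2 = f"{p}_C1", f"{p}_C2"
        s1, s2 = f"{p}_S1", f"{p}_S2"
        g1, g2 = f"{p}_G1", f"{p}_G2"
        records += [
            (gp1, None, None, "M"),
            (gp2, None, None, "F"),
            (c1, gp1, gp2, "M"),
            (c2, gp1, gp2, "F"),
            (s1, None, None, "F"),
            (s2, None, None, "M"),
            (g1, c1, s1, None),
            (g2, s2, c2, None),
        ]
    return _make_pedigree(records)


@dataclass(frozen=True)
class SubsetOrdering:
    """Greedy relatedness-based ordering of pedigree members.

    ``kept_ids`` lists individuals in greedy addition order; ``removed_ids``
    are seed members dropped for having zero kinship to every other seed
    member; ``zero_kinship_tail`` flags appended individuals that had zero
    kinship to the whole set when added (tie pool exhausted).
    """

    kept_ids: tuple
    removed_ids: tuple
    zero_kinship_tail: tuple = ()


def cumulative_kinship_ordering(k: KinshipMatrix, seed_ids) -> SubsetOrdering:
    """Order individuals by greedy maximal summed kinship to the current set.

    ``seed_ids`` is either an iterable of ids or the
    :data:`START_FROM_MOST_RELATED` sentinel.  In seed mode, seed members
    with zero kinship to every other seed member are removed first; the
    pruned seed (in ascending id order) starts the kept list.  In sentinel
    mode the kept list starts from the single individual with the largest
    total kinship to all others.  Remaining individuals are appended one at
    a time, choosing the candidate with the greatest sum of kinship
    coefficients to the current set; ties, and candidates with zero
    kinship once the related pool is exhausted, are resolved by ascending
    id (the latter are flagged in ``zero_kinship_tail``).
    """
    phi = k.phi
    n = k.n
    order_rank = {ind: r for r, ind in enumerate(sorted(map(str, k.ids)))}

    def rank(ind):
        return order_rank[str(ind)]

    removed: list = []
    if isinstance(seed_ids, str) and seed_ids == START_FROM_MOST_RELATED:
        totals = phi.sum(axis=1) - np.diag(phi)
        best = min(
            range(n), key=lambda i: (-totals[i], rank(k.ids[i]))
        )
        kept_idx = [best]
    else:
        seed = list(seed_ids)
        idx = k.index(seed)
        sub = phi[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, 0.0)
        related = sub.sum(axis=1) > 0.0
        removed = [seed[j] for j in range(len(seed)) if not related[j]]
        pruned = [seed[j] for j in range(len(seed)) if related[j]]
        if not pruned:
            raise PedigreeValidationError("no related individuals in seed")
        pruned.sort(key=rank)
        kept_idx = list(k.index(pruned))

    in_set = np.zeros(n, dtype=bool)
    in_set[kept_idx] = True
    # cumulative kinship of every individual to the current kept set
    cum = phi[:, kept_idx].sum(axis=1)
    tail: list = []
    kept = list(kept_idx)
    candidates = [i for i in range(n) if not in_set[i]]
    candidates.sort(key=lambda i: rank(k.ids[i]))
    remaining = set(candidates)
    while remaining:
        best = min(remaining, key=lambda i: (-cum[i], rank(k.ids[i])))
        if cum[best] == 0.0:
            tail.append(k.ids[best])
        kept.append(best)
        remaining.discard(best)
        cum += phi[:, best]
    return SubsetOrdering(
        kept_ids=tuple(k.ids[i] for i in kept),
        removed_ids=tuple(removed),
        zero_kinship_tail=tuple(tail),
    )
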