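"""Pedigree parsing, validation, and numerator relationship matrices.

The numerator relationship matrix ``A`` holds expected additive genetic
relationships between animals implied by the pedigree; its diagonal is
``1 + F`` where ``F`` is the inbreeding coefficient.  The animal model needs
``A``'s sparse inverse, which Henderson's rules build directly from the
pedigree in linear time once inbreeding coefficients are known
(Meuwissen & Luo recursion, Quaas adjustment for inbred parents).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve_triangular

__all__ = [
    "Pedigree",
    "PedigreeError",
    "RelationshipMatrix",
    "AInverse",
    "read_pedigree",
    "inbreeding",
    "a_matrix",
    "a_inverse",
    "subset_relationship",
    "prune_to_ancestors",
    "write_a_inverse",
]

UNKNOWN = -1
#: dense A is refused above this many animals unless the caller raises the cap
DENSE_CAP = 5000


class PedigreeError(ValueError):
    """Invalid pedigree: duplicates, cycles, or sex-inconsistent parents."""


@dataclass(frozen=True)
class RelationshipMatrix:
    """Additive relationship matrix for an ordered set of animals."""

    ids: tuple[str, ...]
    values: np.ndarray          # (n, n) symmetric, a_ij
    inbreeding: np.ndarray      # (n,) F_i = a_ii - 1

    def inverse(self) -> "AInverse":
        """Dense inverse (for service-sire submatrices, which are small)."""
        sign, logdet = np.linalg.slogdet(self.values)
        if sign <= 0:
            raise PedigreeError("relationship matrix is not positive definite")
        inv = np.linalg.inv(self.values)
        return AInverse(ids=self.ids, matrix=sp.csc_matrix(inv), log_det_a=logdet)


@dataclass(frozen=True)
class AInverse:
    """Sparse inverse of a relationship matrix plus log|A| for REML."""

    ids: tuple[str, ...]
    matrix: sp.csc_matrix
    log_det_a: float

    @property
    def n(self) -> int:
        return len(self.ids)


class Pedigree:
    """Validated, topologically sorted pedigree.

    Parameters are index arrays into ``ids``; ``-1`` marks an unknown parent.
    Every known parent precedes its offspring in the sorted order; ties are
    broken by input order so construction is deterministic.
    """

    def __init__(self, ids: list[str], sire: np.ndarray, dam: np.ndarray):
        self.ids: tuple[str, ...] = tuple(ids)
        self.sire = np.asarray(sire, dtype=np.int64)
        self.dam = np.asarray(dam, dtype=np.int64)
        self._pos = {a: i for i, a in enumerate(self.ids)}
        self._F: np.ndarray | None = None
        self._d: np.ndarray | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_triples(
        cls, triples: list[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        """Build from (animal, sire, dam) rows; ``None`` = unknown parent.

        Parents appearing only in the sire/dam columns are appended as
        founders.  Raises :class:`PedigreeError` on duplicate animals with
        conflicting parents, sex-inconsistent usage, self-parenting, or
        cycles (the offending chain is reported).
        """
        seen: dict[str, tuple[str | None, str | None]] = {}
        order: list[str] = []
        for animal, s, d in triples:
            animal = str(animal)
            s = None if s is None else str(s)
            d = None if d is None else str(d)
            if animal in seen:
                if seen[animal] != (s, d):
                    raise PedigreeError(
                        f"duplicate animal {animal!r} with conflicting parents "
                        f"{seen[animal]} vs {(s, d)}"
                    )
                continue
            seen[animal] = (s, d)
            order.append(animal)
        # implicit founders: parents never listed as animals
        for animal in list(order):
            for parent in seen[animal]:
                if parent is not None and parent not in seen:
                    seen[parent] = (None, None)
                    order.append(parent)
        sires_used = {s for s, _ in seen.values() if s is not None}
        dams_used = {d for _, d in seen.values() if d is not None}
        both = sires_used & dams_used
        if both:
            raise PedigreeError(
                f"sex-inconsistent identifiers used as both sire and dam: "
                f"{sorted(both)[:5]}"
            )
        sorted_ids = cls._toposort(order, seen)
        pos = {a: i for i, a in enumerate(sorted_ids)}
        sire = np.array(
            [pos[seen[a][0]] if seen[a][0] is not None else UNKNOWN for a in sorted_ids]
        )
        dam = np.array(
            [pos[seen[a][1]] if seen[a][1] is not None else UNKNOWN for a in sorted_ids]
        )
        return cls(sorted_ids, sire, dam)

    @staticmethod
    def _toposort(
        order: list[str], parents: dict[str, tuple[str | None, str | None]]
    ) -> list[str]:
        rank = {a: i for i, a in enumerate(order)}
        children: dict[str, list[str]] = {a: [] for a in order}
        indeg = {a: 0 for a in order}
        for a in order:
            for p in parents[a]:
                if p is not None:
                    if p == a:
                        raise PedigreeError(f"cycle: animal {a!r} is its own parent")
                    children[p].append(a)
                    indeg[a] += 1
        heap = [rank[a] for a in order if indeg[a] == 0]
        heapq.heapify(heap)
        out: list[str] = []
        while heap:
            a = order[heapq.heappop(heap)]
            out.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(heap, rank[c])
        if len(out) != len(order):
            leftover = [a for a in order if indeg[a] > 0]
            chain = Pedigree._find_cycle(leftover, parents)
            raise PedigreeError(f"cycle detected in pedigree: {' -> '.join(chain)}")
        return out

    @staticmethod
    def _find_cycle(nodes, parents) -> list[str]:
        node_set = set(nodes)
        for start in nodes:
            path, cur, seen = [], start, set()
            while cur is not None and cur in node_set:
                if cur in seen:
                    i = path.index(cur)
                    return path[i:] + [cur]
                seen.add(cur)
                path.append(cur)
                s, d = parents[cur]
                cur = s if s in node_set else d
        return nodes[:3]

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, animal: str) -> bool:
        return animal in self._pos

    def index(self, animal: str) -> int:
        return self._pos[animal]

    def indices(self, animals) -> np.ndarray:
        missing = [a for a in animals if a not in self._pos]
        if missing:
            raise PedigreeError(f"identifiers not in pedigree: {missing[:10]}")
        return np.array([self._pos[a] for a in animals], dtype=np.int64)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    # -- inbreeding & Mendelian variance ----------------------------------

    def _compute_f(self) -> None:
        """Meuwissen & Luo: F_i from path coefficients, one animal at a time.

        Also stores d_i = Var(mendelian sampling)/sigma_a^2, the within-family
        variance coefficient (1 for founders; 0.5 - 0.25(F_s + F_d) with both
        parents known; unknown parents enter with F = -1).
        """
        n = len(self)
        F = np.zeros(n)
        d = np.ones(n)
        sire, dam = self.sire, self.dam

        def fcoef(p: int) -> float:
            return F[p] if p >= 0 else -1.0

        for i in range(n):
            s, dd = sire[i], dam[i]
            d[i] = 0.5 - 0.25 * (fcoef(s) + fcoef(dd))
            if s == UNKNOWN or dd == UNKNOWN:
                F[i] = 0.0
                continue
            # accumulate L-row of i over its ancestors, largest index first
            L: dict[int, float] = {i: 1.0}
            heap = [-i]
            visited = set()
            aii = 0.0
            while heap:
                j = -heapq.heappop(heap)
                if j in visited:
                    continue
                visited.add(j)
                lj = L[j]
                aii += lj * lj * d[j]
                for p in (sire[j], dam[j]):
                    if p >= 0:
                        if p not in L:
                            L[p] = 0.0
                            heapq.heappush(heap, -p)
                        L[p] += 0.5 * lj
            F[i] = aii - 1.0
        self._F, self._d = F, d

    @property
    def F(self) -> np.ndarray:
        if self._F is None:
            self._compute_f()
        return self._F

    @property
    def mendelian_d(self) -> np.ndarray:
        if self._d is None:
            self._compute_f()
        return self._d


# ---------------------------------------------------------------------------


def read_pedigree(
    path,
    unknown_token: str = "0",
    sep: str | None = None,
    has_header: bool = False,
) -> Pedigree:
    """Read a delimited pedigree file (animal, sire, dam[, ...]).

    ``sep=None`` sniffs whitespace vs comma.  Extra columns (birth date,
    sex) are ignored.  Tokens equal to ``unknown_token`` (and empty fields)
    mean unknown parent.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        header=0 if has_header else None,
        dtype=str,
    )
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file needs >= 3 columns (animal, sire, dam)")

    def clean(tok) -> str | None:
        if tok is None or (isinstance(tok, float) and np.isnan(tok)):
            return None
        tok = str(tok).strip()
        return None if tok in ("", unknown_token) else tok

    triples = [
        (str(a).strip(), clean(s), clean(d))
        for a, s, d in df.iloc[:, :3].itertuples(index=False)
    ]
    return Pedigree.from_triples(triples)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F_i in pedigree order (founders 0)."""
    return ped.F.copy()


def a_matrix(ped: Pedigree, max_animals: int = DENSE_CAP) -> RelationshipMatrix:
    """Dense numerator relationship matrix by the tabular method."""
    n = len(ped)
    if n > max_animals:
        raise PedigreeError(
            f"pedigree has {n} animals > dense cap {max_animals}; "
            "use a_inverse() for estimation or raise max_animals"
        )
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ids=ped.ids, values=A, inbreeding=A.diagonal() - 1.0)


def a_inverse(ped: Pedigree) -> AInverse:
    """Sparse A^-1 by Henderson's rules with inbreeding (Quaas adjustment).

    Each animal contributes alpha_i = 1/d_i times the pattern
    {1, -1/2, 1/4} to the (animal, animal), (animal, parent), and
    (parent, parent) cells.  Also returns log|A| = sum log d_i.
    """
    n = len(ped)
    d = ped.mendelian_d
    if np.any(d <= 0):
        bad = ped.ids[int(np.argmin(d))]
        raise PedigreeError(f"non-positive Mendelian variance at {bad!r}")
    rows, cols, vals = [], [], []
    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in parents:
            rows += [i, p]; cols += [p, i]; vals += [-0.5 * alpha] * 2
            for q in parents:
                rows.append(p); cols.append(q); vals.append(0.25 * alpha)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return AInverse(ids=ped.ids, matrix=mat, log_det_a=float(np.sum(np.log(d))))


def _lower_factor(ped: Pedigree) -> sp.csr_matrix:
    """(I - P) with P holding 0.5 at (animal, parent); unit lower triangular."""
    n = len(ped)
    rows, cols, vals = list(range(n)), list(range(n)), [1.0] * n
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                rows.append(i); cols.append(p); vals.append(-0.5)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def subset_relationship(ped: Pedigree, ids) -> RelationshipMatrix:
    """Rows/columns of the full A restricted to ``ids``.

    Relationships are propagated through the *full* pedigree
    (A = (I-P)^-1 D (I-P)^-T), then sliced, so the result is exact even when
    the subset animals' common ancestors are outside the subset.  Intended
    for service-sire submatrices.
    """
    ids = list(dict.fromkeys(ids))  # dedup, keep order
    idx = ped.indices(ids)
    n, m = len(ped), len(ids)
    IP = _lower_factor(ped)
    E = np.zeros((n, m))
    E[idx, np.arange(m)] = 1.0
    # columns of A at idx: solve (I-P)' t = e_j, scale by D, solve (I-P) x = t
    T = spsolve_triangular(IP.T.tocsr(), E, lower=False)
    T *= ped.mendelian_d[:, None]
    X = spsolve_triangular(IP, T, lower=True)
    sub = X[idx, :]
    sub = 0.5 * (sub + sub.T)
    return RelationshipMatrix(
        ids=tuple(ids), values=sub, inbreeding=sub.diagonal() - 1.0
    )


def prune_to_ancestors(ped: Pedigree, phenotyped) -> Pedigree:
    """Keep the given animals and their full ancestor closure.

    Service sires should be included in ``phenotyped`` by the caller if
    their relationship matrix is needed.  Unconnected individuals are
    dropped; relative order is preserved.
    """
    keep = set(ped.indices(phenotyped))
    stack = list(keep)
    while stack:
        i = stack.pop()
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0 and p not in keep:
                keep.add(p)
                stack.append(p)
    sel = sorted(keep)
    old2new = {o: k for k, o in enumerate(sel)}
    remap = lambda p: old2new[p] if p >= 0 else UNKNOWN
    return Pedigree(
        [ped.ids[i] for i in sel],
        np.array([remap(ped.sire[i]) for i in sel]),
        np.array([remap(ped.dam[i]) for i in sel]),
    )


def write_a_inverse(ainv: AInverse, path) -> None:
    """Export A^-1 as 1-based (i, j, value) coordinate text, lower triangle."""
    coo = sp.tril(ainv.matrix).tocoo()
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1} {j + 1} {v:.12g}\n")
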