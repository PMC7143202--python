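"""Pedigree data model and numerator-relationship machinery.

The additive (numerator) relationship matrix ``A`` describes expected
identity-by-descent between animals given the pedigree.  This module provides

* :class:`Pedigree` — validated, topologically ordered animal/sire/dam triples;
* :func:`build_A_tabular` — the recursive tabular method (the oracle, O(n²));
* :func:`compute_inbreeding` — Meuwissen & Luo style recursion, avoids the full A;
* :func:`build_A_inverse` — sparse A⁻¹ by Henderson's rules with inbreeding;
* :func:`subset_A22` — the genotyped-animal submatrix of A and its inverse.

All matrices carry the animal ids they are indexed by; order mismatches are an
error, never silently reindexed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or bad lookups."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Parameters
    ----------
    ids
        Animal identifiers, unique, in an order where every parent precedes
        its offspring.
    sire, dam
        Integer positions of each animal's parents within ``ids``;
        ``UNKNOWN`` (−1) marks an unknown parent.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(self.sire) != n or len(self.dam) != n:
            raise PedigreeError("ids, sire and dam must have equal length")
        if len(set(self.ids.tolist())) != n:
            raise PedigreeError("animal ids are not unique")
        for name, parent in (("sire", self.sire), ("dam", self.dam)):
            bad = (parent != UNKNOWN) & ((parent < 0) | (parent >= n))
            if bad.any():
                raise PedigreeError(f"{name} index out of range")
            # parents precede offspring; also rules out self-ancestry cycles
            late = parent >= np.arange(n)
            if (late & (parent != UNKNOWN)).any():
                raise PedigreeError(f"{name} does not precede offspring in ordering")
        self._index = {a: i for i, a in enumerate(self.ids.tolist())}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        """Positions of ``animal_ids`` in pedigree order; unknown id is an error."""
        try:
            return np.array([self._index[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message content
            raise PedigreeError(f"animal id {exc.args[0]!r} not in pedigree") from exc

    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    @classmethod
    def from_parent_ids(cls, ids, sire_ids, dam_ids, unknown=(0, "0", None, "NA", "")) -> "Pedigree":
        """Build from parent *identifiers* (not positions); 0/NA = unknown."""
        ids = list(ids)
        index = {a: i for i, a in enumerate(ids)}
        unknown_set = set(unknown)

        def resolve(parents):
            out = np.full(len(ids), UNKNOWN, dtype=np.int64)
            for i, p in enumerate(parents):
                if p in unknown_set or (isinstance(p, float) and np.isnan(p)):
                    continue
                if p not in index:
                    raise PedigreeError(f"parent id {p!r} not among animal ids")
                out[i] = index[p]
            return out

        return cls(np.asarray(ids), resolve(list(sire_ids)), resolve(list(dam_ids)))

    def to_frame(self) -> pd.DataFrame:
        def parent_ids(parent):
            return [self.ids[p] if p != UNKNOWN else 0 for p in parent]

        return pd.DataFrame(
            {"animal": self.ids, "sire": parent_ids(self.sire), "dam": parent_ids(self.dam)}
        )


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix together with the ids it is indexed by."""

    matrix: object  # dense ndarray or scipy sparse
    ids: np.ndarray
    is_inverse: bool = False

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise PedigreeError("matrix shape does not match id count")

    def dense(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return self.matrix.toarray()
        return np.asarray(self.matrix)

    def require_same_order(self, other: "RelationshipMatrix") -> None:
        if len(self.ids) != len(other.ids) or (self.ids != other.ids).any():
            raise PedigreeError("relationship matrices are indexed by different id orders")


def prune_pedigree(ped: Pedigree, keep_ids) -> Pedigree:
    """Restrict to ``keep_ids`` and all their ancestors.

    Standard evaluation practice: animals that neither have records nor are
    ancestors of recorded animals carry no information and only inflate the
    equations.  Metadata attributes (``sex``, ``generation``) are carried
    over when present.
    """
    keep = set(ped.index_of(keep_ids).tolist())
    stack = sorted(keep, reverse=True)
    while stack:
        i = stack.pop()
        for par in (ped.sire[i], ped.dam[i]):
            if par != UNKNOWN and par not in keep:
                keep.add(int(par))
                stack.append(int(par))
    order = np.array(sorted(keep))
    remap = {int(old): new for new, old in enumerate(order)}

    def remap_parent(parent):
        return np.array([remap[int(p)] if p != UNKNOWN else UNKNOWN for p in parent[order]])

    new = Pedigree(ped.ids[order], remap_parent(ped.sire), remap_parent(ped.dam))
    for attr in ("sex", "generation"):
        if hasattr(ped, attr):
            setattr(new, attr, getattr(ped, attr)[order])
    return new


def build_A_tabular(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the recursive tabular method.

    ``a_ii = 1 + F_i`` with ``F_i = 0.5·a(sire_i, dam_i)``; off-diagonals by
    ``a_ij = 0.5·(a_{j,s(i)} + a_{j,d(i)})`` for j < i.  Quadratic in animals —
    this is the oracle implementation, fine at desk scale.
    """
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0)
    return RelationshipMatrix(A, ped.ids)


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients by the Meuwissen–Luo recursion.

    Computes F_i = 0.5·a(sire_i, dam_i) without forming A, using the
    decomposition A = L·diag(d)·L′ and accumulating each animal's L row
    by ancestor traversal.  O(total ancestry) rather than O(n²) memory.
    """
    n = len(ped)
    F = np.zeros(n)
    dvec = np.zeros(n)  # Mendelian sampling variances, filled in pedigree order
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == UNKNOWN or d == UNKNOWN:
            F[i] = 0.0
        else:
            # a(s,d) = Σ_k L_sk · L_dk · d_k over common ancestors k, where L
            # rows are built by pushing halves up the pedigree; joint traversal
            # in decreasing index order touches only actual ancestors.
            cs: dict[int, float] = {int(s): 1.0}
            cd: dict[int, float] = {int(d): 1.0}
            active = set(cs) | set(cd)
            asd = 0.0
            while active:
                k = max(active)
                active.discard(k)
                vs = cs.pop(k, 0.0)
                vd = cd.pop(k, 0.0)
                asd += vs * vd * dvec[k]
                for row, v in ((cs, vs), (cd, vd)):
                    if v == 0.0:
                        continue
                    for par in (sire[k], dam[k]):
                        if par != UNKNOWN:
                            row[int(par)] = row.get(int(par), 0.0) + 0.5 * v
                            active.add(int(par))
            F[i] = 0.5 * asd
        if s != UNKNOWN and d != UNKNOWN:
            dvec[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN:
            dvec[i] = 0.75 - 0.25 * F[s]
        elif d != UNKNOWN:
            dvec[i] = 0.75 - 0.25 * F[d]
        else:
            dvec[i] = 1.0
    return F


def mendelian_sampling_variance(ped: Pedigree, F: np.ndarray | None = None,
                                use_inbreeding: bool = True) -> np.ndarray:
    """Per-animal Mendelian sampling variance d_i (as a fraction of σa²)."""
    if F is None:
        F = compute_inbreeding(ped) if use_inbreeding else np.zeros(len(ped))
    elif not use_inbreeding:
        F = np.zeros(len(ped))
    d = np.empty(len(ped))
    for i in range(len(ped)):
        s, dm = ped.sire[i], ped.dam[i]
        if s != UNKNOWN and dm != UNKNOWN:
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        elif s != UNKNOWN:
            d[i] = 0.75 - 0.25 * F[s]
        elif dm != UNKNOWN:
            d[i] = 0.75 - 0.25 * F[dm]
        else:
            d[i] = 1.0
    return d


def build_A_inverse(ped: Pedigree, use_inbreeding: bool = True) -> RelationshipMatrix:
    """Sparse A⁻¹ assembled by Henderson's rules.

    With ``use_inbreeding=True`` (default) the Mendelian-sampling variances
    account for parental inbreeding, so the result is the exact inverse of the
    tabular A.  The flag exists for sensitivity checks only.
    """
    n = len(ped)
    d = mendelian_sampling_variance(ped, use_inbreeding=use_inbreeding)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        add(i, i, alpha)
        for p in parents:
            add(i, p, -alpha / 2.0)
            add(p, i, -alpha / 2.0)
        for p in parents:
            for q in parents:
                add(p, q, alpha / 4.0)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(Ainv, ped.ids, is_inverse=True)


def subset_A22(ped: Pedigree, genotyped_ids) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """A22 (tabular A restricted to genotyped animals, in the given order) and its inverse.

    The inverse is computed by direct dense factorization — adequate at the
    scale this package targets; this is the documented scaling boundary.
    """
    idx = ped.index_of(genotyped_ids)
    A = build_A_tabular(ped).dense()
    A22 = A[np.ix_(idx, idx)]
    ids = np.asarray(list(genotyped_ids))
    A22_inv = np.linalg.inv(A22)
    return (
        RelationshipMatrix(A22, ids),
        RelationshipMatrix(A22_inv, ids, is_inverse=True),
    )
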