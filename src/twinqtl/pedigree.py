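"""Pedigree container and numerator-relationship machinery.

Animals are stored in a pandas table ordered parents-first (topological
order).  Unknown parents are encoded as ``-1``.  Breed composition is kept
as one ``breed:<label>`` column per breed; fractions sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """A topologically ordered animal/sire/dam graph.

    ``table`` columns: ``id`` (int), ``sire``/``dam`` (int, -1 if unknown),
    ``sex`` ("M"/"F"), ``birth_year`` (int), ``herd`` (int, -1 if none),
    ``generation`` (int) and one ``breed:<label>`` column per breed.
    Row position is the internal animal index used by all matrix code.
    """

    table: pd.DataFrame

    def __post_init__(self):
        self.validate()

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def sire_idx(self) -> np.ndarray:
        return self._parent_indices()[0]

    @property
    def dam_idx(self) -> np.ndarray:
        return self._parent_indices()[1]

    def _parent_indices(self) -> Tuple[np.ndarray, np.ndarray]:
        if not hasattr(self, "_pidx"):
            pos = pd.Series(np.arange(len(self.table)), index=self.table["id"])
            out = []
            for col in ("sire", "dam"):
                p = self.table[col].to_numpy()
                idx = np.full(len(p), UNKNOWN, dtype=np.int64)
                known = p != UNKNOWN
                idx[known] = pos.loc[p[known]].to_numpy()
                out.append(idx)
            self._pidx = tuple(out)
        return self._pidx

    def index_of(self, ids: Iterable[int]) -> np.ndarray:
        pos = pd.Series(np.arange(len(self.table)), index=self.table["id"])
        return pos.loc[np.asarray(list(ids))].to_numpy()

    @property
    def breed_columns(self) -> list:
        return [c for c in self.table.columns if c.startswith("breed:")]

    def breed_fraction(self, breed: str) -> np.ndarray:
        col = f"breed:{breed}"
        if col not in self.table.columns:
            return np.zeros(len(self.table))
        return self.table[col].to_numpy(dtype=float)

    # -- validation ------------------------------------------------------
    def validate(self) -> "Pedigree":
        t = self.table
        required = {"id", "sire", "dam", "sex", "birth_year"}
        missing = required - set(t.columns)
        if missing:
            raise PedigreeError(f"pedigree table lacks columns {sorted(missing)}")
        if t["id"].duplicated().any():
            raise PedigreeError("duplicate animal ids")
        pos = pd.Series(np.arange(len(t)), index=t["id"])
        for col in ("sire", "dam"):
            p = t[col].to_numpy()
            known = p != UNKNOWN
            if known.any():
                if not pd.Index(p[known]).isin(pos.index).all():
                    bad = set(p[known]) - set(pos.index)
                    raise PedigreeError(f"unknown {col} ids: {sorted(bad)[:5]}")
                if (pos.loc[p[known]].to_numpy() >= np.nonzero(known)[0]).any():
                    raise PedigreeError(
                        "pedigree is not topologically ordered "
                        f"(a {col} appears at or after its offspring)"
                    )
        bcols = self.breed_columns
        if bcols:
            s = t[bcols].to_numpy(dtype=float).sum(axis=1)
            if np.abs(s - 1.0).max() > 1e-9:
                raise PedigreeError("breed fractions must sum to 1 within 1e-9")
        return self

    # -- relationship machinery ------------------------------------------
    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients by the Meuwissen-Luo algorithm."""
        return _meuwissen_luo(*self._parent_indices())[0]

    def mendelian_variance_coefficients(self) -> np.ndarray:
        """Within-family (Mendelian-sampling) variance coefficients d_i of
        the decomposition A = T D T'."""
        return _meuwissen_luo(*self._parent_indices())[1]

    def relationship_matrix(self) -> np.ndarray:
        """Dense additive relationship matrix A by the tabular method.

        Quadratic in the number of animals; intended for toy-scale oracles
        and small evaluations.
        """
        s, d = self._parent_indices()
        n = len(self.table)
        A = np.zeros((n, n))
        for i in range(n):
            si, di = s[i], d[i]
            if si != UNKNOWN and di != UNKNOWN:
                A[i, i] = 1.0 + 0.5 * A[si, di]
            else:
                A[i, i] = 1.0
            for j in range(i):
                aij = 0.0
                if si != UNKNOWN:
                    aij += 0.5 * A[j, si]
                if di != UNKNOWN:
                    aij += 0.5 * A[j, di]
                A[i, j] = A[j, i] = aij
        return A

    def a_inverse(self) -> sp.csr_matrix:
        """Sparse inverse of the relationship matrix A with inbreeding.

        Henderson's rules with Mendelian-sampling variances from the
        Meuwissen-Luo pass, so the inverse is exact for inbred pedigrees.
        """
        s, d = self._parent_indices()
        n = len(self.table)
        _, dvec = _meuwissen_luo(s, d)
        rows = []
        cols = []
        vals = []
        for i in range(n):
            w = 1.0 / dvec[i]
            parents = [p for p in (s[i], d[i]) if p != UNKNOWN]
            rows.append(i); cols.append(i); vals.append(w)
            for p in parents:
                rows += [i, p]; cols += [p, i]; vals += [-0.5 * w, -0.5 * w]
            for p in parents:
                for q in parents:
                    rows.append(p); cols.append(q); vals.append(0.25 * w)
        return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    def log_det_a(self) -> float:
        """log |A| = sum log d_i (A = T D T', T unit triangular)."""
        return float(np.log(self.mendelian_variance_coefficients()).sum())

    def gene_flow_operator(self) -> Tuple[sp.csr_matrix, np.ndarray]:
        """(I - P, d) with P the half-parent matrix, so A = T D T' with
        T = (I - P)^-1.  Lets A act on vectors via two O(n) triangular
        solves without ever factorizing A or its inverse."""
        s, dpar = self._parent_indices()
        n = len(self.table)
        rows, cols, vals = [], [], []
        for i in range(n):
            for par in (s[i], dpar[i]):
                if par != UNKNOWN:
                    rows.append(i); cols.append(par); vals.append(-0.5)
        Tinv = sp.coo_matrix(
            (vals + [1.0] * n, (rows + list(range(n)), cols + list(range(n)))),
            shape=(n, n),
        ).tocsr()
        return Tinv, self.mendelian_variance_coefficients()


def _meuwissen_luo(sire: np.ndarray, dam: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Inbreeding coefficients F and Mendelian variances d (Meuwissen & Luo).

    Returns (F, d) with d_i = 0.5 - 0.25 (F_s + F_d) for two known parents,
    0.75 - 0.25 F_p for one, and 1 for founders.
    """
    n = len(sire)
    F = np.zeros(n)
    d = np.ones(n)
    memo: dict = {}
    for i in range(n):
        si, di = sire[i], dam[i]
        if si == UNKNOWN and di == UNKNOWN:
            d[i] = 1.0
        elif si == UNKNOWN or di == UNKNOWN:
            p = si if si != UNKNOWN else di
            # F_i = 0 when one parent is unknown (no traceable common
            # ancestry), but the Mendelian variance still shrinks.
            d[i] = 0.75 - 0.25 * F[p]
        else:
            F[i] = 0.5 * _pair_relationship(si, di, sire, dam, F, memo)
            d[i] = 0.5 - 0.25 * (F[si] + F[di])
    return F, d


def _pair_relationship(i, j, sire, dam, F, memo) -> float:
    """Additive relationship a_ij computed recursively (memoised)."""
    if i == UNKNOWN or j == UNKNOWN:
        return 0.0
    if i > j:
        i, j = j, i
    key = (i, j)
    if key in memo:
        return memo[key]
    if i == j:
        val = 1.0 + F[i]
    else:
        # j is the younger animal (topological order): go through j's parents
        val = 0.5 * (
            _pair_relationship(i, sire[j], sire, dam, F, memo)
            + _pair_relationship(i, dam[j], sire, dam, F, memo)
        )
    memo[key] = val
    return val
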