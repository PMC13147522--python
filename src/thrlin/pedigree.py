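"""Pedigree handling and random-effect precision structures.

The additive-genetic random effect is ``u ~ N(0, G0 (x) A)`` where ``A`` is
the numerator relationship matrix of the pedigree and ``G0`` the among-trait
genetic covariance.  The mixed-model equations only need the sparse inverse,
assembled here by Henderson's rules, and the combined precision
``S = blockdiag(0, A^-1 (x) G0^-1)`` (trait-within-animal equation order).
A single-step ``H^-1`` combining pedigree and genomic relationships is also
provided; the solvers accept any symmetric PSD precision interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "PrecisionStructure",
    "read_pedigree",
    "write_pedigree",
    "a_matrix",
    "a_inverse",
    "inbreeding_coefficients",
    "build_S",
    "h_inverse",
]


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Renumbered pedigree: animals 0..n-1, parents precede offspring.

    ``sire``/``dam`` hold the renumbered parent index or -1 for unknown.
    ``labels`` maps the internal index back to the user's identifiers.
    """

    sire: np.ndarray
    dam: np.ndarray
    labels: np.ndarray

    @property
    def n(self) -> int:
        return self.sire.size

    @classmethod
    def from_arrays(cls, animal, sire, dam) -> "Pedigree":
        """Build and topologically sort a pedigree; 0/""/NaN = unknown parent."""
        animal = np.asarray(animal)
        sire = np.asarray(sire)
        dam = np.asarray(dam)
        n = animal.size
        if len(set(animal.tolist())) != n:
            raise PedigreeError("duplicate animal identifiers in pedigree")
        idx = {a: i for i, a in enumerate(animal.tolist())}

        def parent_index(p):
            if p is None or (isinstance(p, float) and np.isnan(p)) or p == 0 or p == "0" or p == "":
                return -1
            if p not in idx:
                raise PedigreeError(f"parent {p!r} not listed as an animal")
            return idx[p]

        s = np.array([parent_index(p) for p in sire.tolist()], dtype=np.int64)
        d = np.array([parent_index(p) for p in dam.tolist()], dtype=np.int64)
        for i in range(n):
            if s[i] == i or d[i] == i:
                raise PedigreeError(f"animal {animal[i]!r} is its own parent")

        # Kahn topological sort so parents precede offspring
        children = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for p in (s[i], d[i]):
                if p >= 0:
                    children[p].append(i)
                    indeg[i] += 1
        order = [i for i in range(n) if indeg[i] == 0]
        head = 0
        while head < len(order):
            v = order[head]
            head += 1
            for ch in children[v]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    order.append(ch)
        if len(order) < n:
            bad = next(i for i in range(n) if indeg[i] > 0)
            raise PedigreeError(
                f"pedigree cycle detected involving animal {animal[bad]}"
            )
        pos = np.empty(n, dtype=np.int64)
        pos[order] = np.arange(n)
        new_s = np.where(s >= 0, 0, -1)
        new_d = np.where(d >= 0, 0, -1)
        new_s[pos[np.arange(n)]] = np.where(s >= 0, pos[np.clip(s, 0, None)], -1)
        new_d[pos[np.arange(n)]] = np.where(d >= 0, pos[np.clip(d, 0, None)], -1)
        return cls(sire=new_s, dam=new_d, labels=animal[order])

    def index_of(self, labels) -> np.ndarray:
        # labels may arrive as str from one file and int from another;
        # compare their string forms
        lookup = {str(a): i for i, a in enumerate(self.labels.tolist())}
        try:
            return np.array([lookup[str(a)] for a in np.asarray(labels).tolist()])
        except KeyError as exc:
            raise PedigreeError(f"animal {exc.args[0]} not in pedigree") from exc


def read_pedigree(path) -> Pedigree:
    """Read a 3-column (animal sire dam) file, whitespace- or comma-delimited."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["animal", "sire", "dam"], dtype=str,
                     skipinitialspace=True)
    df = df.fillna("0")
    return Pedigree.from_arrays(df["animal"].values, df["sire"].values,
                                df["dam"].values)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the renumbered pedigree (1-based indices, 0 = unknown)."""
    with open(path, "w") as fh:
        for i in range(ped.n):
            fh.write(f"{i + 1} {ped.sire[i] + 1} {ped.dam[i] + 1}\n")


def a_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method (test oracle)."""
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        f_i = 0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + f_i
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    return A


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Pedigree inbreeding coefficients F (tabular recursion)."""
    return np.diag(a_matrix(ped)) - 1.0


def a_inverse(ped: Pedigree, inbreeding: bool = False) -> sp.csr_matrix:
    """Sparse inverse of the numerator relationship matrix (Henderson's rules).

    ``inbreeding=False`` (default) uses Mendelian-sampling variances for a
    non-inbred population (1, 3/4 or 1/2 of the additive variance for 0, 1 or
    2 known parents); ``inbreeding=True`` adjusts them with the parents'
    inbreeding coefficients.
    """
    n = ped.n
    F = inbreeding_coefficients(ped) if inbreeding else np.zeros(n)
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        dii = 1.0
        if s >= 0:
            dii -= 0.25 * (1.0 + F[s])
        if d >= 0:
            dii -= 0.25 * (1.0 + F[d])
        alpha = 1.0 / dii
        ent = [(i, i, alpha)]
        for p in (s, d):
            if p >= 0:
                ent.append((i, p, -0.5 * alpha))
                ent.append((p, i, -0.5 * alpha))
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    ent.append((p, q, 0.25 * alpha))
        for r, c, v in ent:
            rows.append(r)
            cols.append(c)
            vals.append(v)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


@dataclass
class PrecisionStructure:
    """Random-effect precision embedded in the full equation system.

    ``matrix`` is the (n_eq x n_eq) sparse symmetric PSD matrix with an
    exactly-zero block on the first ``n_fixed_equations`` rows/columns and
    ``K^-1 (x) G0^-1`` (trait-within-animal order) on the random-effect
    equations.
    """

    matrix: sp.csr_matrix
    n_fixed_equations: int
    n_traits: int
    n_levels: int


def build_S(g0, relationship_inverse, n_fixed_equations: int) -> PrecisionStructure:
    """Assemble ``S = blockdiag(0, K^-1 (x) G0^-1)``.

    ``relationship_inverse`` is any sparse symmetric PSD matrix (pedigree
    ``A^-1``, genomic, single-step ``H^-1`` or identity); ``g0`` is the
    among-trait genetic covariance.  Random-effect equations are ordered
    trait-within-animal.
    """
    g0 = np.atleast_2d(np.asarray(g0, dtype=float))
    try:
        np.linalg.cholesky(g0)
    except np.linalg.LinAlgError as exc:
        raise PedigreeError("G0 is not positive definite") from exc
    kinv = sp.csr_matrix(relationship_inverse)
    g0_inv = np.linalg.inv(g0)
    G_inv = sp.kron(kinv, sp.csr_matrix(g0_inv), format="csr")
    nf = int(n_fixed_equations)
    S = sp.block_diag([sp.csr_matrix((nf, nf)), G_inv], format="csr")
    return PrecisionStructure(matrix=S, n_fixed_equations=nf,
                              n_traits=g0.shape[0], n_levels=kinv.shape[0])


def h_inverse(a_inv: sp.spmatrix, a_dense_22: np.ndarray, grm: np.ndarray,
              genotyped_ids, blend: float = 0.05) -> sp.csr_matrix:
    """Single-step precision ``H^-1 = A^-1 + blockdiag(0, Gb^-1 - A22^-1)``.

    ``grm`` is the genomic relationship among ``genotyped_ids`` (indices into
    the renumbered pedigree) and ``a_dense_22`` the corresponding pedigree
    submatrix; ``Gb = (1 - blend) * grm + blend * a_dense_22``.
    """
    genotyped_ids = np.asarray(genotyped_ids, dtype=np.int64)
    a_inv = sp.csr_matrix(a_inv)
    if genotyped_ids.size == 0:
        return a_inv
    Gb = (1.0 - blend) * np.asarray(grm, dtype=float) + blend * np.asarray(
        a_dense_22, dtype=float
    )
    try:
        Gb_inv = np.linalg.inv(Gb)
        a22_inv = np.linalg.inv(np.asarray(a_dense_22, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise PedigreeError("singular blended GRM or A22 block") from exc
    diff = Gb_inv - a22_inv
    n = a_inv.shape[0]
    rows = np.repeat(genotyped_ids, genotyped_ids.size)
    cols = np.tile(genotyped_ids, genotyped_ids.size)
    upd = sp.coo_matrix((diff.ravel(), (rows, cols)), shape=(n, n))
    return (a_inv + upd.tocsr()).tocsr()
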