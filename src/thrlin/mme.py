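"""Assembly and solution of the working mixed-model equations.

Each Newton-Raphson round solves ``(W' Rt^-1 W + S) theta = W' Rt^-1 yt``
where ``Rt`` (the working residual covariance) and the pseudo-data ``yt``
are rebuilt from the current truncated-moment quantities, while the EM
M-step solves the same system with the actual residual covariance ``R`` and
the liability expectations as data.  Both cases reduce to summing per-record
contributions ``W_i' M_i W_i`` and ``W_i' M_i y_i`` with a per-record
symmetric weight matrix ``M_i`` over the record's observed traits, which is
what :func:`assemble` implements (vectorized over records sharing a
missingness pattern).

Equation order (fixed throughout the package): fixed effects trait-major
(trait t's ``p`` coefficients at ``t*p .. t*p+p-1``), then breeding values
trait-within-animal (animal ``a``, trait ``t`` at ``T*p + a*T + t``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import ModelSpec, RecordSet, Theta, pattern_schur
from .pedigree import PrecisionStructure

__all__ = [
    "PseudoRecord",
    "MMESystem",
    "rtilde_inverse",
    "rtilde_matrix",
    "pseudo_data",
    "assemble",
    "GroupContribution",
    "solve",
]


class MMEError(ValueError):
    pass


@dataclass
class PseudoRecord:
    """Working response, weight matrix and gradient contribution of a record."""

    ytilde: np.ndarray
    rtilde_inv: np.ndarray
    z: np.ndarray
    obs_traits: np.ndarray  # global trait indices the blocks refer to


@dataclass
class GroupContribution:
    """Vectorized per-pattern inputs to :func:`assemble`.

    ``weights`` is (n_g, To, To) holding ``M_i`` for every record of the
    group; ``ytilde`` is (n_g, To); ``obs_traits`` are the global trait
    indices of the observed columns.
    """

    rows: np.ndarray
    obs_traits: np.ndarray
    weights: np.ndarray
    ytilde: np.ndarray


@dataclass
class MMESystem:
    """Sparse symmetric system ``C theta = rhs`` with ``C = W' M W + S``."""

    C: sp.csr_matrix
    rhs: np.ndarray

    def gradient(self, theta_vec: np.ndarray) -> np.ndarray:
        """Log-posterior gradient ``rhs - C theta`` at the assembly point."""
        return self.rhs - self.C @ theta_vec

    def convergence_metric(self, theta_vec: np.ndarray) -> float:
        """``||rhs - C theta||_2 / ||rhs||_2`` (the solvers' stopping rule)."""
        denom = np.linalg.norm(self.rhs)
        if denom == 0.0:
            return 0.0
        return float(np.linalg.norm(self.gradient(theta_vec)) / denom)


# ---------------------------------------------------------------------------
# working residual blocks
# ---------------------------------------------------------------------------

def rtilde_inverse_blocks(gamma: np.ndarray, b_mat: np.ndarray,
                          r22_inv: np.ndarray) -> np.ndarray:
    """Closed-form inverse of the working residual covariance.

    With ``B = R12 R22^-1``::

        Rt^-1 = [  gamma       -gamma B            ]
                [ -B' gamma     B' gamma B + R22^-1 ]

    vectorized over a leading batch axis of ``gamma`` if present.  The block
    form is exact (never formed by numerically inverting ``Rt``).
    """
    gamma = np.asarray(gamma, dtype=float)
    batched = gamma.ndim == 3
    if not batched:
        gamma = gamma[None]
    n, c, _ = gamma.shape
    mo = b_mat.shape[1]
    out = np.empty((n, c + mo, c + mo))
    gB = gamma @ b_mat  # (n, c, mo)
    out[:, :c, :c] = gamma
    out[:, :c, c:] = -gB
    out[:, c:, :c] = -np.transpose(gB, (0, 2, 1))
    out[:, c:, c:] = np.einsum("qc,ncd->nqd", b_mat.T, gB) + r22_inv[None]
    return out if batched else out[0]


def rtilde_inverse(gamma: np.ndarray, spec: ModelSpec, cat_obs=None,
                   cont_obs=None) -> np.ndarray:
    """Per-record ``Rt^-1`` for observed categorical/continuous subsets."""
    if cat_obs is None:
        cat_obs = np.arange(spec.c)
    if cont_obs is None:
        cont_obs = np.arange(spec.m)
    _, b_mat = pattern_schur(spec, cat_obs, cont_obs)
    im = np.asarray(cont_obs, dtype=int) + spec.c
    r22 = spec.R[np.ix_(im, im)]
    r22_inv = np.linalg.inv(r22) if im.size else np.zeros((0, 0))
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim == 2:
        w = np.linalg.eigvalsh(0.5 * (gamma + gamma.T))
        if w.min(initial=0.0) < -1e-8:
            raise MMEError("gamma has a negative eigenvalue beyond the safeguard floor")
    return rtilde_inverse_blocks(gamma, b_mat, r22_inv)


def rtilde_matrix(gamma: np.ndarray, spec: ModelSpec, cat_obs=None,
                  cont_obs=None) -> np.ndarray:
    """The working residual covariance ``Rt`` itself (test oracle):
    ``[[gamma^-1 + R12 R22^-1 R21, R12], [R21, R22]]``."""
    if cat_obs is None:
        cat_obs = np.arange(spec.c)
    if cont_obs is None:
        cont_obs = np.arange(spec.m)
    ic = np.asarray(cat_obs, dtype=int)
    im = np.asarray(cont_obs, dtype=int) + spec.c
    R = spec.R
    R12 = R[np.ix_(ic, im)]
    R22 = R[np.ix_(im, im)]
    sig_part = R12 @ np.linalg.solve(R22, R12.T) if im.size else 0.0
    top = np.linalg.inv(gamma) + sig_part
    return np.block([[top, R12], [R12.T, R22]])


def pseudo_data(mu: np.ndarray, y2_obs: np.ndarray, resid2: np.ndarray,
                delta: np.ndarray, gamma: np.ndarray, spec: ModelSpec,
                cat_obs=None, cont_obs=None) -> PseudoRecord:
    """Pseudo-observation ``yt_i = (mu_i + gamma^-1 delta_i, y2_i)``, the
    working weight ``Rt^-1`` and the gradient contribution
    ``z_i = (delta_i, -B' delta_i + R22^-1 resid2_i)`` of a single record.

    ``mu`` is the conditional liability mean (which already contains
    ``W1 theta1 + B (y2 - W2 theta2)``) and ``resid2 = y2 - W2 theta2``, so
    the identity ``W theta + Rt z = yt`` holds by construction.
    """
    if cat_obs is None:
        cat_obs = np.arange(spec.c)
    if cont_obs is None:
        cont_obs = np.arange(spec.m)
    gamma = np.atleast_2d(gamma)
    try:
        yhat1 = mu + np.linalg.solve(gamma, delta)
    except np.linalg.LinAlgError:
        # singular gamma (untruncated cell): eigenvalue-floored solve
        w, V = np.linalg.eigh(gamma)
        w = np.clip(w, 1e-10, None)
        yhat1 = mu + V @ ((V.T @ delta) / w)
    ytilde = np.concatenate([yhat1, y2_obs])
    rtinv = rtilde_inverse(gamma, spec, cat_obs, cont_obs)
    obs = np.concatenate([np.asarray(cat_obs, int),
                          spec.c + np.asarray(cont_obs, int)])
    z = gradient_contribution(delta, resid2, spec, cat_obs, cont_obs)[0]
    return PseudoRecord(ytilde=ytilde, rtilde_inv=rtinv, z=z, obs_traits=obs)


def gradient_contribution(delta: np.ndarray, resid2: np.ndarray,
                          spec: ModelSpec, cat_obs=None, cont_obs=None) -> np.ndarray:
    """``z_i = (delta_i, -B' delta_i + R22^-1 resid2_i)`` with
    ``resid2_i = y2_i - W2i theta2`` (vectorized over a leading axis)."""
    if cat_obs is None:
        cat_obs = np.arange(spec.c)
    if cont_obs is None:
        cont_obs = np.arange(spec.m)
    _, b_mat = pattern_schur(spec, cat_obs, cont_obs)
    im = np.asarray(cont_obs, dtype=int) + spec.c
    delta = np.atleast_2d(delta)
    resid2 = np.atleast_2d(resid2)
    if im.size:
        r22_inv = np.linalg.inv(spec.R[np.ix_(im, im)])
        z2 = -delta @ b_mat + resid2 @ r22_inv
    else:
        z2 = np.zeros((delta.shape[0], 0))
    return np.concatenate([delta, z2], axis=1)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble(groups, data: RecordSet, S: PrecisionStructure) -> MMESystem:
    """Sum per-record contributions ``W_i' M_i W_i`` / ``W_i' M_i y_i`` into
    the sparse system, vectorized over records within each
    :class:`GroupContribution`, and add the precision ``S``."""
    T = S.n_traits
    p = data.n_fixed_coef
    nf = T * p
    n_eq = nf + S.n_levels * T
    if S.matrix.shape[0] != n_eq:
        raise MMEError(
            f"precision structure has {S.matrix.shape[0]} equations, data implies {n_eq}"
        )
    X = data.X
    aidx = data.animal_index
    rows_acc, cols_acc, vals_acc = [], [], []
    rhs = np.zeros(n_eq)
    for g in groups:
        M = g.weights
        yt = g.ytilde
        rws = g.rows
        Xg = X[rws]
        ag = aidx[rws]
        obs = np.asarray(g.obs_traits, dtype=int)
        To = obs.size
        v = np.einsum("nij,nj->ni", M, yt)  # M_i yt_i
        for i1 in range(To):
            t1 = obs[i1]
            # rhs, fixed block of t1
            rhs[t1 * p:(t1 + 1) * p] += Xg.T @ v[:, i1]
            # rhs, random equations (a, t1)
            np.add.at(rhs, nf + ag * T + t1, v[:, i1])
            for i2 in range(To):
                t2 = obs[i2]
                w = M[:, i1, i2]
                # fixed(t1) x fixed(t2)
                blk = np.einsum("n,np,nq->pq", w, Xg, Xg)
                rr, cc = np.meshgrid(np.arange(t1 * p, (t1 + 1) * p),
                                     np.arange(t2 * p, (t2 + 1) * p), indexing="ij")
                rows_acc.append(rr.ravel())
                cols_acc.append(cc.ravel())
                vals_acc.append(blk.ravel())
                # fixed(t1) x random(t2)
                rr = np.repeat(np.arange(t1 * p, (t1 + 1) * p)[None, :], rws.size, 0)
                cc = (nf + ag * T + t2)[:, None] * np.ones((1, p), dtype=np.int64)
                vv = (w[:, None] * Xg)
                rows_acc += [rr.ravel(), cc.ravel()]
                cols_acc += [cc.ravel(), rr.ravel()]
                vals_acc += [vv.ravel(), vv.ravel()]
                # random(t1) x random(t2)
                rows_acc.append(nf + ag * T + t1)
                cols_acc.append(nf + ag * T + t2)
                vals_acc.append(w)
    Cdata = sp.coo_matrix(
        (np.concatenate(vals_acc),
         (np.concatenate(rows_acc), np.concatenate(cols_acc))),
        shape=(n_eq, n_eq),
    ).tocsr()
    C = Cdata + S.matrix
    return MMESystem(C=C.tocsr(), rhs=rhs)


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

def solve(system: MMESystem, method: str = "direct", tol: float = 1e-10,
          maxiter: int = 5000, x0: np.ndarray = None) -> np.ndarray:
    """Solve ``C theta = rhs`` by sparse LU (default) or Jacobi-preconditioned
    conjugate gradients (also usable matrix-free / on singular-but-consistent
    systems)."""
    C, rhs = system.C, system.rhs
    if method == "direct":
        try:
            # symmetric-pattern minimum-degree ordering: far less fill-in
            # than the default on MME-structured matrices
            lu = spla.splu(C.tocsc(), permc_spec="MMD_AT_PLUS_A")
        except RuntimeError as exc:
            raise MMEError(f"direct factorization failed: {exc}") from exc
        return lu.solve(rhs)
    if method == "pcg":
        d = C.diagonal()
        d = np.where(d > 0, d, 1.0)
        M = spla.LinearOperator(C.shape, matvec=lambda x: x / d)
        hist = []

        def cb(xk):
            hist.append(float(np.linalg.norm(rhs - C @ xk)))

        x, info = spla.cg(C, rhs, x0=x0, rtol=tol, atol=0.0, maxiter=maxiter,
                          M=M, callback=cb)
        if info > 0:
            raise MMEError(
                f"PCG did not converge in {maxiter} iterations; "
                f"residual history tail: {hist[-5:]}"
            )
        return x
    raise MMEError(f"unknown solve method {method!r}")
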