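"""Truncated multivariate normal numerics.

The threshold model maps an observed ordinal category to a rectangle on the
latent liability scale.  Everything the MAP solvers need from that rectangle
is collected here:

* the rectangle probability ``P(lower < X <= upper)`` for ``X ~ N(mu, Sigma)``,
* the mean and covariance of ``X`` restricted to the rectangle,
* the derived working quantities ``delta = Sigma^-1 (E_T[X] - mu)`` and
  ``gamma = Sigma^-1 - Sigma^-1 Var_T(X) Sigma^-1`` that enter the gradient
  and Hessian of the joint log posterior,
* univariate closed forms (the single-categorical-trait fast path), and
* a rejection-sampling Monte-Carlo oracle used by the test suite.

Moments follow the classical reduction of truncated-normal moments to
marginal densities of the truncated distribution (Tallis-style recursions):
the mean needs the ``c`` one-dimensional marginal densities evaluated at the
box faces, the second moment additionally needs the bivariate marginal
densities at the box edges.  Rectangle probabilities in dimension > 2 use
scipy's Genz recursive quasi-Monte-Carlo integrator with a fixed internal
seed so solver runs are bit-reproducible; dimensions 1 and 2 use closed
forms / fixed-node quadrature that are exact to close to machine precision.

Infinite bounds are represented by ``numpy.inf`` and propagated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import multivariate_normal

__all__ = [
    "TruncationRegion",
    "TruncatedMoments",
    "UnivariateMoments",
    "mvn_probability",
    "tmvn_mean",
    "tmvn_cov",
    "tmvn_moments",
    "univariate_moments",
    "tmvn_mc_oracle",
    "bvn_rectangle",
    "bivariate_truncated_moments",
    "univariate_batch",
]

#: cell probabilities below this floor are clamped before division
PROB_FLOOR = 1e-12

#: absolute tolerance for Genz quasi-Monte-Carlo integration (dim > 2)
MVN_ABSEPS = 1e-10

#: fixed internal seed for the quasi-Monte-Carlo integrator
_MVN_SEED = 186283


class TmvnError(ValueError):
    """Raised for invalid truncation regions or covariance inputs."""


@dataclass(frozen=True)
class TruncationRegion:
    """Axis-aligned rectangle ``prod_j (lower_j, upper_j]`` on the liability scale.

    Half-infinite sides are written with ``-numpy.inf`` / ``numpy.inf``.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != hi.shape or lo.ndim != 1:
            raise TmvnError("lower and upper must be 1-D vectors of equal length")
        if np.any(lo >= hi):
            j = int(np.argmax(lo >= hi))
            raise TmvnError(
                f"empty truncation region: lower[{j}]={lo[j]} >= upper[{j}]={hi[j]}"
            )
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.all((x > self.lower) & (x <= self.upper), axis=-1)


@dataclass
class TruncatedMoments:
    """Moments of ``N(mu, sigma)`` restricted to a rectangle.

    ``delta`` and ``gamma`` are the multivariate working quantities of the
    Newton-Raphson update: ``delta = sigma^-1 (mean - mu)`` and
    ``gamma = sigma^-1 - sigma^-1 cov sigma^-1``.
    """

    prob: float
    mean: np.ndarray
    cov: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    floored: bool = False
    safeguarded: bool = False


@dataclass
class UnivariateMoments:
    """Closed-form working quantities for a single categorical trait."""

    eta_lower: float
    eta_upper: float
    P: float
    delta: float
    gamma: float
    ltilde: float
    floored: bool = False


# ---------------------------------------------------------------------------
# rectangle probabilities
# ---------------------------------------------------------------------------

def _check_spd(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise TmvnError("sigma must be a square matrix")
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise TmvnError("sigma must be symmetric")
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise TmvnError("sigma is not positive definite") from exc
    return sigma


# 20-point Gauss-Legendre nodes/weights on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(20)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def _bvn_upper(h, k, rho: float):
    """P(X > h, Y > k) for standard bivariate normal, vectorized in h, k.

    Drezner-Wesolowsky quadrature on the arcsine-transformed correlation
    integral; accuracy ~1e-14 for |rho| <= 0.95.  Infinite arguments are
    handled exactly.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    out = np.empty(h.shape, dtype=float)

    # degenerate bounds
    inf_mask = np.isinf(h) | np.isinf(k)
    if np.any(inf_mask):
        hh, kk = h[inf_mask], k[inf_mask]
        res = np.zeros(hh.shape)
        both_lo = (hh == -np.inf) & (kk == -np.inf)
        res[both_lo] = 1.0
        only_h = (hh == -np.inf) & np.isfinite(kk)
        res[only_h] = ndtr(-kk[only_h])
        only_k = (kk == -np.inf) & np.isfinite(hh)
        res[only_k] = ndtr(-hh[only_k])
        # any +inf bound -> probability 0 (already zeros)
        out[inf_mask] = res

    fin = ~inf_mask
    if np.any(fin):
        hf, kf = h[fin], k[fin]
        if abs(rho) < 1e-15:
            out[fin] = ndtr(-hf) * ndtr(-kf)
        else:
            asr = np.arcsin(float(np.clip(rho, -1.0, 1.0)))
            theta = asr * _GL_X  # (q,)
            sn = np.sin(theta)
            cs2 = 1.0 - sn**2
            hk = hf * kf
            hs = 0.5 * (hf**2 + kf**2)
            # integrand over quadrature nodes, vectorized: (n, q)
            ex = np.exp((sn * hk[:, None] - hs[:, None]) / cs2[None, :])
            integral = asr * (ex @ _GL_W) / (2.0 * np.pi)
            out[fin] = ndtr(-hf) * ndtr(-kf) + integral
    return np.clip(out, 0.0, 1.0)


def bvn_rectangle(lo1, hi1, lo2, hi2, mu1, mu2, s1: float, s2: float, rho: float):
    """P(lo1 < X <= hi1, lo2 < Y <= hi2), (X, Y) bivariate normal, vectorized.

    ``mu1, mu2`` may be arrays (per-record conditional means); the standard
    deviations ``s1, s2`` and correlation ``rho`` are scalars shared by all
    records, which is the per-missingness-pattern structure the solvers use.
    """
    a1 = (np.asarray(lo1, dtype=float) - mu1) / s1
    b1 = (np.asarray(hi1, dtype=float) - mu1) / s1
    a2 = (np.asarray(lo2, dtype=float) - mu2) / s2
    b2 = (np.asarray(hi2, dtype=float) - mu2) / s2
    # inclusion-exclusion on the upper-orthant function
    p = (
        _bvn_upper(a1, a2, rho)
        - _bvn_upper(a1, b2, rho)
        - _bvn_upper(b1, a2, rho)
        + _bvn_upper(b1, b2, rho)
    )
    return np.clip(p, 0.0, 1.0)


def mvn_probability(lower, upper, mu, sigma, tol: float = MVN_ABSEPS) -> float:
    """``P(lower < X <= upper)`` for ``X ~ N(mu, sigma)``.

    Deterministic: dimensions 1-2 use closed forms / fixed-node quadrature;
    higher dimensions use Genz recursive integration with a fixed internal
    seed and absolute tolerance ``tol``.
    """
    if tol <= 0:
        raise TmvnError("tol must be positive")
    region = TruncationRegion(lower, upper)  # validates emptiness
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = _check_spd(np.atleast_2d(sigma))
    if not (region.dim == mu.size == sigma.shape[0]):
        raise TmvnError("dimension mismatch between region, mu and sigma")
    lo, hi = region.lower, region.upper
    c = region.dim
    if c == 1:
        s = np.sqrt(sigma[0, 0])
        return float(ndtr((hi[0] - mu[0]) / s) - ndtr((lo[0] - mu[0]) / s))
    if c == 2:
        s1, s2 = np.sqrt(np.diag(sigma))
        rho = sigma[0, 1] / (s1 * s2)
        return float(
            bvn_rectangle(lo[0], hi[0], lo[1], hi[1], mu[0], mu[1], s1, s2, rho)
        )
    val = multivariate_normal.cdf(
        hi,
        mean=mu,
        cov=sigma,
        lower_limit=lo,
        abseps=tol,
        releps=0.0,
        rng=np.random.default_rng(_MVN_SEED),
    )
    return float(np.clip(val, 0.0, 1.0))


# ---------------------------------------------------------------------------
# truncated moments, general dimension
# ---------------------------------------------------------------------------

def _marginal_density_1(q: int, x: float, lo, hi, sigma) -> float:
    """Unnormalized 1-D marginal density of the truncated distribution.

    ``phi(x; 0, sigma_qq) * P(remaining box | X_q = x)``; caller divides by
    the cell probability.  Zero at infinite ``x``.
    """
    if not np.isfinite(x):
        return 0.0
    c = sigma.shape[0]
    sqq = sigma[q, q]
    dens = np.exp(-0.5 * x * x / sqq) / np.sqrt(2.0 * np.pi * sqq)
    if c == 1:
        return float(dens)
    rest = [j for j in range(c) if j != q]
    cond_mu = sigma[rest, q] * (x / sqq)
    cond_sig = sigma[np.ix_(rest, rest)] - np.outer(sigma[rest, q], sigma[q, rest]) / sqq
    p_rest = mvn_probability(lo[rest] - cond_mu, hi[rest] - cond_mu,
                             np.zeros(c - 1), cond_sig)
    return float(dens * p_rest)


def _marginal_density_2(k: int, q: int, x: float, y: float, lo, hi, sigma) -> float:
    """Unnormalized bivariate marginal density of the truncated distribution."""
    if not (np.isfinite(x) and np.isfinite(y)):
        return 0.0
    c = sigma.shape[0]
    pair = [k, q]
    sig2 = sigma[np.ix_(pair, pair)]
    det = sig2[0, 0] * sig2[1, 1] - sig2[0, 1] ** 2
    quad = (
        sig2[1, 1] * x * x - 2.0 * sig2[0, 1] * x * y + sig2[0, 0] * y * y
    ) / det
    dens = np.exp(-0.5 * quad) / (2.0 * np.pi * np.sqrt(det))
    if c == 2:
        return float(dens)
    rest = [j for j in range(c) if j not in pair]
    sol = np.linalg.solve(sig2, np.array([x, y]))
    cond_mu = sigma[np.ix_(rest, pair)] @ sol
    cond_sig = (
        sigma[np.ix_(rest, rest)]
        - sigma[np.ix_(rest, pair)] @ np.linalg.solve(sig2, sigma[np.ix_(pair, rest)])
    )
    p_rest = mvn_probability(lo[rest] - cond_mu, hi[rest] - cond_mu,
                             np.zeros(len(rest)), cond_sig)
    return float(dens * p_rest)


def _univariate_truncated(a: float, b: float, sd: float):
    """(prob, mean, var) of N(0, sd^2) truncated to (a, b]."""
    al, be = a / sd, b / sd
    p = float(ndtr(be) - ndtr(al))
    pf = max(p, PROB_FLOOR)
    pa = np.exp(-0.5 * al * al) / np.sqrt(2 * np.pi) if np.isfinite(al) else 0.0
    pb = np.exp(-0.5 * be * be) / np.sqrt(2 * np.pi) if np.isfinite(be) else 0.0
    apa = al * pa if np.isfinite(al) else 0.0
    bpb = be * pb if np.isfinite(be) else 0.0
    mean = sd * (pa - pb) / pf
    var = sd * sd * (1.0 + (apa - bpb) / pf - ((pa - pb) / pf) ** 2)
    return p, mean, var


def tmvn_moments(region: TruncationRegion, mu, sigma,
                 method: str = "auto") -> TruncatedMoments:
    """Probability, mean, covariance and working quantities on a rectangle.

    The mean uses the marginal-density identity
    ``E_T[X] = mu + sigma @ (F(lower) - F(upper))`` and the second moment the
    corresponding identity involving univariate and bivariate marginal
    densities of the truncated distribution.  Cells with probability below
    ``PROB_FLOOR`` are clamped (flagged via ``floored``); an indefinite
    numerical ``gamma`` is symmetrized and eigenvalue-floored (flagged via
    ``safeguarded``).

    ``method="auto"`` takes the univariate closed form at c=1;
    ``method="generic"`` always runs the marginal-density machinery (used to
    cross-check the closed forms).
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = _check_spd(np.atleast_2d(sigma))
    c = region.dim
    if not (c == mu.size == sigma.shape[0]):
        raise TmvnError("dimension mismatch between region, mu and sigma")
    lo = region.lower - mu
    hi = region.upper - mu
    floored = False

    if c == 1 and method == "auto":
        sd = float(np.sqrt(sigma[0, 0]))
        p, m, v = _univariate_truncated(lo[0], hi[0], sd)
        floored = p < PROB_FLOOR
        mean = np.array([mu[0] + m])
        cov = np.array([[v]])
        delta = np.array([m / sigma[0, 0]])
        gamma = np.array([[(1.0 - v / sigma[0, 0]) / sigma[0, 0]]])
        return TruncatedMoments(max(p, PROB_FLOOR), mean, cov, delta, gamma,
                                floored=floored)

    p = mvn_probability(region.lower, region.upper, mu, sigma)
    floored = p < PROB_FLOOR
    p_used = max(p, PROB_FLOOR)

    f_lo = np.array([_marginal_density_1(q, lo[q], lo, hi, sigma) for q in range(c)])
    f_hi = np.array([_marginal_density_1(q, hi[q], lo, hi, sigma) for q in range(c)])
    f_lo /= p_used
    f_hi /= p_used
    dvec = f_lo - f_hi
    mean_c = sigma @ dvec

    # diagonal (single-index) face terms a_k F_k(a_k) - b_k F_k(b_k)
    face = np.array([
        (lo[k] * f_lo[k] if np.isfinite(lo[k]) else 0.0)
        - (hi[k] * f_hi[k] if np.isfinite(hi[k]) else 0.0)
        for k in range(c)
    ])
    # edge (pair) terms D[k, q]
    D = np.zeros((c, c))
    for k in range(c):
        for q in range(c):
            if q == k:
                continue
            D[k, q] = (
                _marginal_density_2(k, q, lo[k], lo[q], lo, hi, sigma)
                - _marginal_density_2(k, q, lo[k], hi[q], lo, hi, sigma)
                - _marginal_density_2(k, q, hi[k], lo[q], lo, hi, sigma)
                + _marginal_density_2(k, q, hi[k], hi[q], lo, hi, sigma)
            ) / p_used

    second = np.array(sigma)  # E[X X'] accumulator, centered scale
    for i in range(c):
        for j in range(c):
            acc = 0.0
            for k in range(c):
                acc += sigma[i, k] * sigma[j, k] / sigma[k, k] * face[k]
                for q in range(c):
                    if q == k:
                        continue
                    acc += (
                        sigma[i, k]
                        * (sigma[j, q] - sigma[k, q] * sigma[j, k] / sigma[k, k])
                        * D[k, q]
                    )
            second[i, j] += acc
    second = 0.5 * (second + second.T)
    cov = second - np.outer(mean_c, mean_c)
    cov = 0.5 * (cov + cov.T)

    safeguarded = False
    w, V = np.linalg.eigh(cov)
    if np.any(w <= 0):
        safeguarded = True
        w = np.clip(w, 1e-10 * max(1.0, w.max()), None)
        cov = V @ np.diag(w) @ V.T

    delta = dvec  # sigma^-1 (mean - mu) = F(lower) - F(upper)
    sig_inv = np.linalg.inv(sigma)
    gamma = sig_inv - sig_inv @ cov @ sig_inv
    gamma = 0.5 * (gamma + gamma.T)
    wg, Vg = np.linalg.eigh(gamma)
    if np.any(wg < 0):
        safeguarded = True
        wg = np.clip(wg, 1e-10, None)
        gamma = Vg @ np.diag(wg) @ Vg.T

    return TruncatedMoments(p_used, mu + mean_c, cov, delta, gamma,
                            floored=floored, safeguarded=safeguarded)


def tmvn_mean(region: TruncationRegion, mu, sigma) -> np.ndarray:
    """Mean of ``N(mu, sigma)`` restricted to ``region``."""
    return tmvn_moments(region, mu, sigma).mean


def tmvn_cov(region: TruncationRegion, mu, sigma) -> np.ndarray:
    """Covariance of ``N(mu, sigma)`` restricted to ``region``."""
    return tmvn_moments(region, mu, sigma).cov


# ---------------------------------------------------------------------------
# univariate closed forms (single categorical trait fast path)
# ---------------------------------------------------------------------------

def univariate_moments(y_category: int, thresholds, mu: float, var: float) -> UnivariateMoments:
    """Closed-form working quantities for an observed ordinal category.

    ``thresholds`` are the K-1 finite cutpoints of a K-category trait;
    category ``k`` (1-based) corresponds to the liability interval
    ``(t_{k-1}, t_k]`` with ``t_0 = -inf`` and ``t_K = +inf``.
    """
    if var <= 0:
        raise TmvnError("var must be positive")
    t = np.concatenate(([-np.inf], np.asarray(thresholds, dtype=float), [np.inf]))
    K = t.size - 1
    if not (1 <= y_category <= K):
        raise TmvnError(f"category {y_category} outside 1..{K}")
    sd = np.sqrt(var)
    eta_lo = (t[y_category - 1] - mu) / sd
    eta_hi = (t[y_category] - mu) / sd
    p = float(ndtr(eta_hi) - ndtr(eta_lo))
    floored = p < PROB_FLOOR
    pf = max(p, PROB_FLOOR)
    phi_lo = np.exp(-0.5 * eta_lo**2) / np.sqrt(2 * np.pi) if np.isfinite(eta_lo) else 0.0
    phi_hi = np.exp(-0.5 * eta_hi**2) / np.sqrt(2 * np.pi) if np.isfinite(eta_hi) else 0.0
    delta = (-phi_hi + phi_lo) / (pf * sd)
    eterm_hi = eta_hi * phi_hi if np.isfinite(eta_hi) else 0.0
    eterm_lo = eta_lo * phi_lo if np.isfinite(eta_lo) else 0.0
    gamma = (eterm_hi - eterm_lo) / (pf * var) + delta**2
    ltilde = mu - sd * (phi_hi - phi_lo) / pf
    return UnivariateMoments(float(eta_lo), float(eta_hi), p, float(delta),
                             float(gamma), float(ltilde), floored=floored)


def univariate_batch(lo, hi, mu, var: float):
    """Vectorized closed-form (P, delta, gamma, ltilde) for scalar truncation.

    ``lo``/``hi`` are the per-record liability bounds (inf allowed), ``mu``
    the per-record conditional means, ``var`` the shared conditional
    variance.  This is the single-observed-categorical-trait fast path of
    the solvers; it matches :func:`univariate_moments` record by record.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sd = np.sqrt(var)
    eta_lo = (lo - mu) / sd
    eta_hi = (hi - mu) / sd
    P = ndtr(eta_hi) - ndtr(eta_lo)
    pf = np.maximum(P, PROB_FLOOR)

    def _phi(x):
        out = np.zeros_like(x)
        f = np.isfinite(x)
        out[f] = np.exp(-0.5 * x[f] ** 2) / np.sqrt(2 * np.pi)
        return out

    phi_lo, phi_hi = _phi(eta_lo), _phi(eta_hi)
    xlo = np.where(np.isfinite(eta_lo), eta_lo, 0.0)
    xhi = np.where(np.isfinite(eta_hi), eta_hi, 0.0)
    delta = (phi_lo - phi_hi) / (pf * sd)
    gamma = (xhi * phi_hi - xlo * phi_lo) / (pf * var) + delta**2
    ltilde = mu - sd * (phi_hi - phi_lo) / pf
    return P, delta, gamma, ltilde


# ---------------------------------------------------------------------------
# vectorized bivariate moments (c = 2 hot path for the solvers)
# ---------------------------------------------------------------------------

def bivariate_truncated_moments(lo, hi, mu, sigma):
    """Vectorized truncated moments for many records sharing one 2x2 ``sigma``.

    Parameters
    ----------
    lo, hi : (n, 2) arrays of rectangle bounds (inf allowed)
    mu : (n, 2) per-record conditional means
    sigma : (2, 2) shared conditional covariance

    Returns
    -------
    prob : (n,), mean : (n, 2), cov : (n, 2, 2), delta : (n, 2),
    gamma : (n, 2, 2) — same quantities as :func:`tmvn_moments`.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = _check_spd(np.atleast_2d(sigma))
    n = mu.shape[0]
    s1, s2 = np.sqrt(np.diag(sigma))
    rho = float(sigma[0, 1] / (s1 * s2))
    a = lo - mu  # centered bounds, (n, 2)
    b = hi - mu

    prob = bvn_rectangle(lo[:, 0], hi[:, 0], lo[:, 1], hi[:, 1],
                         mu[:, 0], mu[:, 1], s1, s2, rho)
    p = np.maximum(prob, PROB_FLOOR)

    sd = np.array([s1, s2])
    det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2

    def _phi1(x, k):
        out = np.zeros_like(x)
        f = np.isfinite(x)
        out[f] = np.exp(-0.5 * (x[f] / sd[k]) ** 2) / (np.sqrt(2 * np.pi) * sd[k])
        return out

    def _cond_prob(x, k):
        """P(other coordinate in its interval | X_k = x), vectorized."""
        o = 1 - k
        cond_sd = np.sqrt(sigma[o, o] - sigma[0, 1] ** 2 / sigma[k, k])
        out = np.zeros(n)
        f = np.isfinite(x)
        cm = sigma[o, k] * x[f] / sigma[k, k]
        out[f] = ndtr((b[f, o] - cm) / cond_sd) - ndtr((a[f, o] - cm) / cond_sd)
        return out

    # unnormalized univariate marginal densities at the four faces
    F_lo = np.stack([_phi1(a[:, k], k) * _cond_prob(a[:, k], k) for k in (0, 1)], axis=1)
    F_hi = np.stack([_phi1(b[:, k], k) * _cond_prob(b[:, k], k) for k in (0, 1)], axis=1)
    F_lo /= p[:, None]
    F_hi /= p[:, None]
    dvec = F_lo - F_hi  # (n, 2) == delta
    mean_c = dvec @ sigma.T

    def _phi2(x, y):
        out = np.zeros(n)
        f = np.isfinite(x) & np.isfinite(y)
        quad = (sigma[1, 1] * x[f] ** 2 - 2 * sigma[0, 1] * x[f] * y[f]
                + sigma[0, 0] * y[f] ** 2) / det
        out[f] = np.exp(-0.5 * quad) / (2 * np.pi * np.sqrt(det))
        return out

    # shared corner term of the bivariate marginal densities
    D = (_phi2(a[:, 0], a[:, 1]) - _phi2(a[:, 0], b[:, 1])
         - _phi2(b[:, 0], a[:, 1]) + _phi2(b[:, 0], b[:, 1])) / p

    xa = np.where(np.isfinite(a), a, 0.0)
    xb = np.where(np.isfinite(b), b, 0.0)
    face = np.stack(
        [xa[:, k] * F_lo[:, k] - xb[:, k] * F_hi[:, k] for k in (0, 1)], axis=1
    )  # (n, 2)

    second = np.empty((n, 2, 2))
    for i in (0, 1):
        for j in (0, 1):
            acc = np.full(n, sigma[i, j])
            for k in (0, 1):
                q = 1 - k
                acc += sigma[i, k] * sigma[j, k] / sigma[k, k] * face[:, k]
                acc += sigma[i, k] * (sigma[j, q] - sigma[k, q] * sigma[j, k] / sigma[k, k]) * D
            second[:, i, j] = acc
    second = 0.5 * (second + np.transpose(second, (0, 2, 1)))
    cov = second - mean_c[:, :, None] * mean_c[:, None, :]
    cov = 0.5 * (cov + np.transpose(cov, (0, 2, 1)))

    sig_inv = np.linalg.inv(sigma)
    gamma = sig_inv[None] - np.einsum("ab,nbc,cd->nad", sig_inv, cov, sig_inv)
    gamma = 0.5 * (gamma + np.transpose(gamma, (0, 2, 1)))

    # eigenvalue floor on gamma (rarely triggered; keeps the Hessian PSD)
    w, V = np.linalg.eigh(gamma)
    bad = w[:, 0] < 0
    if np.any(bad):
        w[bad] = np.clip(w[bad], 1e-10, None)
        gamma[bad] = np.einsum("nab,nb,ncb->nac", V[bad], w[bad], V[bad])

    return prob, mu + mean_c, cov, dvec, gamma


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

def tmvn_mc_oracle(region: TruncationRegion, mu, sigma, n_draws: int = 10**6,
                   seed: int = 0):
    """Rejection-sampling estimate of (mean, cov, prob) with standard errors.

    Returns a dict with keys ``mean``, ``cov``, ``prob``, ``mean_se``,
    ``cov_se``, ``prob_se``, ``n_accepted``.  Used as the independent oracle
    in the test suite; intentionally naive.
    """
    if n_draws < 10**4:
        raise TmvnError("n_draws must be at least 1e4 for a usable oracle")
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = _check_spd(np.atleast_2d(sigma))
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(mu, sigma, size=n_draws, method="cholesky")
    inside = region.contains(X)
    n_acc = int(inside.sum())
    if n_acc < max(10, n_draws * 1e-4):
        raise TmvnError(
            f"acceptance rate {n_acc / n_draws:.2e} too low; "
            "increase n_draws or use a larger region"
        )
    acc = X[inside]
    prob = n_acc / n_draws
    prob_se = np.sqrt(prob * (1 - prob) / n_draws)
    mean = acc.mean(axis=0)
    cov = np.cov(acc, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    mean_se = np.sqrt(np.diag(cov) / n_acc)
    # SE of covariance entries via the delta method on centered products
    ctr = acc - mean
    prod = ctr[:, :, None] * ctr[:, None, :]
    cov_se = prod.std(axis=0, ddof=1) / np.sqrt(n_acc)
    return {
        "mean": mean, "cov": cov, "prob": prob,
        "mean_se": mean_se, "cov_se": cov_se, "prob_se": prob_se,
        "n_accepted": n_acc,
    }
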