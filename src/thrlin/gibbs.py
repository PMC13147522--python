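"""Single-site Gibbs sampler benchmark for the threshold-linear model.

With variances and thresholds known, the posterior of the liabilities and
location parameters is sampled by alternating (i) truncated-normal draws of
each categorical liability given the record's other traits and the current
solutions, and (ii) single-site normal draws of every equation of the
linear mixed-model equations with the current (liability, continuous) data.
Posterior means of the breeding values are the benchmark against which the
MAP solvers are validated.

The liability pass updates one categorical trait at a time across all
records (records are conditionally independent given ``theta``, so the
vectorized per-trait update realizes an exact single-site scan); the
location pass is a deterministic-order single-site sweep compiled with
numba.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
from scipy.special import ndtr, ndtri

from .model import ModelSpec, RecordSet, Theta
from .pedigree import PrecisionStructure
from .working import build_linear_system, category_rectangles

__all__ = ["GibbsResults", "gibbs_run", "sample_liabilities"]

_UCLIP = 1e-14  # uniform draws clipped into (eps, 1-eps) for tail robustness


@numba.njit(cache=True)
def _site_sweep(indptr, indices, cdata, diag, rhs, theta, z):
    n = rhs.size
    for k in range(n):
        acc = 0.0
        for jj in range(indptr[k], indptr[k + 1]):
            j = indices[jj]
            if j != k:
                acc += cdata[jj] * theta[j]
        mean = (rhs[k] - acc) / diag[k]
        theta[k] = mean + z[k] / np.sqrt(diag[k])


@dataclass
class GibbsResults:
    """Posterior means with Monte-Carlo standard errors (batch means)."""

    theta_mean: Theta
    theta_mcse: np.ndarray
    n_samples: int
    burn_in: int
    thin: int
    seed: int
    n_tail_clips: int = 0


def _trunc_normal(rng, mean, sd, lo, hi):
    """Vectorized inverse-CDF truncated-normal draws on (lo, hi]."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    width = b - a
    clipped = int(np.sum(width < 1e-12))
    u = a + rng.random(mean.shape) * width
    u = np.clip(u, _UCLIP, 1.0 - _UCLIP)
    x = mean + sd * ndtri(u)
    # numerical insurance: keep draws inside the interval
    return np.clip(x, np.nextafter(lo, hi), hi), clipped


def _liability_plans(data: RecordSet, spec: ModelSpec, groups):
    """Per pattern and categorical trait: regression weights of the full
    conditional on the record's other observed traits, and its variance."""
    plans = []
    for g in groups:
        obs = np.concatenate([np.asarray(g.cat_obs, int),
                              spec.c + np.asarray(g.cont_obs, int)])
        R_obs = spec.R[np.ix_(obs, obs)]
        per_trait = []
        for pos, j in enumerate(g.cat_obs):
            others = np.delete(np.arange(obs.size), pos)
            if others.size:
                w = np.linalg.solve(R_obs[np.ix_(others, others)],
                                    R_obs[others, pos])
                var = R_obs[pos, pos] - R_obs[pos, others] @ w
            else:
                w = np.zeros(0)
                var = R_obs[pos, pos]
            per_trait.append((pos, j, others, w, float(var)))
        plans.append((g, obs, per_trait))
    return plans


def sample_liabilities(rng, liabilities, eta, data: RecordSet, spec: ModelSpec,
                       plans) -> int:
    """One scan of truncated-normal liability updates, in place.

    ``liabilities`` is (n, c) (NaN where unobserved), ``eta = W theta`` is
    (n, T).  Returns the number of near-degenerate intervals hit.
    """
    clips = 0
    for g, obs, per_trait in plans:
        rows = g.rows
        lo, hi = category_rectangles(data, spec, g)
        for pos, j, others, w, var in per_trait:
            # residuals of the other observed traits at current values
            vals = np.concatenate([
                liabilities[np.ix_(rows, g.cat_obs)],
                data.y2[np.ix_(rows, g.cont_obs)],
            ], axis=1)
            resid = vals - eta[rows][:, obs]
            cond_mean = eta[rows, j] + resid[:, others] @ w
            draw, c = _trunc_normal(rng, cond_mean, np.sqrt(var),
                                    lo[:, pos], hi[:, pos])
            liabilities[rows, j] = draw
            clips += c
    return clips


def gibbs_run(data: RecordSet, spec: ModelSpec, S: PrecisionStructure,
              n_samples: int = 10000, burn_in: int = 1000, thin: int = 1,
              seed: int = 0, theta0: Theta = None,
              n_batches: int = 20) -> GibbsResults:
    """Run the sampler and return posterior means of all location parameters.

    ``n_samples`` is the total chain length; samples after ``burn_in`` are
    accumulated every ``thin`` sweeps.  Reproducible given ``seed``.
    """
    if n_samples <= burn_in:
        raise ValueError("n_samples must exceed burn_in")
    rng = np.random.default_rng(seed)
    groups = data.pattern_groups()
    plans = _liability_plans(data, spec, groups)
    p = data.n_fixed_coef
    T = S.n_traits
    nf = T * p
    n_eq = nf + S.n_levels * T

    theta = theta0 if theta0 is not None else Theta.zeros(p, S.n_levels, T)
    vec = theta.vector.copy()

    # initialize liabilities at conditional means of their category interval
    liabilities = np.full((data.n_records, spec.c), np.nan)
    eta = Theta.from_vector(vec, p, S.n_levels, T).linear_predictor(data)
    for g, obs, per_trait in plans:
        lo, hi = category_rectangles(data, spec, g)
        for pos, j, others, w, var in per_trait:
            mid_lo = np.where(np.isfinite(lo[:, pos]), lo[:, pos], hi[:, pos] - 1.0)
            mid_hi = np.where(np.isfinite(hi[:, pos]), hi[:, pos], lo[:, pos] + 1.0)
            liabilities[g.rows, j] = 0.5 * (mid_lo + mid_hi)

    # constant coefficient matrix of the linear MME (data part + S)
    ydot0 = np.where(np.isnan(liabilities), 0.0, liabilities)
    sys0 = build_linear_system(theta, ydot0, data, spec, S, groups)
    C = sys0.C.tocsr()
    diag = C.diagonal()
    if np.any(diag <= 0):
        k = int(np.argmax(diag <= 0))
        raise ValueError(f"zero diagonal in equation {k}; system not sampleable")

    # per-pattern pieces for the fast rhs rebuild each sweep
    rhs_plans = []
    for g, obs, per_trait in plans:
        R_inv = np.linalg.inv(spec.R[np.ix_(obs, obs)])
        rhs_plans.append((g, obs, R_inv))

    def build_rhs():
        rhs = np.zeros(n_eq)
        for g, obs, R_inv in rhs_plans:
            rows = g.rows
            ydot = np.concatenate([
                liabilities[np.ix_(rows, g.cat_obs)],
                data.y2[np.ix_(rows, g.cont_obs)],
            ], axis=1)
            v = ydot @ R_inv.T
            Xg = data.X[rows]
            ag = data.animal_index[rows]
            for i, t in enumerate(obs):
                rhs[t * p:(t + 1) * p] += Xg.T @ v[:, i]
                np.add.at(rhs, nf + ag * T + t, v[:, i])
        return rhs

    acc_sum = np.zeros(n_eq)
    n_kept = 0
    batch_sums = np.zeros((n_batches, n_eq))
    batch_counts = np.zeros(n_batches, dtype=np.int64)
    kept_total = (n_samples - burn_in) // thin
    clips = 0

    for sweep in range(n_samples):
        eta = Theta.from_vector(vec, p, S.n_levels, T).linear_predictor(data)
        clips += sample_liabilities(rng, liabilities, eta, data, spec, plans)
        rhs = build_rhs()
        z = rng.standard_normal(n_eq)
        _site_sweep(C.indptr, C.indices, C.data, diag, rhs, vec, z)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            acc_sum += vec
            b = min(n_kept * n_batches // max(kept_total, 1), n_batches - 1)
            batch_sums[b] += vec
            batch_counts[b] += 1
            n_kept += 1

    mean_vec = acc_sum / n_kept
    with np.errstate(invalid="ignore", divide="ignore"):
        bm = batch_sums[batch_counts > 0] / batch_counts[batch_counts > 0, None]
    nb = bm.shape[0]
    mcse = bm.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.full(n_eq, np.nan)
    return GibbsResults(
        theta_mean=Theta.from_vector(mean_vec, p, S.n_levels, T),
        theta_mcse=mcse, n_samples=n_samples, burn_in=burn_in, thin=thin,
        seed=seed, n_tail_clips=clips,
    )
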