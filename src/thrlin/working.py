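"""Per-round working quantities shared by the NR and EM solvers.

Both algorithms walk the records once per outer round: compute the
conditional distribution of the observed liabilities given the continuous
traits, the truncated-normal moments on the observed category rectangle,
and turn them into either the Newton-Raphson working system (weights
``Rt^-1`` and pseudo-data ``yt``) or the EM liability expectations.
Records are processed in vectorized batches per missingness pattern, with
closed forms for one or two observed categorical traits and the generic
integrator above that.
"""

from __future__ import annotations

import numpy as np

from . import tmvn
from .mme import GroupContribution, MMESystem, assemble, rtilde_inverse_blocks
from .model import ModelSpec, RecordSet, Theta, conditional_moments, pattern_schur
from .pedigree import PrecisionStructure

__all__ = [
    "category_rectangles",
    "group_moments",
    "build_nr_system",
    "liability_expectations",
    "log_posterior",
    "build_linear_system",
]


def category_rectangles(data: RecordSet, spec: ModelSpec, group):
    """Liability-scale bounds (lo, hi), each (n_g, c_obs), for the observed
    categories of one pattern group."""
    rows = group.rows
    los, his = [], []
    for j in group.cat_obs:
        lo_j, hi_j = spec.category_bounds(j, data.categories[rows, j])
        los.append(lo_j)
        his.append(hi_j)
    if not los:
        n = rows.size
        return np.zeros((n, 0)), np.zeros((n, 0))
    return np.column_stack(los), np.column_stack(his)


def group_moments(mu: np.ndarray, sigma: np.ndarray, lo: np.ndarray,
                  hi: np.ndarray, need_cov: bool, force_generic: bool = False):
    """Truncated moments for a batch of records sharing one ``sigma``.

    Returns ``(prob, mean, delta, gamma)``; ``gamma`` is None when
    ``need_cov`` is False (EM only needs the mean).  ``force_generic``
    routes everything through the generic integrator (cross-checking the
    closed-form fast paths).
    """
    n, c = mu.shape
    if c == 0:
        z = np.zeros((n, 0))
        return np.ones(n), z, z, np.zeros((n, 0, 0))
    if force_generic:
        prob = np.empty(n)
        mean = np.empty((n, c))
        delta = np.empty((n, c))
        gamma = np.empty((n, c, c)) if need_cov else None
        for i in range(n):
            mom = tmvn.tmvn_moments(tmvn.TruncationRegion(lo[i], hi[i]), mu[i],
                                    sigma)
            prob[i], mean[i], delta[i] = mom.prob, mom.mean, mom.delta
            if need_cov:
                gamma[i] = mom.gamma
        return prob, mean, delta, gamma
    if c == 1:
        var = float(sigma[0, 0])
        P, delta, gamma, ltilde = tmvn.univariate_batch(lo[:, 0], hi[:, 0],
                                                        mu[:, 0], var)
        g = gamma[:, None, None] if need_cov else None
        return P, ltilde[:, None], delta[:, None], g
    if c == 2:
        prob, mean, cov, delta, gamma = tmvn.bivariate_truncated_moments(
            lo, hi, mu, sigma)
        return prob, mean, delta, (gamma if need_cov else None)
    prob = np.empty(n)
    mean = np.empty((n, c))
    delta = np.empty((n, c))
    gamma = np.empty((n, c, c)) if need_cov else None
    for i in range(n):
        mom = tmvn.tmvn_moments(tmvn.TruncationRegion(lo[i], hi[i]), mu[i], sigma)
        prob[i], mean[i], delta[i] = mom.prob, mom.mean, mom.delta
        if need_cov:
            gamma[i] = mom.gamma
    return prob, mean, delta, gamma


def _pattern_pieces(data, spec, theta, group):
    cm = conditional_moments(data, group, theta, spec)
    lo, hi = category_rectangles(data, spec, group)
    return cm, lo, hi


def build_nr_system(theta: Theta, data: RecordSet, spec: ModelSpec,
                    S: PrecisionStructure, groups=None) -> MMESystem:
    """One pass over the data at the current solutions: working weights
    ``Rt_i^-1`` and pseudo-data ``yt_i`` per record, assembled into the
    sparse system ``(W' Rt^-1 W + S) theta = W' Rt^-1 yt``."""
    if groups is None:
        groups = data.pattern_groups()
    contribs = []
    for g in groups:
        cm, lo, hi = _pattern_pieces(data, spec, theta, g)
        _, _, delta, gamma = group_moments(cm.mu, cm.sigma, lo, hi, need_cov=True)
        c_obs = g.cat_obs.size
        im = spec.c + np.asarray(g.cont_obs, dtype=int)
        r22_inv = (np.linalg.inv(spec.R[np.ix_(im, im)]) if im.size
                   else np.zeros((0, 0)))
        y2_obs = data.y2[np.ix_(g.rows, g.cont_obs)]
        if c_obs:
            # yhat1 = mu + gamma^-1 delta, batched
            yhat1 = cm.mu + np.linalg.solve(gamma, delta[..., None])[..., 0]
            weights = rtilde_inverse_blocks(gamma, cm.b_mat, r22_inv)
            ytilde = np.concatenate([yhat1, y2_obs], axis=1)
        else:
            weights = np.broadcast_to(r22_inv, (g.rows.size, im.size, im.size))
            ytilde = y2_obs
        obs = np.concatenate([np.asarray(g.cat_obs, int),
                              spec.c + np.asarray(g.cont_obs, int)])
        contribs.append(GroupContribution(rows=g.rows, obs_traits=obs,
                                          weights=weights, ytilde=ytilde))
    return assemble(contribs, data, S)


def liability_expectations(theta: Theta, data: RecordSet, spec: ModelSpec,
                           groups=None) -> np.ndarray:
    """E-step: ``ltilde_ij = E[l_ij | y1i, y2i, theta]`` for every observed
    categorical record cell; NaN where unobserved.  (n, c)."""
    if groups is None:
        groups = data.pattern_groups()
    out = np.full((data.n_records, spec.c), np.nan)
    for g in groups:
        if g.cat_obs.size == 0:
            continue
        cm, lo, hi = _pattern_pieces(data, spec, theta, g)
        _, mean, _, _ = group_moments(cm.mu, cm.sigma, lo, hi, need_cov=False)
        out[np.ix_(g.rows, g.cat_obs)] = mean
    return out


def build_linear_system(theta: Theta, ydot_cat: np.ndarray, data: RecordSet,
                        spec: ModelSpec, S: PrecisionStructure,
                        groups=None) -> MMESystem:
    """The ordinary multi-trait MME ``(W' R^-1 W + S) theta = W' R^-1 ydot``
    with ``ydot = (ltilde, y2)`` as data (the EM M-step; also the system the
    Gibbs benchmark samples around).  Weights depend only on the missingness
    pattern, not on ``theta``."""
    if groups is None:
        groups = data.pattern_groups()
    contribs = []
    for g in groups:
        obs = np.concatenate([np.asarray(g.cat_obs, int),
                              spec.c + np.asarray(g.cont_obs, int)])
        R_obs = spec.R[np.ix_(obs, obs)]
        w = np.linalg.inv(R_obs)
        ydot = np.concatenate([
            ydot_cat[np.ix_(g.rows, g.cat_obs)],
            data.y2[np.ix_(g.rows, g.cont_obs)],
        ], axis=1)
        contribs.append(GroupContribution(
            rows=g.rows, obs_traits=obs,
            weights=np.broadcast_to(w, (g.rows.size,) + w.shape), ytilde=ydot,
        ))
    return assemble(contribs, data, S)


def log_posterior(theta: Theta, data: RecordSet, spec: ModelSpec,
                  S: PrecisionStructure, groups=None) -> float:
    """Joint log posterior (up to additive constants): the sum of log cell
    probabilities, the Gaussian log likelihood of the continuous records and
    the random-effect prior ``-theta' S theta / 2``."""
    if groups is None:
        groups = data.pattern_groups()
    total = 0.0
    for g in groups:
        cm, lo, hi = _pattern_pieces(data, spec, theta, g)
        c_obs = g.cat_obs.size
        if c_obs == 1:
            P, _, _, _ = tmvn.univariate_batch(lo[:, 0], hi[:, 0], cm.mu[:, 0],
                                               float(cm.sigma[0, 0]))
        elif c_obs == 2:
            s1, s2 = np.sqrt(np.diag(cm.sigma))
            rho = float(cm.sigma[0, 1] / (s1 * s2))
            P = tmvn.bvn_rectangle(lo[:, 0], hi[:, 0], lo[:, 1], hi[:, 1],
                                   cm.mu[:, 0], cm.mu[:, 1], s1, s2, rho)
        elif c_obs > 2:
            P = np.array([
                tmvn.mvn_probability(lo[i], hi[i], cm.mu[i], cm.sigma)
                for i in range(g.rows.size)
            ])
        else:
            P = None
        if P is not None:
            total += float(np.sum(np.log(np.maximum(P, tmvn.PROB_FLOOR))))
        if g.cont_obs.size:
            im = spec.c + np.asarray(g.cont_obs, dtype=int)
            R22 = spec.R[np.ix_(im, im)]
            eta = theta.linear_predictor(data)[g.rows][:, im]
            resid = data.y2[np.ix_(g.rows, g.cont_obs)] - eta
            total += -0.5 * float(np.sum(resid * np.linalg.solve(R22, resid.T).T))
    vec = theta.vector
    total += -0.5 * float(vec @ (S.matrix @ vec))
    return total
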