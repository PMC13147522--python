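"""Expectation-Maximization MAP estimation with SQUAREM acceleration.

The complete data are the liabilities: the E-step replaces each unobserved
liability by its truncated-normal conditional expectation given the
observed category, the continuous traits and the current solutions; the
M-step solves an ordinary multi-trait linear MME with those expectations as
phenotypes.  The M-step coefficient matrix ``W' R^-1 W + S`` does not
depend on ``theta``, so its sparse factorization is computed once and
reused across all rounds — the main reason each EM round is cheaper than a
Newton-Raphson round (it needs only the truncated mean, never the
truncated covariance).

Convergence is measured with the same relative-residual criterion as the
NR solver (evaluated on the NR working system) so the two algorithms share
one stopping semantics.  Squared-extrapolation (SQUAREM) acceleration is
applied after each pair of plain EM steps, falling back to the plain
iterate whenever the extrapolated point worsens the metric.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse.linalg as spla

from . import working
from .model import ModelSpec, RecordSet, Theta
from .nr import ConvergenceError
from .pedigree import PrecisionStructure

__all__ = ["em_estep", "em_mstep", "squarem_accelerate", "em_solve", "EMEngine"]


def em_estep(theta: Theta, data: RecordSet, spec: ModelSpec, groups=None) -> np.ndarray:
    """Liability expectations ``ltilde`` (n, c); NaN where unobserved."""
    return working.liability_expectations(theta, data, spec, groups)


class EMEngine:
    """Caches the constant M-step system pieces across rounds."""

    def __init__(self, data: RecordSet, spec: ModelSpec, S: PrecisionStructure,
                 groups=None):
        self.data = data
        self.spec = spec
        self.S = S
        self.groups = data.pattern_groups() if groups is None else groups
        self._lu = None
        self.factorizations = 0  # exposed so tests can assert reuse

    def mstep(self, ltilde: np.ndarray) -> Theta:
        sys_m = working.build_linear_system(
            Theta.zeros(self.data.n_fixed_coef, self.S.n_levels, self.S.n_traits),
            ltilde, self.data, self.spec, self.S, self.groups)
        if self._lu is None:
            self._lu = spla.splu(sys_m.C.tocsc(), permc_spec="MMD_AT_PLUS_A")
            self.factorizations += 1
        vec = self._lu.solve(sys_m.rhs)
        return Theta.from_vector(vec, self.data.n_fixed_coef, self.S.n_levels,
                                 self.S.n_traits)

    def em_step(self, theta: Theta) -> Theta:
        return self.mstep(em_estep(theta, self.data, self.spec, self.groups))

    def metric(self, theta: Theta) -> float:
        sysw = working.build_nr_system(theta, self.data, self.spec, self.S,
                                       self.groups)
        return sysw.convergence_metric(theta.vector)


def em_mstep(ltilde: np.ndarray, data: RecordSet, spec: ModelSpec,
             S: PrecisionStructure) -> Theta:
    """Solve the ordinary multi-trait MME with ``(ltilde, y2)`` as data."""
    return EMEngine(data, spec, S).mstep(ltilde)


def squarem_accelerate(theta_prev: np.ndarray, theta_em1: np.ndarray,
                       theta_em2: np.ndarray) -> np.ndarray:
    """Squared-extrapolation update from three consecutive EM iterates.

    ``r = x1 - x0``, ``v = x2 - x1 - r``, steplength
    ``alpha = -||r|| / ||v||`` clamped to <= -1, extrapolated point
    ``x0 - 2 alpha r + alpha^2 v``.  Returns ``theta_em2`` unchanged when the
    step direction has already collapsed (``||v|| = 0``).
    """
    r = theta_em1 - theta_prev
    v = theta_em2 - theta_em1 - r
    nv = np.linalg.norm(v)
    if nv == 0.0:
        return theta_em2
    alpha = -np.linalg.norm(r) / nv
    alpha = min(alpha, -1.0)
    return theta_prev - 2.0 * alpha * r + alpha**2 * v


def em_solve(data: RecordSet, spec: ModelSpec, S: PrecisionStructure,
             tol: float = 1e-12, max_rounds: int = 1000,
             accelerate: bool = True, theta0: Theta = None,
             track_logpost: bool = False):
    """SQUAREM-accelerated EM to the shared relative-residual tolerance.

    Returns ``(theta, info)``; ``info['rounds']`` counts E/M pairs
    (including those consumed inside acceleration cycles) and
    ``info['metric_trace']`` records the stopping metric at every accepted
    iterate, crossing ``tol`` exactly once at the end.
    """
    eng = EMEngine(data, spec, S)
    p = data.n_fixed_coef
    if theta0 is None:
        theta0 = Theta.zeros(p, S.n_levels, S.n_traits)
    theta = theta0
    metric = eng.metric(theta)
    trace = [metric]
    logpost = []
    if track_logpost:
        logpost.append(working.log_posterior(theta, data, spec, S, eng.groups))
    rounds = 0
    accel_accepted = 0
    while metric >= tol:
        if rounds >= max_rounds:
            raise ConvergenceError(
                f"EM did not reach tol={tol:g} in {max_rounds} rounds "
                f"(metric {metric:.3e})", trace=trace)
        if not accelerate:
            theta = eng.em_step(theta)
            rounds += 1
        else:
            x0 = theta.vector
            th1 = eng.em_step(theta)
            m1 = eng.metric(th1)
            rounds += 1
            if m1 < tol:
                theta, metric = th1, m1
                trace.append(metric)
                break
            th2 = eng.em_step(th1)
            rounds += 1
            acc_vec = squarem_accelerate(x0, th1.vector, th2.vector)
            acc = Theta.from_vector(acc_vec, p, S.n_levels, S.n_traits)
            m2 = eng.metric(th2)
            macc = eng.metric(acc)
            if macc < m2:
                theta, metric = acc, macc
                accel_accepted += 1
            else:
                theta, metric = th2, m2
            trace.append(metric)
            if track_logpost:
                logpost.append(
                    working.log_posterior(theta, data, spec, S, eng.groups))
            continue
        metric = eng.metric(theta)
        trace.append(metric)
        if track_logpost:
            logpost.append(
                working.log_posterior(theta, data, spec, S, eng.groups))
    info = {
        "rounds": rounds,
        "metric_trace": trace,
        "logpost_trace": logpost,
        "accelerations_accepted": accel_accepted,
        "converged": True,
        "final_metric": metric,
        "factorizations": eng.factorizations,
    }
    return theta, info
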