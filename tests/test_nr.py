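"""Newton-Raphson solver: derivative correctness, fixed points, linear limit."""

import numpy as np
import pytest

from thrlin import working
from thrlin.model import Theta
from thrlin.nr import ConvergenceError, NRState, nr_round, nr_solve, pev
from thrlin.pedigree import a_inverse, build_S


def _toy_S(spec, records, ped):
    return build_S(spec.G0, a_inverse(ped), records.n_fixed_coef * spec.n_traits)


def fd_gradient(f, x, h=1e-5):
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def fd_hessian(f, x, h=1e-3):
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = (f(x + ei + ej) - f(x + ei - ej)
                       - f(x - ei + ej) + f(x - ei - ej)) / (4 * h * h)
            H[j, i] = H[i, j]
    return H


class TestDerivatives:
    def test_gradient_and_hessian_match_finite_differences(self, toy_bundle):
        """Assembled gradient rhs - C theta and Hessian -C must match central
        finite differences of the directly-integrated log posterior."""
        spec, records, ped = toy_bundle
        S = _toy_S(spec, records, ped)
        p, T, na = records.n_fixed_coef, spec.n_traits, ped.n
        rng = np.random.default_rng(17)
        vec = 0.2 * rng.normal(size=p * T + na * T)
        th = Theta.from_vector(vec, p, na, T)
        sys = working.build_nr_system(th, records, spec, S)

        def f(x):
            return working.log_posterior(Theta.from_vector(x, p, na, T),
                                         records, spec, S)

        g_fd = fd_gradient(f, vec)
        g_an = sys.gradient(vec)
        assert np.abs(g_fd - g_an).max() < 1e-5
        H_fd = fd_hessian(f, vec)
        H_an = -sys.C.toarray()
        assert np.abs(H_fd - H_an).max() < 1e-5

    def test_gradient_vanishes_at_converged_theta(self, toy_bundle):
        spec, records, ped = toy_bundle
        S = _toy_S(spec, records, ped)
        theta, info = nr_solve(records, spec, S, tol=1e-12)
        sys = working.build_nr_system(theta, records, spec, S)
        assert np.abs(sys.gradient(theta.vector)).max() < 1e-6


class TestNRIteration:
    def test_linear_data_converges_in_one_round(self, linear_sim):
        b = linear_sim
        S = build_S(b.spec.G0, a_inverse(b.pedigree),
                    b.records.n_fixed_coef * b.spec.n_traits)
        theta, info = nr_solve(b.records, b.spec, S, tol=1e-12)
        assert info["rounds"] == 1

    def test_fixed_point_is_stationary(self, toy_bundle):
        spec, records, ped = toy_bundle
        S = _toy_S(spec, records, ped)
        theta, info = nr_solve(records, spec, S, tol=1e-12)
        st = NRState(theta=theta)
        nxt = nr_round(st, records, spec, S)
        assert np.abs(nxt.theta.vector - theta.vector).max() < 1e-10

    def test_update_is_newton_step(self, toy_bundle):
        # theta_1 = theta_0 - H^-1 grad with H, grad from finite differences
        spec, records, ped = toy_bundle
        S = _toy_S(spec, records, ped)
        p, T, na = records.n_fixed_coef, spec.n_traits, ped.n
        vec0 = np.zeros(p * T + na * T)
        st = NRState(theta=Theta.from_vector(vec0, p, na, T))
        nxt = nr_round(st, records, spec, S)

        def f(x):
            return working.log_posterior(Theta.from_vector(x, p, na, T),
                                         records, spec, S)

        # theta1 = theta0 - H^-1 grad = theta0 + (-H)^-1 grad
        step = np.linalg.solve(-fd_hessian(f, vec0), fd_gradient(f, vec0))
        assert np.abs(nxt.theta.vector - (vec0 + step)).max() < 1e-5

    def test_metric_trace_decreasing_and_crossing(self, toy_bundle):
        spec, records, ped = toy_bundle
        S = _toy_S(spec, records, ped)
        _, info = nr_solve(records, spec, S, tol=1e-12)
        trace = info["metric_trace"]
        assert all(t >= 1e-12 for t in trace[:-1])
        assert trace[-1] < 1e-12
        assert all(b < a for a, b in zip(trace, trace[1:]))

    def test_log_posterior_non_decreasing(self, toy_bundle):
        spec, records, ped = toy_bundle
        S = _toy_S(spec, records, ped)
        _, info = nr_solve(records, spec, S, tol=1e-12, track_logpost=True)
        lp = info["logpost_trace"]
        assert all(b >= a - 1e-8 for a, b in zip(lp, lp[1:]))

    def test_max_rounds_raises_with_trace(self, toy_bundle):
        spec, records, ped = toy_bundle
        S = _toy_S(spec, records, ped)
        with pytest.raises(ConvergenceError) as ei:
            nr_solve(records, spec, S, tol=1e-12, max_rounds=1)
        assert len(ei.value.trace) >= 1

    def test_closed_form_and_generic_paths_agree(self, toy_bundle, monkeypatch):
        """Routing all truncated moments through the generic integrator must
        reproduce the fast-path trajectory."""
        spec, records, ped = toy_bundle
        S = _toy_S(spec, records, ped)
        theta_fast, _ = nr_solve(records, spec, S, tol=1e-10)
        orig = working.group_moments
        monkeypatch.setattr(
            working, "group_moments",
            lambda *a, **k: orig(*a, **{**k, "force_generic": True}))
        theta_gen, _ = nr_solve(records, spec, S, tol=1e-10)
        assert np.abs(theta_fast.vector - theta_gen.vector).max() < 1e-8


class TestPEV:
    def test_matches_dense_inverse(self, toy_bundle):
        spec, records, ped = toy_bundle
        S = _toy_S(spec, records, ped)
        theta, info = nr_solve(records, spec, S, tol=1e-12)
        sys = info["system"]
        targets = np.arange(sys.C.shape[0])
        dense = np.diag(np.linalg.inv(sys.C.toarray()))
        assert np.allclose(pev(sys, targets), dense, atol=1e-8)

    def test_information_ordering(self, small_sim):
        """An animal with many measured progeny is better known than a
        parentless animal without records."""
        from thrlin.api import ThresholdLinearModel
        b = small_sim
        m = ThresholdLinearModel.from_bundle(b)
        res = m.fit(method="nr", tol=1e-10)
        sys = res.info["system"]
        T = b.spec.n_traits
        nf = b.records.n_fixed_coef * T
        n_prog = np.bincount(
            np.concatenate([b.pedigree.sire[b.pedigree.sire >= 0],
                            b.pedigree.dam[b.pedigree.dam >= 0]]),
            minlength=b.pedigree.n)
        busy = int(np.argmax(n_prog))
        founders = np.nonzero((b.pedigree.sire < 0) & (n_prog == 0))[0]
        lonely = int(founders[0])
        pv = pev(sys, [nf + busy * T + 3, nf + lonely * T + 3])
        assert pv[0] < pv[1]
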