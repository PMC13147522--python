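"""Working mixed-model-equation blocks, assembly and solvers."""

import numpy as np
import pytest

from thrlin import working
from thrlin.mme import (
    GroupContribution, MMEError, assemble, gradient_contribution,
    pseudo_data, rtilde_inverse, rtilde_matrix, solve,
)
from thrlin.model import ModelSpec, RecordSet, Theta
from thrlin.pedigree import a_inverse, build_S
from thrlin.tmvn import TruncationRegion, tmvn_moments

from conftest import dense_linear_mme, make_spd, random_pedigree


def _spec(R, c, thresholds=None):
    T = R.shape[0]
    if thresholds is None:
        thresholds = [np.array([0.0])] * c
    return ModelSpec(trait_names=[f"t{i}" for i in range(T)], n_categorical=c,
                     thresholds=thresholds, R=R, G0=np.eye(T), fixed_factors=[])


class TestRtildeInverse:
    def test_univariate_reduction(self):
        # c=1: the block matrix with scalar gamma
        R = np.array([[1.0, 0.4, 0.2], [0.4, 1.3, 0.5], [0.2, 0.5, 1.8]])
        spec = _spec(R, c=1)
        gamma = np.array([[0.63]])
        out = rtilde_inverse(gamma, spec)
        r12 = R[:1, 1:]
        R22_inv = np.linalg.inv(R[1:, 1:])
        g = 0.63
        expected = np.block([
            [np.array([[g]]), -g * r12 @ R22_inv],
            [-g * (r12 @ R22_inv).T,
             g * R22_inv @ r12.T @ r12 @ R22_inv + R22_inv],
        ])
        assert np.allclose(out, expected, atol=1e-12)

    def test_inverse_of_block_rtilde(self):
        rng = np.random.default_rng(2)
        R = make_spd(4, rng)
        spec = _spec(R, c=2)
        gamma = make_spd(2, rng, scale=0.3)
        out = rtilde_inverse(gamma, spec)
        Rt = rtilde_matrix(gamma, spec)
        assert np.allclose(out @ Rt, np.eye(4), atol=1e-10)

    def test_block_diagonal_when_r12_zero(self):
        R = np.diag([1.0, 1.2, 0.8, 2.0])
        spec = _spec(R, c=2)
        gamma = np.array([[0.5, 0.1], [0.1, 0.7]])
        out = rtilde_inverse(gamma, spec)
        assert np.allclose(out[:2, :2], gamma)
        assert np.allclose(out[:2, 2:], 0.0)
        assert np.allclose(out[2:, 2:], np.diag([1 / 0.8, 0.5]))

    def test_negative_gamma_rejected(self):
        R = make_spd(3, np.random.default_rng(0))
        spec = _spec(R, c=2)
        with pytest.raises(MMEError, match="negative eigenvalue"):
            rtilde_inverse(np.array([[1.0, 0.0], [0.0, -0.5]]), spec)


class TestPseudoData:
    def test_identity_w_theta_plus_rz_equals_ytilde(self):
        """The defining identity of the pseudo-observations, on random records."""
        rng = np.random.default_rng(7)
        R = make_spd(4, rng)
        spec = _spec(R, c=2)
        for _ in range(5):
            w1theta = rng.normal(size=2)
            w2theta = rng.normal(size=2)
            y2 = rng.normal(size=2)
            resid2 = y2 - w2theta
            sigma = R[:2, :2] - R[:2, 2:] @ np.linalg.inv(R[2:, 2:]) @ R[2:, :2]
            b_mat = R[:2, 2:] @ np.linalg.inv(R[2:, 2:])
            mu = w1theta + b_mat @ resid2
            mom = tmvn_moments(TruncationRegion([0, -np.inf], [np.inf, 0.0]),
                               mu, sigma)
            pr = pseudo_data(mu, y2, resid2, mom.delta, mom.gamma, spec)
            Rt = rtilde_matrix(mom.gamma, spec)
            wtheta = np.concatenate([w1theta, w2theta])
            assert np.allclose(wtheta + Rt @ pr.z, pr.ytilde, atol=1e-10)

    def test_all_continuous_record(self):
        R = make_spd(2, np.random.default_rng(1))
        spec = _spec(R, c=0, thresholds=[])
        y2 = np.array([0.5, -1.0])
        resid2 = np.array([0.2, -0.4])
        pr = pseudo_data(np.zeros(0), y2, resid2, np.zeros(0),
                         np.zeros((0, 0)), spec, cat_obs=np.array([], int))
        assert np.allclose(pr.ytilde, y2)
        assert np.allclose(pr.z, np.linalg.solve(R, resid2))

    def test_univariate_yhat_form(self):
        # c=1: yhat = delta/gamma + W1 theta + r12 R22^-1 (y2 - W2 theta)
        rng = np.random.default_rng(9)
        R = make_spd(3, rng)
        spec = _spec(R, c=1)
        w1theta = 0.4
        resid2 = rng.normal(size=2)
        b_mat = R[:1, 1:] @ np.linalg.inv(R[1:, 1:])
        mu = w1theta + float((b_mat @ resid2)[0])
        sigma = float(R[0, 0] - (b_mat @ R[1:, :1])[0, 0])
        from thrlin.tmvn import univariate_moments
        um = univariate_moments(2, [0.0], mu, sigma)
        pr = pseudo_data(np.array([mu]), resid2 + 1.0, resid2,
                         np.array([um.delta]), np.array([[um.gamma]]), spec)
        assert pr.ytilde[0] == pytest.approx(um.delta / um.gamma + mu, abs=1e-10)


class TestAssemble:
    def _toy_system(self, n=5, T=2, seed=0, duplicate=False):
        rng = np.random.default_rng(seed)
        R = make_spd(T, rng)
        spec = _spec(R, c=0, thresholds=[])
        ped = random_pedigree(n, rng)
        y2 = rng.normal(size=(n, T))
        idx = np.arange(n)
        if duplicate:
            idx = np.concatenate([idx, idx[:1]])
            y2 = np.vstack([y2, y2[:1]])
        rs = RecordSet(animal_index=idx, categories=np.zeros((idx.size, 0), int),
                       y2=y2, X=np.ones((idx.size, 1)), fixed_names=["mu"])
        S = build_S(make_spd(T, rng), a_inverse(ped), T * 1)
        return rs, spec, S

    def test_all_continuous_matches_dense_textbook_mme(self):
        rs, spec, S = self._toy_system()
        th = Theta.zeros(1, S.n_levels, S.n_traits)
        sys = working.build_nr_system(th, rs, spec, S)
        Cd, rd = dense_linear_mme(rs, spec, S)
        assert np.allclose(sys.C.toarray(), Cd, atol=1e-10)
        assert np.allclose(sys.rhs, rd, atol=1e-10)

    def test_duplicated_record_doubles_data_part(self):
        rs1, spec, S = self._toy_system()
        rs2, _, _ = self._toy_system(duplicate=True)
        th = Theta.zeros(1, S.n_levels, S.n_traits)
        C1 = working.build_nr_system(th, rs1, spec, S).C.toarray()
        C2 = working.build_nr_system(th, rs2, spec, S).C.toarray()
        D1 = C1 - S.matrix.toarray()
        D2 = C2 - S.matrix.toarray()
        # the duplicated animal's data contribution doubles, others unchanged
        a0 = S.n_traits * 1 + 0  # first random equation block
        assert np.allclose(D2[a0:a0 + 2, a0:a0 + 2], 2 * D1[a0:a0 + 2, a0:a0 + 2])
        assert np.allclose(D2[a0 + 2:, a0 + 2:], D1[a0 + 2:, a0 + 2:])

    def test_gradient_identity(self, toy_bundle):
        # grad = rhs - C theta at the assembly point
        spec, records, ped = toy_bundle
        S = build_S(spec.G0, a_inverse(ped), records.n_fixed_coef * 3)
        rng = np.random.default_rng(3)
        th = Theta(b=rng.normal(size=(1, 3)) * 0.1,
                   u=rng.normal(size=(3, 3)) * 0.1)
        sys = working.build_nr_system(th, records, spec, S)
        g = sys.gradient(th.vector)
        assert np.allclose(g, sys.rhs - sys.C @ th.vector)


class TestSolve:
    def test_identity_system(self):
        import scipy.sparse as sp
        from thrlin.mme import MMESystem
        r = np.arange(5.0)
        sys = MMESystem(C=sp.eye(5, format="csr"), rhs=r)
        assert np.allclose(solve(sys), r)

    def test_direct_vs_pcg_agree(self):
        rng = np.random.default_rng(11)
        ped = random_pedigree(100, rng)
        rs = RecordSet(animal_index=np.arange(100),
                       categories=np.zeros((100, 0), int),
                       y2=rng.normal(size=(100, 2)), X=np.ones((100, 1)),
                       fixed_names=["mu"])
        spec = _spec(make_spd(2, rng), c=0, thresholds=[])
        S = build_S(make_spd(2, rng), a_inverse(ped), 2)
        th = Theta.zeros(1, 100, 2)
        sys = working.build_nr_system(th, rs, spec, S)
        xd = solve(sys, method="direct")
        xp = solve(sys, method="pcg", tol=1e-13)
        assert np.abs(xd - xp).max() < 1e-8

    def test_pcg_on_singular_consistent_system(self):
        import scipy.sparse as sp
        from thrlin.mme import MMESystem
        # rank-deficient PSD system with consistent rhs
        A = np.array([[2.0, -1.0, -1.0], [-1.0, 2.0, -1.0], [-1.0, -1.0, 2.0]])
        x_true = np.array([1.0, -2.0, 1.0])
        sys = MMESystem(C=sp.csr_matrix(A), rhs=A @ x_true)
        x = solve(sys, method="pcg", tol=1e-12)
        assert np.linalg.norm(A @ x - sys.rhs) < 1e-8
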