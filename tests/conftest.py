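"""Shared fixtures and independent dense oracles for the test suite."""

import numpy as np
import pytest

from thrlin.model import ModelSpec, RecordSet
from thrlin.pedigree import Pedigree
from thrlin import simulate as sim_mod


def make_spd(dim, rng, scale=1.0):
    A = rng.normal(size=(dim, dim))
    return scale * (A @ A.T + dim * np.eye(dim))


@pytest.fixture(scope="session")
def toy_bundle():
    """3 animals (sire, dam, offspring), 2 categorical + 1 continuous trait.

    Small enough for brute-force finite differences of the log posterior.
    """
    ped = Pedigree(sire=np.array([-1, -1, 0]), dam=np.array([-1, -1, 1]),
                   labels=np.array([1, 2, 3]))
    R = np.array([
        [1.0, 0.3, 0.2],
        [0.3, 1.0, 0.25],
        [0.2, 0.25, 1.5],
    ])
    G0 = np.array([
        [0.4, 0.1, 0.15],
        [0.1, 0.5, 0.2],
        [0.15, 0.2, 0.8],
    ])
    spec = ModelSpec(trait_names=["d1", "d2", "w"], n_categorical=2,
                     thresholds=[np.array([0.0]), np.array([0.0, 0.7])],
                     R=R, G0=G0, fixed_factors=[])
    records = RecordSet(
        animal_index=np.array([0, 1, 2]),
        categories=np.array([[2, 1], [1, 3], [2, 2]]),
        y2=np.array([[0.5], [-0.3], [1.1]]),
        X=np.ones((3, 1)),
        fixed_names=["intercept"],
        animal_labels=np.array([1, 2, 3]),
    )
    return spec, records, ped


@pytest.fixture(scope="session")
def small_sim():
    """A 400-animal realization of the 4-trait validation scenario."""
    return sim_mod.make_validation_scenario(scale=400, seed=11, n_generations=4)


@pytest.fixture(scope="session")
def linear_sim():
    """Continuous-traits-only variant (the linear-model limit)."""
    cfg = sim_mod.SimConfig(n_animals=300, n_generations=3, seed=23)
    G2 = cfg.G0[2:, 2:]
    R2 = cfg.R[2:, 2:]
    cfg = sim_mod.SimConfig(
        n_animals=300, n_generations=3, seed=23, G0=G2, R=R2,
        thresholds=(), trait_names=("cont1", "cont2"), n_categorical=0,
        sex_effect=np.array([0.4, 0.5]), gen_trend=np.array([0.1, 0.1]),
    )
    return sim_mod.simulate(cfg)


def dense_linear_mme(data, spec, S):
    """Dense textbook multi-trait MME for fully linear (continuous) data:
    ``C = sum_i W_i' R^-1 W_i + S``, built record by record with explicit
    incidence matrices.  Independent of the sparse assembly code."""
    T = spec.n_traits
    p = data.n_fixed_coef
    n_anim = S.n_levels
    n_eq = T * p + n_anim * T
    C = S.matrix.toarray().copy()
    rhs = np.zeros(n_eq)
    R_inv = np.linalg.inv(spec.R)
    for i in range(data.n_records):
        W = np.zeros((T, n_eq))
        a = data.animal_index[i]
        for t in range(T):
            W[t, t * p:(t + 1) * p] = data.X[i]
            W[t, T * p + a * T + t] = 1.0
        y = data.y2[i]
        C += W.T @ R_inv @ W
        rhs += W.T @ R_inv @ y
    return C, rhs


def random_pedigree(n, rng, founder_frac=0.3):
    """Random valid pedigree with parents preceding offspring."""
    n_found = max(2, int(n * founder_frac))
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    sex = rng.integers(0, 2, size=n)
    sex[:2] = [0, 1]
    for i in range(n_found, n):
        males = np.nonzero(sex[:i] == 0)[0]
        females = np.nonzero(sex[:i] == 1)[0]
        sire[i] = rng.choice(males)
        dam[i] = rng.choice(females)
    return Pedigree(sire=sire, dam=dam, labels=np.arange(1, n + 1))
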