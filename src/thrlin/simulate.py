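"""Synthetic data generator for the validation experiments.

Emulates the validation design of the methods: a 4-trait model (one binary
trait, one 3-category trait, two continuous traits) with sex and generation
as systematic effects and an additive genetic effect over a pedigree
spanning several overlapping generations without directional selection.
Breeding values follow the additive infinitesimal model
(``u ~ N(0, G0 (x) A)``, founders drawn from ``N(0, G0)``, offspring from
the mid-parent mean plus Mendelian sampling); phenotypes add a correlated
residual per animal and categorical traits are discretized through fixed
thresholds on the liability scale.

The default covariance components give moderate heritabilities (0.2-0.4 on
the liability/phenotype scale), nonzero genetic and residual correlations
among all traits and unit residual variances for the categorical traits
(the standard probit identification); all values are plain config fields
and fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ModelSpec, RecordSet
from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "SimBundle",
    "default_spec",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate",
    "make_validation_scenario",
    "biased_variance_scenarios",
]


def _corr_to_cov(var, corr):
    sd = np.sqrt(np.asarray(var, dtype=float))
    return np.asarray(corr, dtype=float) * np.outer(sd, sd)


_DEFAULT_G_VAR = [0.25, 0.40, 0.60, 1.00]
_DEFAULT_G_CORR = [
    [1.0, 0.4, 0.3, 0.2],
    [0.4, 1.0, 0.3, 0.3],
    [0.3, 0.3, 1.0, 0.5],
    [0.2, 0.3, 0.5, 1.0],
]
_DEFAULT_R_VAR = [1.0, 1.0, 1.4, 1.5]
_DEFAULT_R_CORR = [
    [1.0, 0.2, 0.15, 0.1],
    [0.2, 1.0, 0.15, 0.15],
    [0.15, 0.15, 1.0, 0.3],
    [0.1, 0.15, 0.3, 1.0],
]
#: sex effect per trait (female level) and per-generation linear trend
_DEFAULT_SEX_EFFECT = [0.2, -0.2, 0.4, 0.5]
_DEFAULT_GEN_TREND = [0.05, -0.05, 0.10, 0.10]


@dataclass
class SimConfig:
    """Study design: the defaults ARE the validation conditions."""

    n_animals: int = 3000
    n_generations: int = 6
    seed: int = 0
    #: probability that a parent is drawn from two generations back
    overlap_rate: float = 0.2
    G0: np.ndarray = None
    R: np.ndarray = None
    thresholds: tuple = ((0.0,), (0.0, 0.8))
    sex_effect: np.ndarray = None
    gen_trend: np.ndarray = None
    trait_names: tuple = ("binary", "cat3", "cont1", "cont2")
    n_categorical: int = 2

    def __post_init__(self):
        if self.G0 is None:
            self.G0 = _corr_to_cov(_DEFAULT_G_VAR, _DEFAULT_G_CORR)
        if self.R is None:
            self.R = _corr_to_cov(_DEFAULT_R_VAR, _DEFAULT_R_CORR)
        self.G0 = np.asarray(self.G0, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.sex_effect is None:
            self.sex_effect = np.asarray(_DEFAULT_SEX_EFFECT[: self.n_traits])
        if self.gen_trend is None:
            self.gen_trend = np.asarray(_DEFAULT_GEN_TREND[: self.n_traits])

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            trait_names=list(self.trait_names),
            n_categorical=self.n_categorical,
            thresholds=[np.asarray(t, dtype=float) for t in self.thresholds],
            R=self.R, G0=self.G0,
            fixed_factors=["sex", "generation"],
        )


@dataclass
class SimBundle:
    """Simulated data plus the true values behind it (for recovery tests)."""

    config: SimConfig
    spec: ModelSpec
    pedigree: Pedigree
    records: RecordSet
    phenotypes: pd.DataFrame
    true_u: np.ndarray
    true_liabilities: np.ndarray
    generation: np.ndarray
    sex: np.ndarray


def simulate_pedigree(config: SimConfig, rng=None):
    """Overlapping-generation pedigree without selection or selfing.

    Generation 1 holds founders; each later animal draws its sire and dam at
    random from the males/females of the previous generation (or, with
    probability ``overlap_rate``, two generations back).  Returns
    ``(Pedigree, generation, sex)`` with sex coded 1=male, 2=female.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_animals
    n_gen = config.n_generations
    if n_gen < 1:
        raise ValueError("need at least one generation")
    per_gen = np.full(n_gen, n // n_gen)
    per_gen[: n % n_gen] += 1
    generation = np.repeat(np.arange(1, n_gen + 1), per_gen)
    sex = rng.integers(1, 3, size=n)  # 1 male, 2 female
    # guarantee both sexes in every generation used as a mating pool
    starts = np.concatenate(([0], np.cumsum(per_gen)))
    for g in range(n_gen):
        sl = slice(starts[g], starts[g + 1])
        if np.all(sex[sl] == sex[starts[g]]):
            sex[starts[g]] = 3 - sex[starts[g]]
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for g in range(1, n_gen):
        cand_gens = [g - 1] + ([g - 2] if g >= 2 else [])
        pools = {}
        for cg in cand_gens:
            sl = np.arange(starts[cg], starts[cg + 1])
            pools[cg] = (sl[sex[sl] == 1], sl[sex[sl] == 2])
        for i in range(starts[g], starts[g + 1]):
            for which in (0, 1):  # sire then dam
                use_older = (g >= 2) and (rng.random() < config.overlap_rate)
                cg = g - 2 if use_older else g - 1
                pool = pools[cg][which]
                if pool.size == 0:
                    pool = pools[g - 1][which]
                if pool.size == 0:
                    raise ValueError(f"no available {'sire' if which == 0 else 'dam'} "
                                     f"for generation {g + 1}")
                pick = int(pool[rng.integers(pool.size)])
                if which == 0:
                    sire[i] = pick
                else:
                    dam[i] = pick
    ped = Pedigree(sire=sire, dam=dam, labels=np.arange(1, n + 1))
    return ped, generation, sex


def simulate_breeding_values(ped: Pedigree, G0: np.ndarray, seed=None, rng=None) -> np.ndarray:
    """Additive breeding values: founders ``N(0, G0)``, offspring mid-parent
    plus Mendelian sampling ``N(0, G0/2)`` (no-inbreeding form)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    T = G0.shape[0]
    L = np.linalg.cholesky(G0)
    n = ped.n
    u = np.zeros((n, T))
    z = rng.standard_normal((n, T))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            u[i] = L @ z[i]
        else:
            mid = 0.5 * ((u[s] if s >= 0 else 0.0) + (u[d] if d >= 0 else 0.0))
            # one unknown parent: treat it as a random founder contribution
            ms_var = 0.5 if (s >= 0 and d >= 0) else 0.75
            u[i] = mid + np.sqrt(ms_var) * (L @ z[i])
    return u


def simulate_phenotypes(ped: Pedigree, u: np.ndarray, config: SimConfig,
                        generation: np.ndarray, sex: np.ndarray,
                        rng=None):
    """Liabilities/phenotypes = fixed effects + u + residual; categorical
    traits discretized by the thresholds (category k iff t_{k-1} < l <= t_k).

    Returns ``(records, phenotype_frame, liabilities)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = ped.n
    T = config.n_traits
    c = config.n_categorical
    e = rng.multivariate_normal(np.zeros(T), config.R, size=n, method="cholesky")
    fixed = ((sex == 2)[:, None] * config.sex_effect[None, :]
             + (generation - 1)[:, None] * config.gen_trend[None, :])
    y = fixed + u + e
    spec = config.model_spec()
    cats = np.zeros((n, c), dtype=np.int64)
    for j in range(c):
        t = np.asarray(config.thresholds[j], dtype=float)
        cats[:, j] = np.searchsorted(t, y[:, j], side="left") + 1
    df = pd.DataFrame({"animal": ped.labels, "sex": sex, "generation": generation})
    for j, name in enumerate(config.trait_names):
        df[name] = cats[:, j] if j < c else y[:, j]
    records = RecordSet.from_dataframe(df, spec, animal_col="animal", ped=ped)
    return records, df, y


def simulate(config: SimConfig) -> SimBundle:
    """Full pipeline: pedigree, breeding values, phenotypes."""
    rng = np.random.default_rng(config.seed)
    ped, generation, sex = simulate_pedigree(config, rng)
    u = simulate_breeding_values(ped, config.G0, rng=rng)
    records, df, liab = simulate_phenotypes(ped, u, config, generation, sex, rng=rng)
    return SimBundle(config=config, spec=config.model_spec(), pedigree=ped,
                     records=records, phenotypes=df, true_u=u,
                     true_liabilities=liab, generation=generation, sex=sex)


def default_spec() -> ModelSpec:
    return SimConfig().model_spec()


def make_validation_scenario(scale: int = 3000, seed: int = 0,
                        n_generations: int = 6) -> SimBundle:
    """The 4-trait validation scenario at ``scale`` animals."""
    if scale < 100:
        raise ValueError("scale must be at least 100")
    return simulate(SimConfig(n_animals=scale, n_generations=n_generations,
                              seed=seed))


def biased_variance_scenarios(G0: np.ndarray) -> dict:
    """The three mis-specified genetic covariance matrices of the
    sensitivity analysis: additive variances of the two categorical traits
    scaled (a: -20%/+10%, b: +20%/-10%, c: -20%/-20%), all other entries at
    their true values."""
    out = {}
    for name, (f1, f2) in {"a": (0.8, 1.1), "b": (1.2, 0.9), "c": (0.8, 0.8)}.items():
        G = np.array(G0, dtype=float, copy=True)
        G[0, 0] *= f1
        G[1, 1] *= f2
        out[name] = G
    return out
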