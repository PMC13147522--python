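"""Model and data containers for the multi-trait threshold-linear model.

The model on the latent scale is ``[l; y2] = W theta + e`` with
``e ~ N(0, R)`` per animal and ``u ~ N(0, G0 (x) A)``: liabilities ``l`` of
the ``c`` categorical traits are never observed, only the category
``y1 = k`` when ``t_{k-1} < l <= t_k``; the ``m`` continuous traits ``y2``
are observed directly.  Thresholds and the covariance matrices ``R`` and
``G0`` are treated as known.

Conventions fixed here and relied on everywhere else:

* traits are ordered categorical-first (``c`` categorical, then ``m``
  continuous);
* category codes are 1-based (1..K); 0 or NaN marks a missing record;
* the parameter vector ``theta`` stacks fixed effects trait-major
  (``p`` coefficients for trait 0, then trait 1, ...) followed by breeding
  values trait-within-animal;
* the fixed-effect design is full rank: the first factor contributes one
  column per level (cell means), every later factor drops its first level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "ModelSpec",
    "RecordSet",
    "Theta",
    "ConditionalMoments",
    "PatternGroup",
    "validate",
    "conditional_moments",
]


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Trait layout, thresholds and (known) covariance components.

    ``thresholds[j]`` holds the K_j - 1 strictly increasing finite cutpoints
    of categorical trait ``j``; the sentinels t_0 = -inf, t_K = +inf are
    implicit.  ``R`` and ``G0`` are (c+m) x (c+m) with the categorical block
    leading.
    """

    trait_names: list
    n_categorical: int
    thresholds: list
    R: np.ndarray
    G0: np.ndarray
    fixed_factors: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        self.G0 = np.atleast_2d(np.asarray(self.G0, dtype=float))
        self.thresholds = [np.asarray(t, dtype=float) for t in self.thresholds]

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def c(self) -> int:
        return self.n_categorical

    @property
    def m(self) -> int:
        return self.n_traits - self.n_categorical

    def n_categories(self, j: int) -> int:
        return self.thresholds[j].size + 1

    def category_bounds(self, j: int, k) -> tuple:
        """Liability interval (t_{k-1}, t_k] of category ``k`` (1-based, array ok)."""
        t = np.concatenate(([-np.inf], self.thresholds[j], [np.inf]))
        k = np.asarray(k, dtype=int)
        return t[k - 1], t[k]

    def check(self) -> None:
        T = self.n_traits
        if not (0 <= self.c <= T):
            raise ModelError("invalid categorical trait count")
        if len(self.thresholds) != self.c:
            raise ModelError("need one threshold vector per categorical trait")
        for j, t in enumerate(self.thresholds):
            if t.size == 0:
                raise ModelError(f"trait {self.trait_names[j]!r}: at least one threshold required")
            if np.any(~np.isfinite(t)):
                raise ModelError(f"trait {self.trait_names[j]!r}: thresholds must be finite")
            if np.any(np.diff(t) <= 0):
                raise ModelError(
                    f"trait {self.trait_names[j]!r}: thresholds not strictly increasing"
                )
        for name, M in (("R", self.R), ("G0", self.G0)):
            if M.shape != (T, T):
                raise ModelError(f"{name} must be {T}x{T}")
            if not np.allclose(M, M.T, atol=1e-10):
                raise ModelError(f"{name} must be symmetric")
            try:
                np.linalg.cholesky(M)
            except np.linalg.LinAlgError as exc:
                raise ModelError(f"{name} is not positive definite") from exc


@dataclass
class PatternGroup:
    """Records sharing one missingness pattern (complete data: one group)."""

    rows: np.ndarray          # record indices
    cat_obs: np.ndarray       # observed categorical trait indices
    cont_obs: np.ndarray      # observed continuous trait indices (0-based in y2)


@dataclass
class RecordSet:
    """Per-animal phenotypes and fixed-effect incidence.

    ``categories`` is (n, c) of 1-based codes with 0 = missing; ``y2`` is
    (n, m) with NaN = missing; ``X`` is the shared (n, p) full-rank
    fixed-effect design whose coefficients are trait-specific.
    """

    animal_index: np.ndarray
    categories: np.ndarray
    y2: np.ndarray
    X: np.ndarray
    fixed_names: list
    animal_labels: np.ndarray = None

    def __post_init__(self) -> None:
        self.categories = np.atleast_2d(np.asarray(self.categories, dtype=np.int64))
        self.y2 = np.atleast_2d(np.asarray(self.y2, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))

    @property
    def n_records(self) -> int:
        return self.animal_index.size

    @property
    def n_fixed_coef(self) -> int:
        return self.X.shape[1]

    @property
    def cat_observed(self) -> np.ndarray:
        return self.categories > 0

    @property
    def cont_observed(self) -> np.ndarray:
        return ~np.isnan(self.y2)

    def pattern_groups(self) -> list:
        """Group records by joint missingness pattern."""
        patt = np.concatenate([self.cat_observed, self.cont_observed], axis=1)
        keys, inverse = np.unique(patt, axis=0, return_inverse=True)
        groups = []
        c = self.categories.shape[1]
        for g in range(keys.shape[0]):
            rows = np.nonzero(inverse == g)[0]
            cat_obs = np.nonzero(keys[g, :c])[0]
            cont_obs = np.nonzero(keys[g, c:])[0]
            groups.append(PatternGroup(rows=rows, cat_obs=cat_obs, cont_obs=cont_obs))
        return groups

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec, animal_col: str,
                       ped: Pedigree = None, missing=("NA", -999)) -> "RecordSet":
        """Build a record set from a tidy phenotype table.

        Categorical trait columns hold 1-based codes, continuous columns real
        values; entries equal to any value in ``missing`` (or NaN) are masked.
        Factor columns named in ``spec.fixed_factors`` are expanded to the
        full-rank design described in the module docstring.
        """
        df = df.copy()
        with pd.option_context("future.no_silent_downcasting", True):
            df = df.replace(list(missing), np.nan)
        df = df.infer_objects(copy=False)
        labels = df[animal_col].values
        if ped is not None:
            aidx = ped.index_of(labels)
        else:
            uniq, aidx = np.unique(labels, return_inverse=True)
        cat_cols = spec.trait_names[: spec.c]
        cont_cols = spec.trait_names[spec.c:]
        cats = np.column_stack([
            pd.to_numeric(df[tc], errors="coerce").fillna(0).astype(np.int64)
            for tc in cat_cols
        ]) if cat_cols else np.zeros((len(df), 0), dtype=np.int64)
        y2 = np.column_stack([
            pd.to_numeric(df[tc], errors="coerce").astype(float) for tc in cont_cols
        ]) if cont_cols else np.zeros((len(df), 0))
        X, names = _design_matrix(df, spec.fixed_factors)
        return cls(animal_index=np.asarray(aidx, dtype=np.int64), categories=cats,
                   y2=y2, X=X, fixed_names=names, animal_labels=labels)


def _design_matrix(df: pd.DataFrame, factors) -> tuple:
    """Full-rank design: first factor cell-means coded, later factors drop
    their first level.  With no factors, a lone intercept column."""
    if not factors:
        return np.ones((len(df), 1)), ["intercept"]
    cols, names = [], []
    for fi, fac in enumerate(factors):
        levels = np.asarray(sorted(pd.unique(df[fac])))
        start = 0 if fi == 0 else 1
        for lev in levels[start:]:
            cols.append((df[fac].values == lev).astype(float))
            names.append(f"{fac}:{lev}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("fixed-effect design is rank deficient (confounded factors)")
    return X, names


@dataclass
class Theta:
    """Solution vector: fixed effects ``b`` and breeding values ``u``.

    ``b`` is (p, T) (coefficient x trait), ``u`` is (n_animals, T); the
    stacked vector uses the global equation order (fixed trait-major, then
    random trait-within-animal).
    """

    b: np.ndarray
    u: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.b.T.ravel(), self.u.ravel()])

    @classmethod
    def from_vector(cls, vec: np.ndarray, p: int, n_animals: int, n_traits: int) -> "Theta":
        nf = p * n_traits
        b = vec[:nf].reshape(n_traits, p).T
        u = vec[nf:].reshape(n_animals, n_traits)
        return cls(b=b, u=u)

    @classmethod
    def zeros(cls, p: int, n_animals: int, n_traits: int) -> "Theta":
        return cls(b=np.zeros((p, n_traits)), u=np.zeros((n_animals, n_traits)))

    def linear_predictor(self, data: RecordSet) -> np.ndarray:
        """Per-record mean ``W theta`` on all traits, (n, T)."""
        return data.X @ self.b + self.u[data.animal_index]


@dataclass
class ConditionalMoments:
    """Conditional distribution of observed liabilities given observed
    continuous traits, shared by one missingness pattern.

    ``mu`` is (n_g, c_obs) per record; ``sigma = R11 - R12 R22^-1 R21`` and
    ``b_mat = R12 R22^-1`` are pattern constants.
    """

    mu: np.ndarray
    sigma: np.ndarray
    b_mat: np.ndarray
    cat_obs: np.ndarray
    cont_obs: np.ndarray


def pattern_schur(spec: ModelSpec, cat_obs: np.ndarray, cont_obs: np.ndarray):
    """(sigma, b_mat) for one missingness pattern; ``b_mat = R12 R22^-1``."""
    c = spec.c
    R = spec.R
    ic = np.asarray(cat_obs, dtype=int)
    im = np.asarray(cont_obs, dtype=int) + c
    R11 = R[np.ix_(ic, ic)]
    if im.size == 0:
        return R11, np.zeros((ic.size, 0))
    R12 = R[np.ix_(ic, im)]
    R22 = R[np.ix_(im, im)]
    try:
        b_mat = np.linalg.solve(R22.T, R12.T).T
    except np.linalg.LinAlgError as exc:
        raise ModelError("singular observed R22 sub-block") from exc
    sigma = R11 - b_mat @ R12.T
    return sigma, b_mat


def conditional_moments(data: RecordSet, group: PatternGroup, theta: Theta,
                        spec: ModelSpec) -> ConditionalMoments:
    """``mu_i = W1i theta1 + R12 R22^-1 (y2i - W2i theta2)`` and the Schur
    complement ``Sigma_i`` for the records of one missingness pattern."""
    sigma, b_mat = pattern_schur(spec, group.cat_obs, group.cont_obs)
    eta = theta.linear_predictor(data)[group.rows]
    mu = eta[:, group.cat_obs]
    if group.cont_obs.size:
        resid2 = (data.y2[np.ix_(group.rows, group.cont_obs)]
                  - eta[:, spec.c + group.cont_obs])
        mu = mu + resid2 @ b_mat.T
    return ConditionalMoments(mu=mu, sigma=sigma, b_mat=b_mat,
                              cat_obs=group.cat_obs, cont_obs=group.cont_obs)


def validate(spec: ModelSpec, data: RecordSet, ped: Pedigree = None) -> dict:
    """Check thresholds, covariances, codes and id resolution.

    Returns summary counts; raises ``ModelError`` with an actionable message
    on the first violated invariant.
    """
    spec.check()
    n, c = data.categories.shape
    if c != spec.c:
        raise ModelError(f"record set has {c} categorical traits, spec has {spec.c}")
    if data.y2.shape[1] != spec.m:
        raise ModelError(f"record set has {data.y2.shape[1]} continuous traits, spec has {spec.m}")
    for j in range(c):
        K = spec.n_categories(j)
        obs = data.categories[:, j]
        bad = np.nonzero((obs < 0) | (obs > K))[0]
        if bad.size:
            who = (data.animal_labels[bad[0]] if data.animal_labels is not None
                   else int(data.animal_index[bad[0]]))
            raise ModelError(
                f"trait {spec.trait_names[j]!r}: category {obs[bad[0]]} outside 1..{K} "
                f"for animal {who}"
            )
    if ped is not None:
        if data.animal_index.max(initial=-1) >= ped.n or data.animal_index.min(initial=0) < 0:
            raise ModelError("record refers to an animal outside the pedigree")
    n_obs_cat = int(data.cat_observed.sum())
    n_obs_cont = int(data.cont_observed.sum())
    return {
        "n_records": n,
        "n_observed_categorical": n_obs_cat,
        "n_observed_continuous": n_obs_cont,
        "n_patterns": len(data.pattern_groups()),
        "n_fixed_coef": data.n_fixed_coef,
    }
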