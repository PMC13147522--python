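"""Model/results interface for threshold-linear mixed models.

``ThresholdLinearModel`` bundles a model specification, a record set and a
random-effect precision structure; ``fit`` dispatches to the
Newton-Raphson or EM MAP solvers or the Gibbs-sampler benchmark and
returns a results object carrying solutions, diagnostics and a summary
table.

Example
-------
>>> from thrlin import simulate, ThresholdLinearModel
>>> bundle = simulate.make_validation_scenario(scale=500, seed=1)
>>> model = ThresholdLinearModel.from_bundle(bundle)
>>> res = model.fit(method="nr")
>>> res.ebv.shape[1] == 4
True
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import em as em_mod
from . import gibbs as gibbs_mod
from . import nr as nr_mod
from .model import ModelSpec, RecordSet, Theta, validate
from .pedigree import Pedigree, PrecisionStructure, a_inverse, build_S

__all__ = ["ThresholdLinearModel", "MAPResults", "GibbsFitResults"]


class ThresholdLinearModel:
    """Multi-trait threshold-linear mixed model with known covariances.

    Parameters
    ----------
    spec : ModelSpec
        Trait layout, thresholds, residual covariance ``R`` and genetic
        covariance ``G0`` (all treated as known).
    records : RecordSet
        Phenotypes and fixed-effect incidence.
    pedigree : Pedigree, optional
        Pedigree used to build the additive relationship inverse.  Either
        this or ``precision`` must be given.
    precision : PrecisionStructure, optional
        Pre-built random-effect precision (pedigree, genomic or single-step);
        overrides ``pedigree``.
    """

    def __init__(self, spec: ModelSpec, records: RecordSet,
                 pedigree: Pedigree = None,
                 precision: PrecisionStructure = None):
        self.spec = spec
        self.records = records
        self.pedigree = pedigree
        if precision is None:
            if pedigree is None:
                raise ValueError("provide a pedigree or a precision structure")
            precision = build_S(spec.G0, a_inverse(pedigree),
                                records.n_fixed_coef * spec.n_traits)
        self.precision = precision
        self.summary_counts = validate(spec, records, pedigree)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec,
                       pedigree: Pedigree, animal_col: str = "animal"):
        records = RecordSet.from_dataframe(df, spec, animal_col=animal_col,
                                           ped=pedigree)
        return cls(spec, records, pedigree=pedigree)

    @classmethod
    def from_bundle(cls, bundle):
        """Build from a :class:`thrlin.simulate.SimBundle`."""
        return cls(bundle.spec, bundle.records, pedigree=bundle.pedigree)

    def fit(self, method: str = "nr", tol: float = 1e-12, **kwargs):
        """Fit by ``"nr"`` (Newton-Raphson), ``"em"`` (SQUAREM EM) or
        ``"gibbs"`` (posterior means)."""
        if method == "nr":
            theta, info = nr_mod.nr_solve(self.records, self.spec,
                                          self.precision, tol=tol, **kwargs)
            return MAPResults(self, theta, method, info)
        if method == "em":
            theta, info = em_mod.em_solve(self.records, self.spec,
                                          self.precision, tol=tol, **kwargs)
            return MAPResults(self, theta, method, info)
        if method == "gibbs":
            kwargs.pop("tol", None)
            res = gibbs_mod.gibbs_run(self.records, self.spec, self.precision,
                                      **kwargs)
            return GibbsFitResults(self, res)
        raise ValueError(f"unknown method {method!r}")


class _ResultsBase:
    model: ThresholdLinearModel
    theta: Theta

    @property
    def fixed_effects(self) -> pd.DataFrame:
        spec = self.model.spec
        names = self.model.records.fixed_names
        rows = []
        for t, trait in enumerate(spec.trait_names):
            for k, nm in enumerate(names):
                rows.append({"trait": trait, "coefficient": nm,
                             "estimate": self.theta.b[k, t]})
        return pd.DataFrame(rows)

    @property
    def ebv(self) -> pd.DataFrame:
        """Breeding values, one row per animal, one column per trait."""
        spec = self.model.spec
        df = pd.DataFrame(self.theta.u, columns=list(spec.trait_names))
        if self.model.pedigree is not None:
            df.insert(0, "animal", self.model.pedigree.labels)
        return df

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"Threshold-linear mixed model ({spec.c} categorical, "
            f"{spec.m} continuous traits)",
            f"records: {self.model.records.n_records}, "
            f"animals: {self.model.precision.n_levels}, "
            f"fixed coefficients/trait: {self.model.records.n_fixed_coef}",
            self._fit_line(),
            "",
            "Fixed effects:",
            self.fixed_effects.pivot(index="coefficient", columns="trait",
                                     values="estimate").to_string(
                float_format=lambda v: f"{v: .4f}"),
            "",
            "Breeding values (first 5 animals):",
            self.ebv.head().to_string(index=False,
                                      float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


@dataclass
class MAPResults(_ResultsBase):
    """Joint posterior-mode solutions with convergence diagnostics."""

    model: ThresholdLinearModel
    theta: Theta
    method: str
    info: dict

    @property
    def n_rounds(self) -> int:
        return self.info["rounds"]

    @property
    def metric_trace(self):
        return self.info["metric_trace"]

    def pev(self, equations) -> np.ndarray:
        """Prediction error variances for selected equations (NR only)."""
        if "system" not in self.info:
            raise ValueError("PEV requires the converged NR working system")
        return nr_mod.pev(self.info["system"], equations)

    def _fit_line(self) -> str:
        return (f"method: {self.method.upper()}, rounds: {self.n_rounds}, "
                f"final relative residual: {self.info['final_metric']:.2e}")


@dataclass
class GibbsFitResults(_ResultsBase):
    """Posterior means from the single-site Gibbs benchmark."""

    model: ThresholdLinearModel
    raw: gibbs_mod.GibbsResults

    @property
    def theta(self) -> Theta:
        return self.raw.theta_mean

    def _fit_line(self) -> str:
        return (f"method: GIBBS, samples: {self.raw.n_samples} "
                f"(burn-in {self.raw.burn_in}, thin {self.raw.thin}), "
                f"seed {self.raw.seed}")
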