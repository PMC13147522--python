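"""Agreement analytics between solution sets (benchmark vs candidate EBVs).

The validation protocol regresses the Gibbs posterior-mean breeding values
on the MAP breeding values trait by trait; near-perfect agreement (slope
~1, intercept ~0, correlation >0.99) is the expected outcome when the
algebra and the sampler target the same model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AgreementReport", "regress_ebv"]


@dataclass
class AgreementReport:
    """Per-trait OLS of benchmark on candidate plus Pearson correlation."""

    table: pd.DataFrame  # columns: trait, correlation, slope, intercept, n

    def min_correlation(self) -> float:
        return float(self.table["correlation"].min())

    def slope_range(self) -> tuple:
        return (float(self.table["slope"].min()), float(self.table["slope"].max()))

    def max_abs_intercept(self) -> float:
        return float(self.table["intercept"].abs().max())

    def passes(self, min_corr: float = 0.99, slope_lo: float = 0.99,
               slope_hi: float = 1.07, max_intercept: float = 0.01) -> bool:
        lo, hi = self.slope_range()
        return (self.min_correlation() > min_corr and lo >= slope_lo
                and hi <= slope_hi and self.max_abs_intercept() <= max_intercept)

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def regress_ebv(benchmark: np.ndarray, candidate: np.ndarray,
                trait_names=None) -> AgreementReport:
    """OLS of benchmark EBV on candidate EBV per trait.

    ``benchmark`` and ``candidate`` are (n_animals, T) arrays aligned on the
    same animals (callers subset to the common animal set first).
    """
    benchmark = np.atleast_2d(np.asarray(benchmark, dtype=float))
    candidate = np.atleast_2d(np.asarray(candidate, dtype=float))
    if benchmark.shape != candidate.shape:
        raise ValueError("benchmark and candidate EBV arrays must align")
    n, T = benchmark.shape
    if n == 0:
        raise ValueError("no overlapping animals")
    if trait_names is None:
        trait_names = [f"trait{t + 1}" for t in range(T)]
    rows = []
    for t in range(T):
        x, y = candidate[:, t], benchmark[:, t]
        sx = x.std()
        if sx == 0:
            raise ValueError(f"zero-variance candidate EBVs for {trait_names[t]!r}")
        slope = float(np.cov(y, x, ddof=1)[0, 1] / x.var(ddof=1))
        intercept = float(y.mean() - slope * x.mean())
        corr = float(np.corrcoef(y, x)[0, 1])
        rows.append({"trait": trait_names[t], "correlation": corr,
                     "slope": slope, "intercept": intercept, "n": n})
    return AgreementReport(table=pd.DataFrame(rows))
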