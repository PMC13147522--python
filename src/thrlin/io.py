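"""Plain-text readers and writers.

File formats (all delimited text):

* pedigree: ``animal sire dam`` (whitespace or comma; 0 = unknown parent)
* phenotypes: header row naming the animal column, the factor columns and
  one column per trait; categorical traits as 1-based codes; missing values
  as ``NA`` or -999
* model config: INI sections ``[traits]``, ``[thresholds]``,
  ``[covariances]``, ``[effects]``
* solutions: ``effect trait level solution``
"""

from __future__ import annotations

import configparser
import io as _io

import numpy as np
import pandas as pd

from .model import ModelSpec, RecordSet
from .pedigree import Pedigree, read_pedigree, write_pedigree  # re-export

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "read_model_config",
    "write_model_config",
    "write_solutions",
    "read_solutions",
]


def read_phenotypes(path, spec: ModelSpec, ped: Pedigree = None,
                    animal_col: str = "animal") -> RecordSet:
    df = pd.read_csv(path, sep=None, engine="python")
    return RecordSet.from_dataframe(df, spec, animal_col=animal_col, ped=ped)


def _parse_matrix(text: str) -> np.ndarray:
    rows = [r for r in text.strip().splitlines() if r.strip()]
    return np.array([[float(v) for v in r.split()] for r in rows])


def _format_matrix(M: np.ndarray) -> str:
    return "\n" + "\n".join("  " + " ".join(f"{v:.10g}" for v in row) for row in M)


def read_model_config(path) -> ModelSpec:
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    names = cp.get("traits", "names").split()
    c = cp.getint("traits", "n_categorical")
    thresholds = [
        np.array([float(v) for v in cp.get("thresholds", nm).split()])
        for nm in names[:c]
    ]
    R = _parse_matrix(cp.get("covariances", "R"))
    G0 = _parse_matrix(cp.get("covariances", "G0"))
    factors = cp.get("effects", "fixed_factors", fallback="").split()
    spec = ModelSpec(trait_names=names, n_categorical=c, thresholds=thresholds,
                     R=R, G0=G0, fixed_factors=factors)
    spec.check()
    return spec


def write_model_config(spec: ModelSpec, path) -> None:
    cp = configparser.ConfigParser()
    cp["traits"] = {
        "names": " ".join(spec.trait_names),
        "n_categorical": str(spec.c),
    }
    cp["thresholds"] = {
        spec.trait_names[j]: " ".join(f"{t:.10g}" for t in spec.thresholds[j])
        for j in range(spec.c)
    }
    cp["covariances"] = {"R": _format_matrix(spec.R),
                         "G0": _format_matrix(spec.G0)}
    cp["effects"] = {"fixed_factors": " ".join(spec.fixed_factors)}
    with open(path, "w") as fh:
        cp.write(fh)


def write_solutions(theta, spec: ModelSpec, records: RecordSet, path,
                    animal_labels=None, pev=None) -> None:
    """Delimited solutions: fixed coefficients then breeding values."""
    buf = _io.StringIO()
    header = "effect trait level solution"
    if pev is not None:
        header += " se"
    buf.write(header + "\n")
    for t, trait in enumerate(spec.trait_names):
        for k, nm in enumerate(records.fixed_names):
            buf.write(f"fixed {trait} {nm} {theta.b[k, t]:.12g}\n")
    n_anim = theta.u.shape[0]
    labels = animal_labels if animal_labels is not None else np.arange(1, n_anim + 1)
    for a in range(n_anim):
        for t, trait in enumerate(spec.trait_names):
            line = f"animal {trait} {labels[a]} {theta.u[a, t]:.12g}"
            if pev is not None:
                line += f" {np.sqrt(pev[a * len(spec.trait_names) + t]):.6g}"
            buf.write(line + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_solutions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+")
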