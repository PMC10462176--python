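"""Core data containers and plain-text I/O.

The package works on paired single-cell measurements: a sparse cells x genes
count matrix (RNA) and a cells x proteins matrix of surface-protein levels
(ADT).  Matrices travel as matrix-market files plus sidecar name lists, so
every artifact on disk stays human-readable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


@dataclass
class ExpressionMatrix:
    """A cells x features measurement matrix with identifiers.

    Parameters
    ----------
    X
        Sparse (CSR) or dense matrix, one row per cell.
    cell_ids
        Unique cell barcodes / identifiers, length ``X.shape[0]``.
    feature_names
        Unique feature display names, length ``X.shape[1]``.
    """

    X: sp.csr_matrix
    cell_ids: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sp.issparse(self.X):
            self.X = sp.csr_matrix(self.X)
        else:
            self.X = sp.csr_matrix(np.asarray(self.X, dtype=float))
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(self.X.shape[0])]
        if not self.feature_names:
            self.feature_names = [f"feat{j}" for j in range(self.X.shape[1])]
        if len(self.cell_ids) != self.X.shape[0]:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {self.X.shape[0]} rows"
            )
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {self.X.shape[1]} columns"
            )

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def toarray(self) -> np.ndarray:
        return np.asarray(self.X.todense(), dtype=float)


def write_expression(matrix: ExpressionMatrix, out_dir: str, prefix: str) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.cells.txt`` / ``<prefix>.features.txt``."""
    os.makedirs(out_dir, exist_ok=True)
    mmwrite(os.path.join(out_dir, f"{prefix}.mtx"), sp.coo_matrix(matrix.X))
    with open(os.path.join(out_dir, f"{prefix}.cells.txt"), "w") as fh:
        fh.write("\n".join(matrix.cell_ids) + "\n")
    with open(os.path.join(out_dir, f"{prefix}.features.txt"), "w") as fh:
        fh.write("\n".join(matrix.feature_names) + "\n")


def read_expression(out_dir: str, prefix: str) -> ExpressionMatrix:
    X = sp.csr_matrix(mmread(os.path.join(out_dir, f"{prefix}.mtx")))
    with open(os.path.join(out_dir, f"{prefix}.cells.txt")) as fh:
        cells = fh.read().split()
    with open(os.path.join(out_dir, f"{prefix}.features.txt")) as fh:
        feats = fh.read().split()
    return ExpressionMatrix(X, cells, feats)


def write_json(obj, path: str) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
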