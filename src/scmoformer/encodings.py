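"""Graph positional encodings for knowledge-graph nodes.

Two encodings are provided, both computed from a symmetric nonnegative
adjacency:

* Laplacian PE — eigenvectors of the symmetric normalized Laplacian
  ``L = I - D^{-1/2} A D^{-1/2}`` belonging to the k smallest non-trivial
  eigenvalues (one trivial ~0 eigenvalue per connected component is skipped).
* Random-walk PE — return probabilities ``(RW_ii, RW^2_ii, ..., RW^k_ii)``
  of the walk operator ``RW = A D^{-1}``.

Edge weights participate in both A and D by default (confidence scores carry
information); set ``binarize=True`` to use the unweighted topology.  Isolated
nodes receive all-zero encoding rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: eigenvalues below this are treated as the trivial per-component mode
TRIVIAL_EIG_TOL = 1e-8


@dataclass
class PEVectors:
    values: np.ndarray      # n_nodes x k
    kind: str               # laplacian | random_walk | none
    k: int


def _prepare(adjacency: sp.spmatrix | np.ndarray, binarize: bool) -> sp.csr_matrix:
    A = sp.csr_matrix(adjacency, dtype=float)
    if (abs(A - A.T) > 1e-12).nnz:
        raise ValueError("adjacency must be symmetric")
    if A.nnz and A.data.min() < 0:
        raise ValueError("adjacency weights must be nonnegative")
    if binarize:
        A = sp.csr_matrix((np.ones_like(A.data), A.indices, A.indptr),
                          shape=A.shape)
    return A


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Pin each eigenvector's sign: largest-|entry| (first on ties) positive."""
    out = U.copy()
    for j in range(U.shape[1]):
        col = U[:, j]
        i = int(np.argmax(np.abs(np.round(col, 12))))
        if col[i] < 0:
            out[:, j] = -col
    return out


def laplacian_pe(adjacency, k: int, binarize: bool = False) -> PEVectors:
    """Eigenvectors of the normalized Laplacian for the k smallest
    non-trivial eigenvalues; unit-norm columns, deterministic signs.

    Computed on the subgraph of non-isolated nodes (isolated nodes get zero
    rows); if fewer than k non-trivial pairs exist the result is zero-padded.
    """
    A = _prepare(adjacency, binarize)
    n = A.shape[0]
    deg = np.asarray(A.sum(axis=1)).ravel()
    active = np.flatnonzero(deg > 0)
    values = np.zeros((n, k))
    if active.size == 0:
        return PEVectors(values, "laplacian", k)
    Asub = A[np.ix_(active, active)].toarray()
    dsub = deg[active]
    Dinv = 1.0 / np.sqrt(dsub)
    L = np.eye(active.size) - (Dinv[:, None] * Asub) * Dinv[None, :]
    L = 0.5 * (L + L.T)
    eigvals, eigvecs = np.linalg.eigh(L)
    keep = np.flatnonzero(eigvals > TRIVIAL_EIG_TOL)
    if keep.size < k:
        warnings.warn(f"only {keep.size} non-trivial eigenpairs for k={k}; "
                      "padding with zeros", stacklevel=2)
    take = keep[:k]
    U = _fix_signs(eigvecs[:, take])
    norms = np.linalg.norm(U, axis=0)
    norms[norms == 0] = 1.0
    values[np.ix_(active, np.arange(take.size))] = U / norms
    return PEVectors(values, "laplacian", k)


def laplacian_spectrum(adjacency, binarize: bool = False) -> np.ndarray:
    """All eigenvalues of the normalized Laplacian of non-isolated nodes."""
    A = _prepare(adjacency, binarize)
    deg = np.asarray(A.sum(axis=1)).ravel()
    active = np.flatnonzero(deg > 0)
    if active.size == 0:
        return np.zeros(0)
    Asub = A[np.ix_(active, active)].toarray()
    Dinv = 1.0 / np.sqrt(deg[active])
    L = np.eye(active.size) - (Dinv[:, None] * Asub) * Dinv[None, :]
    return np.linalg.eigvalsh(0.5 * (L + L.T))


def random_walk_pe(adjacency, k: int, binarize: bool = False) -> PEVectors:
    """Self-return probabilities after 1..k steps of ``RW = A D^{-1}``."""
    A = _prepare(adjacency, binarize)
    n = A.shape[0]
    deg = np.asarray(A.sum(axis=1)).ravel()
    safe = np.where(deg > 0, deg, 1.0)
    RW = (A @ sp.diags(1.0 / safe)).toarray()
    RW[:, deg == 0] = 0.0
    values = np.zeros((n, k))
    P = np.eye(n)
    for step in range(k):
        P = RW @ P
        values[:, step] = np.diag(P)
    values[deg == 0] = 0.0
    return PEVectors(values, "random_walk", k)


def compute_pe(adjacency, kind: str, k: int, binarize: bool = False) -> PEVectors:
    """Dispatch on ``kind`` in {laplacian, random_walk, none}."""
    if kind == "laplacian":
        return laplacian_pe(adjacency, k, binarize)
    if kind == "random_walk":
        return random_walk_pe(adjacency, k, binarize)
    if kind == "none":
        n = sp.csr_matrix(adjacency).shape[0]
        return PEVectors(np.zeros((n, 0)), "none", 0)
    raise ValueError(f"unknown PE kind {kind!r}")


def inject_pe(features: np.ndarray, pe: PEVectors,
              weight: np.ndarray | None = None,
              bias: np.ndarray | None = None) -> np.ndarray:
    """``features + pe @ weight + bias`` — the learned additive combination.

    With ``kind='none'`` or a zero-initialized projection (the default) this
    is the identity, so PE only perturbs features once training moves the
    projection weights.
    """
    if pe.kind == "none" or pe.values.shape[1] == 0:
        return features
    d = features.shape[1]
    W = np.zeros((pe.values.shape[1], d)) if weight is None else weight
    out = features + pe.values @ W
    if bias is not None:
        out = out + bias
    return out
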