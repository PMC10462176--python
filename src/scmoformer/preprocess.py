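"""Count normalization and node-feature initialization.

Cells enter the model as SVD-reduced coordinates of the library-size
normalized, log-transformed, per-gene centered expression matrix.  Gene
features are the weighted sum of cell features with the normalized counts as
weights; target-modality (protein) features are a seeded index-keyed
embedding table that the model treats as learnable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data import ExpressionMatrix
from .simdata import LOGNORM_SCALE

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Dense cells x genes matrix after normalize -> log1p -> per-gene centering."""

    values: np.ndarray
    scale: float
    gene_means: np.ndarray     # per-gene means removed by centering


@dataclass
class NodeFeatures:
    """Initial embeddings for the three node types."""

    h_cell0: np.ndarray        # Nc x d0
    h_gene0: np.ndarray        # Ng x d0
    h_protein0: np.ndarray     # Np x d_emb (learnable in the model)
    d0: int


def normalize_log_center(counts: ExpressionMatrix | np.ndarray | sp.spmatrix,
                         scale: float = LOGNORM_SCALE) -> NormalizedMatrix:
    """Library-size normalization, ``log1p``, then per-gene mean centering.

    Cells with zero totals give all-zero rows before centering (warned).
    """
    X = counts.X if isinstance(counts, ExpressionMatrix) else counts
    X = np.asarray(X.todense(), dtype=float) if sp.issparse(X) \
        else np.asarray(X, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    n_empty = int(np.sum(totals == 0))
    if n_empty:
        logger.warning("%d cells with zero totals left as zero rows", n_empty)
    safe = np.where(totals > 0, totals, 1.0)
    Y = np.log1p(scale * X / safe)
    means = Y.mean(axis=0)
    out = Y - means
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite values after normalization")
    return NormalizedMatrix(values=out, scale=scale, gene_means=means)


def svd_reduce(normalized: NormalizedMatrix | np.ndarray, d0: int,
               seed: int = 0) -> np.ndarray:
    """Project cells onto the top ``d0`` singular directions, returning U·Sigma.

    A dense LAPACK SVD is used; ``seed`` is accepted for interface stability
    (the decomposition itself is deterministic).
    """
    X = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    if d0 < 1:
        raise ValueError("d0 must be >= 1")
    if d0 > min(X.shape):
        raise ValueError(f"d0={d0} exceeds min matrix dimension {min(X.shape)}")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :d0] * s[:d0]


def svd_components(normalized: NormalizedMatrix | np.ndarray, d0: int
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(U·Sigma, singular values, V) — V enables reconstruction checks."""
    X = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return U[:, :d0] * s[:d0], s[:d0], Vt[:d0].T


def init_gene_features(normalized_rna: NormalizedMatrix | np.ndarray,
                       h_cell0: np.ndarray) -> np.ndarray:
    """Gene features as the normalized-count-weighted sum of cell features."""
    X = normalized_rna.values if isinstance(normalized_rna, NormalizedMatrix) \
        else np.asarray(normalized_rna, dtype=float)
    return X.T @ h_cell0


def init_protein_features(n_proteins: int, d_emb: int, seed: int = 0) -> np.ndarray:
    """Seeded index-keyed embedding table for the target modality."""
    rng = np.random.default_rng(seed)
    return rng.normal(scale=1.0 / np.sqrt(d_emb), size=(n_proteins, d_emb))


def initialize_node_features(rna: ExpressionMatrix, n_proteins: int,
                             d0: int = 128, d_emb: int = 512,
                             seed: int = 0,
                             scale: float = LOGNORM_SCALE) -> NodeFeatures:
    """The full initialization pipeline for the RNA -> protein direction."""
    norm = normalize_log_center(rna, scale=scale)
    d0 = min(d0, min(norm.values.shape))
    h_cell0 = svd_reduce(norm, d0, seed=seed)
    h_gene0 = init_gene_features(norm, h_cell0)
    h_protein0 = init_protein_features(n_proteins, d_emb, seed=seed)
    return NodeFeatures(h_cell0=h_cell0, h_gene0=h_gene0,
                        h_protein0=h_protein0, d0=d0)
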