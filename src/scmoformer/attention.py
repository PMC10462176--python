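"""Scaled dot-product attention and its kernelized linear approximation.

The exact form ``Attn(h) = softmax(Q K^T / sqrt(d)) h`` costs O(n^2) in the
number of rows.  The linear form replaces the softmax kernel
``exp(q.k / sqrt(d))`` by an inner product of positive random features
``phi(x) = exp(W x - |x|^2 / 2) / sqrt(r)`` (W iid standard normal), after
which attention factorizes as ``D^{-1} Q' (K'^T h)`` and is computed in
O(n r d) without ever materializing an n x n matrix.  The two agree exactly
in degenerate cases (n = 1, all keys identical) and converge statistically as
r grows.

These are plain-numpy reference operations; the model's trainable layers
reuse the same formulas through the autodiff engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AttentionInputs:
    Q: np.ndarray      # n x d queries
    K: np.ndarray      # n x d keys
    h: np.ndarray      # n x d input embeddings, used as values

    def __post_init__(self) -> None:
        if not (self.Q.shape == self.K.shape and
                self.Q.shape[0] == self.h.shape[0]):
            raise ValueError(
                f"shape mismatch: Q{self.Q.shape} K{self.K.shape} h{self.h.shape}")

    @property
    def d(self) -> int:
        return self.Q.shape[1]


@dataclass
class KernelFeatures:
    Qp: np.ndarray     # n x r, strictly positive
    Kp: np.ndarray
    r: int
    seed: int


def softmax_attention(inputs: AttentionInputs) -> np.ndarray:
    """Exact row-stochastic attention, numerically stabilized."""
    scores = inputs.Q @ inputs.K.T / np.sqrt(inputs.d)
    scores = scores - scores.max(axis=1, keepdims=True)
    weights = np.exp(scores)
    weights /= weights.sum(axis=1, keepdims=True)
    return weights @ inputs.h


def kernel_feature_map(X: np.ndarray, r: int, seed: int = 0,
                       orthogonal: bool = False) -> np.ndarray:
    """Positive random features: ``exp(x W^T - |x|^2/2) / sqrt(r)``.

    Satisfies ``E[phi(x) . phi(y)] = exp(x . y)``.  With ``orthogonal=True``
    the rows of W are drawn in orthogonalized blocks (norms preserved), which
    reduces estimator variance without changing the expectation.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((r, d))
    if orthogonal:
        W = _orthogonal_blocks(W, rng)
    sq = 0.5 * np.sum(X * X, axis=1, keepdims=True)
    return np.exp(X @ W.T - sq) / np.sqrt(r)


def _orthogonal_blocks(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    r, d = W.shape
    out = np.empty_like(W)
    for start in range(0, r, d):
        block = W[start:start + d]
        G = rng.standard_normal((d, d))
        Qm, _ = np.linalg.qr(G)
        norms = np.linalg.norm(block, axis=1)
        out[start:start + d] = Qm[: block.shape[0]] * norms[:, None]
    return out


def make_kernel_features(Q: np.ndarray, K: np.ndarray, r: int, seed: int = 0,
                         orthogonal: bool = False) -> KernelFeatures:
    """Map queries and keys (scaled by d^{-1/4} so that phi(q).phi(k)
    approximates the softmax kernel exp(q.k/sqrt(d))) with a SHARED draw W."""
    d = Q.shape[1]
    scale = d ** -0.25
    rng_seed = seed
    Qs, Ks = Q * scale, K * scale
    X = np.vstack([Qs, Ks])
    feats = kernel_feature_map(X, r, seed=rng_seed, orthogonal=orthogonal)
    n = Q.shape[0]
    return KernelFeatures(Qp=feats[:n], Kp=feats[n:], r=r, seed=seed)


def linear_attention(feats: KernelFeatures, h: np.ndarray) -> np.ndarray:
    """Factored attention ``D^{-1} Q' (K'^T h)``, O(n r d) time and memory."""
    Qp, Kp = feats.Qp, feats.Kp
    context = Kp.T @ h                      # r x d
    normalizer = Qp @ Kp.sum(axis=0)        # n, equals Q'(K'^T 1)
    bad = np.flatnonzero(normalizer == 0)
    if bad.size:
        raise FloatingPointError(
            f"zero attention normalizer at rows {bad[:5].tolist()}")
    return (Qp @ context) / normalizer[:, None]


def performer_attention(Q: np.ndarray, K: np.ndarray, h: np.ndarray,
                        r: int, seed: int = 0,
                        orthogonal: bool = False) -> np.ndarray:
    """Convenience wrapper: the full linear approximation of
    ``softmax_attention(AttentionInputs(Q, K, h))``."""
    return linear_attention(make_kernel_features(Q, K, r, seed, orthogonal), h)
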