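"""Shared variance stabilization and dimensionality-reduction helpers."""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA


def log_zscore(X: np.ndarray) -> np.ndarray:
    """log1p then per-feature z-scaling (zero-variance features pass as 0)."""
    Y = np.log1p(np.asarray(X, dtype=float))
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (Y - mu) / sd


def fit_pca(X: np.ndarray, n_components: int, seed: int = 0) -> PCA:
    n_components = min(n_components, X.shape[1], max(1, X.shape[0] - 1))
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    pca.fit(X)
    return pca


def l2_normalize(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms = np.where(norms > 0, norms, 1.0)
    return X / norms
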