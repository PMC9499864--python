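"""Pseudotime ordering of pixels along gradual lipid-profile transitions.

Tissue injury produces a continuum of pixel states (healthy tubule ->
maladaptive repair) rather than discrete types.  Pixels are ordered along
that continuum by diffusion pseudotime: a k-nearest-neighbor graph is built
in PCA space, turned into a diffusion operator with an adaptive Gaussian
kernel, and each pixel's pseudotime is its diffusion distance from the
centroid of a user-chosen root (the healthy cluster or a single pixel),
shifted so the minimum is 0.  Correlating pseudotime with isotopologue
enrichment then reveals how labeling changes along the injury axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors

from ._preprocess import fit_pca, log_zscore
from .errors import ValidationError
from .msi_data import PseudoImage, render_pseudoimage

__all__ = [
    "TrajectoryResult",
    "pseudotime",
    "correlate_pseudotime_enrichment",
    "spatial_trajectory_map",
]


@dataclass
class TrajectoryResult:
    pseudotime: np.ndarray  # NaN on pixels unreachable from the root
    root: tuple[str, int]
    provenance: dict = field(default_factory=dict)


def _diffusion_coords(
    pcs: np.ndarray, k: int, n_dcs: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Diffusion-map coordinates and the component labels of the kNN graph."""
    n = pcs.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    sigma = dist[:, -1]  # adaptive bandwidth: distance to the k-th neighbor
    sigma = np.where(sigma > 0, sigma, 1e-12)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    d = dist[:, 1:].ravel()
    w = np.exp(-(d**2) / (sigma[rows] * sigma[cols]))
    W = sparse.csr_matrix((w, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)

    n_comp, comp = connected_components(W, directed=False)
    deg = np.asarray(W.sum(axis=1)).ravel()
    deg = np.where(deg > 0, deg, 1.0)
    Dinv = sparse.diags(1.0 / np.sqrt(deg))
    S = Dinv @ W @ Dinv  # symmetric normalized operator
    n_ev = min(n_dcs + 1, n - 1)
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(n)
    vals, vecs = eigsh(S, k=n_ev, which="LA", v0=v0)
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    psi = Dinv @ vecs  # right eigenvectors of the random-walk operator
    # drop stationary eigenvectors (one per connected component)
    keep = vals < 1 - 1e-10
    vals, psi = vals[keep], psi[:, keep]
    vals = np.clip(vals, None, 1 - 1e-10)
    coords = psi * (vals / (1 - vals))
    return coords, comp


def pseudotime(
    counts: np.ndarray,
    root: tuple[str, int],
    k: int = 30,
    seed: int = 0,
    n_pcs: int = 30,
    n_dcs: int = 10,
    labels: np.ndarray | None = None,
    on_disconnected: str = "error",
) -> TrajectoryResult:
    """Diffusion pseudotime from a root cluster or pixel.

    ``root`` is ``("pixel", index)`` or ``("cluster", label)`` (the latter
    requires ``labels``).  Pixels outside the root's connected component
    raise an error, or become NaN with ``on_disconnected="nan"``.
    """
    counts = np.asarray(counts, dtype=float)
    X = log_zscore(counts)
    pcs = fit_pca(X, n_pcs, seed).transform(X)
    coords, comp = _diffusion_coords(pcs, k, n_dcs, seed)

    kind, ident = root
    if kind == "pixel":
        root_idx = np.array([int(ident)])
    elif kind == "cluster":
        if labels is None:
            raise ValidationError("cluster root requires labels")
        root_idx = np.where(np.asarray(labels) == ident)[0]
    else:
        raise ValidationError("root must be ('pixel', i) or ('cluster', c)")
    if root_idx.size == 0:
        raise ValidationError(f"root {root!r} matches no pixels")

    root_comp = comp[root_idx[0]]
    reachable = comp == root_comp
    if not reachable.all():
        if on_disconnected == "error":
            bad = np.where(~reachable)[0]
            raise ValidationError(
                f"{bad.size} pixels unreachable from the root "
                f"(first few: {bad[:5].tolist()}); pass "
                "on_disconnected='nan' to keep them as NaN"
            )
        if on_disconnected != "nan":
            raise ValidationError("on_disconnected must be 'error' or 'nan'")

    centroid = coords[root_idx].mean(axis=0)
    d = np.linalg.norm(coords - centroid, axis=1)
    d[~reachable] = np.nan
    finite = d[reachable]
    pt = d - finite.min()
    return TrajectoryResult(
        pseudotime=pt,
        root=root,
        provenance=dict(k=k, seed=seed, n_pcs=n_pcs, n_dcs=n_dcs,
                        method="diffusion pseudotime"),
    )


def correlate_pseudotime_enrichment(
    tr: TrajectoryResult, enrichment: np.ndarray, names: list[str] | None = None
) -> pd.DataFrame:
    """Spearman correlation of pseudotime with per-pixel enrichment values.

    ``enrichment`` is per-pixel scalar or (n_pixels, n_isotopologues).
    Ties get average ranks; p-values use the t-approximation.  Fewer than 3
    non-NaN pairs for a column is an error.
    """
    e = np.asarray(enrichment, dtype=float)
    if e.ndim == 1:
        e = e[:, None]
    if e.shape[0] != tr.pseudotime.size:
        raise ValidationError("enrichment rows must match pixels")
    names = names or [f"series_{i}" for i in range(e.shape[1])]
    rows = []
    for j, name in enumerate(names):
        ok = ~np.isnan(tr.pseudotime) & ~np.isnan(e[:, j])
        if ok.sum() < 3:
            raise ValidationError(
                f"fewer than 3 valid pairs for {name!r}"
            )
        r, p = spearmanr(tr.pseudotime[ok], e[ok, j])
        rows.append(dict(name=name, r=float(r), p=float(p), n=int(ok.sum())))
    return pd.DataFrame(rows)


def spatial_trajectory_map(
    tr: TrajectoryResult,
    coords: np.ndarray,
    clip_q: float | None = 0.99,
    pixel_size_um: float = 5.0,
) -> PseudoImage:
    """Render pseudotime back onto the tissue grid (hotspot-clipped)."""
    return render_pseudoimage(
        tr.pseudotime,
        coords,
        clip_q=clip_q,
        value_label="pseudotime",
        pixel_size_um=pixel_size_um,
    )
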