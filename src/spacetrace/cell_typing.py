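"""Cell typing of MSI pixels from lipid profiles.

Pixels are treated like cells in a single-cell workflow: TIC-normalized
intensities are turned into pseudo-counts (x100, floored), variance
stabilized by log1p + per-feature z-scoring, reduced by PCA, and clustered
with Leiden community detection on a shared-nearest-neighbor graph.  A
2-D/3-D UMAP embedding supports visualization; the 3-D embedding maps to RGB
for molecular-histology images.  Immunofluorescence rasters acquired after
MSI can be resampled onto the pixel grid to select stain-positive pixels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from ._preprocess import fit_pca, log_zscore
from .errors import ValidationError
from .msi_data import PixelMatrix

__all__ = [
    "ClusterAssignment",
    "IFOverlay",
    "to_counts",
    "embed",
    "cluster",
    "cluster_k",
    "embedding_to_rgb",
    "register_if",
]


@dataclass
class ClusterAssignment:
    """Per-pixel cluster labels (0-based, ordered by decreasing size)."""

    labels: np.ndarray
    embedding2d: np.ndarray | None = None
    embedding3d: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class IFOverlay:
    """Stain values resampled to the MSI grid plus the selection mask."""

    channel: str
    values: np.ndarray  # per-pixel stain value, thresholded
    mask: np.ndarray  # True where the footprint is fully stain-positive


def to_counts(pm: PixelMatrix | np.ndarray) -> np.ndarray:
    """Pseudo-count transform: floor(100 x TIC-normalized intensity).

    Warns (does not fail) if rows do not sum to ~1, since callers may pass
    subsets of a normalized matrix.
    """
    X = pm.intensities if isinstance(pm, PixelMatrix) else np.asarray(pm, dtype=float)
    sums = X.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        warnings.warn(
            "to_counts input rows do not sum to 1; did you TIC-normalize?",
            stacklevel=2,
        )
    return np.floor(100.0 * X).astype(np.int64)


def embed(
    counts: np.ndarray,
    dims: int = 2,
    seed: int = 0,
    n_neighbors: int = 15,
    n_pcs: int = 30,
) -> np.ndarray:
    """UMAP embedding of pseudo-counts (log1p -> z-scale -> PCA -> UMAP).

    Deterministic for a fixed seed (single-threaded UMAP).
    """
    import umap  # deferred: numba compilation is slow at import time

    counts = np.asarray(counts, dtype=float)
    if dims not in (2, 3):
        raise ValidationError("dims must be 2 or 3")
    if counts.shape[0] < 10 or counts.shape[1] < 2:
        raise ValidationError("need >= 10 pixels and >= 2 features")
    if counts.shape[0] <= n_neighbors:
        raise ValidationError("fewer pixels than n_neighbors")
    X = log_zscore(counts)
    pcs = fit_pca(X, n_pcs, seed).transform(X)
    reducer = umap.UMAP(
        n_components=dims,
        n_neighbors=n_neighbors,
        random_state=seed,
        n_jobs=1,
    )
    return np.asarray(reducer.fit_transform(pcs), dtype=float)


def _snn_graph(pcs: np.ndarray, k: int) -> sparse.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = pcs.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)  # includes self at position 0
    rows = np.repeat(np.arange(n), k + 1)
    A = sparse.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (A @ A.T).tocoo()  # counts of shared neighbors per pair
    union = 2 * (k + 1) - shared.data
    jaccard = shared.data / union
    keep = (shared.row != shared.col) & (jaccard > 1.0 / 15.0)
    return sparse.csr_matrix(
        (jaccard[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )


def cluster(
    counts: np.ndarray,
    resolution: float = 1.0,
    seed: int = 0,
    k: int = 15,
    n_pcs: int = 30,
) -> ClusterAssignment:
    """Leiden clustering on the SNN graph built in PCA space.

    Labels are re-numbered by decreasing cluster size and are deterministic
    for a fixed seed.
    """
    import igraph
    import leidenalg

    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] <= k:
        raise ValidationError("fewer pixels than neighbors parameter")
    X = log_zscore(counts)
    pcs = fit_pca(X, n_pcs, seed).transform(X)
    snn = _snn_graph(pcs, k)
    labels = _leiden_on_graph(snn, resolution, seed)
    return ClusterAssignment(
        labels=labels,
        provenance=dict(resolution=resolution, k=k, n_pcs=n_pcs, seed=seed),
    )


def _leiden_on_graph(
    snn: sparse.csr_matrix, resolution: float, seed: int
) -> np.ndarray:
    import igraph
    import leidenalg

    coo = sparse.triu(snn.maximum(snn.T), k=1).tocoo()
    g = igraph.Graph(
        n=snn.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    raw = np.asarray(part.membership)
    order = np.argsort(-np.bincount(raw), kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    return remap[raw]


def cluster_k(
    counts: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    k: int = 15,
    n_pcs: int = 30,
) -> ClusterAssignment:
    """Leiden clustering consolidated to an exact cluster count.

    Leiden is run at the smallest resolution (geometric ladder) that yields
    at least ``n_clusters`` communities; surplus communities are then merged
    by Ward agglomeration of their PCA-space centroids.  The merge step is
    needed because Leiden never joins communities that are disconnected in
    the SNN graph — discrete pseudo-counts routinely shatter one cell type
    into several graph islands with near-identical centroids.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] <= k:
        raise ValidationError("fewer pixels than neighbors parameter")
    if n_clusters < 1:
        raise ValidationError("n_clusters must be >= 1")
    X = log_zscore(counts)
    pcs = fit_pca(X, n_pcs, seed).transform(X)
    snn = _snn_graph(pcs, k)

    labels, res = None, None
    for res in (0.01, 0.05, 0.2, 1.0, 3.0, 10.0):
        labels = _leiden_on_graph(snn, res, seed)
        if labels.max() + 1 >= n_clusters:
            break
    got = labels.max() + 1
    if got > n_clusters:
        labels = _merge_to_k(labels, pcs, n_clusters)
    return ClusterAssignment(
        labels=labels,
        provenance=dict(
            n_clusters_target=n_clusters,
            resolution=res,
            n_leiden_communities=int(got),
            k=k,
            n_pcs=n_pcs,
            seed=seed,
        ),
    )


def _merge_to_k(labels: np.ndarray, pcs: np.ndarray, n_clusters: int) -> np.ndarray:
    """Ward-merge cluster centroids down to ``n_clusters`` communities."""
    from sklearn.cluster import AgglomerativeClustering

    got = labels.max() + 1
    centroids = np.vstack([pcs[labels == c].mean(axis=0) for c in range(got)])
    agg = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
    merged = agg.fit_predict(centroids)
    out = merged[labels]
    order = np.argsort(-np.bincount(out), kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    return remap[out]


def embedding_to_rgb(embedding3d: np.ndarray) -> np.ndarray:
    """Map a 3-D embedding to 8-bit RGB, one axis per channel.

    Each axis is min-max scaled to 0-255 independently and truncated to
    integer; a degenerate axis (max == min) maps to channel 0.
    """
    e = np.asarray(embedding3d, dtype=float)
    if e.ndim != 2 or e.shape[1] != 3:
        raise ValidationError("embedding must be (n, 3)")
    lo = e.min(axis=0)
    span = e.max(axis=0) - lo
    out = np.zeros_like(e)
    ok = span > 0
    out[:, ok] = (e[:, ok] - lo[ok]) / span[ok] * 255.0
    return np.floor(np.clip(out, 0, 255)).astype(np.uint8)


def register_if(
    stain_image: np.ndarray,
    coords: np.ndarray,
    scale: int,
    channel: str = "",
    cutoff_pct: float = 5.0,
) -> IFOverlay:
    """Resample an aligned 8-bit stain image onto the MSI pixel grid.

    ``scale`` native stain pixels per MSI pixel side (the caller provides
    the affine alignment; this routine only block-resamples).  The stain is
    averaged over each MSI pixel footprint; averaged values below
    ``ceil(cutoff_pct/100 * 255)`` (13 at the default 5% cutoff) are set to
    0.  The selection mask keeps only MSI pixels whose footprint is fully
    stain-positive after thresholding the native image — partially covered
    pixels are excluded.
    """
    stain = np.asarray(stain_image, dtype=float)
    coords = np.asarray(coords, dtype=int)
    if stain.ndim != 2:
        raise ValidationError("stain image must be 2-D grayscale")
    if scale < 1:
        raise ValidationError("scale must be >= 1")
    need_h = (coords[:, 1].max() + 1) * scale
    need_w = (coords[:, 0].max() + 1) * scale
    if stain.shape[0] < need_h or stain.shape[1] < need_w:
        raise ValidationError(
            f"stain image {stain.shape} does not cover the MSI grid "
            f"(needs at least {(need_h, need_w)})"
        )
    thr = math.ceil(cutoff_pct / 100.0 * 255.0)
    native = np.where(stain < thr, 0.0, stain)
    values = np.empty(coords.shape[0])
    mask = np.empty(coords.shape[0], dtype=bool)
    for i, (x, y) in enumerate(coords):
        block_raw = stain[y * scale : (y + 1) * scale, x * scale : (x + 1) * scale]
        block_thr = native[y * scale : (y + 1) * scale, x * scale : (x + 1) * scale]
        v = block_raw.mean()
        values[i] = 0.0 if v < thr else v
        mask[i] = bool(np.all(block_thr > 0))
    return IFOverlay(channel=channel, values=values, mask=mask)
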