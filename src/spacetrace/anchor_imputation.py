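"""Anchor-based transfer of isotope-labeling data between sections.

Measuring a labeling timecourse requires one tissue section per tracer and
timepoint, so no single pixel carries the whole timecourse.  The fix: lipid
profiles are cell-type specific and stable over the 2-hour labeling window,
so pixels with matching lipid profiles in two sections represent the same
cell type.  "Anchors" — mutual nearest neighbor pixel pairs in a shared
lipid projection — link a query section to each labeled reference section,
and the labeled-metabolite intensities of the reference are imputed onto the
query pixels by anchor-weighted k-nearest-neighbor averaging.  Stacking the
imputed blocks yields one dataset in which every control pixel carries the
complete labeling timecourse for every tracer.

The procedure follows the transfer (projection) pathway of the anchor
framework of single-cell data integration: the reference PCA basis is
computed on the reference and the query is projected onto it, rather than a
joint CCA.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from ._preprocess import fit_pca, l2_normalize, log_zscore
from .cell_typing import to_counts
from .errors import AnchorError, ValidationError
from .msi_data import PixelMatrix

__all__ = [
    "AnchorParams",
    "AnchorSet",
    "ImputedDataset",
    "find_anchors",
    "transfer",
    "integrate_timecourse",
]


@dataclass(frozen=True)
class AnchorParams:
    """Tunables of anchor finding and transfer.

    n_pcs: dimensionality of the reference PCA projection.
    k_anchor: neighbors used for the mutual-nearest-neighbor search.
    k_filter: an anchor is kept only if its reference member is among the
        k_filter nearest reference pixels of its query member in the
        (log1p, L2-normalized) feature space.
    k_score: neighborhood size for the shared-neighbor anchor score.
    k_weight: anchors averaged per query pixel during transfer.
    sigma: Gaussian bandwidth of the transfer weights; None = per-pixel
        mean distance to the selected anchors.
    min_similarity: anchors whose members' cosine similarity in the shared
        log1p feature space falls below this are discarded — mutual nearest
        neighbors always exist geometrically, so a rank-based filter alone
        cannot detect datasets that share no cell types.
    """

    n_pcs: int = 30
    k_anchor: int = 5
    k_filter: int = 200
    k_score: int = 30
    k_weight: int = 50
    sigma: float | None = None
    min_similarity: float = 0.5
    seed: int = 0


@dataclass
class AnchorSet:
    """Scored query<->reference pixel pairs plus the shared projection."""

    pairs: np.ndarray  # (m, 2) int: query index, reference index
    scores: np.ndarray  # (m,) in [0, 1]
    query_proj: np.ndarray  # (n_query, n_pcs), L2-normalized
    ref_proj: np.ndarray  # (n_ref, n_pcs), L2-normalized
    params: AnchorParams

    def __post_init__(self) -> None:
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValidationError("pairs must be (m, 2)")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValidationError("scores must lie in [0, 1]")
        if len(np.unique(self.pairs, axis=0)) != len(self.pairs):
            raise ValidationError("duplicate anchor pairs")


@dataclass
class ImputedDataset:
    """Control section plus per-(tracer, timepoint) imputed blocks.

    Each block is a dict entry ``(tracer, timepoint_min) -> (values, ids)``
    with ``values`` aligned to the control pixel order.
    """

    base: PixelMatrix
    blocks: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def block(self, tracer: str, timepoint_min: float) -> np.ndarray:
        return self.blocks[(tracer, float(timepoint_min))][0]

    def block_feature_ids(self, tracer: str, timepoint_min: float) -> list[str]:
        return self.blocks[(tracer, float(timepoint_min))][1]


def find_anchors(
    query: np.ndarray,
    reference: np.ndarray,
    params: AnchorParams = AnchorParams(),
) -> AnchorSet:
    """Find scored anchors between two count matrices on shared features.

    Steps: (1) log1p + z-scale each dataset; (2) fit PCA on the reference
    and project the query onto it; (3) L2-normalize; (4) mutual nearest
    neighbors at ``k_anchor`` become candidate anchors; (5) each anchor is
    scored by the overlap of the ``k_score``-neighborhoods (among reference
    pixels) of its two members, min-max scaled to [0, 1]; (6) anchors whose
    reference member is not among the ``k_filter`` nearest reference pixels
    of the query member in the feature space are dropped.
    """
    query = np.asarray(query, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if query.ndim != 2 or reference.ndim != 2:
        raise ValidationError("query and reference must be 2-D")
    if query.shape[1] != reference.shape[1]:
        raise AnchorError(
            "query and reference must share an identical ordered feature "
            f"set; got {query.shape[1]} vs {reference.shape[1]} features"
        )
    nq, nr = query.shape[0], reference.shape[0]
    k_anchor = min(params.k_anchor, nr, nq)

    Xq = log_zscore(query)
    Xr = log_zscore(reference)
    pca = fit_pca(Xr, params.n_pcs, params.seed)
    Uq = l2_normalize(pca.transform(Xq))
    Ur = l2_normalize(pca.transform(Xr))

    nn_r = NearestNeighbors(n_neighbors=min(max(k_anchor, params.k_score), nr)).fit(Ur)
    nn_q = NearestNeighbors(n_neighbors=min(k_anchor, nq)).fit(Uq)
    _, q2r = nn_r.kneighbors(Uq, n_neighbors=k_anchor)
    _, r2q = nn_q.kneighbors(Ur, n_neighbors=min(k_anchor, nq))

    # mutual nearest neighbors
    r2q_sets = [set(row) for row in r2q]
    pairs = [
        (i, j)
        for i in range(nq)
        for j in q2r[i]
        if i in r2q_sets[j]
    ]
    # exact-duplicate completion: a row identical to its same-index partner
    # is a mutual nearest neighbor at distance zero, but index-order tie
    # breaking in the kNN query can drop it when many rows are duplicated
    # (quantized counts); include it deterministically so self-transfer on
    # identical datasets is exact.
    if query.shape == reference.shape:
        eq = np.where(np.all(query == reference, axis=1))[0]
        pairs.extend((int(i), int(i)) for i in eq)
    if not pairs:
        raise AnchorError(
            "no mutual-nearest-neighbor anchors; relax k_anchor or check "
            "that the datasets overlap"
        )
    pairs = np.unique(np.asarray(pairs, dtype=int), axis=0)

    # shared-neighbor score: overlap of the two members' k_score
    # neighborhoods among reference pixels
    k_score = min(params.k_score, nr)
    _, q_nbrs = nn_r.kneighbors(Uq[pairs[:, 0]], n_neighbors=k_score)
    _, r_nbrs = nn_r.kneighbors(Ur[pairs[:, 1]], n_neighbors=k_score)
    raw = np.array(
        [len(set(a) & set(b)) for a, b in zip(q_nbrs, r_nbrs)], dtype=float
    )
    span = raw.max() - raw.min()
    scores = (raw - raw.min()) / span if span > 0 else np.ones_like(raw)

    # feature-space filter: log1p, L2-normalized (shared scale across the
    # two datasets, unlike the per-dataset z-scoring above)
    k_filter = min(params.k_filter, nr)
    Fq = l2_normalize(np.log1p(query))
    Fr = l2_normalize(np.log1p(reference))
    nn_f = NearestNeighbors(n_neighbors=k_filter).fit(Fr)
    _, f_nbrs = nn_f.kneighbors(Fq[pairs[:, 0]], n_neighbors=k_filter)
    in_rank = np.array(
        [pairs[m, 1] in set(f_nbrs[m]) for m in range(len(pairs))]
    )
    cosine = np.einsum(
        "mf,mf->m", Fq[pairs[:, 0]], Fr[pairs[:, 1]]
    )  # rows are L2-normalized
    keep = in_rank & (cosine >= params.min_similarity)
    pairs, scores = pairs[keep], scores[keep]
    if len(pairs) == 0:
        raise AnchorError(
            "all anchors removed by the feature-space filter (rank or "
            "similarity); the datasets may share no cell types — relax "
            "k_filter/min_similarity only if overlap is certain"
        )
    return AnchorSet(
        pairs=pairs, scores=scores, query_proj=Uq, ref_proj=Ur, params=params
    )


def transfer(
    anchors: AnchorSet,
    reference_values: np.ndarray,
    k_weight: int | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """Impute reference feature values onto every query pixel.

    For each query pixel the ``k_weight`` nearest anchors (distance to the
    anchors' query members in the shared projection) are combined with
    weights ``exp(-d^2 / sigma^2) * score``, normalized to sum 1; the
    imputed value is the weighted mean of the reference members' values.
    Imputed values are therefore convex combinations of reference values.
    """
    reference_values = np.asarray(reference_values, dtype=float)
    single = reference_values.ndim == 1
    if single:
        reference_values = reference_values[:, None]
    if reference_values.shape[0] != anchors.ref_proj.shape[0]:
        raise ValidationError(
            "reference_values rows must match reference pixels"
        )
    m = len(anchors.pairs)
    k_weight = k_weight if k_weight is not None else anchors.params.k_weight
    if k_weight > m:
        warnings.warn(
            f"k_weight={k_weight} exceeds the {m} available anchors; "
            "clamping",
            stacklevel=2,
        )
        k_weight = m
    sigma = sigma if sigma is not None else anchors.params.sigma

    anchor_q = anchors.query_proj[anchors.pairs[:, 0]]
    nn = NearestNeighbors(n_neighbors=k_weight).fit(anchor_q)
    d, idx = nn.kneighbors(anchors.query_proj)

    if k_weight == 1:
        # among equidistant nearest anchors prefer a pixel's self-pair
        # (query member == the pixel itself, distance exactly 0), so that
        # query == reference reproduces the reference exactly
        for a_idx in np.where(anchors.pairs[:, 0] == anchors.pairs[:, 1])[0]:
            i = anchors.pairs[a_idx, 0]
            idx[i, 0] = a_idx
            d[i, 0] = 0.0

    if sigma is None:
        sig = d.mean(axis=1, keepdims=True)  # per-pixel mean anchor distance
    else:
        sig = np.full((d.shape[0], 1), float(sigma))
    sig = np.where(sig > 0, sig, 1.0)
    w = np.exp(-(d**2) / sig**2) * anchors.scores[idx]
    totals = w.sum(axis=1, keepdims=True)
    flat = totals[:, 0] <= 0
    if np.any(flat):  # all selected scores zero: fall back to uniform
        w[flat] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    w /= totals

    ref_members = anchors.pairs[idx, 1]  # (n_query, k_weight)
    out = np.einsum("qk,qkf->qf", w, reference_values[ref_members])
    return out[:, 0] if single else out


def integrate_timecourse(
    control: PixelMatrix,
    labeled: list[PixelMatrix],
    lipid_ids: list[str],
    params: AnchorParams = AnchorParams(),
) -> ImputedDataset:
    """Assemble the imputed timecourse dataset on the control section.

    For each labeled section, anchors are found on the shared lipid features
    and every non-lipid (metabolite/isotopologue) feature is transferred
    onto the control pixels; blocks are keyed by (tracer, timepoint).  The
    control's own measured metabolite features, if present, provide the
    t = 0 block for every tracer.  All matrices must be TIC-normalized.
    """
    ds = ImputedDataset(base=control)
    missing = [f for f in lipid_ids if f not in control.feature_ids]
    if missing:
        raise AnchorError(f"control lacks lipid features {missing[:5]}")
    lipid_idx = [control.feature_index(f) for f in lipid_ids]
    q_counts = to_counts(control.intensities)[:, lipid_idx]
    tracers_seen = set()
    for pm in labeled:
        if pm.tracer == "none":
            raise ValidationError(
                f"labeled section {pm.section_id!r} lacks tracer metadata"
            )
        key = (pm.tracer, float(pm.timepoint_min))
        if key in ds.blocks:
            raise ValidationError(f"duplicate (tracer, timepoint) key {key}")
        missing = [f for f in lipid_ids if f not in pm.feature_ids]
        if missing:
            raise AnchorError(
                f"section {pm.section_id!r} lacks lipid features {missing[:5]}"
            )
        metab_ids = [f for f in pm.feature_ids if f not in set(lipid_ids)]
        r_idx = [pm.feature_index(f) for f in lipid_ids]
        r_counts = to_counts(pm.intensities)[:, r_idx]
        anchors = find_anchors(q_counts, r_counts, params)
        values = transfer(
            anchors, pm.subset_features(metab_ids).intensities
        )
        ds.blocks[key] = (values, metab_ids)
        ds.provenance[str(key)] = dict(
            section_id=pm.section_id,
            n_anchors=len(anchors.pairs),
            params=dataclasses.asdict(params),
        )
        tracers_seen.add(pm.tracer)

    control_metabs = [
        f for f in control.feature_ids if f not in set(lipid_ids)
    ]
    if control_metabs:
        base_vals = control.subset_features(control_metabs).intensities
        for tr in tracers_seen:
            key = (tr, 0.0)
            if key not in ds.blocks:
                ds.blocks[key] = (base_vals.copy(), control_metabs)
                ds.provenance[str(key)] = dict(
                    section_id=control.section_id, source="control t=0"
                )
    return ds
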