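"""Leave-one-factor-out validation of imputation performance.

The protocol: take a section (or pair of sections) where metabolites were
actually measured, withhold the metabolite features from one part (the
query), impute them back from the other part (the reference) via lipid
anchors, and compare imputed against directly measured values with
Spearman's correlation — per pixel and, after clustering the query's pixels
on lipids, per cluster.  Correlations are graded: r > 0.8 very strong,
0.6 < r <= 0.8 strong, 0.4 < r <= 0.6 moderate.  The accuracy of downstream
enrichment calculations is summarized as the mean over clusters and
metabolites of the ratio of imputed to directly measured average fraction
enrichment (labeled isotopologues over total), which should sit near 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .anchor_imputation import AnchorParams, find_anchors, transfer
from .cell_typing import cluster, cluster_k, to_counts
from .errors import ValidationError
from .msi_data import PixelMatrix, tic_normalize

__all__ = [
    "ValidationReport",
    "split_half",
    "grade_correlation",
    "cross_validate",
]


@dataclass
class ValidationReport:
    pixel_r: pd.Series  # per metabolite feature
    cluster_r: pd.Series
    pixel_mean_r: float
    cluster_mean_r: float
    grades: dict
    enrichment_ratio_mean: float | None
    enrichment_ratio_sd: float | None
    n_clusters: int
    n_pixels: int
    n_anchors: int
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = dict(
            pixel_r=self.pixel_r.to_dict(),
            cluster_r=self.cluster_r.to_dict(),
            pixel_mean_r=self.pixel_mean_r,
            cluster_mean_r=self.cluster_mean_r,
            grades=self.grades,
            enrichment_ratio_mean=self.enrichment_ratio_mean,
            enrichment_ratio_sd=self.enrichment_ratio_sd,
            n_clusters=self.n_clusters,
            n_pixels=self.n_pixels,
            n_anchors=self.n_anchors,
            provenance=self.provenance,
        )
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"pixel_r": self.pixel_r, "cluster_r": self.cluster_r}
        )
        df["cluster_grade"] = [grade_correlation(r) for r in df["cluster_r"]]
        return df


def split_half(
    pm: PixelMatrix, axis: str = "vertical"
) -> tuple[PixelMatrix, PixelMatrix]:
    """Bisect a section at the median coordinate.

    ``vertical`` splits on x (left | right), ``horizontal`` on y.  With an
    odd number of grid lines the larger half receives the median line.
    """
    if axis not in ("vertical", "horizontal"):
        raise ValidationError("axis must be 'vertical' or 'horizontal'")
    c = pm.coords[:, 0] if axis == "vertical" else pm.coords[:, 1]
    med = np.median(c)
    left = c < med
    if not left.any() or left.all():
        raise ValidationError(
            "cannot bisect: all pixels share the split coordinate"
        )
    a = pm.subset_pixels(left)
    b = pm.subset_pixels(~left)
    a.section_id = pm.section_id + "_A"
    b.section_id = pm.section_id + "_B"
    return a, b


def grade_correlation(r: float) -> str:
    """Grade a Spearman correlation per the validation rule.

    r > 0.8: very_strong; 0.6 < r <= 0.8: strong; 0.4 < r <= 0.6: moderate;
    anything else (including negative): ungraded.
    """
    if abs(r) > 1:
        raise ValidationError(f"|r| > 1 ({r})")
    if r > 0.8:
        return "very_strong"
    if r > 0.6:
        return "strong"
    if r > 0.4:
        return "moderate"
    return "ungraded"


def _enrichment_per_pixel(
    values: np.ndarray, ids: list[str], features: pd.DataFrame
) -> dict:
    """Per-metabolite labeled-over-total enrichment from intensity columns."""
    idx = {f: i for i, f in enumerate(ids)}
    metab = features[features["kind"] == "metabolite"]
    bases = metab[metab["isotopologue_index"].isna()]
    out = {}
    for _, b in bases.iterrows():
        cc = int(b["carbon_count"])
        fids = [b["feature_id"]] + [
            f
            for f in (f"{b['feature_id']}_M+{n}" for n in range(1, cc + 1))
            if f in idx
        ]
        # need the unlabeled peak and at least one labeled isotopologue
        if b["feature_id"] not in idx or len(fids) < 2:
            continue
        M = values[:, [idx[f] for f in fids]]
        total = M.sum(axis=1)
        labeled = M[:, 1:].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[b["feature_id"]] = np.where(total > 0, labeled / total, np.nan)
    return out


def cross_validate(
    query: PixelMatrix,
    reference: PixelMatrix,
    lipid_ids: list[str],
    metabolite_ids: list[str],
    features: pd.DataFrame | None = None,
    params: AnchorParams = AnchorParams(),
    n_clusters: int | None = None,
    resolution: float = 1.0,
    seed: int = 0,
) -> ValidationReport:
    """Withhold, impute and score the query's metabolite features.

    Both halves are passed with metabolites still present; TIC
    normalization runs on the full feature set of each half, after which
    the query's metabolite columns become the withheld truth.  Anchors are
    found on lipid pseudo-counts, metabolite intensities transferred from
    the reference, and Spearman correlations computed per metabolite
    feature at the pixel level and on cluster means (clusters from Leiden
    on the query's lipids; ``n_clusters`` targets an exact count, otherwise
    ``resolution`` applies).  If ``features`` provides isotopologue
    groupings, the imputed/detected enrichment ratio is also reported.
    """
    qn = tic_normalize(query)
    rn = tic_normalize(reference)
    for fid in lipid_ids + metabolite_ids:
        if fid not in qn.feature_ids or fid not in rn.feature_ids:
            raise ValidationError(f"feature {fid!r} missing from a half")

    truth = qn.subset_features(metabolite_ids).intensities
    # floor the full normalized matrix, then take lipid columns (identical
    # values, but the row-sum sanity check sees the whole spectrum)
    q_lip = [qn.feature_index(f) for f in lipid_ids]
    r_lip = [rn.feature_index(f) for f in lipid_ids]
    q_counts = to_counts(qn.intensities)[:, q_lip]
    r_counts = to_counts(rn.intensities)[:, r_lip]

    anchors = find_anchors(q_counts, r_counts, params)
    imputed = transfer(anchors, rn.subset_features(metabolite_ids).intensities)

    pixel_r = {}
    for j, fid in enumerate(metabolite_ids):
        r, _ = spearmanr(imputed[:, j], truth[:, j])
        pixel_r[fid] = float(r)
    pixel_r = pd.Series(pixel_r)

    if n_clusters is not None:
        ca = cluster_k(q_counts, n_clusters, seed=seed)
    else:
        ca = cluster(q_counts, resolution=resolution, seed=seed)
    labels = ca.labels
    n_cl = ca.n_clusters
    cl_imputed = np.vstack(
        [imputed[labels == c].mean(axis=0) for c in range(n_cl)]
    )
    cl_truth = np.vstack(
        [truth[labels == c].mean(axis=0) for c in range(n_cl)]
    )
    cluster_r = {}
    for j, fid in enumerate(metabolite_ids):
        r, _ = spearmanr(cl_imputed[:, j], cl_truth[:, j])
        cluster_r[fid] = float(r)
    cluster_r = pd.Series(cluster_r)

    ratio_mean = ratio_sd = None
    if features is not None:
        imp_enr = _enrichment_per_pixel(imputed, metabolite_ids, features)
        det_enr = _enrichment_per_pixel(truth, metabolite_ids, features)
        ratios = []
        for met in imp_enr:
            for c in range(n_cl):
                sel = labels == c
                det = np.nanmean(det_enr[met][sel])
                imp = np.nanmean(imp_enr[met][sel])
                if det > 0:
                    ratios.append(imp / det)
        if ratios:
            ratio_mean = float(np.mean(ratios))
            ratio_sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0

    pm_r = float(pixel_r.mean())
    cm_r = float(cluster_r.mean())
    return ValidationReport(
        pixel_r=pixel_r,
        cluster_r=cluster_r,
        pixel_mean_r=pm_r,
        cluster_mean_r=cm_r,
        grades=dict(
            pixel=grade_correlation(pm_r), cluster=grade_correlation(cm_r)
        ),
        enrichment_ratio_mean=ratio_mean,
        enrichment_ratio_sd=ratio_sd,
        n_clusters=n_cl,
        n_pixels=qn.n_pixels,
        n_anchors=len(anchors.pairs),
        provenance=dict(
            seed=seed,
            n_clusters_target=n_clusters,
            resolution=resolution,
            anchor_params=params.__dict__,
        ),
    )
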