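"""Dynamic-metabolism quantities from the imputed labeling timecourse.

For every pixel, metabolite and tracer the imputed isotopologue intensities
M+0..M+n are corrected for natural 13C abundance and converted to fraction
enrichment (each isotopologue over the summed metabolite abundance in that
pixel).  Timecourses are summarized as the trapezoid area under the
enrichment-versus-time curve divided by total time ("AUC normalized to
total time"), a time-averaged labeling measure robust to the non-steady
state of a 2-hour incubation.  Carbon contributions of different nutrients
to a downstream metabolite (e.g. glutamate via M+2/M+3/M+5) use the
fractional-contribution convention sum(n * f_n) / C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .anchor_imputation import ImputedDataset
from .constants import P_C13
from .errors import ValidationError
from .isotope_correction import correct_matrix, correction_matrix

__all__ = [
    "EnrichmentTensor",
    "fraction_enrichment",
    "auc_mean_enrichment",
    "carbon_contribution",
    "TRACER_GLUTAMATE_ISOTOPOLOGUES",
    "compute_enrichment",
    "summarize_by_cluster",
    "paired_cluster_test",
]

#: Glutamate isotopologues attributable to each tracer after one turn of
#: glycolysis/TCA: glucose labels M+2 (PDH) and M+3 (pyruvate carboxylase
#: route), glutamine labels M+5 directly and M+3 after one oxidative turn,
#: linoleate contributes M+2 via acetyl-CoA.
TRACER_GLUTAMATE_ISOTOPOLOGUES: dict[str, tuple[int, ...]] = {
    "glc13": (2, 3),
    "gln13": (3, 5),
    "lin13": (2,),
}


@dataclass
class EnrichmentTensor:
    """Fraction enrichment on axes pixel x metabolite x isotopologue x
    timepoint x tracer (NaN where a combination was not measured or the
    metabolite total was 0)."""

    data: xr.DataArray

    @property
    def metabolites(self) -> list[str]:
        return [str(m) for m in self.data.coords["metabolite"].values]

    def series(
        self, metabolite: str, isotopologue: int, tracer: str
    ) -> np.ndarray:
        """(n_pixels, n_timepoints) slice for one isotopologue/tracer."""
        return (
            self.data.sel(
                metabolite=metabolite, isotopologue=isotopologue, tracer=tracer
            )
            .transpose("pixel", "timepoint")
            .values
        )

    def timepoints(self, tracer: str) -> np.ndarray:
        sl = self.data.sel(tracer=tracer)
        present = ~np.isnan(sl).all(dim=["pixel", "metabolite", "isotopologue"])
        return np.sort(sl.coords["timepoint"].values[present.values])


def fraction_enrichment(intensities: np.ndarray) -> np.ndarray:
    """Isotopologue fractions: each intensity over the metabolite total.

    Accepts a single M+0..M+n vector or rows of pixels.  An all-zero vector
    yields NaN fractions.  Negative input is an error (correct for natural
    abundance first; the corrector is non-negative by construction).
    """
    x = np.asarray(intensities, dtype=float)
    if np.any(x < 0):
        raise ValidationError("negative intensities; correct/clip first")
    total = x.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, x / np.where(total > 0, total, 1.0), np.nan)
    return out


def auc_mean_enrichment(
    series: np.ndarray, timepoints_min: np.ndarray
) -> float | np.ndarray:
    """Trapezoid AUC of enrichment over time, divided by total time.

    ``series`` may be 1-D (one timecourse) or 2-D with timepoints on the
    last axis.  Timepoints must be strictly increasing and start at 0.
    NaN anywhere in a timecourse propagates to its result.
    """
    t = np.asarray(timepoints_min, dtype=float)
    y = np.asarray(series, dtype=float)
    if t.size < 2:
        raise ValidationError("need at least 2 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("timepoints must be strictly increasing")
    if t[0] != 0:
        raise ValidationError("timecourse must start at t = 0")
    if y.shape[-1] != t.size:
        raise ValidationError("series length must match timepoints")
    area = np.trapezoid(y, t, axis=-1)
    return area / (t[-1] - t[0])


def carbon_contribution(
    fractions: np.ndarray,
    isotopologues: tuple[int, ...],
    n_carbons: int,
    convention: str = "fractional",
) -> float | np.ndarray:
    """Direct carbon contribution of one nutrient to a metabolite.

    ``fractions`` indexes fraction enrichment by isotopologue (position n =
    M+n); ``isotopologues`` lists the tracer-attributable n values.  The
    default convention is sum(n * f_n) / n_carbons (fraction of the
    metabolite's carbon atoms sourced from the nutrient); ``convention=
    'sum'`` returns the plain sum of the listed fractions.
    """
    f = np.asarray(fractions, dtype=float)
    for n in isotopologues:
        if n > n_carbons:
            raise ValidationError(
                f"isotopologue M+{n} exceeds carbon count {n_carbons}"
            )
    if convention == "fractional":
        return sum(n * f[..., n] for n in isotopologues) / n_carbons
    if convention == "sum":
        return sum(f[..., n] for n in isotopologues)
    raise ValidationError(f"unknown convention {convention!r}")


def compute_enrichment(
    imputed: ImputedDataset,
    features: pd.DataFrame,
    correct_na: bool = True,
    p: float = P_C13,
) -> EnrichmentTensor:
    """Build the enrichment tensor from an imputed timecourse dataset.

    For each (tracer, timepoint) block and base metabolite the M+0..M+n
    columns are gathered, optionally natural-abundance corrected per pixel,
    and converted to fraction enrichment.
    """
    metab = features[features["kind"] == "metabolite"]
    bases = metab[metab["isotopologue_index"].isna()]
    keys = sorted(imputed.blocks)
    tracers = sorted({k[0] for k in keys})
    tps = sorted({k[1] for k in keys})
    max_c = int(bases["carbon_count"].max())
    n_pixels = imputed.base.n_pixels

    shape = (n_pixels, len(bases), max_c + 1, len(tps), len(tracers))
    arr = np.full(shape, np.nan)
    cms = {}
    for bi, (_, b) in enumerate(bases.iterrows()):
        cc = int(b["carbon_count"])
        fids = [b["feature_id"]] + [
            f"{b['feature_id']}_M+{n}" for n in range(1, cc + 1)
        ]
        if correct_na and cc not in cms:
            cms[cc] = correction_matrix(cc, p)
        for (tracer, tp), (values, ids) in imputed.blocks.items():
            idx = {f: i for i, f in enumerate(ids)}
            if not all(f in idx for f in fids):
                continue
            M = values[:, [idx[f] for f in fids]]
            if correct_na:
                M = correct_matrix(M, cms[cc])
            fr = fraction_enrichment(M)
            arr[:, bi, : cc + 1, tps.index(tp), tracers.index(tracer)] = fr
    da = xr.DataArray(
        arr,
        dims=("pixel", "metabolite", "isotopologue", "timepoint", "tracer"),
        coords=dict(
            pixel=np.arange(n_pixels),
            metabolite=list(bases["feature_id"]),
            isotopologue=np.arange(max_c + 1),
            timepoint=tps,
            tracer=tracers,
        ),
    )
    return EnrichmentTensor(data=da)


def summarize_by_cluster(
    tensor: EnrichmentTensor,
    labels: np.ndarray,
    min_pixels: int = 1,
) -> pd.DataFrame:
    """Per-cluster mean +/- s.d. of AUC-normalized enrichment.

    The AUC over the tracer's timecourse is computed per pixel, then
    averaged within clusters (NaN pixels excluded).  Returns a tidy frame
    ``cluster, metabolite, isotopologue, tracer, mean_auc_enrichment, sd,
    n_pixels``.
    """
    labels = np.asarray(labels)
    if labels.size != tensor.data.sizes["pixel"]:
        raise ValidationError("labels must cover the tensor's pixels")
    rows = []
    for tracer in [str(t) for t in tensor.data.coords["tracer"].values]:
        tps = tensor.timepoints(tracer)
        if tps.size < 2:
            continue
        for met in tensor.metabolites:
            cc_slice = tensor.data.sel(metabolite=met, tracer=tracer)
            for iso in cc_slice.coords["isotopologue"].values:
                series = (
                    cc_slice.sel(isotopologue=iso, timepoint=tps)
                    .transpose("pixel", "timepoint")
                    .values
                )
                if np.isnan(series).all():
                    continue
                auc = auc_mean_enrichment(series, tps)
                for cl in np.unique(labels):
                    vals = auc[labels == cl]
                    vals = vals[~np.isnan(vals)]
                    if vals.size < min_pixels:
                        warnings.warn(
                            f"cluster {cl} empty for {met} M+{iso} "
                            f"({tracer}); omitted",
                            stacklevel=2,
                        )
                        continue
                    rows.append(
                        dict(
                            cluster=int(cl),
                            metabolite=met,
                            isotopologue=int(iso),
                            tracer=tracer,
                            mean_auc_enrichment=float(vals.mean()),
                            sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                            n_pixels=int(vals.size),
                        )
                    )
    return pd.DataFrame(rows)


def paired_cluster_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired two-tailed t-test between matched replicate summaries."""
    res = stats.ttest_rel(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)
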