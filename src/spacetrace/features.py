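"""Feature annotation: m/z matching and 13C-isotopologue assignment.

The feature table is a pandas DataFrame with columns

``feature_id, mz, kind, name, carbon_count, base_metabolite_id,
isotopologue_index``

where ``kind`` is ``lipid`` or ``metabolite``; ``carbon_count`` and the
isotopologue columns are only set on metabolite rows.  An ``M+n``
isotopologue of a base metabolite sits ``n * 1.003355`` Da above the base
peak.  ppm errors are computed relative to the reference m/z (database
convention).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DELTA_C13
from .errors import ValidationError
from .msi_data import PixelMatrix

__all__ = [
    "FEATURE_COLUMNS",
    "make_feature_table",
    "read_feature_table",
    "validate_feature_table",
    "match_mz",
    "assign_isotopologues",
    "detect_labeled_features",
]

FEATURE_COLUMNS = [
    "feature_id",
    "mz",
    "kind",
    "name",
    "carbon_count",
    "base_metabolite_id",
    "isotopologue_index",
]


def make_feature_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Build a feature table from row dicts, filling optional columns."""
    df = pd.DataFrame(list(rows))
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            df[col] = None
    df = df[FEATURE_COLUMNS]
    validate_feature_table(df)
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a reference table TSV (``name, mz, kind, carbon_count`` at
    minimum) into the canonical feature-table layout."""
    df = pd.read_csv(path, sep="\t")
    if "feature_id" not in df.columns:
        df["feature_id"] = df["name"]
    return make_feature_table(df.to_dict("records"))


def validate_feature_table(df: pd.DataFrame) -> None:
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValidationError(f"duplicate feature_id {dup!r}")
    if (df["mz"].dropna() <= 0).any():
        raise ValidationError("mz must be positive")
    iso = df.dropna(subset=["isotopologue_index"])
    if len(iso):
        base_carbons = df.set_index("feature_id")["carbon_count"]
        for _, row in iso.iterrows():
            base = row["base_metabolite_id"]
            if base is None or base not in base_carbons.index:
                raise ValidationError(
                    f"isotopologue {row['feature_id']!r} names unknown base "
                    f"{base!r}"
                )
            cc = base_carbons[base]
            if pd.notna(cc) and row["isotopologue_index"] > cc:
                raise ValidationError(
                    f"isotopologue index {row['isotopologue_index']} exceeds "
                    f"carbon count {cc} of {base!r}"
                )


def match_mz(
    observed_mz: Sequence[float],
    reference: Sequence[tuple[float, str]],
    tol_ppm: float,
) -> pd.DataFrame:
    """Match observed m/z values against a reference list.

    Every (observed, reference) pair with ``|delta|/ref_mz * 1e6 < tol_ppm``
    is reported; ties for one observed value are ordered by ascending ppm
    error.  Returns a DataFrame ``observed_index, observed_mz,
    reference_index, reference_mz, reference_name, ppm_error``.
    """
    if tol_ppm <= 0:
        raise ValidationError("tol_ppm must be positive")
    obs = np.asarray(observed_mz, dtype=float)
    ref_mz = np.array([r[0] for r in reference], dtype=float)
    ref_name = [r[1] for r in reference]
    out = []
    for i, m in enumerate(obs):
        ppm = np.abs(m - ref_mz) / ref_mz * 1e6
        hits = np.where(ppm < tol_ppm)[0]
        for j in hits[np.argsort(ppm[hits])]:
            out.append(
                dict(
                    observed_index=i,
                    observed_mz=m,
                    reference_index=int(j),
                    reference_mz=ref_mz[j],
                    reference_name=ref_name[j],
                    ppm_error=ppm[j],
                )
            )
    return pd.DataFrame(
        out,
        columns=[
            "observed_index",
            "observed_mz",
            "reference_index",
            "reference_mz",
            "reference_name",
            "ppm_error",
        ],
    )


def assign_isotopologues(
    base: pd.DataFrame, max_n: int | None = None
) -> pd.DataFrame:
    """Emit expected M+1..M+n isotopologue rows for each base metabolite.

    Expected m/z is ``base_mz + n * 1.003355``.  ``max_n`` defaults to each
    base's carbon count and may not exceed it.
    """
    rows = []
    for _, b in base.iterrows():
        cc = b.get("carbon_count")
        if pd.isna(cc):
            raise ValidationError(
                f"base {b['feature_id']!r} lacks carbon_count"
            )
        cc = int(cc)
        top = cc if max_n is None else int(max_n)
        if top > cc:
            raise ValidationError(
                f"max_n={top} exceeds carbon count {cc} of "
                f"{b['feature_id']!r}"
            )
        for n in range(1, top + 1):
            rows.append(
                dict(
                    feature_id=f"{b['feature_id']}_M+{n}",
                    mz=b["mz"] + n * DELTA_C13,
                    kind="metabolite",
                    name=f"{b.get('name') or b['feature_id']} M+{n}",
                    carbon_count=cc,
                    base_metabolite_id=b["feature_id"],
                    isotopologue_index=n,
                )
            )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def detect_labeled_features(
    control: PixelMatrix,
    labeled: PixelMatrix,
    candidates: Sequence[str],
    min_ratio: float = 3.0,
) -> pd.Series:
    """Flag candidate features whose mean intensity in the labeled section
    is at least ``min_ratio`` times the control mean.

    Mirrors selecting labeled peaks by comparing control and labeling
    spectra.  A candidate absent from either matrix is an error.
    """
    flags = {}
    for fid in candidates:
        if fid not in control.feature_ids or fid not in labeled.feature_ids:
            raise ValidationError(f"candidate {fid!r} absent from a matrix")
        c = control.intensities[:, control.feature_index(fid)].mean()
        l = labeled.intensities[:, labeled.feature_index(fid)].mean()
        flags[fid] = bool(l >= min_ratio * c) if c > 0 else bool(l > 0)
    return pd.Series(flags, name="labeled")
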