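"""Pixel-level MSI data model, I/O, normalization and pseudoimage rendering.

A :class:`PixelMatrix` holds the peak-picked, per-pixel intensity table of one
tissue section together with its integer grid coordinates and acquisition
metadata (tracer, labeling timepoint, pixel size).  The on-disk format is a
plain TSV: columns ``section_id, x, y`` followed by one column per feature id.
An imzML reader producing the same container is provided for instrument
exports; peaks are binned to a caller-supplied feature list by ppm tolerance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import TRACERS
from .errors import FormatError, ValidationError

__all__ = [
    "PixelMatrix",
    "PseudoImage",
    "read_pixel_matrix",
    "write_pixel_matrix",
    "read_imzml",
    "tic_normalize",
    "hotspot_clip",
    "render_pseudoimage",
    "save_pseudoimage",
]

_COORD_COLUMNS = ("section_id", "x", "y")


@dataclass
class PixelMatrix:
    """Peak intensities of one section: pixels x features plus grid coords.

    Coordinates are 0-based integer grid positions ``(x=column, y=row)`` with
    the origin at the top-left of the measured area.
    """

    section_id: str
    coords: np.ndarray  # (n_pixels, 2) int, columns (x, y)
    intensities: np.ndarray  # (n_pixels, n_features) float, >= 0
    feature_ids: list[str]
    tracer: str = "none"
    timepoint_min: float = 0.0
    group: str = ""
    pixel_size_um: float = 5.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.feature_ids = list(self.feature_ids)
        if self.tracer not in TRACERS:
            raise ValidationError(
                f"unknown tracer {self.tracer!r}; expected one of {TRACERS}"
            )
        if self.timepoint_min < 0:
            raise ValidationError("timepoint_min must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be an (n, 2) array")
        if self.intensities.ndim != 2:
            raise ValidationError("intensities must be 2-D")
        if self.coords.shape[0] != self.intensities.shape[0]:
            raise ValidationError(
                "coordinate rows and intensity rows differ: "
                f"{self.coords.shape[0]} vs {self.intensities.shape[0]}"
            )
        if self.intensities.shape[1] != len(self.feature_ids):
            raise ValidationError(
                "feature_ids length does not match intensity columns"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("feature_ids must be unique")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")
        if np.any(self.intensities < 0):
            i, j = np.argwhere(self.intensities < 0)[0]
            raise ValidationError(
                f"negative intensity at pixel (x={self.coords[i, 0]}, "
                f"y={self.coords[i, 1]}), feature {self.feature_ids[j]!r}"
            )
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != self.coords.shape[0]:
            # identify one duplicate for the error message
            seen: set[tuple[int, int]] = set()
            for x, y in map(tuple, self.coords):
                if (x, y) in seen:
                    raise ValidationError(f"duplicate coordinate ({x}, {y})")
                seen.add((x, y))

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None

    def subset_features(self, ids: Sequence[str]) -> "PixelMatrix":
        """Return a copy restricted to ``ids`` (in the given order)."""
        idx = [self.feature_index(f) for f in ids]
        return dataclasses.replace(
            self, intensities=self.intensities[:, idx], feature_ids=list(ids)
        )

    def subset_pixels(self, mask: np.ndarray) -> "PixelMatrix":
        """Return a copy restricted to pixels where ``mask`` is True."""
        mask = np.asarray(mask)
        return dataclasses.replace(
            self, coords=self.coords[mask], intensities=self.intensities[mask]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.feature_ids)
        df.insert(0, "y", self.coords[:, 1])
        df.insert(0, "x", self.coords[:, 0])
        df.insert(0, "section_id", self.section_id)
        return df


@dataclass
class PseudoImage:
    """Raster rendering of a per-pixel value at the original coordinates.

    ``raster`` is indexed ``[row, col]`` (= ``[y, x]`` relative to
    ``extent``); a third axis of length 3 carries RGB channels.  Cells with
    no measurement hold NaN (scalar) or black (RGB).
    """

    raster: np.ndarray
    extent: tuple[int, int, int, int]  # (xmin, xmax, ymin, ymax), inclusive
    value_label: str = ""
    pixel_size_um: float = 5.0


def read_pixel_matrix(
    path: str | Path,
    *,
    tracer: str = "none",
    timepoint_min: float = 0.0,
    group: str = "",
    pixel_size_um: float = 5.0,
) -> PixelMatrix:
    """Read the TSV pixel-matrix dialect.

    The header must start with ``section_id, x, y``; every further column is
    a feature id.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"section_id": str})
    missing = [c for c in _COORD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing coordinate column(s) {missing}")
    feature_ids = [c for c in df.columns if c not in _COORD_COLUMNS]
    if not feature_ids:
        raise FormatError(f"{path}: no feature columns")
    sections = df["section_id"].unique()
    if len(sections) != 1:
        raise FormatError(
            f"{path}: expected a single section, found {list(sections)}"
        )
    intens = df[feature_ids].to_numpy(dtype=float)
    if np.any(intens < 0):
        i, j = np.argwhere(intens < 0)[0]
        raise ValidationError(
            f"{path}: negative intensity at row {i}, "
            f"feature {feature_ids[j]!r}"
        )
    return PixelMatrix(
        section_id=str(sections[0]),
        coords=df[["x", "y"]].to_numpy(dtype=int),
        intensities=intens,
        feature_ids=feature_ids,
        tracer=tracer,
        timepoint_min=timepoint_min,
        group=group,
        pixel_size_um=pixel_size_um,
    )


def write_pixel_matrix(pm: PixelMatrix, path: str | Path) -> None:
    """Write ``pm`` in the TSV dialect read by :func:`read_pixel_matrix`."""
    pm.to_frame().to_csv(path, sep="\t", index=False)


def read_imzml(
    path: str | Path,
    feature_mzs: Sequence[float],
    *,
    feature_ids: Sequence[str] | None = None,
    tol_ppm: float = 5.0,
    section_id: str | None = None,
    **metadata,
) -> PixelMatrix:
    """Read a (continuous or processed mode) imzML file into a PixelMatrix.

    Centroided peaks are binned to ``feature_mzs``: each spectrum peak is
    assigned to the closest feature m/z within ``tol_ppm`` and intensities
    falling into the same bin are summed.  imzML coordinates are 1-based;
    they are shifted to the package's 0-based convention.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    feature_mzs = np.asarray(feature_mzs, dtype=float)
    order = np.argsort(feature_mzs)
    sorted_mz = feature_mzs[order]
    if feature_ids is None:
        feature_ids = [f"mz_{m:.4f}" for m in feature_mzs]
    parser = ImzMLParser(str(path))
    n = len(parser.coordinates)
    coords = np.zeros((n, 2), dtype=int)
    intens = np.zeros((n, feature_mzs.size), dtype=float)
    for i, (cx, cy, *_rest) in enumerate(parser.coordinates):
        coords[i] = (cx - 1, cy - 1)
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=float)
        ints = np.asarray(ints, dtype=float)
        if mzs.size == 0:
            continue
        pos = np.searchsorted(sorted_mz, mzs)
        pos = np.clip(pos, 1, sorted_mz.size - 1) if sorted_mz.size > 1 else np.zeros_like(pos)
        left = sorted_mz[np.maximum(pos - 1, 0)]
        right = sorted_mz[np.minimum(pos, sorted_mz.size - 1)]
        nearest = np.where(np.abs(mzs - left) <= np.abs(mzs - right), np.maximum(pos - 1, 0), pos)
        target = sorted_mz[nearest]
        ppm = np.abs(mzs - target) / target * 1e6
        ok = ppm < tol_ppm
        np.add.at(intens[i], order[nearest[ok]], ints[ok])
    return PixelMatrix(
        section_id=section_id or path.stem,
        coords=coords,
        intensities=intens,
        feature_ids=list(feature_ids),
        **metadata,
    )


def tic_normalize(pm: PixelMatrix) -> PixelMatrix:
    """Divide each pixel's feature vector by its total ion count.

    Output rows sum to 1.  Pixels with zero total are an error (drop them
    first with :meth:`PixelMatrix.subset_pixels` if desired).
    """
    totals = pm.intensities.sum(axis=1)
    zero = totals <= 0
    if np.any(zero):
        bad = [(int(x), int(y)) for x, y in pm.coords[zero][:10]]
        raise ValidationError(
            f"zero-TIC pixel(s) at coords {bad}"
            + (" ..." if zero.sum() > 10 else "")
        )
    return dataclasses.replace(pm, intensities=pm.intensities / totals[:, None])


def hotspot_clip(values: np.ndarray, q: float = 0.99) -> np.ndarray:
    """Clip values above the ``q``-quantile to that quantile.

    The quantile uses linear interpolation between order statistics.  Used
    to suppress hotspot pixels in rendered images; monotone, and idempotent
    whenever ``q * (n - 1)`` lands on an order statistic (re-clipping an
    interpolated cap can lower it slightly otherwise).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("hotspot_clip: empty input")
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValidationError("hotspot_clip: no finite values")
    if not 0 < q <= 1:
        raise ValidationError("hotspot_clip: q must be in (0, 1]")
    cap = np.quantile(finite, q)
    return np.where(values > cap, cap, values)


def render_pseudoimage(
    values: np.ndarray,
    coords: np.ndarray,
    *,
    pixel_size_um: float = 5.0,
    clip_q: float | None = None,
    value_label: str = "",
    extent: tuple[int, int, int, int] | None = None,
) -> PseudoImage:
    """Place per-pixel values back on the tissue grid.

    ``values`` is either scalar per pixel or an (n, 3) RGB array.  ``extent``
    defaults to the bounding box of ``coords``; explicit extents that do not
    cover all coordinates are an error.  ``clip_q`` applies
    :func:`hotspot_clip` to scalar values before rendering.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=int)
    if values.shape[0] != coords.shape[0]:
        raise ValidationError("values and coords must have equal length")
    rgb = values.ndim == 2
    if rgb and values.shape[1] != 3:
        raise ValidationError("RGB values must have 3 channels")
    if extent is None:
        xmin, ymin = coords.min(axis=0)
        xmax, ymax = coords.max(axis=0)
        extent = (int(xmin), int(xmax), int(ymin), int(ymax))
    xmin, xmax, ymin, ymax = extent
    if (
        coords[:, 0].min() < xmin
        or coords[:, 0].max() > xmax
        or coords[:, 1].min() < ymin
        or coords[:, 1].max() > ymax
    ):
        raise ValidationError("coordinate outside declared extent")
    h, w = ymax - ymin + 1, xmax - xmin + 1
    if rgb:
        raster = np.zeros((h, w, 3), dtype=float)  # background = black
    else:
        if clip_q is not None:
            values = hotspot_clip(values, clip_q)
        raster = np.full((h, w), np.nan)
    raster[coords[:, 1] - ymin, coords[:, 0] - xmin] = values
    return PseudoImage(
        raster=raster,
        extent=extent,
        value_label=value_label,
        pixel_size_um=pixel_size_um,
    )


def save_pseudoimage(img: PseudoImage, path: str | Path) -> None:
    """Write a pseudoimage as PNG/TIFF (format chosen from the suffix).

    Scalar rasters are min-max scaled to 8-bit grayscale with NaN rendered
    as 0; RGB rasters are written as-is after rounding to 8-bit.
    """
    from PIL import Image

    r = img.raster
    if r.ndim == 3:
        arr = np.clip(np.nan_to_num(r), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(str(path))
        return
    finite = r[np.isfinite(r)]
    lo = finite.min() if finite.size else 0.0
    hi = finite.max() if finite.size else 1.0
    span = hi - lo if hi > lo else 1.0
    arr = np.zeros(r.shape, dtype=np.uint8)
    mask = np.isfinite(r)
    arr[mask] = np.round((r[mask] - lo) / span * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))
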