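"""Synthetic multi-section MSI datasets with known ground truth.

The simulator emulates the tissue-slice labeling experiment: serial sections
of one tissue share cell-type lipid archetypes, each section is incubated
with one uniformly 13C-labeled nutrient for one duration, and every pixel
records lipid peaks plus metabolite isotopologue peaks.  Ground truth (the
per-pixel cell-type map, lipid archetypes and labeling kinetics) is emitted
alongside so every pipeline stage can be checked against it.

Model choices:

* Spatial layout: seeded Voronoi blobs (a few sites per cell type) give
  contiguous regions with realistic spatial autocorrelation, loosely
  mimicking kidney zonation.  Each section draws its own layout — serial
  sections share composition, not exact geometry.
* Labeling kinetics: mono-exponential saturation f(t) = P(1 - exp(-k t)),
  the simplest monotone model for a 2-hour non-steady-state incubation.
  At plateau the labeled fraction is distributed over a per-metabolite set
  of isotopologues (the "split").
* Isotope physics: the true isotopologue vector of every pixel is
  forward-convolved with the natural-abundance matrix of
  :mod:`spacetrace.isotope_correction`, so a t=0 section shows the pure
  natural-abundance pattern.
* Noise: multiplicative lognormal (mean 1, configurable CV) per
  pixel x feature, plus a per-pixel lognormal TIC gain; emitted intensities
  are TIC-unnormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_TIMEPOINTS, P_C13
from .errors import ValidationError
from .features import make_feature_table
from .isotope_correction import correction_matrix, forward_convolve
from .msi_data import PixelMatrix

__all__ = [
    "Kinetics",
    "SimConfig",
    "SyntheticTruth",
    "kinetic_model",
    "generate",
    "generate_replicate",
    "feature_table",
    "truth_enrichment",
    "generate_gradient",
]

#: Default metabolite panel: (name, carbon count, base m/z of [M-H]-).
DEFAULT_METABOLITES = (
    ("hexose", 6, 179.0561),
    ("lactate", 3, 89.0244),
    ("glutamate", 5, 146.0459),
    ("malate", 4, 133.0142),
)


@dataclass(frozen=True)
class Kinetics:
    """Labeling kinetics of one (cell type, metabolite, tracer)."""

    plateau: float  # P in [0, 1]
    rate: float  # k in 1/min
    split: dict  # {n: fraction at plateau}, sums to 1, n >= 1

    def __post_init__(self) -> None:
        if not 0 <= self.plateau <= 1:
            raise ValidationError("plateau must lie in [0, 1]")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        if abs(sum(self.split.values()) - 1) > 1e-9:
            raise ValidationError("isotopologue split must sum to 1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated experiment."""

    shape: tuple[int, int] = (100, 100)  # (nx, ny) grid
    n_types: int = 6
    n_lipids: int = 40
    metabolites: tuple = DEFAULT_METABOLITES
    tracers: dict = field(
        default_factory=lambda: {
            tr: tuple(t for t in tps if t > 0)
            for tr, tps in DEFAULT_TIMEPOINTS.items()
        }
    )
    noise_cv: float = 0.2
    tic_cv: float = 0.1
    sites_per_type: int = 10  # many small blobs: scattered tubule sections
    proportion_jitter: float = 0.0  # +/- relative jitter of type weights
    lipid_mean: float = 10.0  # median archetype lipid intensity
    lipid_sigma: float = 1.0  # lognormal spread of archetype intensities
    metab_base: float = 4.0  # abundance of the lowest type level
    metab_level_step: float = 1.5  # spacing factor between type levels
    p_c13: float = P_C13
    pixel_size_um: float = 5.0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValidationError("need at least 2 cell types")
        if self.shape[0] < 20 or self.shape[1] < 20:
            raise ValidationError("grid must be at least 20x20")
        if self.noise_cv < 0 or self.tic_cv < 0:
            raise ValidationError("noise CVs must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with a simulated dataset."""

    config: SimConfig
    seed: int
    coords: np.ndarray  # shared (n_pixels, 2) grid
    type_maps: dict  # section_id -> per-pixel type labels
    lipid_archetypes: np.ndarray  # (n_types, n_lipids)
    metabolite_levels: np.ndarray  # (n_types, n_metabolites) total abundance
    kinetics: dict  # (type, metabolite_name, tracer) -> Kinetics


def kinetic_model(t: float | np.ndarray, plateau: float, rate: float):
    """Mono-exponential labeling: f(t) = P (1 - exp(-k t))."""
    if not 0 <= plateau <= 1:
        raise ValidationError("plateau must lie in [0, 1]")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t must be non-negative")
    out = plateau * (1.0 - np.exp(-rate * t))
    return float(out) if out.ndim == 0 else out


def _lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise; cv=0 returns exact ones."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=size)


def _default_split(n_carbons: int) -> dict:
    """Plateau isotopologue split: fully labeled plus a half-label route."""
    full = n_carbons
    half = max(1, n_carbons // 2)
    if half == full:
        return {full: 1.0}
    return {half: 0.3, full: 0.7}


def feature_table(config: SimConfig) -> pd.DataFrame:
    """Feature table matching the simulator's emitted feature ids."""
    rows = [
        dict(feature_id=f"lip{i:02d}", mz=400.0 + 12.3 * i, kind="lipid")
        for i in range(config.n_lipids)
    ]
    for name, cc, mz in config.metabolites:
        rows.append(
            dict(
                feature_id=name,
                mz=mz,
                kind="metabolite",
                name=name,
                carbon_count=cc,
            )
        )
        for n in range(1, cc + 1):
            rows.append(
                dict(
                    feature_id=f"{name}_M+{n}",
                    mz=mz + n * 1.003355,
                    kind="metabolite",
                    name=f"{name} M+{n}",
                    carbon_count=cc,
                    base_metabolite_id=name,
                    isotopologue_index=n,
                )
            )
    return make_feature_table(rows)


def _layout(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Voronoi-blob type map over the grid; returns (coords, labels)."""
    nx, ny = config.shape
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    n_sites = config.n_types * config.sites_per_type
    sites = rng.uniform(0, (nx, ny), size=(n_sites, 2))
    site_type = np.repeat(np.arange(config.n_types), config.sites_per_type)
    weights = np.ones(config.n_types)
    if config.proportion_jitter > 0:
        weights *= 1.0 + config.proportion_jitter * rng.uniform(
            -1, 1, size=config.n_types
        )
    d = np.linalg.norm(
        coords[:, None, :].astype(float) - sites[None, :, :], axis=2
    )
    d /= weights[site_type][None, :]  # heavier types reach further
    labels = site_type[np.argmin(d, axis=1)]
    # guarantee every type appears (re-seed missing types onto random pixels)
    for t in range(config.n_types):
        if not np.any(labels == t):
            labels[rng.integers(0, labels.size, size=5)] = t
    return coords, labels


def _draw_truth(config: SimConfig, seed: int) -> SyntheticTruth:
    rng = np.random.default_rng(seed)
    arch = rng.lognormal(
        mean=np.log(config.lipid_mean),
        sigma=config.lipid_sigma,
        size=(config.n_types, config.n_lipids),
    )
    n_met = len(config.metabolites)
    levels = np.empty((config.n_types, n_met))
    base_levels = config.metab_base * config.metab_level_step ** np.arange(
        config.n_types
    )
    for m in range(n_met):
        levels[:, m] = base_levels[rng.permutation(config.n_types)]
    kinetics = {}
    for t in range(config.n_types):
        for name, cc, _mz in config.metabolites:
            for tracer in config.tracers:
                kinetics[(t, name, tracer)] = Kinetics(
                    plateau=float(rng.uniform(0.15, 0.6)),
                    rate=float(rng.uniform(0.01, 0.05)),
                    split=_default_split(cc),
                )
    return SyntheticTruth(
        config=config,
        seed=seed,
        coords=np.empty((0, 2), dtype=int),
        type_maps={},
        lipid_archetypes=arch,
        metabolite_levels=levels,
        kinetics=kinetics,
    )


def _section(
    config: SimConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator,
    section_id: str,
    tracer: str,
    timepoint: float,
) -> PixelMatrix:
    coords, labels = _layout(config, rng)
    truth.type_maps[section_id] = labels
    if truth.coords.size == 0:
        truth.coords = coords
    n = coords.shape[0]

    lipids = truth.lipid_archetypes[labels] * _lognormal(
        rng, config.noise_cv, (n, config.n_lipids)
    )
    blocks = [lipids]
    fids = [f"lip{i:02d}" for i in range(config.n_lipids)]
    for m, (name, cc, _mz) in enumerate(config.metabolites):
        cm = correction_matrix(cc, config.p_c13)
        totals = truth.metabolite_levels[labels, m] * _lognormal(
            rng, config.noise_cv, n
        )
        iso = np.zeros((n, cc + 1))
        if tracer == "none" or timepoint == 0:
            iso[:, 0] = 1.0
        else:
            f = np.empty(n)
            split = np.zeros((n, cc + 1))
            for t in range(config.n_types):
                kin = truth.kinetics[(t, name, tracer)]
                sel = labels == t
                f[sel] = kinetic_model(timepoint, kin.plateau, kin.rate)
                for nn, frac in kin.split.items():
                    split[sel, nn] = frac
            iso[:, 0] = 1.0 - f
            iso += split * f[:, None]
        iso *= totals[:, None]
        iso = forward_convolve(iso, cm)
        iso *= _lognormal(rng, config.noise_cv, (n, cc + 1))
        blocks.append(iso)
        fids += [name] + [f"{name}_M+{nn}" for nn in range(1, cc + 1)]

    X = np.hstack(blocks)
    X *= _lognormal(rng, config.tic_cv, n)[:, None]  # per-pixel TIC gain
    return PixelMatrix(
        section_id=section_id,
        coords=coords,
        intensities=X,
        feature_ids=fids,
        tracer=tracer,
        timepoint_min=timepoint,
        pixel_size_um=config.pixel_size_um,
    )


def generate(
    config: SimConfig = SimConfig(), seed: int = 0
) -> tuple[PixelMatrix, list[PixelMatrix], SyntheticTruth]:
    """Simulate one control section plus labeled sections per tracer and
    timepoint.  Fully reproducible from ``seed``; each section consumes its
    own spawned random stream, so sections share archetypes and kinetics
    but have independent layouts and noise."""
    truth = _draw_truth(config, seed)
    streams = np.random.SeedSequence(seed).spawn(
        1 + sum(len(tps) for tps in config.tracers.values())
    )
    control = _section(
        config, truth, np.random.default_rng(streams[0]), "control", "none", 0.0
    )
    labeled = []
    i = 1
    for tracer, tps in sorted(config.tracers.items()):
        for tp in tps:
            sid = f"{tracer}_t{tp:g}"
            labeled.append(
                _section(
                    config,
                    truth,
                    np.random.default_rng(streams[i]),
                    sid,
                    tracer,
                    float(tp),
                )
            )
            i += 1
    return control, labeled, truth


def generate_replicate(
    truth: SyntheticTruth,
    seed: int,
    section_id: str,
    tracer: str,
    timepoint: float,
    config: SimConfig | None = None,
) -> PixelMatrix:
    """Draw one additional section from an existing ground truth.

    Emulates a biological replicate (another slice or animal): same
    archetypes and kinetics, independent layout and noise.  ``config`` may
    override the original study conditions (e.g. perturb cell-type
    proportions or noise for the replicate).
    """
    cfg = config if config is not None else truth.config
    rng = np.random.default_rng(seed)
    return _section(cfg, truth, rng, section_id, tracer, float(timepoint))


def truth_enrichment(
    truth: SyntheticTruth,
    tracer: str,
    timepoints: np.ndarray | None = None,
    fine: int | None = None,
) -> pd.DataFrame:
    """Oracle AUC-normalized enrichment per (type, metabolite, isotopologue).

    With ``timepoints`` the trapezoid runs over exactly those sampled
    times — the correct oracle for a pipeline that measured those
    timepoints.  With ``fine`` (number of grid points) a dense trapezoid of
    f(t) over [0, T] approximates the continuous time average; ``timepoints``
    then supplies only the total time T.
    """
    if timepoints is None and fine is None:
        raise ValidationError("provide timepoints and/or fine")
    t_sample = np.asarray(
        timepoints
        if timepoints is not None
        else [0.0, max(DEFAULT_TIMEPOINTS[tracer])],
        dtype=float,
    )
    T = t_sample[-1]
    grid = np.linspace(0.0, T, fine) if fine is not None else t_sample
    rows = []
    for (t, name, tr), kin in sorted(truth.kinetics.items()):
        if tr != tracer:
            continue
        f = kinetic_model(grid, kin.plateau, kin.rate)
        auc = np.trapezoid(f, grid) / T
        for n, frac in sorted(kin.split.items()):
            rows.append(
                dict(
                    type=t,
                    metabolite=name,
                    isotopologue=n,
                    auc_enrichment=auc * frac,
                )
            )
        rows.append(
            dict(
                type=t,
                metabolite=name,
                isotopologue=0,
                auc_enrichment=1.0 - auc,
            )
        )
    return pd.DataFrame(rows)


def generate_gradient(
    n_cols: int = 80,
    n_rows: int = 6,
    n_lipids: int = 30,
    noise_cv: float = 0.05,
    enrichment_slope: float = -1.0,
    seed: int = 0,
) -> tuple[PixelMatrix, np.ndarray, np.ndarray]:
    """A 1-D lipid-profile gradient for trajectory tests.

    Profiles interpolate between two archetypes along x; returns the
    section, the true position s in [0, 1] per pixel, and a synthetic
    per-pixel enrichment that changes linearly along the gradient
    (``enrichment_slope`` < 0 means enrichment falls with s) with the same
    multiplicative noise.
    """
    rng = np.random.default_rng(seed)
    a = rng.lognormal(np.log(10), 1.0, size=n_lipids)
    b = rng.lognormal(np.log(10), 1.0, size=n_lipids)
    xs, ys = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    s = coords[:, 0] / (n_cols - 1)
    profiles = (1 - s)[:, None] * a[None, :] + s[:, None] * b[None, :]
    profiles = profiles * _lognormal(rng, noise_cv, profiles.shape)
    pm = PixelMatrix(
        section_id="gradient",
        coords=coords,
        intensities=profiles,
        feature_ids=[f"lip{i:02d}" for i in range(n_lipids)],
    )
    base = 0.5 - 0.4 * s if enrichment_slope < 0 else 0.1 + 0.4 * s
    enrichment = base * _lognormal(rng, noise_cv, s.size)
    return pm, s, enrichment
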