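"""Pipeline configuration (validated) and end-to-end orchestration.

A :class:`PipelineConfig` gathers every tunable of the pipeline in one
validated document (unknown keys are rejected).  :func:`run_pipeline`
executes simulate -> cluster -> impute -> dynamics -> trajectory ->
validate -> render and writes a manifest of every artifact with its SHA-256
hash, so identical configs and seeds yield identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import anchor_imputation as ai
from . import cell_typing, dynamics, msi_data, trajectory, validation
from . import synthetic_tissue as st

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

log = logging.getLogger("spacetrace")


class SimSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape: tuple[int, int] = (48, 48)
    n_types: int = 4
    n_lipids: int = 30
    noise_cv: float = 0.2
    tic_cv: float = 0.1
    proportion_jitter: float = 0.0
    tracers: dict[str, list[float]] = Field(
        default_factory=lambda: {"glc13": [15, 30, 60, 120]}
    )


class AnchorSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_pcs: int = 30
    k_anchor: int = 5
    k_filter: int = 200
    k_score: int = 30
    k_weight: int = 50
    sigma: float | None = None


class ClusterSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    resolution: float = 1.0
    k: int = 15
    n_pcs: int = 30
    n_clusters: int | None = None


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: Path = Path("spacetrace_out")
    sim: SimSettings = Field(default_factory=SimSettings)
    anchor: AnchorSettings = Field(default_factory=AnchorSettings)
    cluster: ClusterSettings = Field(default_factory=ClusterSettings)
    clip_q: float = 0.99
    p_c13: float = 0.0107
    validate_axis: str = "vertical"
    trajectory_root_cluster: int = 0


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full synthetic pipeline; returns the artifact manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save_df(df, name):
        p = out / name
        df.to_csv(p, sep="\t", index=False)
        artifacts.append(p)
        return p

    log.info("simulate: %s", cfg.sim.model_dump())
    sim_cfg = st.SimConfig(
        shape=tuple(cfg.sim.shape),
        n_types=cfg.sim.n_types,
        n_lipids=cfg.sim.n_lipids,
        noise_cv=cfg.sim.noise_cv,
        tic_cv=cfg.sim.tic_cv,
        proportion_jitter=cfg.sim.proportion_jitter,
        tracers={k: tuple(v) for k, v in cfg.sim.tracers.items()},
        p_c13=cfg.p_c13,
    )
    control, labeled, truth = st.generate(sim_cfg, seed=cfg.seed)
    feats = st.feature_table(sim_cfg)
    lipid_ids = list(feats.loc[feats["kind"] == "lipid", "feature_id"])
    for pm in [control] + labeled:
        p = out / f"{pm.section_id}.tsv"
        msi_data.write_pixel_matrix(pm, p)
        artifacts.append(p)
    save_df(feats, "features.tsv")

    # cell typing on the control section (floor the full normalized matrix,
    # then take lipid columns: identical values, row-sum check intact)
    cn = msi_data.tic_normalize(control)
    lipid_idx = [cn.feature_index(f) for f in lipid_ids]
    counts = cell_typing.to_counts(cn.intensities)[:, lipid_idx]
    if cfg.cluster.n_clusters is not None:
        ca = cell_typing.cluster_k(
            counts, cfg.cluster.n_clusters, seed=cfg.seed, k=cfg.cluster.k,
            n_pcs=cfg.cluster.n_pcs,
        )
    else:
        ca = cell_typing.cluster(
            counts, resolution=cfg.cluster.resolution, seed=cfg.seed,
            k=cfg.cluster.k, n_pcs=cfg.cluster.n_pcs,
        )
    cl_df = control.to_frame()[["section_id", "x", "y"]]
    cl_df["cluster"] = ca.labels
    save_df(cl_df, "clusters.tsv")

    # imputation of the labeling timecourse onto the control
    params = ai.AnchorParams(seed=cfg.seed, **cfg.anchor.model_dump())
    normalized_labeled = [msi_data.tic_normalize(pm) for pm in labeled]
    ds = ai.integrate_timecourse(cn, normalized_labeled, lipid_ids, params)
    for (tracer, tp), (values, ids) in sorted(ds.blocks.items()):
        import pandas as pd

        block = pd.DataFrame(values, columns=ids)
        block.insert(0, "y", control.coords[:, 1])
        block.insert(0, "x", control.coords[:, 0])
        save_df(block, f"imputed_{tracer}_t{tp:g}.tsv")

    # enrichment dynamics
    tensor = dynamics.compute_enrichment(ds, feats, p=cfg.p_c13)
    summary = dynamics.summarize_by_cluster(tensor, ca.labels)
    save_df(summary, "dynamics_summary.tsv")

    # trajectory on the control lipids
    tr = trajectory.pseudotime(
        counts,
        root=("cluster", cfg.trajectory_root_cluster),
        seed=cfg.seed,
        labels=ca.labels,
        on_disconnected="nan",
    )
    tr_df = cl_df[["section_id", "x", "y"]].copy()
    tr_df["pseudotime"] = tr.pseudotime
    save_df(tr_df, "pseudotime.tsv")
    img = trajectory.spatial_trajectory_map(
        tr, control.coords, clip_q=cfg.clip_q
    )
    p = out / "pseudotime.png"
    msi_data.save_pseudoimage(img, p)
    artifacts.append(p)

    # leave-one-factor-out validation on the last labeled section
    val_section = labeled[-1]
    half_a, half_b = validation.split_half(val_section, cfg.validate_axis)
    metab_ids = [f for f in val_section.feature_ids if f not in set(lipid_ids)]
    report = validation.cross_validate(
        half_a,
        half_b,
        lipid_ids,
        metab_ids,
        features=feats,
        params=params,
        n_clusters=cfg.sim.n_types,
        seed=cfg.seed,
    )
    p = out / "validation.json"
    report.to_json(p)
    artifacts.append(p)

    # resolved config + manifest (outdir omitted: implied by location)
    p = out / "config.resolved.yaml"
    resolved = json.loads(cfg.model_dump_json())
    resolved.pop("outdir", None)
    with open(p, "w") as fh:
        yaml.safe_dump(resolved, fh)
    artifacts.append(p)
    manifest = {
        str(a.relative_to(out)): _sha256(a) for a in sorted(artifacts)
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
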