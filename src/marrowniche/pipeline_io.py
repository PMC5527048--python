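"""File formats, statistics plumbing, and the end-to-end analysis pipeline.

Formats
-------
* Volumes: one uint8 label TIFF (0 marrow / 1 vessel / 2 bone) and one int32
  MK-id TIFF, written in ZYX page order, plus a ``volume.json`` sidecar with
  the voxel spacing (x, y, z in µm) and the label legend.
* Trajectories: CSV with header ``track_id,frame,t_min,x_um,y_um[,z_um]`` and
  an optional ``excluded`` column.
* Reports: plain JSON.

All randomness flows from the seeds recorded in :class:`RunConfig`; a re-run
with the same config reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import stats

from . import __version__
from .core import LABEL_LEGEND, VolumeGrid
from .motion_analysis import Trajectory, cohort_summary
from .placement_sim import (
    DEFAULT_REPLICATES,
    compare_scenarios,
    sim_nva,
    sim_random,
)
from .spatial_metrics import (
    ASSOCIATION_THRESHOLD_UM,
    BONE_THRESHOLD_UM,
    annotate_population,
    distance_map,
    pooled_slice_va_fraction,
    summarize_population,
    vessel_to_vessel_distances,
    virtual_slice_metrics,
)
from .synthetic_data import (
    GeneratorConfig,
    TrajectoryConfig,
    sample_mk_diameters,
    synthesize_volume,
)

log = logging.getLogger("marrowniche")

LABELS_TIF = "labels.tif"
MK_IDS_TIF = "mk_ids.tif"
SIDECAR_JSON = "volume.json"


# -- volume I/O -----------------------------------------------------------


def write_volume(grid: VolumeGrid, outdir) -> Path:
    """Write label + MK-id TIFF stacks with a JSON spacing sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # arrays are (x, y, z); TIFF pages conventionally run along z
    tifffile.imwrite(outdir / LABELS_TIF, grid.labels.transpose(2, 1, 0))
    tifffile.imwrite(outdir / MK_IDS_TIF, grid.mk_ids.transpose(2, 1, 0).astype(np.int32))
    sidecar = {
        "spacing_um": list(grid.spacing),
        "shape_xyz": list(grid.shape),
        "axes": "ZYX pages; arrays in this package are indexed (x, y, z)",
        "legend": LABEL_LEGEND,
    }
    (outdir / SIDECAR_JSON).write_text(json.dumps(sidecar, indent=2))
    return outdir


def read_volume(indir) -> VolumeGrid:
    indir = Path(indir)
    sidecar = json.loads((indir / SIDECAR_JSON).read_text())
    labels = tifffile.imread(indir / LABELS_TIF).transpose(2, 1, 0)
    mk_path = indir / MK_IDS_TIF
    mk_ids = tifffile.imread(mk_path).transpose(2, 1, 0) if mk_path.exists() else None
    return VolumeGrid(labels, tuple(sidecar["spacing_um"]), mk_ids)


def volume_from_masks(
    vessel: np.ndarray | None,
    bone: np.ndarray | None,
    mk_ids: np.ndarray | None,
    spacing,
) -> VolumeGrid:
    """Assemble a grid from separate boolean/label masks (e.g. one TIFF each)."""
    ref = next(m for m in (vessel, bone, mk_ids) if m is not None)
    labels = np.zeros(ref.shape, dtype=np.uint8)
    if vessel is not None:
        labels[np.asarray(vessel) > 0] = 1
    if bone is not None:
        labels[np.asarray(bone) > 0] = 2
    return VolumeGrid(labels, spacing, mk_ids)


# -- trajectory I/O -------------------------------------------------------


def write_trajectories(trajs: list[Trajectory], path) -> Path:
    path = Path(path)
    rows = []
    for traj in trajs:
        d = traj.d
        for frame, pos in enumerate(traj.positions):
            row = {
                "track_id": traj.track_id,
                "frame": frame,
                "t_min": frame * traj.dt_min,
                "x_um": pos[0],
                "y_um": pos[1],
            }
            if d == 3:
                row["z_um"] = pos[2]
            row["excluded"] = int(traj.excluded)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_trajectories(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    required = {"track_id", "frame", "t_min", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    cols = ["x_um", "y_um"] + (["z_um"] if "z_um" in df.columns else [])
    trajs = []
    for track_id, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        t = sub["t_min"].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0:
            raise ValueError(f"track {track_id} has fewer than 2 frames")
        if not np.allclose(dt, dt[0]):
            raise ValueError(f"track {track_id} is not uniformly sampled")
        excluded = bool(sub["excluded"].iloc[0]) if "excluded" in sub.columns else False
        trajs.append(
            Trajectory(
                track_id=track_id,
                dt_min=float(dt[0]),
                positions=sub[cols].to_numpy(dtype=float),
                excluded=excluded,
            )
        )
    return trajs


# -- statistics plumbing --------------------------------------------------


def significance_stars(p: float) -> str:
    """Star coding: * < 0.05, ** < 0.01, *** < 0.001, else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    stars: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def group_compare(groups: list) -> GroupComparison:
    """Two groups: two-sided Mann–Whitney U (normal approximation, tie-corrected);
    three or more: one-way ANOVA."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least 2 groups with at least 2 values each")
    if len(groups) == 2:
        res = stats.mannwhitneyu(
            groups[0], groups[1], alternative="two-sided", method="asymptotic"
        )
        return GroupComparison(
            "mann-whitney-u", float(res.statistic), float(res.pvalue),
            significance_stars(float(res.pvalue)),
        )
    res = stats.f_oneway(*groups)
    return GroupComparison(
        "one-way-anova", float(res.statistic), float(res.pvalue),
        significance_stars(float(res.pvalue)),
    )


# -- end-to-end pipeline --------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of the full synthesis → analysis → simulation run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    trajectories: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    n_replicates: int = DEFAULT_REPLICATES
    association_threshold: float = ASSOCIATION_THRESHOLD_UM
    bone_threshold: float = BONE_THRESHOLD_UM
    slice_thickness: float = 10.0
    slice_axis: int = 2
    reference_lag: float = 10.0
    max_lag_fraction: float = 0.25
    significance_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.significance_level < 1.0:
            raise ValueError("significance level must lie in (0, 1)")
        for name in ("association_threshold", "bone_threshold", "slice_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        gen = GeneratorConfig(**raw.pop("generator", {}))
        trk = TrajectoryConfig(**raw.pop("trajectories", {}))
        return cls(generator=gen, trajectories=trk, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Synthesize a volume, analyze it, run SimR/SimNVA, and analyze tracks.

    Returns the report dict; with ``outdir`` also writes the volume, the
    trajectory CSV, and ``report.json``.  Deterministic for a fixed config.
    Any stage failure is re-raised with the stage name; partial outputs
    written so far are preserved.
    """
    report: dict = {"software": {"name": "marrowniche", "version": __version__}}
    report["config"] = config.to_dict()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(config.seed).generate_state(2 * config.n_replicates + 2)
    seeds = [int(s % (2**31)) for s in seeds]
    stage = "synth-volume"
    try:
        gen_cfg = dataclasses.replace(config.generator, seed=seeds[0])
        log.info("stage=%s seed=%d", stage, gen_cfg.seed)
        grid, network, objects = synthesize_volume(gen_cfg)
        if outdir is not None:
            write_volume(grid, outdir / "volume")

        stage = "analyze-volume"
        vessel_map = distance_map(grid.vessel_mask, grid.spacing)
        bone_map = (
            distance_map(grid.bone_mask, grid.spacing)
            if grid.bone_mask.any()
            else None
        )
        _, annotations = annotate_population(
            grid,
            objects,
            association_threshold=config.association_threshold,
            bone_threshold=config.bone_threshold,
            vessel_map=vessel_map,
            bone_map=bone_map,
        )
        observed = summarize_population(annotations, objects)
        spacings = vessel_to_vessel_distances(grid, vessel_map=vessel_map)
        sections = virtual_slice_metrics(
            grid,
            annotations,
            thickness=config.slice_thickness,
            axis=config.slice_axis,
        )
        report["scaffold"] = {
            "n_vessel_nodes": int(len(network.nodes)),
            "n_vessel_edges": int(len(network.edges)),
            "vessel_volume_fraction": float(grid.vessel_mask.mean()),
            "median_vessel_spacing_um": float(np.median(spacings))
            if spacings.size
            else None,
            "n_spacing_maxima": int(spacings.size),
        }
        report["observed"] = observed.to_dict()
        report["virtual_slicing"] = {
            "thickness_um": config.slice_thickness,
            "axis": config.slice_axis,
            "va_fraction_2d": pooled_slice_va_fraction(sections),
            "va_fraction_3d": observed.va_fraction,
            "n_slabs": len(sections),
        }

        stage = "simulate"
        va_objects = [
            o for o, a in zip(objects, annotations) if a.vessel_associated
        ]
        nva_diams = np.array(
            [
                o.equivalent_diameter_um
                for o, a in zip(objects, annotations)
                if not a.vessel_associated
            ]
        )
        all_diams = np.array([o.equivalent_diameter_um for o in objects])
        results = []
        for rep in range(config.n_replicates):
            log.info("stage=simulate scenario=SimR replicate=%d", rep)
            results.append(
                sim_random(
                    grid, all_diams, seeds[2 + rep],
                    association_threshold=config.association_threshold,
                    vessel_map=vessel_map, bone_map=bone_map,
                )
            )
            if nva_diams.size:
                log.info("stage=simulate scenario=SimNVA replicate=%d", rep)
                results.append(
                    sim_nva(
                        grid, va_objects, nva_diams,
                        seeds[2 + config.n_replicates + rep],
                        association_threshold=config.association_threshold,
                        vessel_map=vessel_map, bone_map=bone_map,
                    )
                )
        comparisons = compare_scenarios(
            observed, results, significance_level=config.significance_level
        )
        report["simulation"] = {
            "n_replicates": config.n_replicates,
            "scenarios": [c.to_dict() for c in comparisons],
        }

        stage = "synth-tracks"
        trk_cfg = dataclasses.replace(config.trajectories, seed=seeds[1])
        from .synthetic_data import simulate_trajectories

        trajs = simulate_trajectories(trk_cfg)
        if outdir is not None:
            write_trajectories(trajs, outdir / "tracks.csv")

        stage = "track"
        cohort = cohort_summary(
            trajs,
            d=trk_cfg.dimensionality,
            max_lag_fraction=config.max_lag_fraction,
            reference_lag=config.reference_lag,
        )
        report["motion"] = cohort.to_dict()
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
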