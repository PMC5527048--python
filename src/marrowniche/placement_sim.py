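"""Monte-Carlo null models for megakaryocyte placement in the marrow.

Two scenarios are compared against an observed (or synthetic "observed")
population:

* **SimR** — every MK is re-placed uniformly at random over the marrow.
  Spheres may touch vessels (that is what makes a simulated cell
  vessel-associated) but never overlap vessel, bone, another MK, or the grid
  exterior; candidates violating a constraint are rejected and redrawn.
* **SimNVA** — the observed vessel-associated (VA) MKs are frozen in place
  and act, together with the vasculature, as a space-limiting scaffold; only
  the non-vessel-associated (NVA) subpopulation is re-placed, uniformly over
  the intervascular space *without* vessel or cell contact, so every placed
  object is NVA by construction.

If the observed NVA cells are spatially unbiased, SimNVA reproduces their
vessel-distance distribution, while SimR — which ignores the vessel bias of
the VA pool — overestimates MK–vessel distances and underestimates the VA
fraction.  That directional contrast is the inference the comparison report
encodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import LABEL_MARROW, MKObject, VolumeGrid, sphere_voxels
from .spatial_metrics import (
    ASSOCIATION_THRESHOLD_UM,
    PopulationSummary,
    annotate_population,
    distance_map,
    summarize_population,
)

MAX_ATTEMPTS = 10_000
#: Replicates per scenario; the reference analysis used n = 6 simulations.
DEFAULT_REPLICATES = 6


@dataclass
class SimulationResult:
    """One SimR or SimNVA realization."""

    scenario: str
    seed: int
    objects: list[MKObject]
    annotations: list
    summary: PopulationSummary
    n_attempted: int
    n_placed: int

    @property
    def va_fraction(self) -> float:
        return self.summary.va_fraction


def _finalize(
    scenario: str,
    grid: VolumeGrid,
    objects: list[MKObject],
    seed: int,
    n_attempted: int,
    vessel_map,
    bone_map,
    association_threshold: float,
) -> SimulationResult:
    _, annotations = annotate_population(
        grid,
        objects,
        association_threshold=association_threshold,
        vessel_map=vessel_map,
        bone_map=bone_map,
    )
    return SimulationResult(
        scenario=scenario,
        seed=seed,
        objects=objects,
        annotations=annotations,
        summary=summarize_population(annotations, objects),
        n_attempted=n_attempted,
        n_placed=len(objects),
    )


def sim_random(
    grid: VolumeGrid,
    diameters,
    seed: int,
    max_attempts: int = MAX_ATTEMPTS,
    *,
    association_threshold: float = ASSOCIATION_THRESHOLD_UM,
    vessel_map: np.ndarray | None = None,
    bone_map: np.ndarray | None = None,
) -> SimulationResult:
    """Fully random placement: centers uniform over marrow voxels, rejection on overlap.

    The scaffold grid is not modified; occupancy is tracked internally.
    Objects are placed largest-first.  Failure to place an object within
    ``max_attempts`` raises with the partial placement count.
    """
    diameters = np.asarray(diameters, dtype=float)
    if diameters.size == 0:
        raise ValueError("diameters must be non-empty")
    labels = grid.labels
    marrow_flat = np.flatnonzero(labels == LABEL_MARROW)
    if marrow_flat.size == 0:
        raise ValueError("grid has no marrow space")
    rng = np.random.default_rng(seed)
    if vessel_map is None and grid.vessel_mask.any():
        vessel_map = distance_map(grid.vessel_mask, grid.spacing)
    if bone_map is None and grid.bone_mask.any():
        bone_map = distance_map(grid.bone_mask, grid.spacing)

    occupancy = np.zeros(grid.shape, dtype=np.int32)
    shape = grid.shape
    objects: list[MKObject] = []
    n_attempted = 0
    for mk_id, slot in enumerate(np.argsort(-diameters), start=1):
        radius = diameters[slot] / 2.0
        placed = False
        for _ in range(max_attempts):
            n_attempted += 1
            center = np.unravel_index(rng.choice(marrow_flat), shape)
            voxels = sphere_voxels(center, radius, grid.spacing, shape)
            if voxels is None:
                continue
            idx = tuple(voxels.T)
            if (labels[idx] != LABEL_MARROW).any() or (occupancy[idx] != 0).any():
                continue
            occupancy[idx] = mk_id
            objects.append(MKObject.from_voxels(mk_id, voxels, grid.spacing))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"SimR: could not place object {mk_id} (diameter "
                f"{diameters[slot]:.1f} µm) within {max_attempts} attempts; "
                f"placed {len(objects)}/{diameters.size}"
            )
    return _finalize(
        "SimR", grid, objects, seed, n_attempted, vessel_map, bone_map,
        association_threshold,
    )


def sim_nva(
    grid: VolumeGrid,
    observed_va_objects: list[MKObject],
    nva_diameters,
    seed: int,
    max_attempts: int = MAX_ATTEMPTS,
    *,
    association_threshold: float = ASSOCIATION_THRESHOLD_UM,
    vessel_map: np.ndarray | None = None,
    bone_map: np.ndarray | None = None,
) -> SimulationResult:
    """Re-place only the NVA subpopulation around a frozen VA scaffold.

    Frozen VA objects are returned unchanged (first in the result).  Each new
    object keeps a center-to-structure clearance of radius + threshold from
    vessels and frozen cells, and a center-to-center clearance of
    ``r_i + r_j + threshold`` from other new objects, which guarantees — by
    the triangle inequality on the voxelized distance map — that the measured
    edge distances stay above the association threshold.
    """
    nva_diameters = np.asarray(nva_diameters, dtype=float)
    labels = grid.labels
    rng = np.random.default_rng(seed)
    if vessel_map is None and grid.vessel_mask.any():
        vessel_map = distance_map(grid.vessel_mask, grid.spacing)
    if bone_map is None and grid.bone_mask.any():
        bone_map = distance_map(grid.bone_mask, grid.spacing)

    frozen_mask = np.zeros(grid.shape, dtype=bool)
    for obj in observed_va_objects:
        frozen_mask[tuple(obj.voxels.T)] = True
    frozen_map = (
        distance_map(frozen_mask, grid.spacing) if frozen_mask.any() else None
    )

    marrow = (labels == LABEL_MARROW) & ~frozen_mask
    shape = grid.shape
    spacing = np.asarray(grid.spacing)

    # admissible centers sorted by clearance to the nearest obstacle (vessel or
    # frozen cell), so the per-object candidate pool is a suffix lookup
    obstacle_map = vessel_map
    if frozen_map is not None:
        obstacle_map = (
            frozen_map if obstacle_map is None else np.minimum(obstacle_map, frozen_map)
        )
    marrow_flat = np.flatnonzero(marrow)
    if obstacle_map is not None:
        clear_vals = obstacle_map.ravel()[marrow_flat]
        order = np.argsort(clear_vals, kind="stable")
        sorted_clearance = clear_vals[order]
        sorted_centers = marrow_flat[order]
    else:
        sorted_clearance = None
        sorted_centers = marrow_flat

    placed_centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    occupancy = np.zeros(grid.shape, dtype=np.int32)
    new_objects: list[MKObject] = []
    n_attempted = 0
    next_id = max(
        [int(o.id) for o in observed_va_objects if isinstance(o.id, (int, np.integer))],
        default=0,
    ) + 1

    for slot in np.argsort(-nva_diameters):
        radius = nva_diameters[slot] / 2.0
        clearance = radius + association_threshold
        if sorted_clearance is not None:
            start = np.searchsorted(sorted_clearance, clearance, side="right")
            pool = sorted_centers[start:]
        else:
            pool = sorted_centers
        if pool.size == 0:
            raise RuntimeError(
                f"SimNVA: no admissible centers for diameter "
                f"{nva_diameters[slot]:.1f} µm; placed "
                f"{len(new_objects)}/{nva_diameters.size}"
            )
        placed = False
        for _ in range(max_attempts):
            n_attempted += 1
            center = np.unravel_index(rng.choice(pool), shape)
            center_um = np.asarray(center) * spacing
            if placed_centers:
                gaps = np.linalg.norm(np.asarray(placed_centers) - center_um, axis=1)
                if (
                    gaps
                    <= np.asarray(placed_radii) + radius + association_threshold
                ).any():
                    continue
            voxels = sphere_voxels(center, radius, grid.spacing, shape)
            if voxels is None:
                continue
            idx = tuple(voxels.T)
            if (labels[idx] != LABEL_MARROW).any() or frozen_mask[idx].any():
                continue
            occupancy[idx] = next_id
            new_objects.append(MKObject.from_voxels(next_id, voxels, grid.spacing))
            placed_centers.append(center_um)
            placed_radii.append(radius)
            next_id += 1
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"SimNVA: could not place object of diameter "
                f"{nva_diameters[slot]:.1f} µm within {max_attempts} attempts; "
                f"placed {len(new_objects)}/{nva_diameters.size}"
            )

    objects = list(observed_va_objects) + new_objects
    result = _finalize(
        "SimNVA", grid, objects, seed, n_attempted, vessel_map, bone_map,
        association_threshold,
    )
    for ann in result.annotations[len(observed_va_objects):]:
        if ann.vessel_associated:  # pragma: no cover - construction guarantees NVA
            raise AssertionError("SimNVA placed a vessel-associated object")
    return result


# -- scenario comparison --------------------------------------------------


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ScenarioComparison:
    scenario: str
    n_replicates: int
    va_fraction_mean: float
    va_fraction_sd: float
    nva_distance_mean: float
    nva_distance_sd: float
    mean_vessel_distance: float
    p_all_distances: float
    p_nva_distances: float
    stars_all: str
    stars_nva: str
    verdict: str

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "n_replicates": self.n_replicates,
            "va_fraction_mean": self.va_fraction_mean,
            "va_fraction_sd": self.va_fraction_sd,
            "nva_distance_mean": self.nva_distance_mean,
            "nva_distance_sd": self.nva_distance_sd,
            "mean_vessel_distance_um": self.mean_vessel_distance,
            "p_all_distances": self.p_all_distances,
            "p_nva_distances": self.p_nva_distances,
            "stars_all": self.stars_all,
            "stars_nva": self.stars_nva,
            "verdict": self.verdict,
        }


def compare_scenarios(
    observed_summary: PopulationSummary,
    sim_results: list[SimulationResult],
    *,
    significance_level: float = 0.05,
) -> list[ScenarioComparison]:
    """Mann–Whitney comparison of observed vs simulated vessel-distance distributions.

    Per scenario: replicate-level mean ± SD of VA fraction and of the mean NVA
    distance; a two-sided Mann–Whitney U test of the observed all-MK vessel
    distances against the scenario's pooled distances (the scenario verdict),
    and the same test on the NVA subsets.  A scenario is "rejected" when the
    pooled all-MK distance test falls below the significance level, otherwise
    "compatible".
    """
    if not sim_results:
        raise ValueError("need at least one simulation replicate")
    comparisons = []
    for scenario in sorted({r.scenario for r in sim_results}):
        reps = [r for r in sim_results if r.scenario == scenario]
        va = np.array([r.va_fraction for r in reps])
        rep_nva_means = np.array(
            [np.mean(r.summary.nva_distances) for r in reps if r.summary.nva_distances.size]
        )
        pooled_all = np.concatenate([r.summary.vessel_distances for r in reps])
        pooled_nva = np.concatenate([r.summary.nva_distances for r in reps])

        p_all = float(
            stats.mannwhitneyu(
                observed_summary.vessel_distances, pooled_all,
                alternative="two-sided", method="asymptotic",
            ).pvalue
        )
        if observed_summary.nva_distances.size and pooled_nva.size:
            p_nva = float(
                stats.mannwhitneyu(
                    observed_summary.nva_distances, pooled_nva,
                    alternative="two-sided", method="asymptotic",
                ).pvalue
            )
        else:
            p_nva = np.nan
        verdict = (
            f"{scenario} rejected"
            if p_all < significance_level
            else f"{scenario} compatible"
        )
        comparisons.append(
            ScenarioComparison(
                scenario=scenario,
                n_replicates=len(reps),
                va_fraction_mean=float(va.mean()),
                va_fraction_sd=float(va.std(ddof=1)) if va.size > 1 else 0.0,
                nva_distance_mean=float(rep_nva_means.mean())
                if rep_nva_means.size
                else np.nan,
                nva_distance_sd=float(rep_nva_means.std(ddof=1))
                if rep_nva_means.size > 1
                else 0.0,
                mean_vessel_distance=float(pooled_all.mean()),
                p_all_distances=p_all,
                p_nva_distances=p_nva,
                stars_all=_stars(p_all),
                stars_nva=_stars(p_nva) if np.isfinite(p_nva) else "na",
                verdict=verdict,
            )
        )
    return comparisons
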