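"""Distance-based morphometry of labeled marrow volumes.

Implements the measurements used to characterize the megakaryocyte (MK)
vascular niche: anisotropic Euclidean distance maps, MK–vessel and MK–bone
edge distances, vessel-to-vessel spacing through intervascular centers,
association classes, and virtual 2D sectioning.

Conventions (see :mod:`marrowniche.core`):

* "edge" distances are center-to-center distances between the nearest MK
  voxel and the nearest vessel (or bone) voxel, i.e. the vessel distance map
  evaluated on the MK's voxels and minimized;
* a cell is *vessel-associated* (VA) when that distance is at most the
  association threshold, 2.0 µm by default — the largest voxel extent, which
  unifies the 3D "within one voxel" rule with the 2D cryo-section "< 2 µm"
  rule;
* *bone-associated* (BA) means strictly less than 100 µm from the bone
  cortex;
* an MK is called *intravascular* when more than half of its voxels carry
  the vessel label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    LABEL_VESSEL,
    MKAnnotation,
    MKObject,
    VolumeGrid,
    _as_spacing,
)

#: Default VA threshold in µm (largest extent of the 0.5 x 0.5 x 2 µm voxel).
ASSOCIATION_THRESHOLD_UM = 2.0
#: Default BA threshold in µm (distance from the bone cortex).
BONE_THRESHOLD_UM = 100.0
#: Fraction of voxels inside the vessel lumen above which an MK is called
#: intravascular.
INTRAVASCULAR_FRACTION = 0.5

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def distance_map(mask: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance (µm) from every voxel center to the nearest mask voxel center.

    Values are 0 on mask voxels.  Raises ``ValueError`` on an empty mask, for
    which the distance is undefined.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = _as_spacing(mask.ndim * [1.0]) if spacing is None else _as_spacing(spacing)
    if not mask.any():
        raise ValueError("distance_map: mask is empty, distance undefined")
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def extract_mk_objects(grid: VolumeGrid) -> list[MKObject]:
    """One :class:`MKObject` per distinct id in ``grid.mk_ids``.

    Each object's voxel set must be 26-connected; ids whose voxels fall apart
    into several components are split into suffixed ids (``"7.1"``, ``"7.2"``,
    ...) with a warning.
    """
    ids = np.unique(grid.mk_ids)
    ids = ids[ids > 0]
    objects: list[MKObject] = []
    for mk_id in ids:
        mask = grid.mk_ids == mk_id
        labeled, n_comp = ndimage.label(mask, structure=_CONN26)
        if n_comp == 1:
            voxels = np.argwhere(mask)
            objects.append(MKObject.from_voxels(int(mk_id), voxels, grid.spacing))
        else:
            warnings.warn(
                f"MK id {int(mk_id)} has {n_comp} 26-connected components; "
                "splitting into suffixed ids",
                stacklevel=2,
            )
            for comp in range(1, n_comp + 1):
                voxels = np.argwhere(labeled == comp)
                objects.append(
                    MKObject.from_voxels(f"{int(mk_id)}.{comp}", voxels, grid.spacing)
                )
    return objects


def annotate_mk(
    mk: MKObject,
    vessel_map: np.ndarray | None,
    bone_map: np.ndarray | None,
    grid: VolumeGrid,
    *,
    association_threshold: float = ASSOCIATION_THRESHOLD_UM,
    bone_threshold: float = BONE_THRESHOLD_UM,
    intravascular_threshold: float = INTRAVASCULAR_FRACTION,
) -> MKAnnotation:
    """Classify one MK against the vessel and bone distance maps.

    ``vessel_map`` / ``bone_map`` must be computed with :func:`distance_map`
    on the same grid; pass ``None`` for a structure absent from the volume
    (the distance is then infinite and the class flag false).
    """
    voxels = mk.voxels
    if (voxels < 0).any() or (voxels >= np.asarray(grid.shape)).any():
        raise ValueError(f"MK {mk.id} has voxels outside the grid")
    idx = tuple(voxels.T)
    vessel_d = float(vessel_map[idx].min()) if vessel_map is not None else np.inf
    bone_d = float(bone_map[idx].min()) if bone_map is not None else np.inf
    intra_frac = float(np.mean(grid.labels[idx] == LABEL_VESSEL))
    return MKAnnotation(
        mk_id=mk.id,
        vessel_edge_distance=vessel_d,
        bone_edge_distance=bone_d,
        vessel_associated=bool(vessel_d <= association_threshold),
        bone_associated=bool(bone_d < bone_threshold),
        intravascular=bool(intra_frac > intravascular_threshold),
        intravascular_fraction=intra_frac,
    )


def annotate_population(
    grid: VolumeGrid,
    objects: list[MKObject] | None = None,
    *,
    association_threshold: float = ASSOCIATION_THRESHOLD_UM,
    bone_threshold: float = BONE_THRESHOLD_UM,
    vessel_map: np.ndarray | None = None,
    bone_map: np.ndarray | None = None,
) -> tuple[list[MKObject], list[MKAnnotation]]:
    """Extract (if needed) and annotate every MK of a grid, sharing distance maps."""
    if objects is None:
        objects = extract_mk_objects(grid)
    if vessel_map is None and grid.vessel_mask.any():
        vessel_map = distance_map(grid.vessel_mask, grid.spacing)
    if bone_map is None and grid.bone_mask.any():
        bone_map = distance_map(grid.bone_mask, grid.spacing)
    annotations = [
        annotate_mk(
            mk,
            vessel_map,
            bone_map,
            grid,
            association_threshold=association_threshold,
            bone_threshold=bone_threshold,
        )
        for mk in objects
    ]
    return objects, annotations


def vessel_to_vessel_distances(
    grid: VolumeGrid,
    *,
    merge_distance: float | None = None,
    vessel_map: np.ndarray | None = None,
) -> np.ndarray:
    """Edge-to-edge spacings (µm) between adjacent vessels.

    Finds local maxima (26-neighborhood, plateau-aware) of the vessel distance
    map restricted to non-vessel, non-bone space — the "centers between two
    adjacent vessels" — and returns twice the map value there.  Maxima closer
    than ``merge_distance`` (default: one voxel diagonal) are merged, keeping
    the largest value; maxima whose every voxel lies on the grid border are
    discarded, because spacing cannot be certified against structures outside
    the imaged volume.
    """
    if not grid.vessel_mask.any():
        raise ValueError("vessel_to_vessel_distances: no vessel voxels")
    if merge_distance is None:
        merge_distance = grid.voxel_diagonal
    if vessel_map is None:
        vessel_map = distance_map(grid.vessel_mask, grid.spacing)
    region = (grid.labels != LABEL_VESSEL) & ~grid.bone_mask

    local_max = ndimage.maximum_filter(vessel_map, size=3, mode="constant", cval=-1.0)
    candidates = (vessel_map >= local_max) & region & (vessel_map > 0)
    if not candidates.any():
        return np.empty(0)

    labeled, n_comp = ndimage.label(candidates, structure=_CONN26)
    shape = np.asarray(grid.shape)
    spacing = np.asarray(grid.spacing)

    reps = np.empty((n_comp, 3))
    values = np.empty(n_comp)
    interior = np.zeros(n_comp, dtype=bool)
    comp_voxels = ndimage.find_objects(labeled)
    for comp in range(1, n_comp + 1):
        sl = comp_voxels[comp - 1]
        sub = labeled[sl] == comp
        vox = np.argwhere(sub) + np.array([s.start for s in sl])
        vals = vessel_map[tuple(vox.T)]
        best = int(np.argmax(vals))
        reps[comp - 1] = vox[best] * spacing
        values[comp - 1] = vals[best]
        interior[comp - 1] = bool(((vox > 0) & (vox < shape - 1)).all(axis=1).any())

    # single-linkage merge of maxima closer than merge_distance
    parent = np.arange(n_comp)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    if n_comp > 1:
        from scipy.spatial import cKDTree

        pairs = cKDTree(reps).query_pairs(merge_distance, output_type="ndarray")
        for a, b in pairs:
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[rb] = ra

    roots = np.array([find(i) for i in range(n_comp)])
    out = []
    for root in np.unique(roots):
        members = roots == root
        if not interior[members].any():
            continue  # entirely on the border: cannot certify the spacing
        out.append(2.0 * values[members].max())
    return np.sort(np.asarray(out))


# -- population summaries -------------------------------------------------


@dataclass
class DistributionSummary:
    n: int
    mean: float
    median: float
    sd: float

    @classmethod
    def from_values(cls, values) -> "DistributionSummary":
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            return cls(0, np.nan, np.nan, np.nan)
        with np.errstate(invalid="ignore"):  # inf distances on vessel-free grids
            return cls(
                int(values.size),
                float(np.mean(values)),
                float(np.median(values)),
                float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
            )

    def to_dict(self) -> dict:
        return {"n": self.n, "mean": self.mean, "median": self.median, "sd": self.sd}


@dataclass
class SubgroupSummary:
    n: int
    va_fraction: float
    nva_distance: DistributionSummary
    diameter: DistributionSummary

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "va_fraction": self.va_fraction,
            "nva_distance": self.nva_distance.to_dict(),
            "diameter": self.diameter.to_dict(),
        }


@dataclass
class PopulationSummary:
    """Cohort-level readouts of an annotated MK population."""

    n_mks: int
    va_fraction: float
    intravascular_fraction: float
    vessel_distances: np.ndarray
    nva_distances: np.ndarray
    diameters: np.ndarray
    nva_distance: DistributionSummary = field(default=None)  # type: ignore[assignment]
    diameter: DistributionSummary = field(default=None)  # type: ignore[assignment]
    bone_associated: SubgroupSummary | None = None
    non_bone_associated: SubgroupSummary | None = None

    def to_dict(self) -> dict:
        return {
            "n_mks": self.n_mks,
            "va_fraction": self.va_fraction,
            "intravascular_fraction": self.intravascular_fraction,
            "nva_distance": self.nva_distance.to_dict(),
            "diameter": self.diameter.to_dict(),
            "bone_associated": self.bone_associated.to_dict()
            if self.bone_associated
            else None,
            "non_bone_associated": self.non_bone_associated.to_dict()
            if self.non_bone_associated
            else None,
        }


def _subgroup(annotations, objects) -> SubgroupSummary:
    va = [a.vessel_associated for a in annotations]
    nva_d = [a.vessel_edge_distance for a in annotations if not a.vessel_associated]
    diam = [o.equivalent_diameter_um for o in objects]
    return SubgroupSummary(
        n=len(annotations),
        va_fraction=float(np.mean(va)) if annotations else np.nan,
        nva_distance=DistributionSummary.from_values(nva_d),
        diameter=DistributionSummary.from_values(diam),
    )


def summarize_population(
    annotations: list[MKAnnotation], objects: list[MKObject]
) -> PopulationSummary:
    """VA fraction, NVA distances, diameters and BA/NBA subgroup readouts."""
    if not annotations:
        raise ValueError("summarize_population: no MKs")
    if len(annotations) != len(objects):
        raise ValueError("annotations and objects must align")
    vessel_d = np.array([a.vessel_edge_distance for a in annotations])
    va = np.array([a.vessel_associated for a in annotations])
    nva_d = vessel_d[~va]
    diameters = np.array([o.equivalent_diameter_um for o in objects])
    ba = np.array([a.bone_associated for a in annotations])
    has_bone = np.isfinite([a.bone_edge_distance for a in annotations]).any()
    pairs = list(zip(annotations, objects))
    return PopulationSummary(
        n_mks=len(annotations),
        va_fraction=float(va.mean()),
        intravascular_fraction=float(np.mean([a.intravascular for a in annotations])),
        vessel_distances=vessel_d,
        nva_distances=nva_d,
        diameters=diameters,
        nva_distance=DistributionSummary.from_values(nva_d),
        diameter=DistributionSummary.from_values(diameters),
        bone_associated=_subgroup(
            [a for a, _ in pairs if a.bone_associated],
            [o for a, o in pairs if a.bone_associated],
        )
        if has_bone
        else None,
        non_bone_associated=_subgroup(
            [a for a, _ in pairs if not a.bone_associated],
            [o for a, o in pairs if not a.bone_associated],
        )
        if has_bone
        else None,
    )


# -- virtual sectioning ---------------------------------------------------


@dataclass
class SectionMetrics:
    """Per-slab 2D readouts emulating a histological section.

    For every MK present in the slab, the in-plane vessel distance is the
    minimum over the slab's planes of the 2D distance between the MK's and the
    vessels' voxels *within the same plane* — vessels above or below the plane
    are invisible, so the 2D distance can only overestimate the 3D one.
    """

    slab_index: int
    axis: int
    mk_vessel_distance_2d: dict
    mk_diameter_2d: dict
    va_fraction_2d: float

    def to_dict(self) -> dict:
        return {
            "slab_index": self.slab_index,
            "axis": self.axis,
            "mk_vessel_distance_2d_um": {
                str(k): v for k, v in self.mk_vessel_distance_2d.items()
            },
            "mk_diameter_2d_um": {str(k): v for k, v in self.mk_diameter_2d.items()},
            "va_fraction_2d": self.va_fraction_2d,
        }


def virtual_slice_metrics(
    grid: VolumeGrid,
    annotations: list[MKAnnotation] | None = None,
    *,
    thickness: float,
    axis: int = 2,
    threshold_2d: float = ASSOCIATION_THRESHOLD_UM,
) -> list[SectionMetrics]:
    """Cut the volume into slabs and reanalyze each as a 2D section.

    The cryo-section association rule (strict ``< threshold_2d``) is applied to
    the in-plane distances.  ``thickness`` must be at least one voxel extent
    along ``axis``.
    """
    spacing = grid.spacing
    if thickness < spacing[axis]:
        raise ValueError("slab thickness smaller than one voxel extent along axis")
    t_vox = max(1, int(round(thickness / spacing[axis])))
    n_planes = grid.shape[axis]
    in_plane_axes = [a for a in range(3) if a != axis]
    in_plane_spacing = [spacing[a] for a in in_plane_axes]

    # per-(slab, mk) minimum of the per-plane 2D distances
    slab_dist: dict[tuple[int, object], float] = {}
    slab_area: dict[tuple[int, object], set] = {}

    vessel = grid.vessel_mask
    mk_ids = grid.mk_ids
    for p in range(n_planes):
        slab = p // t_vox
        v2d = np.take(vessel, p, axis=axis)
        m2d = np.take(mk_ids, p, axis=axis)
        if not m2d.any():
            continue
        if v2d.any():
            d2d = ndimage.distance_transform_edt(~v2d, sampling=in_plane_spacing)
        else:
            d2d = None
        for mk_id in np.unique(m2d):
            if mk_id == 0:
                continue
            where = m2d == mk_id
            dist = float(d2d[where].min()) if d2d is not None else np.inf
            key = (slab, int(mk_id))
            slab_dist[key] = min(dist, slab_dist.get(key, np.inf))
            slab_area.setdefault(key, set()).update(map(tuple, np.argwhere(where)))

    pixel_area = in_plane_spacing[0] * in_plane_spacing[1]
    out: list[SectionMetrics] = []
    for slab in range((n_planes + t_vox - 1) // t_vox):
        keys = [k for k in slab_dist if k[0] == slab]
        if not keys:
            continue
        dists = {k[1]: slab_dist[k] for k in sorted(keys, key=lambda k: str(k[1]))}
        diams = {
            k[1]: 2.0 * np.sqrt(len(slab_area[k]) * pixel_area / np.pi)
            for k in sorted(keys, key=lambda k: str(k[1]))
        }
        va2d = float(np.mean([d < threshold_2d for d in dists.values()]))
        out.append(
            SectionMetrics(
                slab_index=slab,
                axis=axis,
                mk_vessel_distance_2d=dists,
                mk_diameter_2d=diams,
                va_fraction_2d=va2d,
            )
        )
    return out


def pooled_slice_va_fraction(sections: list[SectionMetrics]) -> float:
    """VA fraction over all (slab, MK) cross-sections of a virtual sectioning."""
    flags = [
        d < ASSOCIATION_THRESHOLD_UM
        for sec in sections
        for d in sec.mk_vessel_distance_2d.values()
    ]
    if not flags:
        return np.nan
    return float(np.mean(flags))
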