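"""Shared containers for labeled marrow volumes and segmented megakaryocytes.

The coordinate convention used throughout the package:

* volume arrays are indexed ``(i, j, k)`` for the physical axes ``(x, y, z)``;
* voxel ``(i, j, k)`` has its *center* at ``(i * sx, j * sy, k * sz)`` in µm,
  where ``spacing = (sx, sy, sz)``;
* all distances are Euclidean distances in µm between voxel centers.

Labels: ``0`` marrow, ``1`` vessel, ``2`` bone.  Megakaryocytes (MKs) live in a
separate integer id array (``0`` = none).  MK ids may overlap the vessel label
(an intravascular cell) but never the bone label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

LABEL_MARROW = 0
LABEL_VESSEL = 1
LABEL_BONE = 2

LABEL_LEGEND = {"marrow": LABEL_MARROW, "vessel": LABEL_VESSEL, "bone": LABEL_BONE}


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3:
        raise ValueError("spacing must have 3 components")
    if any(v <= 0 for v in s):
        raise ValueError("spacing components must be > 0")
    return s


@dataclass
class VolumeGrid:
    """Anisotropic labeled 3D voxel volume (marrow / vessel / bone + MK ids)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    mk_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        self.spacing = _as_spacing(self.spacing)
        if self.mk_ids is None:
            self.mk_ids = np.zeros(self.labels.shape, dtype=np.int32)
        else:
            self.mk_ids = np.asarray(self.mk_ids)
        if self.mk_ids.shape != self.labels.shape:
            raise ValueError("mk_ids and labels must share shape")
        if np.any((self.mk_ids > 0) & (self.labels == LABEL_BONE)):
            raise ValueError("MK ids may not overlap the bone label")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in µm³."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voxel_diagonal(self) -> float:
        """Length of one voxel body diagonal in µm."""
        return float(np.linalg.norm(self.spacing))

    @property
    def vessel_mask(self) -> np.ndarray:
        return self.labels == LABEL_VESSEL

    @property
    def bone_mask(self) -> np.ndarray:
        return self.labels == LABEL_BONE

    @property
    def marrow_mask(self) -> np.ndarray:
        return self.labels == LABEL_MARROW

    def index_to_um(self, index) -> np.ndarray:
        """Physical center position(s) in µm of voxel index / index array."""
        return np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.labels.copy(), self.spacing, self.mk_ids.copy())


MKId = Union[int, str]


@dataclass
class MKObject:
    """One segmented or simulated megakaryocyte as a voxel set.

    ``voxels`` is an ``(n, 3)`` integer array of grid indices.  The equivalent
    diameter is that of the sphere with the same voxel volume,
    ``(6 V / π)^(1/3)``.
    """

    id: MKId
    voxels: np.ndarray
    centroid_um: np.ndarray
    volume_um3: float
    equivalent_diameter_um: float

    @classmethod
    def from_voxels(cls, mk_id: MKId, voxels: np.ndarray, spacing) -> "MKObject":
        voxels = np.atleast_2d(np.asarray(voxels, dtype=np.int64))
        if voxels.size == 0:
            raise ValueError("MK voxel set must be non-empty")
        spacing = np.asarray(_as_spacing(spacing))
        volume = voxels.shape[0] * float(np.prod(spacing))
        centroid = voxels.mean(axis=0) * spacing
        diameter = (6.0 * volume / np.pi) ** (1.0 / 3.0)
        return cls(mk_id, voxels, centroid, volume, diameter)


@dataclass
class MKAnnotation:
    """Distance- and class-annotations for one MK against vessel and bone."""

    mk_id: MKId
    vessel_edge_distance: float
    bone_edge_distance: float
    vessel_associated: bool
    bone_associated: bool
    intravascular: bool
    intravascular_fraction: float

    def to_dict(self) -> dict:
        return {
            "mk_id": self.mk_id,
            "vessel_edge_distance_um": self.vessel_edge_distance,
            "bone_edge_distance_um": self.bone_edge_distance,
            "vessel_associated": bool(self.vessel_associated),
            "bone_associated": bool(self.bone_associated),
            "intravascular": bool(self.intravascular),
            "intravascular_fraction": self.intravascular_fraction,
        }


# -- sphere rasterization -------------------------------------------------

_OFFSET_CACHE: dict = {}


def sphere_offsets(radius_um: float, spacing) -> np.ndarray:
    """Voxel index offsets whose centers lie within ``radius_um`` of a voxel center.

    The center voxel (offset 0,0,0) is always included, so even spheres smaller
    than one voxel rasterize to a non-empty set.
    """
    spacing = _as_spacing(spacing)
    key = (round(float(radius_um), 9), spacing)
    cached = _OFFSET_CACHE.get(key)
    if cached is not None:
        return cached
    half = [int(np.floor(radius_um / s)) for s in spacing]
    ax = [np.arange(-h, h + 1) for h in half]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    d2 = (gx * spacing[0]) ** 2 + (gy * spacing[1]) ** 2 + (gz * spacing[2]) ** 2
    keep = d2 <= radius_um**2 + 1e-9
    offsets = np.stack([gx[keep], gy[keep], gz[keep]], axis=1).astype(np.int64)
    if len(_OFFSET_CACHE) > 256:
        _OFFSET_CACHE.clear()
    _OFFSET_CACHE[key] = offsets
    return offsets


def sphere_voxels(
    center_index, radius_um: float, spacing, shape
) -> np.ndarray | None:
    """Grid indices of a rasterized sphere, or ``None`` if it leaves the grid."""
    center_index = np.asarray(center_index, dtype=np.int64)
    offsets = sphere_offsets(radius_um, spacing)
    voxels = offsets + center_index
    if (voxels < 0).any() or (voxels >= np.asarray(shape)).any():
        return None
    return voxels
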