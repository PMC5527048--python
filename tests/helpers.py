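"""Independent oracles and fixture geometries shared across the test suite.

The oracles here deliberately avoid the code paths they check: the distance
oracle is a pairwise minimum over mask voxels, the MSD oracle an explicit
double loop, and the cylinder/sheet scaffolds are built directly from
coordinate arithmetic rather than via the package's rasterizer.
"""

from __future__ import annotations

import numpy as np

from marrowniche.core import LABEL_MARROW, LABEL_VESSEL, VolumeGrid


def brute_force_distance_map(mask: np.ndarray, spacing) -> np.ndarray:
    """Min-over-all-pairs Euclidean distance to the nearest mask voxel center."""
    spacing = np.asarray(spacing, dtype=float)
    pts = np.argwhere(mask) * spacing
    grids = np.meshgrid(*[np.arange(s) for s in mask.shape], indexing="ij")
    centers = np.stack(grids, axis=-1).reshape(-1, 3) * spacing
    d2 = np.full(centers.shape[0], np.inf)
    for chunk in np.array_split(np.arange(pts.shape[0]), max(1, pts.shape[0] // 256)):
        d2 = np.minimum(d2, ((centers[:, None, :] - pts[chunk][None, :, :]) ** 2).sum(-1).min(1))
    return np.sqrt(d2).reshape(mask.shape)


def brute_force_msd(positions: np.ndarray, dt: float, max_lag: int):
    """Time-averaged MSD by an explicit double loop over (start, lag) pairs."""
    n = positions.shape[0]
    taus, msds, pairs = [], [], []
    for k in range(1, max_lag + 1):
        total, count = 0.0, 0
        for i in range(n - k):
            diff = positions[i + k] - positions[i]
            total += float(diff @ diff)
            count += 1
        taus.append(k * dt)
        msds.append(total / count)
        pairs.append(count)
    return np.array(taus), np.array(msds), np.array(pairs)


def make_cylinder_grid(
    shape=(240, 240, 20),
    spacing=(0.5, 0.5, 2.0),
    radius: float = 10.0,
    center=(60.0, 60.0),
) -> VolumeGrid:
    """A single straight vessel cylinder along z in an otherwise empty marrow box."""
    x = np.arange(shape[0]) * spacing[0]
    y = np.arange(shape[1]) * spacing[1]
    rho2 = (x[:, None] - center[0]) ** 2 + (y[None, :] - center[1]) ** 2
    labels = np.zeros(shape, dtype=np.uint8)
    labels[rho2 <= radius**2] = LABEL_VESSEL
    return VolumeGrid(labels, spacing)


def make_sheets_grid(
    gap_um: float = 40.0,
    spacing=(0.5, 0.5, 2.0),
    cross=(80, 80, 20),
) -> VolumeGrid:
    """Two parallel vessel sheets (planes perpendicular to x) a fixed gap apart."""
    sx = spacing[0]
    first = 20
    second = first + int(round(gap_um / sx))
    shape = (second + first + 1, cross[1], cross[2])
    labels = np.full(shape, LABEL_MARROW, dtype=np.uint8)
    labels[first] = LABEL_VESSEL
    labels[second] = LABEL_VESSEL
    return VolumeGrid(labels, spacing)
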