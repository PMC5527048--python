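import numpy as np
import pytest
from scipy import ndimage

from marrowniche.core import (
    LABEL_BONE,
    LABEL_MARROW,
    LABEL_VESSEL,
    MKObject,
    VolumeGrid,
    sphere_voxels,
)
from marrowniche.spatial_metrics import (
    annotate_mk,
    annotate_population,
    distance_map,
    extract_mk_objects,
    summarize_population,
    vessel_to_vessel_distances,
    virtual_slice_metrics,
)

from helpers import brute_force_distance_map, make_cylinder_grid, make_sheets_grid

SPACING = (0.5, 0.5, 2.0)


class TestDistanceMap:
    def test_anisotropic_neighbor_distances(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        d = distance_map(mask, SPACING)
        assert d[2, 2, 2] == 0.0
        assert d[3, 2, 2] == 0.5  # x neighbor
        assert d[2, 3, 2] == 0.5  # y neighbor
        assert d[2, 2, 3] == 2.0  # z neighbor

    def test_zero_on_mask_voxels(self, rng):
        mask = rng.random((10, 10, 6)) < 0.2
        d = distance_map(mask, SPACING)
        assert (d[mask] == 0).all()
        assert (d[~mask] > 0).all()

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            distance_map(np.zeros((4, 4, 4), dtype=bool), SPACING)

    def test_matches_bruteforce_exactly(self, rng):
        for _ in range(5):
            shape = tuple(rng.integers(4, hi) for hi in (21, 21, 11))
            mask = rng.random(shape) < 0.05
            if not mask.any():
                mask[tuple(rng.integers(0, s) for s in shape)] = True
            assert np.array_equal(
                distance_map(mask, SPACING), brute_force_distance_map(mask, SPACING)
            )

    def test_mirror_symmetry(self, rng):
        mask = rng.random((12, 10, 8)) < 0.1
        mask[0, 0, 0] = True
        d = distance_map(mask, SPACING)
        for axis in range(3):
            flipped = distance_map(np.flip(mask, axis=axis), SPACING)
            assert np.allclose(np.flip(d, axis=axis), flipped)


class TestExtractObjects:
    def test_blob_volume_and_diameter(self):
        grid = VolumeGrid(np.zeros((6, 6, 6), dtype=np.uint8), SPACING)
        grid.mk_ids[1, 1, 1] = 3
        grid.mk_ids[2, 1, 1] = 3
        grid.mk_ids[1, 2, 1] = 3
        grid.mk_ids[2, 2, 1] = 3
        grid.mk_ids[2, 2, 2] = 3
        (obj,) = extract_mk_objects(grid)
        assert obj.id == 3
        assert obj.volume_um3 == pytest.approx(5 * 0.5 * 0.5 * 2.0)
        assert obj.equivalent_diameter_um == pytest.approx((6 * 2.5 / np.pi) ** (1 / 3))

    def test_empty_id_array(self):
        grid = VolumeGrid(np.zeros((4, 4, 4), dtype=np.uint8), SPACING)
        assert extract_mk_objects(grid) == []

    def test_touching_distinct_ids_stay_separate(self):
        grid = VolumeGrid(np.zeros((4, 4, 4), dtype=np.uint8), SPACING)
        grid.mk_ids[1, 1, 1] = 1
        grid.mk_ids[2, 1, 1] = 2  # face-sharing but different ids
        objs = extract_mk_objects(grid)
        assert [o.id for o in objs] == [1, 2]

    def test_disconnected_id_splits_with_warning(self):
        grid = VolumeGrid(np.zeros((8, 4, 4), dtype=np.uint8), SPACING)
        grid.mk_ids[0, 0, 0] = 5
        grid.mk_ids[6, 2, 2] = 5
        with pytest.warns(UserWarning, match="components"):
            objs = extract_mk_objects(grid)
        assert sorted(o.id for o in objs) == ["5.1", "5.2"]

    def test_volume_conservation(self, paper_volume):
        grid, objects = paper_volume.grid, paper_volume.objects
        assert int((grid.mk_ids > 0).sum()) == sum(o.voxels.shape[0] for o in objects)


class TestAnnotate:
    def _grid_with_vessel_plane(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels[0] = LABEL_VESSEL
        return VolumeGrid(labels, SPACING)

    def test_face_contact_is_vessel_associated(self):
        grid = self._grid_with_vessel_plane()
        grid.mk_ids[1, 5, 5] = 1
        objs, anns = annotate_population(grid)
        assert anns[0].vessel_edge_distance == 0.5
        assert anns[0].vessel_associated

    def test_intravascular_mk(self):
        labels = np.full((6, 6, 6), LABEL_VESSEL, dtype=np.uint8)
        grid = VolumeGrid(labels, SPACING)
        grid.mk_ids[2:4, 2:4, 2:4] = 1
        objs, anns = annotate_population(grid)
        assert anns[0].intravascular_fraction == 1.0
        assert anns[0].intravascular

    def test_mk_outside_grid_is_an_error(self):
        grid = self._grid_with_vessel_plane()
        mk = MKObject.from_voxels(1, np.array([[20, 0, 0]]), SPACING)
        vm = distance_map(grid.vessel_mask, grid.spacing)
        with pytest.raises(ValueError, match="outside"):
            annotate_mk(mk, vm, None, grid)

    def test_sphere_to_cylinder_distance(self):
        # sphere (r = 10 µm) centered 40 µm from the axis of a cylinder
        # (r = 10 µm): edge-to-edge distance is 20 µm up to one voxel diagonal
        grid = make_cylinder_grid(shape=(240, 160, 30), radius=10.0, center=(40.0, 40.0))
        center_idx = (int(80 / 0.5), int(40 / 0.5), 15)  # 40 µm right of the axis
        voxels = sphere_voxels(center_idx, 10.0, grid.spacing, grid.shape)
        grid.mk_ids[tuple(voxels.T)] = 1
        objs, anns = annotate_population(grid)
        assert anns[0].vessel_edge_distance == pytest.approx(20.0, abs=grid.voxel_diagonal)

    def test_bone_association_threshold_is_exact(self):
        labels = np.zeros((300, 8, 8), dtype=np.uint8)
        labels[0] = LABEL_BONE
        grid = VolumeGrid(labels, SPACING)
        # centers at 99.5 µm (index 199) and 100.0 µm (index 200) from the cortex
        grid.mk_ids[199, 3, 3] = 1
        grid.mk_ids[200, 5, 5] = 2
        objs, anns = annotate_population(grid)
        by_id = {a.mk_id: a for a in anns}
        assert by_id[1].bone_associated  # 99.5 < 100
        assert not by_id[2].bone_associated  # 100.0 is not < 100

    def test_dilating_vessels_never_increases_distances(self, rng):
        labels = np.zeros((24, 24, 12), dtype=np.uint8)
        labels[rng.random(labels.shape) < 0.05] = LABEL_VESSEL
        grid = VolumeGrid(labels, SPACING)
        free = np.argwhere(labels == LABEL_MARROW)
        for mk_id, row in enumerate(free[rng.choice(len(free), 5, replace=False)], 1):
            grid.mk_ids[tuple(row)] = mk_id
        objs, anns = annotate_population(grid)

        dilated = ndimage.binary_dilation(grid.vessel_mask, np.ones((3, 3, 3)))
        dilated_labels = np.where(dilated, LABEL_VESSEL, LABEL_MARROW).astype(np.uint8)
        dilated_labels[grid.mk_ids > 0] = LABEL_MARROW
        grid2 = VolumeGrid(dilated_labels, SPACING, grid.mk_ids)
        objs2, anns2 = annotate_population(grid2)
        for a, b in zip(anns, anns2):
            assert b.vessel_edge_distance <= a.vessel_edge_distance + 1e-12

    def test_annotation_biconditionals(self, paper_volume):
        for a in paper_volume.annotations:
            assert a.vessel_associated == (a.vessel_edge_distance <= 2.0)
            assert a.bone_associated == (a.bone_edge_distance < 100.0)
            assert a.vessel_edge_distance >= 0 and a.bone_edge_distance >= 0


class TestVesselToVessel:
    def test_parallel_sheets_spacing(self):
        grid = make_sheets_grid(gap_um=40.0)
        spacings = vessel_to_vessel_distances(grid)
        assert spacings.size > 0
        assert np.all(np.abs(spacings - 40.0) <= grid.voxel_diagonal)

    def test_single_sheet_has_no_interior_maximum(self):
        grid = make_sheets_grid(gap_um=40.0)
        labels = grid.labels.copy()
        labels[labels == LABEL_VESSEL] = LABEL_MARROW
        labels[20] = LABEL_VESSEL  # keep only one sheet
        single = VolumeGrid(labels, grid.spacing)
        assert vessel_to_vessel_distances(single).size == 0

    def test_no_vessels_is_an_error(self):
        grid = VolumeGrid(np.zeros((6, 6, 6), dtype=np.uint8), SPACING)
        with pytest.raises(ValueError, match="vessel"):
            vessel_to_vessel_distances(grid)

    def test_scaffold_median_matches_target(self, paper_volume):
        spacings = vessel_to_vessel_distances(
            paper_volume.grid, vessel_map=paper_volume.vessel_map
        )
        assert 32.0 <= np.median(spacings) <= 54.0


class TestSummarize:
    def test_all_va_population(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels[0] = LABEL_VESSEL
        grid = VolumeGrid(labels, SPACING)
        grid.mk_ids[1, 2, 2] = 1
        grid.mk_ids[1, 7, 7] = 2
        objs, anns = annotate_population(grid)
        summary = summarize_population(anns, objs)
        assert summary.va_fraction == 1.0
        assert summary.nva_distances.size == 0

    def test_biased_population_va_fraction(self, paper_volume):
        assert paper_volume.observed.va_fraction >= paper_volume.config.vessel_bias

    def test_ba_nba_split_respects_threshold(self, paper_volume):
        s = paper_volume.observed
        ba = [a for a in paper_volume.annotations if a.bone_edge_distance < 100.0]
        assert s.bone_associated.n == len(ba)
        assert s.bone_associated.n + s.non_bone_associated.n == s.n_mks


class TestVirtualSlicing:
    def _coplanar_grid(self):
        labels = np.zeros((40, 40, 10), dtype=np.uint8)
        labels[4, :, :] = LABEL_VESSEL
        grid = VolumeGrid(labels, SPACING)
        grid.mk_ids[10, 20, 3] = 1  # same plane set as the vessel sheet
        return grid

    def test_coplanar_2d_equals_3d(self):
        grid = self._coplanar_grid()
        objs, anns = annotate_population(grid)
        sections = virtual_slice_metrics(grid, anns, thickness=10.0, axis=2)
        d2 = [s.mk_vessel_distance_2d.get(1) for s in sections if 1 in s.mk_vessel_distance_2d]
        assert min(d2) == pytest.approx(anns[0].vessel_edge_distance)

    def test_out_of_slab_vessel_is_missed(self):
        labels = np.zeros((20, 20, 12), dtype=np.uint8)
        labels[:, :, 11] = LABEL_VESSEL  # vessel only in the top planes
        grid = VolumeGrid(labels, SPACING)
        grid.mk_ids[10, 10, 1] = 1
        objs, anns = annotate_population(grid)
        sections = virtual_slice_metrics(grid, anns, thickness=10.0, axis=2)
        bottom = [s for s in sections if 1 in s.mk_vessel_distance_2d][0]
        assert bottom.mk_vessel_distance_2d[1] > anns[0].vessel_edge_distance
        assert np.isinf(bottom.mk_vessel_distance_2d[1])

    def test_2d_distance_never_below_3d(self, paper_volume):
        sections = virtual_slice_metrics(
            paper_volume.grid, paper_volume.annotations, thickness=10.0, axis=2
        )
        d3 = {a.mk_id: a.vessel_edge_distance for a in paper_volume.annotations}
        for sec in sections:
            for mk_id, d2 in sec.mk_vessel_distance_2d.items():
                assert d2 >= d3[mk_id] - 1e-9

    def test_too_thin_slab_is_an_error(self):
        grid = self._coplanar_grid()
        with pytest.raises(ValueError, match="thickness"):
            virtual_slice_metrics(grid, thickness=1.0, axis=2)
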