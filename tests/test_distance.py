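import math

import numpy as np
import pytest

from lhseg.distance import (
    DistanceRecord,
    SurfacePointSet,
    convert_to_um,
    euclidean_anisotropic,
    extract_surface,
    measure_distances,
    min_distance,
)
from lhseg.stack import ChannelRole, VoxelSpacing
from lhseg.zlink import objects_from_label_volume

from .oracles import min_surface_distance_brute, random_blob_volume


def _objects(labels):
    return objects_from_label_volume(labels)


class TestExtractSurface:
    def test_single_voxel(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[1, 1, 1] = 1
        sps = extract_surface(_objects(labels)[0])
        assert sps.points.tolist() == [[1, 1, 1]]

    def test_solid_cube_has_26_surface_voxels(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[1:4, 1:4, 1:4] = 1
        sps = extract_surface(_objects(labels)[0])
        assert len(sps.points) == 26  # 27 voxels minus the interior one

    def test_thin_sheet_is_all_surface(self):
        labels = np.zeros((3, 6, 6), dtype=np.int32)
        labels[1] = 1
        sps = extract_surface(_objects(labels)[0])
        assert len(sps.points) == 36


class TestAnisotropicDistance:
    def test_coincident_points(self):
        assert euclidean_anisotropic((3, 4, 5), (3, 4, 5), sd=2.5) == 0.0

    @pytest.mark.parametrize("sd", [0.5, 1.0, 5.0])
    def test_planar_345(self, sd):
        assert euclidean_anisotropic((0, 0, 0), (3, 4, 0), sd) == pytest.approx(5.0)

    def test_pure_z_scales_with_sd(self):
        assert euclidean_anisotropic((0, 0, 0), (0, 0, 2), sd=2.0) == pytest.approx(4.0)

    def test_invalid_sd(self):
        with pytest.raises(ValueError):
            euclidean_anisotropic((0, 0, 0), (1, 1, 1), sd=0)


def _sps(points, oid=0, cls=ChannelRole.OSTEOBLAST):
    return SurfacePointSet(object_id=oid, points=np.array(points), object_class=cls)


class TestMinDistance:
    def test_single_point_pair(self):
        rec = min_distance(_sps([(0, 0, 0)], 0), [_sps([(10, 0, 0)], 1)], sd=1.0)
        assert rec.distance_px == pytest.approx(10.0)
        assert rec.hsc_point == (0, 0, 0)
        assert rec.target_point == (10, 0, 0)

    def test_nearest_target_object_wins(self):
        far = _sps([(10, 0, 0)], 1)
        near = _sps([(6, 0, 0)], 2)
        rec = min_distance(_sps([(0, 0, 0)], 0), [far, near], sd=1.0)
        assert rec.distance_px == pytest.approx(6.0)
        assert rec.target_object_id == 2

    def test_touching_objects_give_exact_zero(self):
        a = _sps([(5, 5, 2)], 0)
        b = _sps([(5, 5, 3)], 1)  # face-adjacent in z
        rec = min_distance(a, [b], sd=3.0)
        assert rec.distance_px == 0.0

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            min_distance(_sps([(0, 0, 0)]), [], sd=1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_bruteforce_on_random_point_sets(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 20, (rng.integers(3, 15), 3))
        b = rng.integers(15, 32, (rng.integers(3, 15), 3))
        sd = float(rng.uniform(0.5, 4.0))
        rec = min_distance(_sps(a, 0), [_sps(b, 1)], sd)
        expected = min_surface_distance_brute(a, b, sd)
        touching = rec.distance_px == 0.0
        if not touching:
            assert rec.distance_px == pytest.approx(expected)
        else:
            assert expected <= max(1.0, sd) + 1e-9

    def test_symmetry_between_objects(self):
        rng = np.random.default_rng(11)
        a = _sps(rng.integers(0, 10, (8, 3)), 0)
        b = _sps(rng.integers(12, 24, (9, 3)), 1)
        d_ab = min_distance(a, [b], sd=2.0).distance_px
        d_ba = min_distance(b, [a], sd=2.0).distance_px
        assert d_ab == pytest.approx(d_ba)


class TestConvertToUm:
    def _rec(self, px):
        return DistanceRecord(
            hsc_id=0, target_class=ChannelRole.BONE, distance_px=px,
            distance_um=None, hsc_point=(0, 0, 0), target_point=(0, 0, 0),
            target_object_id=0,
        )

    def test_scaling(self):
        rec = convert_to_um(self._rec(10.0), VoxelSpacing(0.5, 0.5, 2.0))
        assert rec.distance_um == pytest.approx(5.0)

    def test_zero_stays_zero(self):
        assert convert_to_um(self._rec(0.0), VoxelSpacing(0.5, 0.5, 2.0)).distance_um == 0.0

    def test_z_step_fixture(self):
        # two voxels apart in z only, 3 um slices, 1 um pixels:
        # pixel-unit distance 2 * (3/1) = 6 -> 6 um
        sp = VoxelSpacing(1.0, 1.0, 3.0)
        rec = min_distance(
            _sps([(4, 4, 0)], 0), [_sps([(4, 4, 2)], 1)], sd=sp.z_factor
        )
        assert convert_to_um(rec, sp).distance_um == pytest.approx(6.0)

    def test_anisotropic_inplane_rejected(self):
        with pytest.raises(ValueError):
            convert_to_um(self._rec(1.0), VoxelSpacing(0.5, 0.6, 2.0))


class TestMeasureDistances:
    def test_missing_target_class_yields_unreachable_record(self):
        labels = np.zeros((3, 8, 8), dtype=np.int32)
        labels[1, 2:4, 2:4] = 1
        cells = _objects(labels)
        recs = measure_distances(
            cells, {ChannelRole.BONE: []}, VoxelSpacing(1, 1, 2)
        )
        assert len(recs) == 1
        assert not recs[0].reachable

    def test_volume_fixture_distance(self):
        labels = np.zeros((1, 5, 12), dtype=np.int32)
        labels[0, 2, 1] = 1
        labels[0, 2, 9] = 2
        objs = _objects(labels)
        cells, targets = [objs[0]], {ChannelRole.BONE: [objs[1]]}
        recs = measure_distances(cells, targets, VoxelSpacing(0.5, 0.5, 1.0))
        assert recs[0].distance_px == pytest.approx(8.0)
        assert recs[0].distance_um == pytest.approx(4.0)
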