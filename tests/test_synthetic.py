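import numpy as np
import pytest
from scipy.spatial.distance import cdist

from lhseg.features import compute_features
from lhseg.stack import ChannelRole, VoxelSpacing
from lhseg.synthetic import (
    SceneSpec,
    brute_force_surface_distance_um,
    generate_object_set,
    generate_scene,
    generate_training_archetypes,
    render_single_object,
)
from lhseg.zlink import objects_from_label_volume


class TestGenerateScene:
    def test_same_spec_is_bit_identical(self):
        s1, t1 = generate_scene(SceneSpec(seed=5))
        s2, t2 = generate_scene(SceneSpec(seed=5))
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(t1.did_labels, t2.did_labels)
        assert t1.table.equals(t2.table)

    def test_different_seeds_differ(self):
        s1, _ = generate_scene(SceneSpec(seed=5))
        s2, _ = generate_scene(SceneSpec(seed=6))
        assert not np.array_equal(s1.data, s2.data)

    def test_truth_classes_are_disjoint(self, scene3):
        _, truth = scene3
        did = truth.did_labels > 0
        ob = truth.osteoblast_labels > 0
        bone = truth.bone_labels > 0
        assert not (did & ob).any()
        assert not (did & bone).any()
        assert not (ob & bone).any()

    def test_object_counts_match_spec(self, scene3):
        _, truth = scene3
        spec = SceneSpec(seed=3)
        counts = truth.table["class"].value_counts()
        assert counts.get("HSC1", 0) == spec.n_hsc1
        assert counts.get("HSC2", 0) == spec.n_hsc2
        assert counts.get("FALSE", 0) == spec.n_debris

    def test_empty_scene_is_pure_noise(self):
        spec = SceneSpec(
            seed=2, n_hsc1=0, n_hsc2=0, n_debris=0,
            n_osteoblast_clusters=0, bone_thickness_px=0, n_bone_cavities=0,
        )
        stack, truth = generate_scene(spec)
        assert truth.table.empty
        assert truth.did_labels.max() == 0
        did = stack.channel(ChannelRole.DID).astype(float)
        assert did.std() > 0  # noise present
        assert did.mean() < 20

    def test_depth_attenuation_dims_deep_slices(self):
        spec = SceneSpec(seed=2, attenuation_per_um=0.05, noise_sd=0.5)
        stack, truth = generate_scene(spec)
        shg = stack.channel(ChannelRole.BONE).astype(float)
        bone = truth.bone_labels > 0
        top = shg[0][bone[0]].mean()
        bottom = shg[-1][bone[-1]].mean()
        assert bottom < 0.7 * top

    def test_truth_distances_match_independent_recomputation(self, scene3):
        _, truth = scene3
        spacing = SceneSpec(seed=3).spacing
        row = truth.table[truth.table["class"] == "HSC1"].iloc[0]
        cell = truth.did_labels == row.object_id
        bone = truth.bone_labels > 0
        # independent check with cdist over surface voxels
        from lhseg.synthetic import _surface_voxels

        sa = _surface_voxels(cell) * [spacing.z_factor, 1, 1]
        sb = _surface_voxels(bone) * [spacing.z_factor, 1, 1]
        expected = cdist(sa, sb).min() * spacing.dx
        assert row.dist_bone_um == pytest.approx(expected)

    def test_touching_pair_has_zero_truth_distance(self, touching_scene):
        _, truth = touching_scene
        assert (truth.table.dist_osteoblast_um == 0).any()

    def test_brute_force_distance_on_known_fixture(self):
        sp = VoxelSpacing(1.0, 1.0, 2.0)
        a = np.zeros((3, 8, 8), bool)
        b = np.zeros((3, 8, 8), bool)
        a[1, 2, 1] = True
        b[1, 2, 6] = True
        assert brute_force_surface_distance_um(a, b, sp) == pytest.approx(5.0)
        b2 = np.zeros((3, 8, 8), bool)
        b2[1, 2, 2] = True  # face-adjacent
        assert brute_force_surface_distance_um(a, b2, sp) == 0.0


class TestSingleObjects:
    def test_class_shapes_are_separable_by_features(self):
        """Rendered round cells must score rounder and less protrusive
        than rendered debris -- the precondition for classification."""
        sph = {"HSC1": [], "FALSE": []}
        prot = {"HSC1": [], "FALSE": []}
        for kind, stack, mask in generate_object_set(0, 5, 0, 5):
            obj = objects_from_label_volume(
                mask.astype(np.int32), stack.channel(ChannelRole.DID),
                ChannelRole.DID,
            )[0]
            f = compute_features(obj, stack)
            sph[kind].append(f["sphericity"])
            prot[kind].append(f["max_protrusion_ratio"])
        assert min(sph["HSC1"]) > max(sph["FALSE"])
        assert max(prot["HSC1"]) < min(prot["FALSE"])

    def test_debris_protrusions_exceed_diameter(self):
        for kind, stack, mask in generate_object_set(3, 0, 0, 6):
            obj = objects_from_label_volume(
                mask.astype(np.int32), stack.channel(ChannelRole.DID),
                ChannelRole.DID,
            )[0]
            f = compute_features(obj, stack)
            assert f["max_protrusion_ratio"] > 0.75

    def test_archetype_counts(self):
        items = generate_training_archetypes(0)
        from collections import Counter

        counts = Counter(kind for kind, *_ in items)
        assert counts == {"HSC1": 2, "HSC2": 5, "FALSE": 11}

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            render_single_object("BLOB", seed=0)


class TestBenchmarkSuite:
    def test_suite_spans_acquisition_conditions(self, suite):
        assert len(suite) == 10
        steps = sorted(stack.spacing.sd for stack, _ in suite)
        assert steps[0] < 2.0 and steps[-1] > 3.5
        for stack, truth in suite:
            assert stack.n_channels == 3
            assert not ((truth.did_labels > 0) & (truth.bone_labels > 0)).any()
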