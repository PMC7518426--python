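"""Phantom generation, rupture injection, and continuity weight maps."""

import math

import numpy as np
import pytest
from scipy import ndimage

from angioseg.phantom import (CONNECTIVITY_26, GenerationError, PhantomSpec,
                              RuptureSpec, VESSEL_CLASSES,
                              count_vessel_components, generate_phantom,
                              inject_ruptures, make_toy_tube,
                              vessel_weight_map)


@pytest.fixture(scope="module")
def phantom():
    return generate_phantom(PhantomSpec(seed=11))


class TestGeneration:
    def test_same_seed_is_bit_identical(self):
        a = generate_phantom(PhantomSpec(seed=3))
        b = generate_phantom(PhantomSpec(seed=3))
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)

    def test_different_seeds_differ(self):
        a = generate_phantom(PhantomSpec(seed=3))
        b = generate_phantom(PhantomSpec(seed=4))
        assert not np.array_equal(a[0].data, b[0].data)

    def test_all_four_foreground_classes_present(self, phantom):
        _, lab, _ = phantom
        assert set(np.unique(lab.data)) == {0, 1, 2, 3, 4}

    def test_noiseless_intensities_are_exact_class_means(self):
        spec = PhantomSpec(seed=5, noise_sigma=0.0)
        vol, lab, _ = generate_phantom(spec)
        assert set(np.unique(vol.data)) == {spec.background_intensity,
                                            spec.vessel_intensity,
                                            spec.bone_intensity}
        vessels = np.isin(lab.data, VESSEL_CLASSES)
        assert (vol.data[vessels] == spec.vessel_intensity).all()
        assert (vol.data[lab.data == 1] == spec.bone_intensity).all()

    def test_vessel_union_single_connected_component(self, phantom):
        _, lab, _ = phantom
        assert count_vessel_components(lab) == 1

    def test_region_bands_partition_vessel_classes(self, phantom):
        _, lab, _ = phantom
        spec = PhantomSpec()
        z1 = int(lab.shape[0] * spec.region_z_fractions[0])
        z2 = int(lab.shape[0] * spec.region_z_fractions[1])
        zs = np.nonzero(lab.data == 2)[0]
        assert zs.max() < z1  # aorta below the first cut
        zs = np.nonzero(lab.data == 4)[0]
        assert zs.min() >= z2  # intracranial above the second cut

    def test_too_small_shape_rejected(self):
        with pytest.raises(GenerationError):
            generate_phantom(PhantomSpec(shape=(16, 16, 16)))

    def test_bone_and_vessel_disjoint(self, phantom):
        _, lab, _ = phantom
        assert ((lab.data == 1) & np.isin(lab.data, VESSEL_CLASSES)).sum() == 0

    def test_spec_invariants_enforced(self):
        with pytest.raises(ValueError):
            PhantomSpec(region_z_fractions=(0.7, 0.3))
        with pytest.raises(ValueError):
            PhantomSpec(bone_intensity=100.0, vessel_intensity=250.0)


class TestRuptures:
    def test_zero_ruptures_label_unchanged(self, phantom):
        _, lab, branches = phantom
        out, record = inject_ruptures(lab, branches, RuptureSpec(count=0))
        np.testing.assert_array_equal(out.data, lab.data)
        assert record.gaps == []

    def test_single_gap_severs_straight_tube(self):
        lab, branch = make_toy_tube(length=24, radius=1.5)
        out, record = inject_ruptures(lab, [branch], RuptureSpec(count=1, seed=2))
        # independent oracle: 26-connected component labeling
        _, n_before = ndimage.label(lab.data > 0, structure=CONNECTIVITY_26)[1], 1
        _, n_after = ndimage.label(out.data > 0, structure=CONNECTIVITY_26)
        assert n_after == 2
        assert record.n_effective == 1

    def test_removed_voxels_were_vessel_labelled(self, phantom):
        _, lab, branches = phantom
        out, record = inject_ruptures(lab, branches, RuptureSpec(count=3, seed=9))
        vox = record.removed_voxels()
        assert len(vox) > 0
        before = lab.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        assert np.isin(before, VESSEL_CLASSES).all()
        after = out.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        assert (after == 0).all()

    def test_component_count_increases_by_effective_gaps(self, phantom):
        _, lab, branches = phantom
        out, record = inject_ruptures(lab, branches, RuptureSpec(count=3, seed=9))
        assert count_vessel_components(out) == 1 + record.n_effective

    def test_gap_interior_to_volume(self, phantom):
        _, lab, branches = phantom
        out, record = inject_ruptures(lab, branches, RuptureSpec(count=2, seed=1))
        vox = record.removed_voxels()
        for axis, dim in enumerate(lab.shape):
            assert vox[:, axis].min() > 0
            assert vox[:, axis].max() < dim - 1

    def test_too_many_gaps_rejected(self):
        lab, branch = make_toy_tube()
        with pytest.raises(ValueError):
            inject_ruptures(lab, [branch], RuptureSpec(count=5))


class TestWeightMap:
    def test_zero_decay_gives_uniform_weights(self, phantom):
        _, lab, branches = phantom
        w = vessel_weight_map(lab, branches, decay=0.0)
        vessel = np.isin(lab.data, VESSEL_CLASSES)
        assert (w[vessel] == 1.0).all()
        assert (w[~vessel] == 0.0).all()

    def test_weights_positive_on_vessel_zero_elsewhere(self, phantom):
        _, lab, branches = phantom
        w = vessel_weight_map(lab, branches, decay=0.1)
        vessel = np.isin(lab.data, VESSEL_CLASSES)
        assert (w[vessel] > 0).all()
        assert (w[~vessel] == 0).all()

    def test_weight_decreases_with_distance_from_root(self):
        lab, branch = make_toy_tube(length=24, radius=1.5)
        root = branch.points[0]
        w = vessel_weight_map(lab, [branch], root_point=root, decay=0.3)
        z0 = int(round(root[0]))
        yc, xc = int(round(root[1])), int(round(root[2]))
        profile = [w[z, yc, xc] for z in range(z0, z0 + 20)]
        assert all(a >= b for a, b in zip(profile, profile[1:]))
        assert profile[0] > profile[-1]

    def test_exponential_decay_matches_hand_computation(self):
        lab, branch = make_toy_tube(length=20, radius=1.2)
        root = branch.points[0]
        decay = 1.0
        w = vessel_weight_map(lab, [branch], root_point=root, decay=decay)
        z0 = int(round(root[0]))
        yc, xc = int(round(root[1])), int(round(root[2]))
        # straight tube: geodesic distance of a centerline voxel == z offset
        for d in (0, 5, 10):
            assert w[z0 + d, yc, xc] == pytest.approx(math.exp(-decay * d), abs=1e-9)

    def test_root_off_tree_rejected(self):
        lab, branch = make_toy_tube()
        with pytest.raises(ValueError):
            vessel_weight_map(lab, [branch], root_point=(0.0, 0.0, 0.0), decay=0.1)
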