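import numpy as np
import pytest

from cytomap.grid import make_grid
from cytomap.probmaps import (
    ProbabilityMap,
    center_of_mass,
    compute_probability_map,
    read_probability_map,
    stack_to_volume,
    threshold_map,
    to_reference,
    write_probability_map,
)
from cytomap.sectioning import Section, SectionStack, slice_volume
from cytomap.volumetry import voxel_count_volume

from conftest import digitize_ball


def _reference(shape=(20, 20, 20), voxel=1.0, origin=(-10, -10, -10)):
    return make_grid(tuple(np.asarray(origin) + voxel / 2), shape, voxel,
                     space_id="reference")


class TestStackToVolume:
    def _cylinder_stack(self, k=3):
        # constant circular cross-section along y
        n = 40
        px = 0.25
        yy, xx = np.mgrid[:n, :n]
        c = (n - 1) / 2
        disk = ((yy - c) ** 2 + (xx - c) ** 2) * px ** 2 <= 4.0
        sections = [Section(i, disk, (px, px)) for i in range(0, 30, k)]
        return SectionStack("s", "cyl", sections, 0.1, k,
                            plane_origin=0.0, inplane_origin=(-c * px, -c * px))

    @pytest.mark.parametrize("mode", ["block", "shape_based"])
    def test_constant_cross_section_exact(self, mode):
        stack = self._cylinder_stack()
        vol = stack_to_volume(stack, mode)
        # every elementary plane inside the sampled range carries the disk
        n_planes = vol.labels.shape[stack.axis]
        per_plane = vol.labels.sum() / n_planes
        assert np.allclose(vol.labels.sum(axis=(0, 2)), per_plane)

    def test_sphere_volume_error_small_in_both_modes(self):
        ball = digitize_ball(3.0, 0.1)
        stack = slice_volume(ball, 1, thickness=0.1, interval=3, offset=1)
        truth = 4 / 3 * np.pi * 27
        for mode in ("block", "shape_based"):
            vol = stack_to_volume(stack, mode)
            err = abs(voxel_count_volume(vol, 1) - truth) / truth
            assert err < 0.03

    def test_shape_based_tracks_drifting_sections_better_than_block(self):
        # a structure whose cross-section translates between sampled
        # sections: distance-transform blending follows the drift while
        # block fill staircases, so shape_based scores the higher Dice
        # against the true digitised volume
        vox = 0.1
        grid = make_grid((-5 + vox / 2, vox / 2, -5 + vox / 2),
                         (100, 80, 100), vox)
        idx = np.indices(grid.labels.shape).reshape(3, -1).T
        w = grid.index_to_world(idx)
        cx = 0.5 * (w[:, 1] - 4.0)  # disk centre drifts along x with y
        inside = ((w[:, 0] - cx) ** 2 + w[:, 2] ** 2) <= 1.5 ** 2
        grid.labels[tuple(idx[inside].T)] = 1
        truth = grid.labels > 0
        stack = slice_volume(grid, 1, thickness=vox, interval=6, offset=1)
        dice = {}
        for mode in ("block", "shape_based"):
            rec = stack_to_volume(stack, mode)
            j0 = int(round((rec.affine[1, 3] - grid.affine[1, 3]) / vox))
            sub = truth[:, j0:j0 + rec.labels.shape[1], :]
            r = rec.labels > 0
            dice[mode] = 2 * (r & sub).sum() / (r.sum() + sub.sum())
        assert dice["shape_based"] > dice["block"]
        assert dice["shape_based"] > 0.95

    def test_all_empty_sections_give_zero_volume(self):
        empty = np.zeros((10, 10), bool)
        sections = [Section(i, empty, (0.5, 0.5)) for i in range(0, 9, 3)]
        stack = SectionStack("s", "x", sections, 0.1, 3)
        assert stack_to_volume(stack, "shape_based").labels.sum() == 0

    def test_single_section_falls_back_to_block(self):
        m = np.zeros((8, 8), bool)
        m[3:5, 3:5] = True
        stack = SectionStack("s", "x", [Section(0, m, (0.5, 0.5))], 0.1, 3)
        with pytest.warns(UserWarning, match="falls back to block"):
            vol = stack_to_volume(stack, "shape_based")
        assert vol.labels.sum() == m.sum()


class TestToReference:
    def test_identity_transform_same_grid(self):
        ref = _reference()
        ball = digitize_ball(3.0, 1.0, margin=7.0)
        ball.affine = ref.affine.copy()  # same grid layout
        out = to_reference(ball, np.eye(4), ref)
        assert np.array_equal(out, ball.labels > 0)

    def test_pure_translation_shifts_exactly(self):
        ref = _reference()
        ball = digitize_ball(2.0, 1.0, margin=8.0)
        ball.affine = ref.affine.copy()
        t = np.eye(4)
        t[0, 3] = 1.0  # one voxel pitch along x
        out = to_reference(ball, t, ref)
        assert np.array_equal(out[1:], (ball.labels > 0)[:-1])

    def test_rotation_preserves_volume_within_nn_bound(self):
        ball = digitize_ball(4.0, 0.5, margin=4.0)
        theta = np.deg2rad(17.0)
        rot = np.eye(4)
        rot[:3, :3] = [[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        ref = make_grid((-9.75, -9.75, -9.75), (40, 40, 40), 0.5)
        out = to_reference(ball, rot, ref)
        v_in = voxel_count_volume(ball, 1)
        v_out = out.sum() * ref.voxel_volume
        assert v_out == pytest.approx(v_in, rel=0.02)

    def test_structure_outside_reference_raises(self):
        ref = _reference()
        ball = digitize_ball(2.0, 1.0, center=(500.0, 0.0, 0.0), margin=3.0)
        with pytest.raises(ValueError, match="outside"):
            to_reference(ball, np.eye(4), ref)


class TestProbabilityMap:
    def test_overlap_percent_semantics(self):
        # ten aligned masks: a voxel covered by exactly one brain reads 10%,
        # a voxel covered by all ten reads 100%
        ref = _reference((8, 8, 8))
        masks = []
        for i in range(10):
            m = np.zeros((8, 8, 8), bool)
            m[2:6, 2:6, 2:6] = True       # common core
            if i == 0:
                m[0, 0, 0] = True         # voxel unique to one subject
            masks.append(m)
        pmap = compute_probability_map(masks, ref, structure="test")
        assert pmap.percent[0, 0, 0] == 10
        assert pmap.percent[3, 3, 3] == 100
        assert pmap.percent[7, 7, 7] == 0

    def test_identical_masks_are_full_overlap(self):
        ref = _reference((6, 6, 6))
        m = np.zeros((6, 6, 6), bool)
        m[1:4, 1:4, 1:4] = True
        pmap = compute_probability_map([m] * 7, ref)
        assert np.array_equal(pmap.percent, m.astype(np.uint8) * 100)

    def test_grid_mismatch_rejected(self):
        ref = _reference((6, 6, 6))
        with pytest.raises(ValueError):
            compute_probability_map([np.zeros((5, 5, 5), bool)], ref)

    def test_percent_lattice(self):
        ref = _reference((4, 4, 4))
        rng = np.random.default_rng(0)
        masks = [rng.random((4, 4, 4)) < 0.5 for _ in range(3)]
        pmap = compute_probability_map(masks, ref)
        assert set(np.unique(pmap.percent)) <= {0, 33, 67, 100}

    def test_mass_conservation(self):
        # sum of exact fractions x voxel volume == mean per-subject volume
        ref = _reference((10, 10, 10))
        rng = np.random.default_rng(1)
        masks = [rng.random((10, 10, 10)) < 0.4 for _ in range(6)]
        pmap = compute_probability_map(masks, ref)
        mean_subject = np.mean([m.sum() for m in masks]) * ref.voxel_volume
        assert pmap.fraction.sum() * ref.voxel_volume == pytest.approx(
            mean_subject, rel=1e-12)

    def test_nifti_roundtrip(self, tmp_path):
        ref = _reference((6, 6, 6))
        rng = np.random.default_rng(2)
        masks = [rng.random((6, 6, 6)) < 0.5 for _ in range(10)]
        pmap = compute_probability_map(masks, ref, structure="x")
        path = tmp_path / "x.nii"
        write_probability_map(pmap, path)
        back = read_probability_map(path, 10, "x")
        assert np.array_equal(back.counts, pmap.counts)


class TestCenterOfMass:
    def test_single_voxel(self):
        ref = _reference((9, 9, 9))
        m = np.zeros((9, 9, 9), bool)
        m[2, 3, 4] = True
        pmap = compute_probability_map([m], ref)
        com = center_of_mass(pmap)
        world = ref.index_to_world(np.array([2, 3, 4]))
        assert com.as_tuple() == tuple(int(round(c)) for c in world)

    def test_two_voxel_midpoint(self):
        ref = _reference((9, 9, 9))
        m = np.zeros((9, 9, 9), bool)
        m[2, 4, 4] = True
        m[6, 4, 4] = True
        pmap = compute_probability_map([m], ref)
        com = center_of_mass(pmap)
        w = (ref.index_to_world(np.array([2, 4, 4]))
             + ref.index_to_world(np.array([6, 4, 4]))) / 2
        assert com.as_tuple() == tuple(int(round(c)) for c in w)

    def test_digitized_ball_center_recovered(self):
        # phantom centred at the kind of coordinate a left-hemisphere
        # auditory-relay centre of mass takes in reference space
        ref = make_grid((-30.5, -40.5, -20.5), (40, 40, 30), 1.0)
        ball = digitize_ball(4.0, 1.0, center=(-16.0, -27.0, -8.0), margin=3.0)
        mask = to_reference(ball, np.eye(4), ref)
        pmap = compute_probability_map([mask], ref, structure="MGB")
        com = center_of_mass(pmap, hemisphere="left")
        assert com.as_tuple() == (-16, -27, -8)

    def test_empty_map_rejected(self):
        ref = _reference((4, 4, 4))
        pmap = ProbabilityMap("x", np.zeros((4, 4, 4), int), 3, ref.affine)
        with pytest.raises(ValueError, match="empty"):
            center_of_mass(pmap)


class TestThreshold:
    def _pmap(self):
        ref = _reference((6, 6, 6))
        rng = np.random.default_rng(3)
        masks = [rng.random((6, 6, 6)) < 0.5 for _ in range(5)]
        return compute_probability_map(masks, ref), masks

    def test_zero_keeps_any_overlap(self):
        pmap, masks = self._pmap()
        assert np.array_equal(threshold_map(pmap, 0),
                              np.logical_or.reduce(masks))

    def test_hundred_keeps_intersection(self):
        pmap, masks = self._pmap()
        assert np.array_equal(threshold_map(pmap, 100),
                              np.logical_and.reduce(masks))

    def test_monotone_in_threshold(self):
        pmap, _ = self._pmap()
        prev = threshold_map(pmap, 0)
        for t in (20, 40, 60, 80, 100):
            cur = threshold_map(pmap, t)
            assert np.all(prev | cur == prev)  # cur is a subset of prev
            prev = cur
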