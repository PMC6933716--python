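"""Segmentation, similarity alignment, voxelization, trait extraction."""

import numpy as np
import pytest

from paniclepheno.cloud3d import (BoundingCube, SimilarityTransform, VoxelGrid,
                                  apply_transform, estimate_reference_transform,
                                  extract_traits, load_voxel_grid,
                                  save_voxel_grid, segment_components,
                                  session_traits, voxelize)
from paniclepheno.errors import (AlignmentError, OutOfBoundsError,
                                 UndefinedTraitError, ValidationError)
from paniclepheno.io import (LABEL_CHECKERBOARD, LABEL_PANICLE, PointCloud)
from paniclepheno.synthetic import (SyntheticPanicleSpec, make_scene,
                                    random_similarity)
from .conftest import random_cloud


class TestSimilarityTransform:
    def test_rejects_non_orthonormal_rotation(self):
        with pytest.raises(ValidationError):
            SimilarityTransform(1.0, np.eye(3) * 2, np.zeros(3))

    def test_rejects_reflection(self):
        flip = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValidationError):
            SimilarityTransform(1.0, flip, np.zeros(3))

    def test_pure_scaling_doubles_distances(self):
        t = SimilarityTransform(2.0, np.eye(3), np.zeros(3))
        a, b = t.apply_points(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        assert np.linalg.norm(a - b) == pytest.approx(2.0)

    def test_inverse_composes_to_identity(self, rng):
        t = random_similarity(rng)
        comp = t.compose(t.inverse())
        assert comp.scale == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(comp.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(comp.translation, 0.0, atol=1e-9)

    def test_apply_then_inverse_restores_cloud(self, rng):
        cloud = random_cloud(rng, 100)
        t = random_similarity(rng)
        back = apply_transform(apply_transform(cloud, t), t.inverse())
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-9)

    def test_identity_transform_is_noop(self, rng):
        cloud = random_cloud(rng, 10)
        out = apply_transform(cloud, SimilarityTransform.identity())
        np.testing.assert_array_equal(out.points, cloud.points)
        np.testing.assert_array_equal(out.colors, cloud.colors)


class TestSegmentation:
    def test_generating_labels_recovered(self, scene):
        cloud, truth = scene
        labeled = segment_components(cloud)
        assert (labeled.labels == truth.labels).mean() >= 0.99

    def test_reference_only_scene_has_no_panicle(self):
        spec = SyntheticPanicleSpec(n_branches=0, seeds_per_branch=0,
                                    rng_seed=1)
        cloud, _ = make_scene(spec)
        labeled = segment_components(cloud)
        assert (labeled.labels == LABEL_PANICLE).sum() == 0

    def test_scene_without_reference_planes_errors(self, rng):
        # a bare panicle-like blob offers no wall support
        cloud = random_cloud(rng, 500, span=5.0)
        with pytest.raises(AlignmentError):
            segment_components(cloud)
            # even if plane extraction finds spurious facets, alignment
            # structure identification must fail
            estimate_reference_transform(segment_components(cloud))

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValidationError):
            segment_components(PointCloud(np.empty((0, 3)), np.empty((0, 3))))


class TestAlignment:
    def test_canonical_scene_maps_to_identity(self, scene):
        cloud, _ = scene
        t = estimate_reference_transform(segment_components(cloud))
        assert t.scale == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)

    def test_known_transform_recovered(self, scene, rng):
        cloud, _ = scene
        truth_t = random_similarity(rng)
        moved = apply_transform(cloud, truth_t)
        recovered = estimate_reference_transform(segment_components(moved))
        comp = recovered.compose(truth_t)
        assert comp.scale == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(comp.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(comp.translation, 0.0, atol=1e-6)

    def test_collinear_landmarks_rejected(self, rng):
        # checkerboard points along one line cannot anchor the frame
        t = np.linspace(0, 1, 200)
        pts = np.outer(t, [1.0, 2.0, 3.0])
        cloud = PointCloud(pts, np.zeros((200, 3)),
                           np.full(200, LABEL_CHECKERBOARD, np.uint8))
        with pytest.raises(AlignmentError):
            estimate_reference_transform(cloud)

    def test_unlabeled_cloud_rejected(self, rng):
        with pytest.raises(AlignmentError):
            estimate_reference_transform(random_cloud(rng, 10))


def brute_force_bins(points, cube):
    """Independent per-point floor binning in pure Python."""
    lo = np.asarray(cube.min_corner)
    edge = cube.edge / cube.resolution
    filled = set()
    for p in points:
        idx = []
        for d in range(3):
            i = int(np.floor((p[d] - lo[d]) / edge))
            idx.append(min(max(i, 0), cube.resolution - 1))
        filled.add(tuple(idx))
    return filled


class TestVoxelize:
    def test_single_point_fills_one_voxel_with_its_color(self):
        cube = BoundingCube((0, 0, 0), 10.0, 10)
        cloud = PointCloud([[3.7, 8.1, 0.2]], [[200, 100, 50]])
        grid = voxelize(cloud, cube)
        assert grid.voxel_count == 1
        np.testing.assert_array_equal(grid.indices, [[3, 8, 0]])
        np.testing.assert_array_equal(grid.mean_colors, [[200, 100, 50]])

    def test_default_resolution_is_1000(self):
        assert BoundingCube().resolution == 1000

    def test_matches_brute_force_oracle(self, rng):
        cube = BoundingCube((0, 0, 0), 1.0, 20)
        for _ in range(5):
            n = int(rng.integers(1, 10_000))
            cloud = PointCloud(rng.random((n, 3)), np.zeros((n, 3)))
            grid = voxelize(cloud, cube)
            got = {tuple(i) for i in grid.indices}
            assert got == brute_force_bins(cloud.points, cube)

    def test_max_face_points_clamped_into_last_voxel(self):
        cube = BoundingCube((0, 0, 0), 1.0, 10)
        grid = voxelize(PointCloud([[1.0, 1.0, 1.0]], [[0, 0, 0]]), cube)
        np.testing.assert_array_equal(grid.indices, [[9, 9, 9]])

    def test_outside_point_raises_with_location(self):
        cube = BoundingCube((0, 0, 0), 1.0, 10)
        with pytest.raises(OutOfBoundsError, match="alignment"):
            voxelize(PointCloud([[0.5, 0.5, 1.5]], [[0, 0, 0]]), cube)

    def test_mean_color_is_arithmetic_mean(self):
        cube = BoundingCube((0, 0, 0), 1.0, 1)
        cloud = PointCloud([[0.1, 0.1, 0.1], [0.9, 0.9, 0.9]],
                           [[0, 0, 0], [100, 200, 50]])
        grid = voxelize(cloud, cube)
        np.testing.assert_allclose(grid.mean_colors, [[50, 100, 25]])

    def test_adding_points_never_decreases_count(self, rng):
        cube = BoundingCube((0, 0, 0), 1.0, 15)
        pts = rng.random((2000, 3))
        counts = [voxelize(PointCloud(pts[:n], np.zeros((n, 3))),
                           cube).voxel_count
                  for n in (10, 100, 500, 2000)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] <= min(2000, 15 ** 3)

    def test_volume_recovery_for_aligned_box(self, rng):
        # box spanning an exact voxel sub-grid: filled fraction == f
        cube = BoundingCube((0, 0, 0), 1.0, 50)
        dims = np.array([50, 30, 25])        # f = 0.3
        n = int(20 * dims.prod())
        pts = rng.random((n, 3)) * (dims / 50)
        grid = voxelize(PointCloud(pts, np.zeros((n, 3))), cube)
        f = grid.voxel_count / 50 ** 3
        assert f == pytest.approx(0.3, rel=0.02)

    def test_grid_round_trip_csv(self, tmp_path, rng):
        cube = BoundingCube((0, 0, 0), 1.0, 20)
        cloud = PointCloud(rng.random((300, 3)),
                           rng.integers(0, 256, (300, 3)))
        grid = voxelize(cloud, cube)
        back = load_voxel_grid(save_voxel_grid(grid, tmp_path / "g.csv"))
        np.testing.assert_array_equal(back.indices, grid.indices)
        np.testing.assert_allclose(back.mean_colors, grid.mean_colors)
        assert back.cube == grid.cube


class TestTraits:
    def test_sum_and_ratio_arithmetic(self):
        cube = BoundingCube((0, 0, 0), 1.0, 10)
        grid = VoxelGrid(cube, [[0, 0, 0], [1, 1, 1], [2, 2, 2]],
                         [[200, 100, 50]] * 3)
        traits = extract_traits(grid)
        assert traits.voxel_count == 3
        assert (traits.color_sum_r, traits.color_sum_g, traits.color_sum_b) \
            == (600.0, 300.0, 150.0)
        assert traits.rg_ratio == pytest.approx(2.0)

    def test_empty_grid_flags_undefined_ratio(self):
        cube = BoundingCube((0, 0, 0), 1.0, 10)
        traits = extract_traits(VoxelGrid(cube, np.empty((0, 3)),
                                          np.empty((0, 3))))
        assert traits.voxel_count == 0
        assert traits.color_sum_r == 0.0
        assert traits.rg_ratio is None
        with pytest.raises(UndefinedTraitError):
            traits.require_rg_ratio()

    def test_color_sums_bounded_by_count(self, scene, small_cube):
        cloud, _ = scene
        traits = session_traits(cloud, cube=small_cube)
        for s in (traits.color_sum_r, traits.color_sum_g,
                  traits.color_sum_b):
            assert 0 <= s <= 255 * traits.voxel_count


class TestSessionPipeline:
    def test_voxel_count_invariant_under_transform(self, scene, small_cube,
                                                   rng):
        cloud, _ = scene
        base = session_traits(cloud, cube=small_cube).voxel_count
        moved = apply_transform(cloud, random_similarity(rng))
        again = session_traits(moved, cube=small_cube).voxel_count
        assert abs(again - base) / base <= 0.01

    def test_growing_volume_and_maturation_across_weeks(self, small_cube):
        counts, ratios = [], []
        for week, stage in zip((1, 2, 3), (0.1, 0.5, 0.9)):
            spec = SyntheticPanicleSpec(week=week, color_stage=stage,
                                        rng_seed=11, layout_seed=77)
            cloud, _ = make_scene(spec)
            traits = session_traits(cloud, cube=small_cube)
            counts.append(traits.voxel_count)
            ratios.append(traits.require_rg_ratio())
        assert counts[0] < counts[1] < counts[2]
        assert ratios[0] < ratios[1] < ratios[2]

    def test_artifacts_persisted_for_audit(self, scene, small_cube, tmp_path):
        cloud, _ = scene
        session_traits(cloud, cube=small_cube, out_dir=tmp_path)
        assert (tmp_path / "aligned_labeled.ply").exists()
        assert (tmp_path / "transform.json").exists()
        assert (tmp_path / "voxel_grid.csv").exists()

    def test_occupancy_tracks_true_volume(self, small_cube):
        spec = SyntheticPanicleSpec(rng_seed=21, point_density=200.0)
        cloud, truth = make_scene(spec)
        traits = session_traits(cloud, cube=small_cube)
        voxel_volume = small_cube.voxel_edge ** 3
        # stems add a little occupancy on top of the seed-union truth
        assert traits.voxel_count * voxel_volume >= 0.75 * truth.true_volume
        assert traits.voxel_count * voxel_volume <= 2.0 * truth.true_volume
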