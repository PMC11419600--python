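"""Landmark centroids and closed-form rigid fitting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import ellipsoid_mesh, make_grid
from voxmap.core import RigidTransform, VoxmapError
from voxmap.landmark_registration import (
    LandmarkGroup,
    LandmarkSpec,
    apply_transform,
    fit_rigid,
    mesh_landmark_centroids,
    stack_landmark_centroids,
)


def random_rigid(rng, max_angle_deg=180.0, max_shift=20.0):
    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
    t = rng.uniform(-max_shift, max_shift, size=3)
    return RigidTransform(rotation=rot, translation=t)


class TestMeshCentroids:
    def test_single_sphere_centroid(self):
        spec = LandmarkSpec([LandmarkGroup("g", ["a"], channel="X")])
        mesh = ellipsoid_mesh("a", (10.0, 20.0, 30.0), (3, 3, 3))
        np.testing.assert_allclose(
            mesh_landmark_centroids([mesh], spec)[0], [10, 20, 30], atol=1e-9)

    def test_two_equal_volumes_give_midpoint(self):
        spec = LandmarkSpec([LandmarkGroup("g", ["a", "b"], channel="X")])
        meshes = [ellipsoid_mesh("a", (0, 0, 0), (2, 2, 2)),
                  ellipsoid_mesh("b", (2, 0, 0), (2, 2, 2))]
        np.testing.assert_allclose(
            mesh_landmark_centroids(meshes, spec)[0], [1, 0, 0], atol=1e-9)

    def test_unknown_mesh_ids_rejected(self):
        spec = LandmarkSpec([LandmarkGroup("g", ["ghost"])])
        with pytest.raises(VoxmapError, match="ghost"):
            mesh_landmark_centroids([ellipsoid_mesh("a", (0, 0, 0), (1, 1, 1))],
                                    spec)


class TestStackCentroids:
    def test_blob_centroid_within_one_voxel_of_generator(self):
        from voxmap.synthetic_scene import SceneSpec, render_stack
        from voxmap.voxel_engine import stack_to_voxels

        spec = SceneSpec(
            name="blob",
            neuron_centroids=[("a", "X", (7.3, 6.8, 7.1))],
            neuron_radii=(3.0, 3.0, 3.0),
            channels=["G"], planted_truth={"G": {"a"}},
            intensity_law=(200.0, 0.0), background_law=(0.0, 0.0),
            blur_sigma=0.0, spacing=(0.5, 0.5, 1.0), shape=(16, 32, 32), seed=0)
        stacks, _ = render_stack(spec)
        grid = stack_to_voxels(stacks["G"])
        lspec = LandmarkSpec([LandmarkGroup("g", ["a"], channel="G")])
        centroid = stack_landmark_centroids({"G": grid}, lspec)[0]
        assert np.all(np.abs(centroid - [7.3, 6.8, 7.1]) < 1.0)

    def test_largest_component_wins(self):
        # two separated blobs: centroid must come from the bigger one only
        centers = np.array([[1.0, 1, 1], [1.5, 1, 1], [2.0, 1, 1],
                            [30.0, 1, 1]])
        grid = make_grid(centers, frame="stack", spacing=(0.5, 1, 1))
        grid.indices[:, 0] = [0, 1, 2, 40]
        grid.stack_shape = (1, 64, 1)
        lspec = LandmarkSpec([LandmarkGroup("g", ["a"], channel="X")])
        centroid = stack_landmark_centroids({"X": grid}, lspec)[0]
        assert centroid[0] == pytest.approx(1.5)

    def test_empty_region_names_group(self):
        grid = make_grid([[1.0, 1, 1]], frame="stack")
        lspec = LandmarkSpec([LandmarkGroup(
            "dorsal-cap", ["a"], channel="X",
            region=((50, 50, 50), (60, 60, 60)))])
        with pytest.raises(VoxmapError, match="dorsal-cap"):
            stack_landmark_centroids({"X": grid}, lspec)


class TestFitRigid:
    def test_identity_on_equal_point_sets(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        transform, rmsd = fit_rigid(pts, pts)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(transform.translation, 0, atol=1e-12)
        assert rmsd < 1e-12

    def test_exact_recovery_of_planted_motion(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        planted = RigidTransform.about_z(90.0, translation=(1, 2, 3))
        transform, rmsd = fit_rigid(src, planted.apply(src))
        np.testing.assert_allclose(transform.rotation, planted.rotation, atol=1e-9)
        np.testing.assert_allclose(transform.translation, planted.translation,
                                   atol=1e-9)
        assert rmsd < 1e-9

    def test_noiseless_recovery_over_many_random_transforms(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            src = rng.uniform(-10, 10, size=(5, 3))
            planted = random_rigid(rng)
            transform, rmsd = fit_rigid(src, planted.apply(src))
            assert rmsd < 1e-9
            np.testing.assert_allclose(transform.rotation, planted.rotation,
                                       atol=1e-8)

    def test_noisy_recovery_translation_coverage(self):
        """sd 0.1 µm landmark noise: translation error < 0.2 µm in ≥ 95/100."""
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(100):
            src = rng.uniform(-10, 10, size=(6, 3))
            planted = random_rigid(rng)
            dst = planted.apply(src) + rng.normal(0, 0.1, size=src.shape)
            transform, rmsd = fit_rigid(src, dst)
            err = np.linalg.norm(transform.translation - planted.translation)
            if err < 0.2:
                hits += 1
        assert hits >= 95

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(3)
        src = rng.uniform(-5, 5, size=(8, 3))
        planted = random_rigid(rng)
        dst = planted.apply(src) + rng.normal(0, 0.05, size=src.shape)
        transform, _ = fit_rigid(src, dst)
        rot_ref, _ = Rotation.align_vectors(
            dst - dst.mean(axis=0), src - src.mean(axis=0))
        np.testing.assert_allclose(transform.rotation, rot_ref.as_matrix(),
                                   atol=1e-6)

    def test_scale_recovery_when_allowed(self):
        rng = np.random.default_rng(4)
        src = rng.uniform(-5, 5, size=(6, 3))
        planted = RigidTransform.about_z(30.0, translation=(1, -2, 0.5))
        dst = 1.3 * planted.apply(src) - 0.3 * planted.translation
        transform, rmsd = fit_rigid(src, dst, allow_scale=True)
        assert transform.scale == pytest.approx(1.3, abs=1e-9)
        assert rmsd < 1e-9

    def test_reflection_corrected_to_proper_rotation(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0],
                        [1, 1, 0.0]])
        dst = src * np.array([1, 1, -1.0])  # mirror through the xy-plane
        transform, _ = fit_rigid(src, dst)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0)

    def test_collinear_points_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        with pytest.raises(VoxmapError, match="collinear"):
            fit_rigid(src, src + 1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(VoxmapError, match="under-determined"):
            fit_rigid(np.zeros((2, 3)), np.zeros((2, 3)))


class TestApplyTransform:
    def test_identity_keeps_centers(self):
        grid = make_grid([[1.0, 2, 3]], frame="stack")
        out = apply_transform(grid, RigidTransform.identity())
        np.testing.assert_array_equal(out.centers, grid.centers)
        assert out.frame == "registered"

    def test_pure_translation(self):
        grid = make_grid([[1.0, 2, 3], [0, 0, 0]], frame="stack")
        out = apply_transform(grid, RigidTransform(translation=np.array([1, 0, 0.0])))
        np.testing.assert_allclose(out.centers[:, 0], grid.centers[:, 0] + 1)

    def test_rotation_then_inverse_round_trips(self):
        rng = np.random.default_rng(5)
        grid = make_grid(rng.uniform(0, 10, size=(50, 3)), frame="stack")
        transform = random_rigid(rng)
        back = apply_transform(apply_transform(grid, transform),
                               transform.inverse())
        np.testing.assert_allclose(back.centers, grid.centers, atol=1e-9)

    def test_preserves_total_expression_volume(self):
        rng = np.random.default_rng(6)
        grid = make_grid(rng.uniform(0, 10, size=(30, 3)),
                         volumes=rng.uniform(0, 1, 30), frame="stack")
        out = apply_transform(grid, random_rigid(rng))
        assert out.total_expression_volume == grid.total_expression_volume
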