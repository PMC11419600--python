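"""Point-in-mesh parity test and voxel→neuron assignment, checked against
analytic membership and an exhaustive brute-force oracle."""

import numpy as np
import pytest

from conftest import ellipsoid_mesh, make_grid
from voxmap.collision_assignment import (
    AssignmentMap,
    assign_voxels,
    neuron_assigned_volume,
    point_in_mesh,
    points_in_mesh,
)
from voxmap.core import NeuronMesh, VoxmapError
from voxmap.synthetic_scene import ellipsoid_contains


def brute_force_assign(grid, meshes):
    """Exhaustive all-pairs assignment: no bounding-box pruning at the
    assignment level; the per-pair point test is the only shared code."""
    amap = AssignmentMap()
    for nm in meshes:
        inside = points_in_mesh(grid.centers, nm)
        rows = np.flatnonzero(inside)
        amap.add(nm.neuron_id, rows, grid.expression_volume[rows])
    return amap


def _winding_number(point, tm):
    """Generalized winding number via summed signed solid angles."""
    a = tm.vertices[tm.faces[:, 0]] - point
    b = tm.vertices[tm.faces[:, 1]] - point
    c = tm.vertices[tm.faces[:, 2]] - point
    la, lb, lc = (np.linalg.norm(v, axis=1) for v in (a, b, c))
    numer = np.einsum("ij,ij->i", a, np.cross(b, c))
    denom = (la * lb * lc + np.einsum("ij,ij->i", a, b) * lc
             + np.einsum("ij,ij->i", b, c) * la
             + np.einsum("ij,ij->i", a, c) * lb)
    return np.arctan2(numer, denom).sum() / (2 * np.pi)


class TestPointInMesh:
    def test_cube_center_inside(self):
        import trimesh

        cube = NeuronMesh("c", trimesh.creation.box(extents=(1, 1, 1)))
        assert point_in_mesh((0.0, 0.0, 0.0), cube)

    def test_point_far_from_sphere_outside(self):
        sphere = ellipsoid_mesh("s", (0, 0, 0), (1, 1, 1))
        assert not point_in_mesh((2.0, 0.0, 0.0), sphere)

    def test_agrees_with_analytic_ellipsoid_membership(self):
        """≥ 99.9% agreement on 10,000 random points; disagreements only
        within the facet-chord shell of the surface."""
        rng = np.random.default_rng(11)
        center = np.array([1.0, -2.0, 3.0])
        radii = np.array([5.0, 3.0, 2.0])
        mesh = ellipsoid_mesh("e", center, radii)
        pts = rng.uniform(-7, 7, size=(10_000, 3)) + center
        parity = points_in_mesh(pts, mesh)
        analytic = ellipsoid_contains(pts, center, radii)
        disagree = parity != analytic
        assert disagree.mean() <= 0.001
        # icosphere subdiv-3 facet chords sit within ~1% of the radius
        q = np.linalg.norm((pts[disagree] - center) / radii, axis=1)
        assert np.all(np.abs(q - 1.0) < 0.02)

    def test_agrees_with_winding_number_oracle(self):
        """Exact agreement with a generalized-winding-number membership test
        (van Oosterom–Strackee signed solid angles) on a bumpy mesh."""
        rng = np.random.default_rng(12)
        mesh = ellipsoid_mesh("e", (0, 0, 0), (3, 2, 1.5), subdivisions=2)
        # perturb vertices radially so the surface is not a clean quadric
        tm = mesh.mesh.copy()
        tm.vertices += 0.05 * np.sin(3 * tm.vertices[:, [1, 2, 0]])
        bumpy = NeuronMesh("b", tm)
        pts = rng.uniform(-3.5, 3.5, size=(2_000, 3))
        ours = points_in_mesh(pts, bumpy)
        ref = np.array([_winding_number(p, tm) > 0.5 for p in pts])
        assert np.array_equal(ours, ref)

    def test_grazing_rays_through_vertices_resolved(self):
        # axis-aligned ray candidates from a cube's symmetry points
        import trimesh

        cube = NeuronMesh("c", trimesh.creation.box(extents=(2, 2, 2)))
        pts = np.array([[0, 0, 0], [0.5, 0.5, 0.5], [-0.9, -0.9, -0.9],
                        [1.5, 0, 0], [0, 0, 1.00001]])
        assert points_in_mesh(pts, cube).tolist() == [
            True, True, True, False, False]


class TestAssignVoxels:
    def test_grid_outside_all_meshes_empty(self):
        grid = make_grid([[50.0, 50, 50]])
        amap = assign_voxels(grid, [ellipsoid_mesh("a", (0, 0, 0), (2, 2, 2))])
        assert amap.totals == {}

    def test_single_containment_credits_full_volume(self):
        grid = make_grid([[0.0, 0, 0]], volumes=[1.0])
        amap = assign_voxels(grid, [ellipsoid_mesh("a", (0, 0, 0), (2, 2, 2))])
        assert amap.assigned_volume("a") == pytest.approx(1.0)

    def test_empty_mesh_set_rejected(self):
        with pytest.raises(VoxmapError, match="empty mesh set"):
            assign_voxels(make_grid([[0.0, 0, 0]]), [])

    def test_duplicate_mesh_ids_rejected(self):
        grid = make_grid([[0.0, 0, 0]])
        meshes = [ellipsoid_mesh("a", (0, 0, 0), (1, 1, 1)),
                  ellipsoid_mesh("a", (5, 0, 0), (1, 1, 1))]
        with pytest.raises(VoxmapError, match="duplicate"):
            assign_voxels(grid, meshes)

    def test_three_ellipsoids_match_brute_force(self):
        rng = np.random.default_rng(21)
        meshes = [ellipsoid_mesh(f"n{i}", c, (2.5, 2.0, 1.5), subdivisions=2)
                  for i, c in enumerate([(3, 3, 3), (12, 3, 3), (3, 12, 3.0)])]
        grid = make_grid(rng.uniform(0, 15, size=(4_000, 3)),
                         volumes=rng.uniform(0.1, 1.0, 4_000))
        fast = assign_voxels(grid, meshes)
        slow = brute_force_assign(grid, meshes)
        assert fast.totals == slow.totals
        for nid in slow.voxel_rows:
            np.testing.assert_array_equal(fast.voxel_rows[nid],
                                          slow.voxel_rows[nid])

    def test_policies_identical_for_disjoint_meshes(self):
        rng = np.random.default_rng(22)
        meshes = [ellipsoid_mesh(f"n{i}", (8.0 * i, 0, 0), (3, 3, 3))
                  for i in range(3)]
        grid = make_grid(rng.uniform(-4, 20, size=(2_000, 3)))
        assert (assign_voxels(grid, meshes, "all").totals
                == assign_voxels(grid, meshes, "nearest").totals)

    def test_nearest_policy_splits_overlapping_meshes(self):
        meshes = [ellipsoid_mesh("a", (0, 0, 0), (3, 3, 3)),
                  ellipsoid_mesh("b", (2, 0, 0), (3, 3, 3))]
        grid = make_grid([[1.5, 0, 0]], volumes=[1.0])  # inside both, nearer b
        all_map = assign_voxels(grid, meshes, "all")
        assert all_map.assigned_volume("a") == all_map.assigned_volume("b") == 1.0
        near_map = assign_voxels(grid, meshes, "nearest")
        assert near_map.assigned_volume("b") == 1.0
        assert near_map.assigned_volume("a") == 0.0

    def test_assigned_never_exceeds_grid_total(self):
        rng = np.random.default_rng(23)
        meshes = [ellipsoid_mesh(f"n{i}", (7.0 * i, 0, 0), (3, 3, 3))
                  for i in range(4)]
        grid = make_grid(rng.uniform(-4, 26, size=(3_000, 3)),
                         volumes=rng.uniform(0, 1, 3_000))
        amap = assign_voxels(grid, meshes)
        total = grid.total_expression_volume
        assert all(v <= total + 1e-9 for v in amap.totals.values())
        assert sum(amap.totals.values()) <= total + 1e-9  # disjoint meshes

    def test_fully_tiled_neuron_recovers_mesh_volume(self):
        """Binary-mode voxels tiling a neuron sum to its volume within a
        one-voxel surface shell."""
        from voxmap.core import ImageStack
        from voxmap.voxel_engine import stack_to_voxels

        radii = (4.0, 4.0, 4.0)
        center = (6.0, 6.0, 6.0)
        mesh = ellipsoid_mesh("a", center, radii)
        shape = (24, 24, 24)
        spacing = (0.5, 0.5, 0.5)
        k, r, c = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        centers = np.column_stack([(r.ravel() + 0.5) * 0.5,
                                   (c.ravel() + 0.5) * 0.5,
                                   (k.ravel() + 0.5) * 0.5])
        vals = np.where(ellipsoid_contains(centers, center, radii), 255, 0)
        stack = ImageStack("G", vals.reshape(shape).astype(np.uint8), *spacing)
        grid = stack_to_voxels(stack)
        amap = assign_voxels(grid.with_centers(grid.centers, "registered"), [mesh])
        # surface shell bound: area × voxel diagonal
        shell = mesh.mesh.area * np.linalg.norm(spacing)
        assert abs(amap.assigned_volume("a") - mesh.volume) < shell

    def test_absent_neuron_reports_zero(self):
        amap = AssignmentMap()
        amap.add("a", np.array([0, 1]), np.array([0.25, 0.25]))
        assert neuron_assigned_volume(amap, "a") == pytest.approx(0.5)
        assert neuron_assigned_volume(amap, "ghost") == 0.0
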