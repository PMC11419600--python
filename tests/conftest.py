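import numpy as np
import pandas as pd
import pytest
import trimesh

from voxmap import synthetic_scene as syn
from voxmap.collision_assignment import assign_voxels
from voxmap.core import NeuronMesh, VoxelGrid
from voxmap.expression_calling import records_from_assignment
from voxmap.landmark_registration import apply_transform, register
from voxmap.voxel_engine import stack_to_voxels


def ellipsoid_mesh(neuron_id, center, radii, subdivisions=3, cell_class=""):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    tm.apply_transform(np.diag([*radii, 1.0]))
    tm.apply_translation(center)
    return NeuronMesh(neuron_id=neuron_id, mesh=tm, cell_class=cell_class)


def make_grid(centers, volumes=None, intensity=None, gene="X",
              spacing=(1.0, 1.0, 1.0), frame="registered"):
    """VoxelGrid straight from explicit centers (indices synthetic)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n = len(centers)
    if volumes is None:
        volumes = np.full(n, float(np.prod(spacing)))
    if intensity is None:
        intensity = np.full(n, 255, dtype=np.uint8)
    idx = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    return VoxelGrid(
        gene=gene, indices=idx, centers=centers,
        intensity=np.asarray(intensity), expression_volume=np.asarray(volumes, float),
        spacing=tuple(spacing), stack_shape=(1, n, 1), frame=frame)


@pytest.fixture(scope="session")
def hindbrain_noiseless():
    """Rendered noiseless hindbrain scene shared across tests."""
    spec, truth = syn.hindbrain_fixture(7, noiseless=True)
    meshes = syn.make_neuron_meshes(spec)
    stacks, _ = syn.render_stack(spec, meshes)
    return {"spec": spec, "truth": truth, "meshes": meshes, "stacks": stacks}


@pytest.fixture(scope="session")
def hindbrain_records(hindbrain_noiseless):
    """Registered per-neuron expression records for the noiseless fixture."""
    spec = hindbrain_noiseless["spec"]
    meshes = hindbrain_noiseless["meshes"]
    grids = {g: stack_to_voxels(s) for g, s in hindbrain_noiseless["stacks"].items()}
    transform, rmsd = register(
        grids, meshes, syn.hindbrain_landmark_spec(spec))
    records = pd.concat(
        [records_from_assignment(
            assign_voxels(apply_transform(grid, transform), meshes), meshes, gene)
         for gene, grid in grids.items()],
        ignore_index=True)
    return {"records": records, "transform": transform, "rmsd": rmsd,
            "grids": grids}
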