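"""Convert image stacks into physically scaled voxel grids.

Each retained voxel carries an *expression volume*: the µm³ of probe
signal credited to it.  Two conventions are offered — ``binary`` credits
the full voxel volume to every voxel at or above the intensity floor;
``weighted`` scales the voxel volume by intensity/255.
"""

from __future__ import annotations

import numpy as np

from .core import ImageStack, VoxelGrid, VoxmapError

MODES = ("binary", "weighted")
DEFAULT_INTENSITY_FLOOR = 10


def voxel_volume(spacing) -> float:
    """Physical volume (µm³) of one voxel: px_x · px_y · dz."""
    px_x, px_y, dz = (float(s) for s in spacing)
    if px_x <= 0 or px_y <= 0 or dz <= 0:
        raise VoxmapError(f"spacing must be positive, got {spacing}")
    return px_x * px_y * dz


def stack_to_voxels(
    stack: ImageStack,
    intensity_floor: int = DEFAULT_INTENSITY_FLOOR,
    mode: str = "binary",
) -> VoxelGrid:
    """Voxelize a stack, keeping pixels with intensity ≥ ``intensity_floor``.

    Voxel centers sit at pixel centers: ``((r+0.5)·px_x, (c+0.5)·px_y,
    (k+0.5)·dz)`` for pixel (row r, column c) of plane k.  Order is
    plane-major then row-major, so grids are deterministic and stable.
    """
    if not 0 <= intensity_floor <= 255:
        raise VoxmapError(f"intensity_floor must be in 0–255, got {intensity_floor}")
    if mode not in MODES:
        raise VoxmapError(f"mode must be one of {MODES}, got {mode!r}")
    vol = voxel_volume(stack.spacing)
    planes = stack.planes
    k, r, c = np.nonzero(planes >= intensity_floor)
    # np.nonzero iterates C-order on (plane, row, col): plane-major, row-major
    indices = np.column_stack([r, c, k]).astype(np.int64)
    intensity = planes[k, r, c]
    centers = np.column_stack([
        (r + 0.5) * stack.px_x,
        (c + 0.5) * stack.px_y,
        (k + 0.5) * stack.dz,
    ])
    if mode == "binary":
        expr = np.full(len(indices), vol, dtype=float)
    else:
        expr = vol * intensity.astype(float) / 255.0
    return VoxelGrid(
        gene=stack.gene,
        indices=indices,
        centers=centers,
        intensity=intensity,
        expression_volume=expr,
        spacing=stack.spacing,
        stack_shape=stack.shape,
    )


def dense_mask(grid: VoxelGrid) -> np.ndarray:
    """Boolean (rows, cols, planes) occupancy array for the retained voxels."""
    mask = np.zeros(
        (grid.stack_shape[1], grid.stack_shape[2], grid.stack_shape[0]), dtype=bool)
    r, c, k = grid.indices.T
    mask[r, c, k] = True
    return mask


def grid_to_table(grid: VoxelGrid):
    """Voxel dump as a DataFrame (i, j, k, x, y, z, intensity, expression_volume)."""
    import pandas as pd

    return pd.DataFrame({
        "i": grid.indices[:, 0],
        "j": grid.indices[:, 1],
        "k": grid.indices[:, 2],
        "x": grid.centers[:, 0],
        "y": grid.centers[:, 1],
        "z": grid.centers[:, 2],
        "intensity": grid.intensity,
        "expression_volume": grid.expression_volume,
    })
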