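"""Core in-memory containers shared across the pipeline.

The pipeline moves between three representations of the same physical
space (all coordinates in micrometres):

* an :class:`ImageStack` — the raw multi-page fluorescence image for one
  probe, with physical pixel size and z-spacing;
* a :class:`VoxelGrid` — the physically scaled voxels retained above an
  intensity floor, each carrying an "expression volume";
* a set of :class:`NeuronMesh` objects — closed triangulated surfaces of
  reconstructed connectome neurons, fixed in the reference (mesh) frame.

A :class:`RigidTransform` maps stack-frame coordinates into the mesh
frame.  Axis convention: +x anterior→posterior (image rows), +y
left→right (image columns), +z ventral→dorsal (image planes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import trimesh


class VoxmapError(Exception):
    """Base class for pipeline errors."""


@dataclass
class ImageStack:
    """One probe channel: ordered z-planes of 8-bit intensities.

    ``planes`` has shape ``(n_planes, n_rows, n_cols)`` with dtype uint8.
    ``px_x`` is the physical size of one row step, ``px_y`` of one column
    step, ``dz`` the spacing between planes (all µm).
    """

    gene: str
    planes: np.ndarray
    px_x: float
    px_y: float
    dz: float

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise VoxmapError(
                f"stack for {self.gene!r} must be 3-D (planes, rows, cols); "
                f"got shape {self.planes.shape}"
            )
        if self.planes.dtype != np.uint8:
            if self.planes.min() < 0 or self.planes.max() > 255:
                raise VoxmapError("stack values must lie in 0–255")
            self.planes = self.planes.astype(np.uint8)
        for name in ("px_x", "px_y", "dz"):
            if not getattr(self, name) > 0:
                raise VoxmapError(f"{name} must be positive")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.px_x, self.px_y, self.dz)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.planes.shape


@dataclass
class VoxelGrid:
    """Sparse physically scaled voxels retained from an image stack.

    ``indices`` holds integer ``(row, col, plane)`` triples, ``centers``
    the corresponding physical centers, ``intensity`` the 8-bit value and
    ``expression_volume`` the µm³ of expression credited to the voxel.
    ``frame`` is ``"stack"`` until a rigid transform maps it into the
    mesh frame (``"registered"``).
    """

    gene: str
    indices: np.ndarray          # (N, 3) int
    centers: np.ndarray          # (N, 3) float, µm
    intensity: np.ndarray        # (N,) uint8
    expression_volume: np.ndarray  # (N,) float, µm³
    spacing: tuple[float, float, float]
    stack_shape: tuple[int, int, int]
    frame: str = "stack"

    def __post_init__(self) -> None:
        n = len(self.indices)
        for name in ("centers", "intensity", "expression_volume"):
            if len(getattr(self, name)) != n:
                raise VoxmapError("voxel arrays must have equal length")
        if self.frame not in ("stack", "registered"):
            raise VoxmapError(f"unknown frame label {self.frame!r}")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def voxel_volume(self) -> float:
        px_x, px_y, dz = self.spacing
        return px_x * px_y * dz

    @property
    def total_expression_volume(self) -> float:
        return float(self.expression_volume.sum())

    def with_centers(self, centers: np.ndarray, frame: str) -> "VoxelGrid":
        return replace(self, centers=centers, frame=frame)


@dataclass
class NeuronMesh:
    """A watertight triangulated neuron surface in mesh-frame µm."""

    neuron_id: str
    mesh: trimesh.Trimesh
    cell_class: str = ""

    def __post_init__(self) -> None:
        if not self.mesh.is_watertight:
            _, counts = np.unique(self.mesh.edges_sorted, axis=0, return_counts=True)
            n_open = int((counts != 2).sum())
            raise VoxmapError(
                f"mesh {self.neuron_id!r} is not watertight ({n_open} open edges)"
            )
        if self.mesh.volume < 0:
            self.mesh.invert()

    @property
    def volume(self) -> float:
        """Enclosed volume (µm³) by signed tetrahedron summation."""
        return float(self.mesh.volume)

    @property
    def bounds(self) -> np.ndarray:
        """Axis-aligned bounding box, shape (2, 3)."""
        return self.mesh.bounds

    @property
    def centroid(self) -> np.ndarray:
        """Centroid of the enclosed volume."""
        return np.asarray(self.mesh.center_mass, dtype=float)


@dataclass
class RigidTransform:
    """Proper rotation + translation (+ optional uniform scale), stack→mesh."""

    rotation: np.ndarray = field(
        default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise VoxmapError("rotation must be 3×3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise VoxmapError("rotation must be orthonormal (RᵀR = I within 1e-9)")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise VoxmapError("rotation must be proper (det +1)")
        if not self.scale > 0:
            raise VoxmapError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.scale * pts @ self.rotation.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(
            rotation=rot_inv,
            translation=-rot_inv @ self.translation / self.scale,
            scale=1.0 / self.scale,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation
            + self.translation,
            scale=self.scale * other.scale,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def about_z(cls, degrees: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        a = np.deg2rad(degrees)
        rot = np.array(
            [[np.cos(a), -np.sin(a), 0.0],
             [np.sin(a), np.cos(a), 0.0],
             [0.0, 0.0, 1.0]]
        )
        return cls(rotation=rot, translation=np.asarray(translation, dtype=float))

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "scale": float(self.scale),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RigidTransform":
        return cls(
            rotation=np.asarray(d["rotation"], dtype=float),
            translation=np.asarray(d["translation"], dtype=float),
            scale=float(d.get("scale", 1.0)),
        )


# Ground-truth labels: gene name -> set of positive neuron ids.
GroundTruthLabels = dict


@dataclass
class CallMatrix:
    """Per-neuron, per-gene expression calls with supporting statistics.

    ``calls`` is a boolean DataFrame (index neuron_id, columns genes).
    ``percent`` and ``relative`` are optional companion DataFrames with
    the same shape; ``cell_class`` an optional Series indexed like calls.
    """

    calls: pd.DataFrame
    percent: pd.DataFrame | None = None
    relative: pd.DataFrame | None = None
    cell_class: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dupes = self.calls.index[self.calls.index.duplicated()].tolist()
            raise VoxmapError(f"duplicate neuron ids in call matrix: {dupes}")
        self.calls = self.calls.astype(bool)
        for name in ("percent", "relative"):
            other = getattr(self, name)
            if other is not None and (
                not other.index.equals(self.calls.index)
                or list(other.columns) != list(self.calls.columns)
            ):
                raise VoxmapError(f"{name} frame must align with calls frame")
        if self.relative is not None:
            vals = self.relative.to_numpy(dtype=float)
            if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
                raise VoxmapError("relative expression must lie in [0, 1]")

    @property
    def neuron_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def genes(self) -> list[str]:
        return list(self.calls.columns)

    def positives(self, gene: str) -> set[str]:
        if gene not in self.calls.columns:
            raise VoxmapError(f"unknown gene {gene!r}")
        col = self.calls[gene]
        return set(col.index[col])
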