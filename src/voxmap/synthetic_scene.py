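"""Connectome-like synthetic scenes with planted expression truth.

Real inputs to this pipeline — whole-CNS confocal HCR stacks and the
reconstructed neuron meshes — live in external archives.  This module
generates stand-ins with the same structure so every downstream stage is
testable without any download: ellipsoidal neuron volumes at
class-stereotyped centroids, multi-channel 8-bit image stacks with
planted per-neuron expression, Gaussian noise and blur, and a known
rigid pose offset between the stack frame and the mesh frame.

Ellipsoids are deliberate: they are watertight, have analytic volumes
((4/3)π·a·b·c) and an exact membership inequality, so every stage can be
checked against a closed form.  Rendering tests membership against the
analytic inequality, not against the meshes, keeping the generator
independent of the collision code it is used to test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage

from .core import GroundTruthLabels, ImageStack, NeuronMesh, RigidTransform, VoxmapError
from .landmark_registration import LandmarkGroup, LandmarkSpec

ICOSPHERE_SUBDIVISIONS = 3

# Rendering conditions used by the packaged fixtures: 8-bit in-cell and
# background intensity laws and a blur mimicking a confocal PSF.  The
# source study states none of these acquisition parameters; values are
# chosen once as confocal-realistic and exposed in config.
DEFAULT_INTENSITY_LAW = (180.0, 25.0)
DEFAULT_BACKGROUND_LAW = (5.0, 3.0)
DEFAULT_BLUR_SIGMA = 0.4          # µm
NOISELESS_INTENSITY_LAW = (200.0, 0.0)
NOISELESS_BACKGROUND_LAW = (0.0, 0.0)


@dataclass
class SceneSpec:
    """Full description of a synthetic scene; rendering is a pure function of it.

    ``neuron_centroids`` lists ``(neuron_id, cell_class, (x, y, z))`` in
    mesh-frame µm.  ``neuron_radii`` gives default per-axis semi-axes,
    optionally overridden per id via ``radii_overrides``.  ``pose_offset``
    maps stack-frame coordinates to mesh-frame coordinates; the rendered
    stack lives in the stack frame, i.e. the scene is the mesh-frame
    content seen through the inverse pose.  ``shape`` is
    ``(n_planes, n_rows, n_cols)``.
    """

    name: str
    neuron_centroids: list[tuple[str, str, tuple[float, float, float]]]
    neuron_radii: tuple[float, float, float]
    channels: list[str]
    planted_truth: GroundTruthLabels
    intensity_law: tuple[float, float] = DEFAULT_INTENSITY_LAW
    background_law: tuple[float, float] = DEFAULT_BACKGROUND_LAW
    blur_sigma: float = DEFAULT_BLUR_SIGMA
    pose_offset: RigidTransform = field(default_factory=RigidTransform.identity)
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    shape: tuple[int, int, int] = (32, 128, 64)
    seed: int = 0
    radii_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [nid for nid, _, _ in self.neuron_centroids]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise VoxmapError(f"duplicate neuron ids in scene: {dupes}")
        pts = np.asarray([c for _, _, c in self.neuron_centroids], dtype=float)
        if len(pts) > 1:
            from scipy.spatial.distance import pdist
            if pdist(pts).min() == 0:
                raise VoxmapError("neuron centroids must be pairwise distinct")
        for radii in [self.neuron_radii, *self.radii_overrides.values()]:
            if not all(r > 0 for r in radii):
                raise VoxmapError("all semi-axes must be positive")
        if not all(s > 0 for s in self.spacing):
            raise VoxmapError("spacing components must be positive")
        known = set(ids)
        for gene, pos in self.planted_truth.items():
            unknown = sorted(set(pos) - known)
            if unknown:
                raise VoxmapError(
                    f"planted truth for {gene!r} names unknown neurons: {unknown}")
        if self.intensity_law[0] <= self.background_law[0]:
            raise VoxmapError("in-cell mean intensity must exceed background mean")

    def radii_for(self, neuron_id: str) -> tuple[float, float, float]:
        return tuple(self.radii_overrides.get(neuron_id, self.neuron_radii))

    @property
    def neuron_ids(self) -> list[str]:
        return [nid for nid, _, _ in self.neuron_centroids]

    def centroid_of(self, neuron_id: str) -> np.ndarray:
        for nid, _, c in self.neuron_centroids:
            if nid == neuron_id:
                return np.asarray(c, dtype=float)
        raise VoxmapError(f"unknown neuron id {neuron_id!r}")

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical stack extents (x, y, z) in µm."""
        n_planes, n_rows, n_cols = self.shape
        px_x, px_y, dz = self.spacing
        return (n_rows * px_x, n_cols * px_y, n_planes * dz)


def ellipsoid_contains(points: np.ndarray, center, radii) -> np.ndarray:
    """Analytic membership: Σ ((pᵢ−cᵢ)/rᵢ)² < 1."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = (pts - np.asarray(center, dtype=float)) / np.asarray(radii, dtype=float)
    return (d ** 2).sum(axis=1) < 1.0


def make_neuron_meshes(spec: SceneSpec) -> list[NeuronMesh]:
    """One watertight triangulated ellipsoid per centroid (ids/classes carried)."""
    meshes = []
    for nid, cls, center in spec.neuron_centroids:
        a, b, c = spec.radii_for(nid)
        tm = trimesh.creation.icosphere(subdivisions=ICOSPHERE_SUBDIVISIONS, radius=1.0)
        tm.apply_transform(np.diag([a, b, c, 1.0]))
        tm.apply_translation(center)
        meshes.append(NeuronMesh(neuron_id=nid, mesh=tm, cell_class=cls))
    return meshes


def _validate_coverage(spec: SceneSpec) -> None:
    """Warn if any neuron (pose-inverted into the stack frame) leaves the stack."""
    inv = spec.pose_offset.inverse()
    ex, ey, ez = spec.extent
    for nid, _, center in spec.neuron_centroids:
        r = max(spec.radii_for(nid))
        p = inv.apply(np.asarray(center, dtype=float))
        lo = p - r
        hi = p + r
        if (lo < 0).any() or hi[0] > ex or hi[1] > ey or hi[2] > ez:
            warnings.warn(
                f"neuron {nid!r} extends beyond the rendered stack "
                f"(stack-frame bounds {lo.round(2)}–{hi.round(2)})",
                stacklevel=3,
            )


def _stack_centers(spec: SceneSpec) -> np.ndarray:
    """(N, 3) stack-frame voxel centers, plane-major then row-major order."""
    n_planes, n_rows, n_cols = spec.shape
    px_x, px_y, dz = spec.spacing
    k, r, c = np.meshgrid(
        np.arange(n_planes), np.arange(n_rows), np.arange(n_cols), indexing="ij")
    return np.column_stack([
        (r.ravel() + 0.5) * px_x,
        (c.ravel() + 0.5) * px_y,
        (k.ravel() + 0.5) * dz,
    ])


def render_stack(
    spec: SceneSpec, meshes: list[NeuronMesh] | None = None
) -> tuple[dict[str, ImageStack], GroundTruthLabels]:
    """Render one 8-bit channel per gene plus the planted truth, verbatim.

    Draw order (fixed so fixtures are stable): channels in spec order;
    per channel, one background field first, then in-cell intensities
    for each planted-positive neuron in centroid-list order (later
    neurons overwrite earlier ones on overlap).  Blur, then clipping to
    0–255, then integer cast with round-half-up.  Membership uses the
    analytic ellipsoid inequality on pose-transformed voxel centers; the
    ``meshes`` argument is accepted for interface symmetry only.
    """
    if min(spec.neuron_radii) < max(spec.spacing):
        warnings.warn(
            "voxel spacing is coarser than the smallest semi-axis; some "
            "neurons may contain no voxel centers",
            stacklevel=2,
        )
    _validate_coverage(spec)
    rng = np.random.default_rng(spec.seed)
    centers_mesh = spec.pose_offset.apply(_stack_centers(spec))
    n_planes, n_rows, n_cols = spec.shape
    bg_mean, bg_sd = spec.background_law
    cell_mean, cell_sd = spec.intensity_law
    px_x, px_y, dz = spec.spacing
    sigma = (spec.blur_sigma / dz, spec.blur_sigma / px_x, spec.blur_sigma / px_y)

    stacks: dict[str, ImageStack] = {}
    for gene in spec.channels:
        field_flat = (
            rng.normal(bg_mean, bg_sd, size=len(centers_mesh))
            if bg_sd > 0 else np.full(len(centers_mesh), float(bg_mean))
        )
        positives = spec.planted_truth.get(gene, set())
        for nid, _, center in spec.neuron_centroids:
            if nid not in positives:
                continue
            mask = ellipsoid_contains(centers_mesh, center, spec.radii_for(nid))
            n_in = int(mask.sum())
            field_flat[mask] = (
                rng.normal(cell_mean, cell_sd, size=n_in)
                if cell_sd > 0 else float(cell_mean)
            )
        vol = field_flat.reshape(n_planes, n_rows, n_cols)
        if spec.blur_sigma > 0:
            vol = ndimage.gaussian_filter(vol, sigma=sigma)
        vol = np.clip(vol, 0.0, 255.0)
        planes = np.floor(vol + 0.5).astype(np.uint8)  # round half up
        stacks[gene] = ImageStack(
            gene=gene, planes=planes, px_x=px_x, px_y=px_y, dz=dz)
    truth = {g: set(ids) for g, ids in spec.planted_truth.items()}
    return stacks, truth


# ---------------------------------------------------------------------------
# hindbrain (motor ganglion) calibration fixture

_HINDBRAIN_POSE = RigidTransform.about_z(4.0, translation=(2.0, -1.5, 1.0))


def _hindbrain_centroids() -> list[tuple[str, str, tuple[float, float, float]]]:
    rows: list[tuple[str, str, tuple[float, float, float]]] = []
    for i in range(7):
        rows.append((f"AMG{i + 1}", "AMG", (8.0 + 6.0 * i, 15.0, 24.0)))
    for i, x in enumerate((12.0, 20.0, 28.0)):
        rows.append((f"MGIN{i + 1}L", "MGIN", (x, 8.0, 10.0)))
        rows.append((f"MGIN{i + 1}R", "MGIN", (x, 22.0, 10.0)))
    for i, x in enumerate((36.0, 44.0, 52.0)):
        rows.append((f"MN{i + 1}L", "MN", (x, 8.0, 10.0)))
        rows.append((f"MN{i + 1}R", "MN", (x, 22.0, 10.0)))
    return rows


def hindbrain_truth() -> GroundTruthLabels:
    """The hindbrain ground truth used to calibrate the call threshold.

    VAChT marks AMG5, the MGINs and the MNs; VGAT marks AMG1–4, 6, 7;
    AMPAR is confined to the left-side MNs.
    """
    mgin = {f"MGIN{i}L" for i in (1, 2, 3)} | {f"MGIN{i}R" for i in (1, 2, 3)}
    mn = {f"MN{i}L" for i in (1, 2, 3)} | {f"MN{i}R" for i in (1, 2, 3)}
    return {
        "VAChT": {"AMG5"} | mgin | mn,
        "VGAT": {"AMG1", "AMG2", "AMG3", "AMG4", "AMG6", "AMG7"},
        "AMPAR": {"MN1L", "MN2L", "MN3L"},
    }


def hindbrain_fixture(
    seed: int, noiseless: bool = False
) -> tuple[SceneSpec, GroundTruthLabels]:
    """Packaged motor-ganglion scene with the known transmitter/receptor truth.

    Planted positives render with expression through the whole cell
    volume (true expression percent far above 8%); negatives receive
    only background (below 2%), so a wide band of thresholds — including
    5.5% — separates them perfectly.
    """
    truth = hindbrain_truth()
    spec = SceneSpec(
        name="hindbrain",
        neuron_centroids=_hindbrain_centroids(),
        neuron_radii=(2.8, 2.8, 2.8),
        radii_overrides={f"AMG{i + 1}": (2.2, 2.5, 2.2) for i in range(7)},
        channels=["VAChT", "VGAT", "AMPAR"],
        planted_truth=truth,
        intensity_law=NOISELESS_INTENSITY_LAW if noiseless else DEFAULT_INTENSITY_LAW,
        background_law=NOISELESS_BACKGROUND_LAW if noiseless else DEFAULT_BACKGROUND_LAW,
        blur_sigma=0.0 if noiseless else DEFAULT_BLUR_SIGMA,
        pose_offset=_HINDBRAIN_POSE,
        spacing=(0.5, 0.5, 1.0),
        shape=(32, 128, 64),
        seed=seed,
    )
    return spec, truth


def hindbrain_landmark_spec(spec: SceneSpec, pad: float = 5.0) -> LandmarkSpec:
    """Four single-neuron landmark groups for the hindbrain fixture.

    Search regions are stack-frame boxes around each landmark's
    approximate position (the pose-inverted centroid), mirroring a user
    pointing at an identifiable blob.
    """
    inv = spec.pose_offset.inverse()
    groups = []
    for name, nid, channel in (
        ("amg-anterior", "AMG1", "VGAT"),
        ("amg-posterior", "AMG7", "VGAT"),
        ("mn-left-posterior", "MN3L", "VAChT"),
        ("mgin-right-anterior", "MGIN1R", "VAChT"),
    ):
        p = inv.apply(spec.centroid_of(nid))
        groups.append(LandmarkGroup(
            name=name, neuron_ids=[nid], channel=channel,
            region=(tuple(p - pad), tuple(p + pad)),
        ))
    return LandmarkSpec(groups=groups)


# ---------------------------------------------------------------------------
# full-CNS scene seeded from the packaged reference call table

# Approximate anterior→posterior / left–right / ventral–dorsal anchors
# for each cell class (µm); members are placed on a 5 µm lattice at the
# free sites nearest their class anchor, so cells are stereotyped,
# disjoint, and deterministic.
_CLASS_ANCHORS: dict[str, tuple[float, float, float]] = {
    "PNIN": (10.0, 16.0, 12.0),
    "BVIN": (14.0, 10.0, 18.0),
    "cor-ass BVIN": (14.0, 22.0, 10.0),
    "Coronet": (22.0, 14.0, 20.0),
    "Eminens": (24.0, 16.0, 28.0),
    "Ambiguous cells": (20.0, 7.0, 7.0),
    "PR (II)": (26.0, 25.0, 14.0),
    "PR (I)": (34.0, 23.0, 17.0),
    "PR (III)": (30.0, 11.0, 17.0),
    "Bipolar prIN": (30.0, 6.0, 12.0),
    "pr-BTN RN": (36.0, 8.0, 21.0),
    "pr-cor RN": (38.0, 18.0, 12.0),
    "prRN": (42.0, 14.0, 17.0),
    "pr-AMG RN": (44.0, 21.0, 11.0),
    "Antenna": (38.0, 16.0, 6.0),
    "AntRN": (46.0, 9.0, 9.0),
    "Nonsensory RN": (48.0, 16.0, 21.0),
    "aaIN": (50.0, 11.0, 16.0),
    "PN RN": (46.0, 24.0, 18.0),
    "PBV PNIN": (52.0, 21.0, 7.0),
    "Neck": (56.0, 16.0, 14.0),
    "AMG": (72.0, 16.0, 26.0),
}
_LR_ANCHORS: dict[str, tuple[float, float, float]] = {
    "ddN": (60.0, 16.0, 15.0),
    "MGIN": (68.0, 16.0, 10.0),
    "MN": (84.0, 16.0, 10.0),
}
_LATTICE_PITCH = 5.0
_CONNECTOME_POSE = RigidTransform.about_z(3.0, translation=(2.0, -3.5, 1.0))


def _lattice_sites() -> np.ndarray:
    xs = np.arange(5.0, 96.0, _LATTICE_PITCH)
    ys = np.arange(6.0, 27.0, _LATTICE_PITCH)
    zs = np.arange(6.0, 27.0, _LATTICE_PITCH)
    return np.array(list(itertools.product(xs, ys, zs)), dtype=float)


def _place_neurons(
    rows: list[tuple[str, str]]
) -> list[tuple[str, str, tuple[float, float, float]]]:
    """Greedy nearest-free-site placement of each neuron near its class anchor."""
    sites = _lattice_sites()
    free = np.ones(len(sites), dtype=bool)
    placed = []
    for nid, cls in rows:
        if cls in _LR_ANCHORS:
            ax, ay, az = _LR_ANCHORS[cls]
            side = nid[-1] if nid[-1] in ("L", "R") else ""
            ay = 8.5 if side == "L" else 23.5 if side == "R" else ay
            anchor = np.array([ax, ay, az])
        else:
            anchor = np.array(_CLASS_ANCHORS.get(cls, (50.0, 16.0, 16.0)))
        d = np.linalg.norm(sites - anchor, axis=1)
        d[~free] = np.inf
        best = int(np.argmin(d))
        free[best] = False
        placed.append((nid, cls, tuple(sites[best])))
    return placed


def connectome_scene(
    seed: int, noiseless: bool = False
) -> tuple[SceneSpec, GroundTruthLabels]:
    """Full-CNS scene: one ellipsoid per reference-table neuron, planted
    truth equal to the packaged published call matrix (5 probes)."""
    from .stack_io import load_reference_calls

    ref = load_reference_calls()
    rows = [(nid, str(ref.cell_class.loc[nid])) for nid in ref.neuron_ids]
    truth = {gene: ref.positives(gene) for gene in ref.genes}
    spec = SceneSpec(
        name="connectome",
        neuron_centroids=_place_neurons(rows),
        neuron_radii=(2.0, 2.0, 2.0),
        channels=list(ref.genes),
        planted_truth=truth,
        intensity_law=NOISELESS_INTENSITY_LAW if noiseless else DEFAULT_INTENSITY_LAW,
        background_law=NOISELESS_BACKGROUND_LAW if noiseless else DEFAULT_BACKGROUND_LAW,
        blur_sigma=0.0 if noiseless else DEFAULT_BLUR_SIGMA,
        pose_offset=_CONNECTOME_POSE,
        spacing=(0.8, 0.8, 1.2),
        shape=(27, 130, 44),
        seed=seed,
    )
    return spec, truth


def connectome_landmark_spec(spec: SceneSpec, pad: float = 2.8) -> LandmarkSpec:
    """VGAT landmark groups mirroring the published alignment criteria.

    The dorsal cap marks the eminens cells; the right-side posterior and
    anterior patches mark the PR-I (pr10 carries the planted VGAT
    signal) and PR-II photoreceptor groups; the dorsal hindbrain patch
    marks the VGAT-positive AMGs.  Groups use the ``region_union``
    selector because the ellipsoid stand-ins for one anatomical patch
    need not be spatially contiguous.
    """
    inv = spec.pose_offset.inverse()
    vgat = spec.planted_truth.get("VGAT", set())

    def group(name: str, ids: list[str]) -> LandmarkGroup:
        pts = np.array([inv.apply(spec.centroid_of(i)) for i in ids])
        return LandmarkGroup(
            name=name, neuron_ids=ids, channel="VGAT",
            region=(tuple(pts.min(axis=0) - pad), tuple(pts.max(axis=0) + pad)),
            selector="region_union",
        )

    amg_pos = sorted(i for i in vgat if i.startswith("AMG"))
    return LandmarkSpec(groups=[
        group("eminens-cap", ["109", "99"]),
        group("pr-i-patch", ["pr10"]),
        group("pr-ii-patch", [f"pr-{s}" for s in "abcdefg"]),
        group("amg-patch", amg_pos),
    ])


# ---------------------------------------------------------------------------
# on-disk scene export

def save_scene(
    spec: SceneSpec,
    out_dir,
    landmarks: LandmarkSpec | None = None,
) -> dict:
    """Render and write a complete scene directory.

    Layout: ``<scene>_<gene>.tif`` per channel, ``spacing.yaml`` sidecar,
    ``truth.json``, ``cells.tsv``, ``meshes/*.obj`` and optionally
    ``landmarks.yaml``.  Returns the manifest of written paths.
    """
    from pathlib import Path

    from . import stack_io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meshes = make_neuron_meshes(spec)
    stacks, truth = render_stack(spec, meshes)
    manifest: dict = {"stacks": {}}
    for gene, stack in stacks.items():
        p = stack_io.write_stack(stack, out_dir / f"{spec.name}_{gene}.tif")
        manifest["stacks"][gene] = str(p)
    stack_io.write_config(
        {"spacing": {"px_x": spec.spacing[0], "px_y": spec.spacing[1],
                     "dz": spec.spacing[2]},
         "scene": spec.name, "seed": spec.seed},
        out_dir / "spacing.yaml")
    manifest["spacing"] = str(out_dir / "spacing.yaml")
    stack_io.write_truth(truth, out_dir / "truth.json")
    manifest["truth"] = str(out_dir / "truth.json")
    with open(out_dir / "cells.tsv", "w", newline="\n") as f:
        f.write("neuron_id\tcell_class\n")
        for nid, cls, _ in spec.neuron_centroids:
            f.write(f"{nid}\t{cls}\n")
    manifest["cells"] = str(out_dir / "cells.tsv")
    stack_io.write_meshes(meshes, out_dir / "meshes")
    manifest["meshes"] = str(out_dir / "meshes")
    if landmarks is not None:
        stack_io.write_config(landmarks.to_dict(), out_dir / "landmarks.yaml")
        manifest["landmarks"] = str(out_dir / "landmarks.yaml")
    return manifest
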