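"""Readers and writers for every on-disk artifact.

Formats: multi-page grayscale TIFF image stacks (8- or 16-bit), OBJ/PLY
neuron meshes, per-plane CSV intensity tables, TSV cell-class tables,
TSV call matrices, JSON ground-truth labels, TSV synapse edge lists and
YAML configs.  Physical units are always micrometres and always flow
from explicit metadata or config — never guessed from file contents.
"""

from __future__ import annotations

import json
import logging
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh
import yaml

from .core import CallMatrix, GroundTruthLabels, ImageStack, NeuronMesh, VoxmapError

log = logging.getLogger(__name__)

MESH_SUFFIXES = (".obj", ".ply")


# ---------------------------------------------------------------------------
# image stacks

def read_stack(path, spacing, gene: str | None = None) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    ``spacing`` is the ``(px_x, px_y, dz)`` physical voxel pitch in µm;
    it must be supplied explicitly.  16-bit inputs are rescaled to 0–255
    by max-normalization then rounded.
    """
    path = Path(path)
    if spacing is None:
        raise VoxmapError(
            f"no physical spacing supplied for {path.name}; spacing must come "
            "from metadata or config, it is never guessed"
        )
    px_x, px_y, dz = (float(s) for s in spacing)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise VoxmapError(
            f"{path.name}: expected grayscale pages, got array of shape {arr.shape} "
            "(RGB / multi-sample TIFFs are unsupported)"
        )
    if arr.dtype == np.uint8:
        planes = arr
    elif arr.dtype == np.uint16:
        peak = int(arr.max())
        if peak == 0:
            planes = arr.astype(np.uint8)
        else:
            planes = np.rint(arr.astype(float) * (255.0 / peak)).astype(np.uint8)
    else:
        raise VoxmapError(f"{path.name}: unsupported TIFF dtype {arr.dtype}")
    if gene is None:
        gene = path.stem
    log.info("read %s: %d planes of %d×%d, spacing (%g, %g, %g) µm",
             path.name, *planes.shape, px_x, px_y, dz)
    return ImageStack(gene=gene, planes=planes, px_x=px_x, px_y=px_y, dz=dz)


def write_stack(stack: ImageStack, path) -> Path:
    """Write an 8-bit multi-page grayscale TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.planes, photometric="minisblack")
    return path


def write_plane_csv(stack: ImageStack, out_dir) -> list[Path]:
    """Write one headerless CSV per z-plane; cell (r, c) is pixel (r, c).

    Files are named ``<gene>_z<k>.csv`` with a zero-padded plane index;
    row-major, LF line endings.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(stack.shape[0] - 1)))
    paths = []
    for k, plane in enumerate(stack.planes):
        p = out_dir / f"{stack.gene}_z{k:0{width}d}.csv"
        np.savetxt(p, plane, fmt="%d", delimiter=",", newline="\n")
        paths.append(p)
    return paths


def read_plane_csv(paths, spacing, gene: str) -> ImageStack:
    """Re-assemble an :class:`ImageStack` from per-plane CSVs (sorted order)."""
    planes = [np.loadtxt(p, delimiter=",", dtype=int, ndmin=2) for p in sorted(map(Path, paths))]
    return ImageStack(gene=gene, planes=np.stack(planes), px_x=spacing[0],
                      px_y=spacing[1], dz=spacing[2])


# ---------------------------------------------------------------------------
# meshes

def _load_one_mesh(path: Path, cell_class: str = "") -> NeuronMesh:
    mesh = trimesh.load(path, force="mesh")
    area = mesh.area_faces
    degenerate = area <= 0
    if degenerate.any():
        warnings.warn(
            f"{path.name}: dropping {int(degenerate.sum())} zero-area faces",
            stacklevel=2,
        )
        mesh.update_faces(~degenerate)
    return NeuronMesh(neuron_id=path.stem, mesh=mesh, cell_class=cell_class)


def read_meshes(path_or_dir, cell_table: pd.DataFrame | None = None) -> list[NeuronMesh]:
    """Load one watertight triangulated mesh per OBJ/PLY file.

    The neuron id is the filename stem.  If a cell table is given, class
    labels are attached and unknown ids rejected.
    """
    path = Path(path_or_dir)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in MESH_SUFFIXES)
        if not files:
            raise VoxmapError(f"no OBJ/PLY meshes found in {path}")
    else:
        files = [path]
    classes = {}
    if cell_table is not None:
        classes = dict(zip(cell_table["neuron_id"], cell_table["cell_class"]))
        unknown = [f.stem for f in files if f.stem not in classes]
        if unknown:
            raise VoxmapError(f"mesh ids missing from cell table: {unknown}")
    return [_load_one_mesh(f, classes.get(f.stem, "")) for f in files]


def write_meshes(meshes: list[NeuronMesh], out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for nm in meshes:
        p = out_dir / f"{nm.neuron_id}.obj"
        nm.mesh.export(p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# tables

def read_cell_table(path) -> pd.DataFrame:
    """Read a TSV of (neuron_id, cell_class) rows."""
    path = Path(path)
    df = _read_tsv(path)
    for col in ("neuron_id", "cell_class"):
        if col not in df.columns:
            raise VoxmapError(f"{path.name}: missing column {col!r}")
    dupes = df["neuron_id"][df["neuron_id"].duplicated()].tolist()
    if dupes:
        raise VoxmapError(f"{path.name}: duplicate neuron ids {dupes}")
    return df[["neuron_id", "cell_class"]].reset_index(drop=True)


def _read_tsv(path: Path) -> pd.DataFrame:
    with open(path) as f:
        header = f.readline().rstrip("\n").split("\t")
        rows = []
        for lineno, line in enumerate(f, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise VoxmapError(
                    f"{path.name}:{lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            rows.append(parts)
    return pd.DataFrame(rows, columns=header)


def read_truth(path, cell_table: pd.DataFrame | None = None) -> GroundTruthLabels:
    """Read ground-truth labels: JSON mapping gene → list of positive ids."""
    path = Path(path)
    with open(path) as f:
        raw = json.load(f)
    truth: GroundTruthLabels = {}
    for gene, ids in raw.items():
        if len(ids) != len(set(ids)):
            raise VoxmapError(f"{path.name}: duplicate ids in truth set for {gene!r}")
        truth[gene] = set(ids)
    if cell_table is not None:
        known = set(cell_table["neuron_id"])
        unknown = sorted(set().union(*truth.values(), set()) - known) if truth else []
        if unknown:
            raise VoxmapError(f"{path.name}: unknown neuron ids in truth: {unknown}")
    return truth


def write_truth(truth: GroundTruthLabels, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump({g: sorted(ids) for g, ids in truth.items()}, f, indent=1)
        f.write("\n")
    return path


def read_edges(path, cell_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a directed synapse edge list TSV with columns pre_id, post_id."""
    path = Path(path)
    df = _read_tsv(path)
    for col in ("pre_id", "post_id"):
        if col not in df.columns:
            raise VoxmapError(f"{path.name}: missing column {col!r}")
    if cell_table is not None:
        known = set(cell_table["neuron_id"])
        unknown = sorted(
            (set(df["pre_id"]) | set(df["post_id"])) - known)
        if unknown:
            raise VoxmapError(f"{path.name}: unknown neuron ids in edges: {unknown}")
    return df[["pre_id", "post_id"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# call matrices

def write_call_matrix(matrix: CallMatrix, path, table1_style: bool = False) -> Path:
    """Write calls as TSV (neuron_id, cell_class, one column per gene).

    Calls are encoded ``1``/``0`` by default; ``table1_style=True`` emits
    ``+``/``0`` for side-by-side comparison with the printed table.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pos, neg = ("+", "0") if table1_style else ("1", "0")
    with open(path, "w", newline="\n") as f:
        f.write("neuron_id\tcell_class\t" + "\t".join(matrix.genes) + "\n")
        for nid in matrix.neuron_ids:
            cls = ""
            if matrix.cell_class is not None:
                cls = str(matrix.cell_class.loc[nid])
            cells = [pos if matrix.calls.at[nid, g] else neg for g in matrix.genes]
            f.write("\t".join([str(nid), cls] + cells) + "\n")
    return path


def read_call_matrix(path) -> CallMatrix:
    """Read a TSV call matrix; accepts both 1/0 and +/0 call encodings."""
    path = Path(path)
    df = _read_tsv(path)
    if "neuron_id" not in df.columns:
        raise VoxmapError(f"{path.name}: missing column 'neuron_id'")
    genes = [c for c in df.columns if c not in ("neuron_id", "cell_class")]
    if not genes:
        raise VoxmapError(f"{path.name}: no gene columns")
    calls = {}
    for g in genes:
        col = df[g].astype(str).str.strip()
        bad = sorted(set(col) - {"+", "0", "1"})
        if bad:
            raise VoxmapError(f"{path.name}: unrecognized call values {bad} in {g!r}")
        calls[g] = col.isin(["+", "1"]).to_numpy()
    frame = pd.DataFrame(calls, index=pd.Index(df["neuron_id"], name="neuron_id"))
    cls = None
    if "cell_class" in df.columns:
        cls = pd.Series(df["cell_class"].to_numpy(), index=frame.index, name="cell_class")
    return CallMatrix(calls=frame, cell_class=cls)


# ---------------------------------------------------------------------------
# packaged reference data

def _data_path(name: str) -> Path:
    return Path(resources.files("voxmap.data") / name)


def load_reference_calls() -> CallMatrix:
    """The packaged transcription of the published 166-neuron call table."""
    return read_call_matrix(_data_path("reference_calls.tsv"))


def load_reference_cell_table() -> pd.DataFrame:
    m = load_reference_calls()
    return pd.DataFrame(
        {"neuron_id": m.neuron_ids, "cell_class": m.cell_class.to_numpy()})


def load_synthetic_edges() -> pd.DataFrame:
    """Synthetic edge fixture: only prose-stated pre→post relations."""
    return read_edges(_data_path("synthetic_edges.tsv"))


def load_synthetic_transmitters() -> CallMatrix:
    """Synthetic transmitter-call fixture for the edge fixture's presynaptic cells."""
    return read_call_matrix(_data_path("synthetic_transmitters.tsv"))


# ---------------------------------------------------------------------------
# config

def read_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise VoxmapError(f"{path}: config must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
    return path
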