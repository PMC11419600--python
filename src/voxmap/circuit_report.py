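"""Circuit-level summaries of a call matrix, and pipeline orchestration.

These queries re-express the study's circuit observations as recounts of
the matrix: per-class positive counts, receptor-profile neuron sets
(e.g. NMDAR+/AMPAR−), left/right asymmetry tables over homologous
pairs, and transmitter/receptor mismatch flags over a synapse edge list.
All reports are pure functions of (matrix, cell table, edges).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import stack_io
from .collision_assignment import assign_voxels
from .core import CallMatrix, VoxmapError
from .expression_calling import (
    DEFAULT_THRESHOLD,
    calibrate_threshold,
    make_call_matrix,
    records_from_assignment,
    score_agreement,
)
from .landmark_registration import LandmarkSpec, apply_transform, register
from .voxel_engine import DEFAULT_INTENSITY_FLOOR, stack_to_voxels

log = logging.getLogger(__name__)

IONOTROPIC_RECEPTORS = ("AMPAR", "NMDAR", "Kainate-R")


def class_summary(matrix: CallMatrix, cell_table: pd.DataFrame) -> pd.DataFrame:
    """Count call-positive neurons per (cell_class, gene), plus class sizes."""
    classes = dict(zip(cell_table["neuron_id"], cell_table["cell_class"]))
    unknown = [nid for nid in matrix.neuron_ids if nid not in classes]
    if unknown:
        raise VoxmapError(f"neuron ids missing from cell table: {unknown}")
    rows = []
    by_class: dict[str, list[str]] = {}
    for nid in matrix.neuron_ids:
        by_class.setdefault(classes[nid], []).append(nid)
    for cls, members in sorted(by_class.items()):
        row = {"cell_class": cls, "n_neurons": len(members)}
        for gene in matrix.genes:
            pos = matrix.positives(gene)
            row[gene] = sum(1 for nid in members if nid in pos)
        rows.append(row)
    return pd.DataFrame(rows)


def receptor_profile(
    matrix: CallMatrix,
    positive_genes: Sequence[str] = (),
    negative_genes: Sequence[str] = (),
    cell_class: str | None = None,
) -> set[str]:
    """Neurons positive for every ``positive_genes`` and negative for every
    ``negative_genes``; optionally restricted to one cell class."""
    for g in list(positive_genes) + list(negative_genes):
        if g not in matrix.genes:
            raise VoxmapError(f"unknown gene {g!r}")
    result = set(matrix.neuron_ids)
    for g in positive_genes:
        result &= matrix.positives(g)
    for g in negative_genes:
        result -= matrix.positives(g)
    if cell_class is not None:
        if matrix.cell_class is None:
            raise VoxmapError("matrix carries no cell classes")
        result = {nid for nid in result
                  if str(matrix.cell_class.loc[nid]) == cell_class}
    return result


def infer_lr_pairs(neuron_ids: Sequence[str]) -> list[tuple[str, str]]:
    """Pair ids by the …L/…R suffix convention (e.g. MN1L/MN1R)."""
    ids = set(neuron_ids)
    pairs = []
    for nid in neuron_ids:
        m = re.fullmatch(r"(.+)L", nid)
        if m and f"{m.group(1)}R" in ids:
            pairs.append((nid, f"{m.group(1)}R"))
    return pairs


def asymmetry_report(
    matrix: CallMatrix, pair_map: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Concordant/discordant call status per (gene, left/right pair).

    A pair is concordant for a gene when both sides carry the same call.
    The summary fraction discordant per gene is computable by recount.
    """
    known = set(matrix.neuron_ids)
    for left, right in pair_map:
        missing = [i for i in (left, right) if i not in known]
        if missing:
            raise VoxmapError(f"pair ({left}, {right}): unmatched ids {missing}")
    rows = []
    for gene in matrix.genes:
        pos = matrix.positives(gene)
        for left, right in pair_map:
            l_call, r_call = left in pos, right in pos
            rows.append({
                "gene": gene, "left_id": left, "right_id": right,
                "left_call": l_call, "right_call": r_call,
                "status": "concordant" if l_call == r_call else "discordant",
            })
    return pd.DataFrame(rows)


def asymmetry_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Fraction of discordant pairs per gene."""
    out = (report.assign(discordant=report["status"] == "discordant")
           .groupby("gene", sort=False)["discordant"]
           .agg(n_pairs="count", n_discordant="sum"))
    out["fraction_discordant"] = out["n_discordant"] / out["n_pairs"]
    return out.reset_index()


@dataclass
class MismatchReport:
    """Postsynaptic neurons with glutamatergic input but no ionotropic receptor."""

    flagged: pd.DataFrame        # neuron_id, glutamatergic partner list
    unresolved: list[str]        # edge endpoints absent from both matrices


def mismatch_flags(
    matrix: CallMatrix,
    edges: pd.DataFrame,
    transmitter_calls: CallMatrix,
    receptor_genes: Sequence[str] = IONOTROPIC_RECEPTORS,
    transmitter_gene: str = "VGLUT",
) -> MismatchReport:
    """Flag neurons whose presynaptic partners are glutamatergic while the
    neuron itself is negative for every ionotropic receptor gene."""
    if transmitter_gene not in transmitter_calls.genes:
        raise VoxmapError(
            f"transmitter matrix lacks the {transmitter_gene!r} marker")
    receptor_genes = [g for g in receptor_genes if g in matrix.genes]
    if not receptor_genes:
        raise VoxmapError("call matrix has none of the receptor genes")
    glut = transmitter_calls.positives(transmitter_gene)
    post_known = set(matrix.neuron_ids)
    pre_known = set(transmitter_calls.neuron_ids)

    unresolved = sorted(
        {p for p in edges["pre_id"] if p not in pre_known}
        | {p for p in edges["post_id"] if p not in post_known}
    )
    if unresolved:
        log.warning("unresolved edge endpoints: %s", unresolved)

    partners: dict[str, list[str]] = {}
    for pre, post in zip(edges["pre_id"], edges["post_id"]):
        if pre in glut and post in post_known:
            partners.setdefault(post, []).append(pre)

    any_receptor = set()
    for g in receptor_genes:
        any_receptor |= matrix.positives(g)
    rows = [
        {"neuron_id": post, "glutamatergic_partners": sorted(set(pres))}
        for post, pres in sorted(partners.items())
        if post not in any_receptor
    ]
    return MismatchReport(
        flagged=pd.DataFrame(rows, columns=["neuron_id", "glutamatergic_partners"]),
        unresolved=unresolved,
    )


# ---------------------------------------------------------------------------
# end-to-end orchestration

def run_pipeline(config: dict | str | Path, out_dir=None) -> dict:
    """simulate-or-read → voxelize → register → assign → call → report.

    ``config`` is a YAML path or an equivalent mapping.  Recognized keys:

    - ``scene``: ``{fixture: hindbrain|connectome, seed, noiseless}`` to
      simulate, or ``{stacks: {gene: path}, spacing: {px_x, px_y, dz},
      meshes: dir, cells: path, landmarks: path, truth: path}`` to read.
    - ``voxelize``: ``{intensity_floor, mode}``.
    - ``register``: ``{allow_scale, manual_transform}``.
    - ``assign``: ``{overlap_policy}``.
    - ``call``: ``{threshold, calibrate}``.
    - ``out``: output directory (overridden by ``out_dir``).

    Every intermediate is serialized under the output directory together
    with a machine-readable run log.  Returns ``{"matrix": CallMatrix,
    "reports": {...}, "paths": {...}}``.
    """
    if not isinstance(config, dict):
        config = stack_io.read_config(config)
    out_dir = Path(out_dir or config.get("out", "voxmap_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()

    scene_cfg = config.get("scene", {})
    stage = "input"
    try:
        if "fixture" in scene_cfg:
            from . import synthetic_scene as syn

            seed = int(scene_cfg.get("seed", 0))
            noiseless = bool(scene_cfg.get("noiseless", False))
            if scene_cfg["fixture"] == "hindbrain":
                spec, truth = syn.hindbrain_fixture(seed, noiseless=noiseless)
                landmarks = syn.hindbrain_landmark_spec(spec)
            elif scene_cfg["fixture"] == "connectome":
                spec, truth = syn.connectome_scene(seed, noiseless=noiseless)
                landmarks = syn.connectome_landmark_spec(spec)
            else:
                raise VoxmapError(f"unknown fixture {scene_cfg['fixture']!r}")
            meshes = syn.make_neuron_meshes(spec)
            stacks, _ = syn.render_stack(spec, meshes)
            cell_table = pd.DataFrame(
                {"neuron_id": [r[0] for r in spec.neuron_centroids],
                 "cell_class": [r[1] for r in spec.neuron_centroids]})
        else:
            spacing_cfg = scene_cfg.get("spacing")
            if spacing_cfg is None:
                raise VoxmapError(
                    "config gives no physical spacing for the input stacks "
                    "(scene.spacing with px_x, px_y, dz in µm is required)")
            spacing = (spacing_cfg["px_x"], spacing_cfg["px_y"], spacing_cfg["dz"])
            stacks = {
                gene: stack_io.read_stack(path, spacing, gene=gene)
                for gene, path in scene_cfg["stacks"].items()
            }
            cell_table = stack_io.read_cell_table(scene_cfg["cells"])
            meshes = stack_io.read_meshes(scene_cfg["meshes"], cell_table)
            landmarks = LandmarkSpec.from_dict(
                stack_io.read_config(scene_cfg["landmarks"]))
            truth = (stack_io.read_truth(scene_cfg["truth"], cell_table)
                     if "truth" in scene_cfg else None)

        stage = "voxelize"
        vox_cfg = config.get("voxelize", {})
        floor = int(vox_cfg.get("intensity_floor", DEFAULT_INTENSITY_FLOOR))
        mode = vox_cfg.get("mode", "binary")
        grids = {g: stack_to_voxels(s, intensity_floor=floor, mode=mode)
                 for g, s in stacks.items()}

        stage = "register"
        reg_cfg = config.get("register", {})
        if "manual_transform" in reg_cfg:
            from .core import RigidTransform

            transform = RigidTransform.from_dict(reg_cfg["manual_transform"])
            rmsd = float("nan")
        else:
            transform, rmsd = register(
                grids, meshes, landmarks,
                allow_scale=bool(reg_cfg.get("allow_scale", False)))
        registered = {g: apply_transform(grid, transform)
                      for g, grid in grids.items()}

        stage = "assign"
        policy = config.get("assign", {}).get("overlap_policy", "all")
        records = pd.concat(
            [records_from_assignment(
                assign_voxels(grid, meshes, overlap_policy=policy), meshes, gene)
             for gene, grid in registered.items()],
            ignore_index=True)

        stage = "call"
        call_cfg = config.get("call", {})
        threshold = float(call_cfg.get("threshold", DEFAULT_THRESHOLD))
        matrix = make_call_matrix(records, threshold=threshold)
        calibration = None
        if truth is not None and call_cfg.get("calibrate", True):
            calibration = calibrate_threshold(records, truth)

        stage = "report"
        summary = class_summary(matrix, cell_table)
        asym = asymmetry_report(matrix, infer_lr_pairs(matrix.neuron_ids))
        reports = {
            "class_summary": summary,
            "asymmetry": asym,
            "asymmetry_summary": asymmetry_summary(asym) if len(asym) else None,
            "calibration": calibration,
            "agreement": (score_agreement(matrix, truth)
                          if truth is not None else None),
            "registration_rmsd": rmsd,
            "transform": transform,
        }

        paths = _serialize_run(
            out_dir, config, cfg_hash, records, matrix, reports, transform)
    except VoxmapError as err:
        raise VoxmapError(
            f"pipeline aborted at stage {stage!r}: {err} "
            f"(artifacts under {out_dir})") from err
    return {"matrix": matrix, "records": records, "reports": reports,
            "paths": paths, "truth": truth}


def _serialize_run(out_dir, config, cfg_hash, records, matrix, reports, transform):
    from . import __version__

    paths = {}
    paths["records"] = str(out_dir / "records.tsv")
    records.to_csv(paths["records"], sep="\t", index=False)
    paths["matrix"] = str(stack_io.write_call_matrix(matrix, out_dir / "matrix.tsv"))
    paths["matrix_table1_style"] = str(stack_io.write_call_matrix(
        matrix, out_dir / "matrix_plus0.tsv", table1_style=True))
    paths["class_summary"] = str(out_dir / "class_summary.tsv")
    reports["class_summary"].to_csv(paths["class_summary"], sep="\t", index=False)
    if len(reports["asymmetry"]):
        paths["asymmetry"] = str(out_dir / "asymmetry.tsv")
        reports["asymmetry"].to_csv(paths["asymmetry"], sep="\t", index=False)
    cal = reports.get("calibration")
    if cal is not None:
        paths["calibration"] = str(out_dir / "calibration.json")
        with open(paths["calibration"], "w") as f:
            json.dump({
                "feasible_interval": list(cal.feasible_interval),
                "chosen_threshold": cal.chosen_threshold,
                "best_balanced_accuracy": cal.best_score,
            }, f, indent=1)
        cal.scores.to_csv(out_dir / "calibration_scores.tsv", sep="\t", index=False)
    paths["transform"] = str(out_dir / "transform.json")
    with open(paths["transform"], "w") as f:
        json.dump(transform.to_dict(), f, indent=1)
    paths["run_log"] = str(out_dir / "run_log.json")
    with open(paths["run_log"], "w") as f:
        json.dump({
            "voxmap_version": __version__,
            "numpy_version": np.__version__,
            "config_sha256": cfg_hash,
            "config": json.loads(json.dumps(config, default=str)),
            "registration_rmsd_um": reports["registration_rmsd"],
        }, f, indent=1)
    return paths
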