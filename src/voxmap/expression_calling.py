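"""Expression statistics, positivity calls, and threshold calibration.

For each neuron and probe the pipeline reports:

* *total expression percent* — 100 × (assigned expression volume) /
  (enclosed mesh volume);
* *relative expression* — the percent divided by the highest percent
  over all neurons for that probe;
* a boolean *call* — positive iff the total expression percent is at
  least the threshold (default 5.5%, inclusive).

The threshold is calibrated against a ground-truth label set (genes
with known positive neurons, e.g. the hindbrain transmitter markers) by
sweeping candidate thresholds and scoring balanced accuracy; the full
feasible interval of maximal-agreement thresholds is reported, not just
one endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .collision_assignment import AssignmentMap
from .core import CallMatrix, GroundTruthLabels, NeuronMesh, VoxmapError

DEFAULT_THRESHOLD = 5.5
DEFAULT_SWEEP = np.round(np.arange(0.5, 20.0 + 1e-9, 0.1), 10)


def expression_percent(assigned_volume: float, cell_volume: float) -> float:
    """100 · assigned / cell volume.  May exceed 100 under overlap policy ``all``."""
    if not cell_volume > 0:
        raise VoxmapError(f"cell volume must be positive, got {cell_volume}")
    return 100.0 * assigned_volume / cell_volume


def relative_expression(percents) -> np.ndarray:
    """Each percent divided by the maximum; an all-zero probe stays all zero."""
    arr = np.asarray(percents, dtype=float)
    peak = arr.max() if arr.size else 0.0
    if peak <= 0:
        return np.zeros_like(arr)
    return arr / peak


def call_positive(percent: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Positive iff percent ≥ threshold (inclusive boundary)."""
    if threshold < 0:
        raise VoxmapError("threshold must be ≥ 0")
    return percent >= threshold


def records_from_assignment(
    amap: AssignmentMap,
    meshes: Sequence[NeuronMesh],
    gene: str,
) -> pd.DataFrame:
    """One row per neuron for one probe: assigned volume, cell volume, percent."""
    rows = []
    for nm in meshes:
        assigned = amap.assigned_volume(nm.neuron_id)
        rows.append({
            "neuron_id": nm.neuron_id,
            "cell_class": nm.cell_class,
            "gene": gene,
            "assigned_volume": assigned,
            "cell_volume": nm.volume,
            "expression_percent": expression_percent(assigned, nm.volume),
        })
    df = pd.DataFrame(rows)
    df["relative_expression"] = relative_expression(df["expression_percent"])
    return df


def make_call_matrix(
    records: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> CallMatrix:
    """Pivot long-format records (one row per neuron × gene) into a matrix."""
    required = {"neuron_id", "gene", "expression_percent"}
    missing = required - set(records.columns)
    if missing:
        raise VoxmapError(f"records missing columns {sorted(missing)}")
    percent = records.pivot(
        index="neuron_id", columns="gene", values="expression_percent")
    if percent.isna().any().any():
        raise VoxmapError("every (neuron, gene) pair must appear exactly once")
    relative = percent.apply(lambda col: relative_expression(col.to_numpy()), axis=0)
    relative = pd.DataFrame(relative, index=percent.index, columns=percent.columns)
    calls = percent >= threshold
    cls = None
    if "cell_class" in records.columns:
        cls = (records.drop_duplicates("neuron_id")
               .set_index("neuron_id")["cell_class"]
               .reindex(percent.index))
    # keep first-seen neuron order rather than pivot's lexical sort
    order = records["neuron_id"].drop_duplicates().tolist()
    genes = records["gene"].drop_duplicates().tolist()
    return CallMatrix(
        calls=calls.loc[order, genes],
        percent=percent.loc[order, genes],
        relative=relative.loc[order, genes],
        cell_class=cls.loc[order] if cls is not None else None,
    )


# ---------------------------------------------------------------------------
# agreement scoring and calibration

def score_agreement(
    calls: CallMatrix,
    truth: GroundTruthLabels,
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene confusion counts and balanced accuracy against truth labels.

    ``universe`` declares the shared neuron set; truth negatives are the
    universe minus the gene's positive set.  Defaults to the matrix's
    neuron ids.  Neurons outside the universe are ignored.
    """
    if universe is None:
        universe = calls.neuron_ids
    universe = [u for u in universe if u in set(calls.neuron_ids)]
    if not universe:
        raise VoxmapError("empty neuron universe for agreement scoring")
    rows = []
    for gene, pos_ids in truth.items():
        if gene not in calls.genes:
            raise VoxmapError(f"truth gene {gene!r} absent from call matrix")
        called = calls.positives(gene)
        tp = fp = fn = tn = 0
        for nid in universe:
            is_pos = nid in pos_ids
            is_called = nid in called
            if is_pos and is_called:
                tp += 1
            elif is_pos:
                fn += 1
            elif is_called:
                fp += 1
            else:
                tn += 1
        sens = tp / (tp + fn) if (tp + fn) else 1.0
        spec = tn / (tn + fp) if (tn + fp) else 1.0
        rows.append({
            "gene": gene, "TP": tp, "FP": fp, "FN": fn, "TN": tn,
            "sensitivity": sens, "specificity": spec,
            "balanced_accuracy": 0.5 * (sens + spec),
        })
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    """Threshold sweep outcome: score table, feasible interval, chosen value."""

    scores: pd.DataFrame            # columns: threshold, balanced_accuracy
    feasible_low: float
    feasible_high: float
    chosen_threshold: float
    confusion: pd.DataFrame         # per-gene confusion at the chosen threshold

    @property
    def feasible_interval(self) -> tuple[float, float]:
        return (self.feasible_low, self.feasible_high)

    @property
    def best_score(self) -> float:
        return float(self.scores["balanced_accuracy"].max())


def calibrate_threshold(
    records: pd.DataFrame,
    truth: GroundTruthLabels,
    sweep: Sequence[float] | None = None,
    universe: Sequence[str] | None = None,
) -> CalibrationResult:
    """Sweep thresholds, score agreement with truth, report the feasible interval.

    The agreement score at each threshold is balanced accuracy averaged
    over the truth genes.  The feasible interval is the set of sweep
    thresholds attaining the maximum; the chosen threshold is its
    midpoint, rounded to the sweep resolution.
    """
    sweep = np.asarray(DEFAULT_SWEEP if sweep is None else sweep, dtype=float)
    if sweep.size == 0 or np.any(np.diff(sweep) <= 0):
        raise VoxmapError("sweep must be nonempty and strictly ascending")
    missing = set(truth) - set(records["gene"].unique())
    if missing:
        raise VoxmapError(f"truth genes absent from records: {sorted(missing)}")
    record_ids = set(records["neuron_id"])
    truth_ids = set().union(*truth.values()) if truth else set()
    if truth_ids and not (truth_ids & record_ids):
        raise VoxmapError("no overlap between truth neurons and records")

    scores = []
    per_thr = []
    for thr in sweep:
        matrix = make_call_matrix(records, threshold=thr)
        conf = score_agreement(matrix, truth, universe=universe)
        per_thr.append(conf)
        scores.append(float(conf["balanced_accuracy"].mean()))
    scores = np.asarray(scores)
    best = scores.max()
    feasible = sweep[np.isclose(scores, best, atol=1e-12)]
    lo, hi = float(feasible.min()), float(feasible.max())
    resolution = float(np.min(np.diff(sweep))) if sweep.size > 1 else 0.1
    mid = (lo + hi) / 2.0
    chosen = float(sweep[np.argmin(np.abs(sweep - mid))]) if resolution else mid
    chosen_conf = per_thr[int(np.flatnonzero(np.isclose(sweep, chosen))[0])]
    return CalibrationResult(
        scores=pd.DataFrame(
            {"threshold": sweep, "balanced_accuracy": scores}),
        feasible_low=lo,
        feasible_high=hi,
        chosen_threshold=chosen,
        confusion=chosen_conf,
    )


def truth_to_matrix(
    truth: GroundTruthLabels, universe: Sequence[str],
    cell_class: Mapping[str, str] | None = None,
) -> CallMatrix:
    """Expand truth labels over a neuron universe into a boolean call matrix."""
    frame = pd.DataFrame(
        {g: [nid in ids for nid in universe] for g, ids in truth.items()},
        index=pd.Index(universe, name="neuron_id"),
    )
    cls = None
    if cell_class is not None:
        cls = pd.Series({nid: cell_class.get(nid, "") for nid in universe},
                        name="cell_class")
    return CallMatrix(calls=frame, cell_class=cls)
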