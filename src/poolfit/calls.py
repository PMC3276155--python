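"""Strain-level fitness calls from across-day trajectories.

A strain is called depleted (fitness defect) or enriched (fitness
advantage) when its combined, replicate-averaged log2 value crosses the
2-fold threshold (|value| >= 1 in log2 units) in at least ``min_timepoints``
of the sampled days -- either any days ("any" mode) or a consecutive run of
sampled days ("sequential" mode, the stringent variant; a missing
measurement breaks a run).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, PoolfitError

DIRECTIONS = ("depleted", "enriched")


@dataclass
class FitnessCall:
    strain_id: str
    direction: str  # depleted | enriched | none | both
    n_qualifying: int
    max_run: int
    passed_any: bool
    passed_sequential: bool
    insufficient: bool = False
    n_qualifying_depleted: int = 0
    n_qualifying_enriched: int = 0
    max_run_depleted: int = 0
    max_run_enriched: int = 0


def _longest_run(qualifies: np.ndarray) -> int:
    best = cur = 0
    for q in qualifies:
        cur = cur + 1 if q else 0
        best = max(best, cur)
    return best


def classify_strain(
    trajectory,
    fold_threshold_log2: float = 1.0,
    min_timepoints: int = 3,
    mode: str = "any",
    strain_id: str = "",
) -> FitnessCall:
    """Classify one strain's per-day values.

    Depletion is evaluated on values <= -threshold and enrichment on
    values >= +threshold, independently; a strain passing both directions
    is reported as ``both``.  Missing days neither qualify nor extend a
    run.  With fewer than ``min_timepoints`` non-missing days the call is
    ``none`` with the insufficiency flag set.
    """
    if mode not in ("any", "sequential"):
        raise PoolfitError(f"unknown call mode: {mode!r}")
    v = np.asarray(trajectory, dtype=float)
    present = ~np.isnan(v)

    if present.sum() < min_timepoints:
        return FitnessCall(strain_id, "none", 0, 0, False, False, insufficient=True)

    qual = {
        "depleted": present & (v <= -fold_threshold_log2),
        "enriched": present & (v >= fold_threshold_log2),
    }
    counts = {d: int(qual[d].sum()) for d in DIRECTIONS}
    runs = {d: _longest_run(qual[d]) for d in DIRECTIONS}
    passed = {
        d: (counts[d] if mode == "any" else runs[d]) >= min_timepoints
        for d in DIRECTIONS
    }

    if passed["depleted"] and passed["enriched"]:
        direction = "both"
    elif passed["depleted"]:
        direction = "depleted"
    elif passed["enriched"]:
        direction = "enriched"
    else:
        direction = "none"

    win = direction if direction in DIRECTIONS else max(DIRECTIONS, key=lambda d: counts[d])
    return FitnessCall(
        strain_id=strain_id,
        direction=direction,
        n_qualifying=counts[win],
        max_run=runs[win],
        passed_any=max(counts.values()) >= min_timepoints,
        passed_sequential=max(runs.values()) >= min_timepoints,
        n_qualifying_depleted=counts["depleted"],
        n_qualifying_enriched=counts["enriched"],
        max_run_depleted=runs["depleted"],
        max_run_enriched=runs["enriched"],
    )


def classify_matrix(
    matrix: pd.DataFrame,
    fold_threshold_log2: float = 1.0,
    min_timepoints: int = 3,
    mode: str = "any",
) -> pd.DataFrame:
    """Apply :func:`classify_strain` to every row of a fitness matrix."""
    records = []
    for strain_id, row in matrix.iterrows():
        call = classify_strain(
            row.to_numpy(),
            fold_threshold_log2=fold_threshold_log2,
            min_timepoints=min_timepoints,
            mode=mode,
            strain_id=str(strain_id),
        )
        records.append(vars(call))
    return pd.DataFrame.from_records(records)


def overlap_calls(calls_a: pd.DataFrame, calls_b: pd.DataFrame, direction: str) -> set:
    """Genes called in the given direction in both call sets.

    Strains passing both directions are counted in neither overlap.
    """
    if direction not in DIRECTIONS:
        raise PoolfitError(f"direction must be one of {DIRECTIONS}, got {direction!r}")

    def genes(calls: pd.DataFrame) -> set:
        col = "gene" if "gene" in calls.columns else "strain_id"
        return set(calls.loc[calls["direction"] == direction, col])

    return genes(calls_a) & genes(calls_b)


def summarize_calls(calls: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    """Per-direction totals with essential/uncharacterized/dubious breakdowns."""
    annot = key.set_index("strain_id")["annotation_class"]
    unknown = set(calls["strain_id"]) - set(annot.index)
    if unknown:
        raise ConsistencyError(f"strain {sorted(unknown)[0]!r} not present in the key")
    rows = []
    for direction in DIRECTIONS:
        sub = calls[calls["direction"] == direction]
        classes = annot.reindex(sub["strain_id"])
        rows.append(
            {
                "direction": direction,
                "total": len(sub),
                "essential": int((classes == "essential").sum()),
                "uncharacterized": int((classes == "uncharacterized").sum()),
                "dubious": int((classes == "dubious").sum()),
            }
        )
    return pd.DataFrame(rows)
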