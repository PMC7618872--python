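"""Segmentation quality measures and aggregate reporting.

Per-case Dice overlap, Hausdorff distance between boundary voxels,
Betti-number agreement with the prior ("correct topology"), folding
percentages of the predicted fields, and — for single structures —
relative perimeter error.  ``evaluate_dataset`` turns a list of cases
into a tidy per-case table plus a summary block in the style of a
results table (mean +/- sd Dice and HD, percentage of topologically
correct cases, scene-topology rate for multi-channel outputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .topology import BettiNumbers, betti_2d, relative_perimeter_error, scene_report

__all__ = ["CaseResult", "dice_score", "hausdorff", "evaluate_dataset", "summarise"]


@dataclass
class CaseResult:
    case_id: str
    dice: list[float]
    hausdorff: list[float]
    betti: list[BettiNumbers]
    topology_correct: bool
    folding_pct: dict[str, float] = field(default_factory=dict)
    rel_perim_err_pct: float = float("nan")
    scene_correct: bool | None = None


def dice_score(A: np.ndarray, B: np.ndarray) -> float:
    """Overlap ``2|A n B| / (|A| + |B|)``; 1.0 when both masks are empty."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    total = A.sum() + B.sum()
    if total == 0:
        return 1.0
    return 2.0 * np.logical_and(A, B).sum() / total


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff(A: np.ndarray, B: np.ndarray, spacing: float = 1.0) -> float:
    """Symmetric Hausdorff distance between boundary voxel centres.

    Euclidean, scaled by ``spacing`` (voxels by default, mm if a voxel
    size is supplied).  NaN if either mask is empty.
    """
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if not A.any() or not B.any():
        return float("nan")
    pa = _boundary_points(A)
    pb = _boundary_points(B)
    d = max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
    return float(d * spacing)


def evaluate_dataset(
    predictions: list[np.ndarray],
    references: list[np.ndarray],
    priors: list[np.ndarray],
    fields: list[dict] | None = None,
    case_ids: list[str] | None = None,
    spacing: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-case metric table and summary statistics.

    ``predictions``/``references``/``priors`` are aligned lists of
    ``[c, H, W]`` binary masks; ``fields`` optionally maps branch name
    to a ``FoldingReport`` per case.  Topology is correct when every
    channel's Betti numbers equal the prior channel's.
    """
    n = len(predictions)
    if len(references) != n or len(priors) != n:
        raise ValueError("predictions, references and priors must have equal length")
    if fields is not None and len(fields) != n:
        raise ValueError("fields must align with predictions")
    case_ids = case_ids or [f"case_{i:04d}" for i in range(n)]

    rows = []
    results: list[CaseResult] = []
    for i in range(n):
        pred = predictions[i] if predictions[i].ndim == 3 else predictions[i][None]
        ref = references[i] if references[i].ndim == 3 else references[i][None]
        prior = priors[i] if priors[i].ndim == 3 else priors[i][None]
        c = pred.shape[0]
        dices = [dice_score(pred[k], ref[k]) for k in range(c)]
        hds = [hausdorff(pred[k], ref[k], spacing) for k in range(c)]
        betti = [betti_2d(pred[k]) for k in range(c)]
        prior_betti = [betti_2d(prior[k]) for k in range(c)]
        topo_ok = all(b == pb for b, pb in zip(betti, prior_betti))
        folding = {}
        if fields is not None:
            folding = {k: rep.percent_nonpositive for k, rep in fields[i].items()}
        rpe = relative_perimeter_error(pred[0], ref[0]) if c == 1 else float("nan")
        scene_ok = None
        if c > 1:
            rep = scene_report(
                pred,
                expected=prior_betti,
                expected_union=betti_2d(np.any(prior, axis=0)),
            )
            scene_ok = bool(rep.union_matches and rep.overlap_voxels == 0)
        results.append(
            CaseResult(case_ids[i], dices, hds, betti, topo_ok, folding, rpe, scene_ok)
        )
        for k in range(c):
            rows.append(
                {
                    "case_id": case_ids[i],
                    "channel": k,
                    "dice": dices[k],
                    "hausdorff": hds[k],
                    "b0": betti[k].b0,
                    "b1": betti[k].b1,
                    "prior_b0": prior_betti[k].b0,
                    "prior_b1": prior_betti[k].b1,
                    "channel_topology_correct": betti[k] == prior_betti[k],
                    "topology_correct": topo_ok,
                    "scene_correct": scene_ok,
                    "rel_perim_err_pct": rpe if k == 0 else float("nan"),
                    **{f"folding_pct_{b}": v for b, v in folding.items()},
                }
            )
    table = pd.DataFrame(rows)
    return table, summarise(table, results)


def summarise(table: pd.DataFrame, results: list[CaseResult]) -> dict:
    """Aggregate a per-case table into result-table style numbers."""
    summary = {
        "n_cases": len(results),
        "dice_mean": float(table["dice"].mean()),
        "dice_sd": float(table["dice"].std(ddof=0)),
        "hd_mean": float(table["hausdorff"].mean()),
        "hd_sd": float(table["hausdorff"].std(ddof=0)),
        "topology_correct_pct": 100.0 * np.mean([r.topology_correct for r in results]),
    }
    for k in range(int(table["channel"].max()) + 1):
        sub = table[table["channel"] == k]
        summary[f"topology_correct_pct_ch{k}"] = 100.0 * float(
            sub["channel_topology_correct"].mean()
        )
    fold_cols = [c for c in table.columns if c.startswith("folding_pct_")]
    if fold_cols:
        any_fold = (table[fold_cols] > 0).any(axis=1)
        per_case = any_fold.groupby(table["case_id"]).any()
        summary["cases_with_folding_pct"] = 100.0 * float(per_case.mean())
        for c in fold_cols:
            summary[c.replace("folding_pct_", "mean_folding_pct_")] = float(
                table[c].mean()
            )
    scene = [r.scene_correct for r in results if r.scene_correct is not None]
    if scene:
        summary["scene_topology_pct"] = 100.0 * float(np.mean(scene))
    return summary
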