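"""Segmentation quality indices and per-object detection accounting.

Pixel-overlap indices between the machine mask M and the expert mask E:

    SI = 2|M∩E| / (|M| + |E|)      similarity index (Dice)
    OF = |M∩E| / |E|               overlap fraction (recall-style)
    OV = |M∩E| / |M∪E|             overlap value (Jaccard)
    EF = |M∩Ē| / |E|               extra fraction (spurious area vs truth)

Object-level accounting matches segmented objects to ground-truth objects
one-to-one (greedy, by decreasing pixel overlap); a segmented object counts
as TP when it covers at least ``tau`` of a truth object's area, otherwise it
is FP (inside or outside the ground-truth area alike); unmatched truth
objects are FN.  Sensitivity = TP / (TP + FN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EvalIndices", "DetectionCounts", "overlap_indices",
           "classify_objects", "sensitivity", "truncate", "summarize"]


@dataclass(frozen=True)
class EvalIndices:
    si: float
    of: float
    ov: float
    ef: float
    n_m: int
    n_e: int
    n_inter: int


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fp: int
    fn: int
    fpi: int
    sensitivity: float


def overlap_indices(m: np.ndarray, e: np.ndarray) -> EvalIndices:
    """Compute SI/OF/OV/EF from two binary masks (E must be non-empty)."""
    m = np.asarray(m).astype(bool)
    e = np.asarray(e).astype(bool)
    if m.shape != e.shape:
        raise ValueError("mask shapes differ")
    n_m = int(m.sum())
    n_e = int(e.sum())
    if n_e == 0:
        raise ValueError("expert mask E is empty; all indices divide by |E|")
    n_inter = int((m & e).sum())
    n_union = n_m + n_e - n_inter
    return EvalIndices(
        si=2.0 * n_inter / (n_m + n_e),
        of=n_inter / n_e,
        ov=n_inter / n_union,
        ef=int((m & ~e).sum()) / n_e,
        n_m=n_m,
        n_e=n_e,
        n_inter=n_inter,
    )


def classify_objects(
    segmented: np.ndarray,
    truth_objects: np.ndarray,
    gta: np.ndarray | None = None,
    tau: float = 0.5,
) -> DetectionCounts:
    """TP/FP/FN accounting between segmented and truth label images.

    A (segmented, truth) pair is a match candidate when their pixel overlap
    is at least ``tau`` of the truth object's area; candidates are matched
    greedily by decreasing overlap, one-to-one.  ``gta`` is accepted for
    interface symmetry with expert annotations but does not alter the rule:
    any unmatched segmented object is a false positive wherever it lies.
    """
    segmented = np.asarray(segmented)
    truth_objects = np.asarray(truth_objects)
    if segmented.shape != truth_objects.shape:
        raise ValueError("label image shapes differ")
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must be in (0, 1], got {tau}")

    seg_ids = np.unique(segmented[segmented > 0])
    truth_ids = np.unique(truth_objects[truth_objects > 0])
    truth_areas = {int(t): int((truth_objects == t).sum()) for t in truth_ids}

    candidates: list[tuple[int, int, int]] = []  # (overlap, seg_id, truth_id)
    both = (segmented > 0) & (truth_objects > 0)
    if both.any():
        pairs, counts = np.unique(
            np.stack([segmented[both], truth_objects[both]]), axis=1, return_counts=True
        )
        for (s, t), c in zip(pairs.T, counts):
            if c >= tau * truth_areas[int(t)]:
                candidates.append((int(c), int(s), int(t)))

    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    matched_seg: set[int] = set()
    matched_truth: set[int] = set()
    for _, s, t in candidates:
        if s not in matched_seg and t not in matched_truth:
            matched_seg.add(s)
            matched_truth.add(t)

    tp = len(matched_truth)
    fp = int(seg_ids.size) - len(matched_seg)
    fn = int(truth_ids.size) - tp
    sens = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    return DetectionCounts(tp=tp, fp=fp, fn=fn, fpi=fp, sensitivity=sens)


def sensitivity(tp: int, fn: int, decimals: int | None = None) -> float:
    """TP / (TP + FN); optionally truncated to ``decimals`` decimal digits.

    Truncation (not rounding) matches the convention of the reported
    per-ROI values, e.g. 2 hits of 3 lesions prints as 0.66.
    """
    if tp + fn <= 0:
        raise ValueError("tp + fn must be positive")
    value = tp / (tp + fn)
    return truncate(value, decimals) if decimals is not None else value


def truncate(value: float, decimals: int) -> float:
    """Truncate toward zero at ``decimals`` decimal digits."""
    factor = 10 ** decimals
    return math.trunc(value * factor) / factor


def summarize(per_roi: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-ROI records into summary tables.

    Each record may carry overlap indices (si, of, ov, ef) and detection
    counts (tp, fp, fn, fpi, sensitivity).  Returns (index summary with
    mean/SD/min/max per index, sensitivity grouped by FPI with ROI counts).
    """
    if not per_roi:
        raise ValueError("no per-ROI records to summarize")
    df = pd.DataFrame(per_roi)
    index_cols = [c for c in ("si", "of", "ov", "ef", "sensitivity") if c in df]
    stats = df[index_cols].agg(["mean", "std", "min", "max"]).T
    stats["std"] = stats["std"].fillna(0.0)
    if {"fpi", "sensitivity"} <= set(df.columns):
        by_fpi = (df.groupby("fpi")["sensitivity"]
                    .agg(n_rois="count", mean_sensitivity="mean")
                    .reset_index())
    else:
        by_fpi = pd.DataFrame(columns=["fpi", "n_rois", "mean_sensitivity"])
    return stats, by_fpi
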