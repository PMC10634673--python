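"""Detection metrics: precision, recall, F1 and a mask-overlap Dice score.

Picks are matched one-to-one to ground-truth particles by minimizing total
center distance (optimal assignment) among pairs closer than a tolerance;
matched picks are true positives, the rest false positives, unmatched truth
false negatives. The default tolerance is half the candidate ground-truth
box width — a pick inside the particle's footprint counts as a hit.

Dice is computed as pixel overlap of the two box-union masks,
``2 |P ∩ G| / (|P| + |G|)``; this is deliberately distinct from F1, which
is the harmonic mean of precision and recall over matched counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["EvalResult", "match_to_ground_truth", "compute_metrics", "evaluate_micrographs"]

_BIG = 1e9  # cost barring out-of-tolerance pairs from the assignment


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    dice: float
    degenerate: bool = False  # a zero-denominator metric was forced to 0
    per_micrograph: dict = field(default_factory=dict)


def match_to_ground_truth(picked, gt, tolerance: float | None = None):
    """One-to-one pick/truth matching within a center-distance tolerance.

    ``tolerance=None`` uses half the ground-truth box width per candidate
    truth particle. Returns ``(tp, fp, fn, pairs)`` with ``pairs`` a list of
    (pick index, gt index).
    """
    if tolerance is not None and tolerance <= 0:
        raise ValueError("tolerance must be positive")
    picked = list(picked)
    gt = list(gt)
    if not picked or not gt:
        return 0, len(picked), len(gt), []
    px = np.array([[p.cx, p.cy] for p in picked])
    gx = np.array([[g.cx, g.cy] for g in gt])
    dist = np.linalg.norm(px[:, None, :] - gx[None, :, :], axis=-1)
    if tolerance is None:
        tol = np.array([g.bw / 2.0 for g in gt])[None, :]
    else:
        tol = np.full((1, len(gt)), float(tolerance))
    cost = np.where(dist <= tol, dist, _BIG)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] < _BIG]
    tp = len(pairs)
    return tp, len(picked) - tp, len(gt) - tp, pairs


def _paint_boxes(particles, dims) -> np.ndarray:
    h, w = dims
    mask = np.zeros((h, w), dtype=bool)
    for p in particles:
        x0 = max(0, int(np.floor(p.cx - p.bw / 2.0)))
        y0 = max(0, int(np.floor(p.cy - p.bh / 2.0)))
        x1 = min(w, int(np.ceil(p.cx + p.bw / 2.0)))
        y1 = min(h, int(np.ceil(p.cy + p.bh / 2.0)))
        if x1 > x0 and y1 > y0:
            mask[y0:y1, x0:x1] = True
    return mask


def compute_metrics(
    tp: int,
    fp: int,
    fn: int,
    picked=(),
    gt=(),
    micrograph_dims: tuple[int, int] | None = None,
    f1_variant: str = "harmonic",
) -> EvalResult:
    """Counts -> metrics; Dice additionally needs boxes and image dims.

    Zero-denominator metrics are reported as 0 with ``degenerate=True``.
    ``f1_variant`` may be ``"harmonic"`` (standard) or ``"geometric"``.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = False
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    degenerate |= (tp + fp == 0) or (tp + fn == 0)
    if precision + recall > 0:
        if f1_variant == "harmonic":
            f1 = 2 * precision * recall / (precision + recall)
        elif f1_variant == "geometric":
            f1 = float(np.sqrt(precision * recall))
        else:
            raise ValueError(f"unknown f1_variant {f1_variant!r}")
    else:
        f1 = 0.0
        degenerate = True

    dice = 0.0
    if micrograph_dims is not None:
        pm = _paint_boxes(picked, micrograph_dims)
        gm = _paint_boxes(gt, micrograph_dims)
        denom = int(pm.sum()) + int(gm.sum())
        if denom:
            dice = 2.0 * int((pm & gm).sum()) / denom
        else:
            degenerate = True
    return EvalResult(
        tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1, dice=dice,
        degenerate=degenerate,
    )


def evaluate_micrographs(
    picks_by_mic: dict,
    gt_by_mic: dict,
    dims_by_mic: dict,
    tolerance: float | None = None,
    f1_variant: str = "harmonic",
) -> EvalResult:
    """Aggregate metrics over a set of micrographs.

    Counts (tp/fp/fn) and mask areas are pooled over micrographs before the
    ratios are formed; a per-micrograph breakdown is attached.
    """
    tp = fp = fn = 0
    inter = area = 0
    per = {}
    for mic_id in sorted(set(picks_by_mic) | set(gt_by_mic)):
        picks = picks_by_mic.get(mic_id, [])
        gts = gt_by_mic.get(mic_id, [])
        t, f, n, _ = match_to_ground_truth(picks, gts, tolerance)
        tp, fp, fn = tp + t, fp + f, fn + n
        dims = dims_by_mic[mic_id]
        pm = _paint_boxes(picks, dims)
        gm = _paint_boxes(gts, dims)
        inter += int((pm & gm).sum())
        area += int(pm.sum()) + int(gm.sum())
        per[mic_id] = compute_metrics(t, f, n, picks, gts, dims, f1_variant)
    result = compute_metrics(tp, fp, fn, f1_variant=f1_variant)
    result.dice = 2.0 * inter / area if area else 0.0
    result.degenerate |= area == 0
    result.per_micrograph = per
    return result
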