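"""Bipartite-matching loss for set-prediction particle detection.

The detector emits a fixed-size set of N scored boxes; the ground truth for
a micrograph holds M <= N particles, padded to N with the no-object class
(written ∅ throughout). Training proceeds in two steps:

1. *Matching*: find the permutation sigma of the N prediction slots that
   minimizes the summed pairwise matching cost

       L_match(y_i, yhat_sigma(i)) =
           -1[c_i != ∅] * p_sigma(i)(c_i) + 1[c_i != ∅] * L_box(b_i, bhat_sigma(i))

   solved exactly with the Hungarian algorithm. The class term uses the raw
   probability (not its log) — matching and loss deliberately differ.

2. *Hungarian loss* over the matched pairs:

       L = sum_i  -log p_sigmahat(i)(c_i)  +  1[c_i != ∅] L_box(b_i, bhat_sigmahat(i))

   with the log-probability term of ∅-matched slots down-weighted (factor
   1/10 by default) to counter the heavy class imbalance, and

       L_box = lambda_iou * L_giou + lambda_l1 * ||b_i - bhat||_1,

   where L_giou = 1 - IoU + |B \\ (b1 ∪ b2)| / |B| and B is the tightest
   axis-aligned box enclosing both.

Boxes are (cx, cy, w, h), normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .autodiff import Tensor, maximum, minimum

__all__ = [
    "LossConfig",
    "MatchAssignment",
    "LossBreakdown",
    "giou_loss",
    "match_cost",
    "optimal_assignment",
    "hungarian_loss",
    "build_cost_matrix",
]

_LOG_CLAMP = 1e-12  # probabilities are clamped here before the log

# weight of the reference-box proximity term in the matching cost (see
# build_cost_matrix): large enough to give each particle a consistent
# preferred slot across training steps, small against a decided class
# probability or a real box-quality difference
TIE_BREAK_WEIGHT = 1.0


@dataclass(frozen=True)
class LossConfig:
    """Hyperparameters of the matching cost and Hungarian loss.

    ``eos_downweight`` multiplies the log-probability term of slots matched
    to ∅ (0.1 encodes the conventional factor-of-10 down-weighting).
    """

    lambda_iou: float = 2.0
    lambda_l1: float = 5.0
    eos_downweight: float = 0.1

    def __post_init__(self):
        if self.lambda_iou < 0 or self.lambda_l1 < 0:
            raise ValueError("lambda weights must be non-negative")
        if self.lambda_iou == 0 and self.lambda_l1 == 0:
            raise ValueError("at least one of lambda_iou, lambda_l1 must be positive")
        if not 0 < self.eos_downweight <= 1:
            raise ValueError("eos_downweight must lie in (0, 1]")


@dataclass
class MatchAssignment:
    """One-to-one slot assignment: ``sigma[i]`` is the prediction slot
    matched to (padded) ground-truth entry ``i``."""

    sigma: np.ndarray
    total_cost: float

    def __post_init__(self):
        s = np.sort(self.sigma)
        if not np.array_equal(s, np.arange(len(self.sigma))):
            raise ValueError("sigma is not a permutation")


@dataclass
class LossBreakdown:
    class_loss: float
    l1_loss: float
    giou_loss: float
    total: float


# ---------------------------------------------------------------------------
# GIoU
# ---------------------------------------------------------------------------

def _giou_terms(b1, b2):
    """Differentiable GIoU loss of two (..., 4) cxcywh box arrays/Tensors."""
    t1 = b1 if isinstance(b1, Tensor) else Tensor(b1)
    t2 = b2 if isinstance(b2, Tensor) else Tensor(b2)

    def corners(t):
        cx, cy, w, h = t[..., 0], t[..., 1], t[..., 2], t[..., 3]
        return cx - w * 0.5, cy - h * 0.5, cx + w * 0.5, cy + h * 0.5

    x1a, y1a, x2a, y2a = corners(t1)
    x1b, y1b, x2b, y2b = corners(t2)
    zero = Tensor(0.0)
    iw = (minimum(x2a, x2b) - maximum(x1a, x1b)).clip_min(0.0)
    ih = (minimum(y2a, y2b) - maximum(y1a, y1b)).clip_min(0.0)
    inter = iw * ih
    area_a = (x2a - x1a) * (y2a - y1a)
    area_b = (x2b - x1b) * (y2b - y1b)
    union = area_a + area_b - inter
    # enclosing box
    ew = maximum(x2a, x2b) - minimum(x1a, x1b)
    eh = maximum(y2a, y2b) - minimum(y1a, y1b)
    enclose = ew * eh
    eps = 1e-12
    # degenerate (zero-area) unions: IoU -> 0, penalty -> 0, loss -> 1
    iou = inter / (union + eps)
    penalty = (enclose - union) / (enclose + eps)
    del zero
    return Tensor(1.0) - iou + penalty


def giou_loss(b1, b2) -> float:
    """Generalized-IoU loss of two single boxes; in [0, 2), symmetric."""
    b1 = np.asarray(b1, dtype=np.float64)
    b2 = np.asarray(b2, dtype=np.float64)
    if b1.shape != (4,) or b2.shape != (4,):
        raise ValueError("expected single (cx, cy, w, h) boxes")
    if b1[2] < 0 or b1[3] < 0 or b2[2] < 0 or b2[3] < 0:
        raise ValueError("box width/height must be non-negative")
    return float(_giou_terms(b1, b2).data)


def giou_loss_pairwise(b1, b2):
    """GIoU loss for every pair: ``b1`` (M, 4) x ``b2`` (K, 4) -> (M, K).

    Accepts Tensors (stays differentiable) or arrays.
    """
    t1 = b1 if isinstance(b1, Tensor) else Tensor(np.asarray(b1, dtype=np.float64))
    t2 = b2 if isinstance(b2, Tensor) else Tensor(np.asarray(b2, dtype=np.float64))
    m = t1.shape[0]
    k = t2.shape[0]
    return _giou_terms(t1.reshape(m, 1, 4), t2.reshape(1, k, 4))


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_cost(yi, yhat_j, cfg: LossConfig) -> float:
    """Pairwise matching cost between one ground-truth entry and one slot.

    ``yi`` is ``(class_label, box)`` with ``class_label is None`` for ∅;
    ``yhat_j`` is ``(class_probs, box)`` where ``class_probs[c]`` is the
    predicted probability of class ``c``.
    """
    ci, bi = yi
    probs, bj = yhat_j
    if ci is None:  # ∅ ground truth: both indicator terms vanish
        return 0.0
    p = float(np.asarray(probs)[ci])
    l1 = float(np.abs(np.asarray(bi) - np.asarray(bj)).sum())
    return -p + cfg.lambda_iou * giou_loss(bi, bj) + cfg.lambda_l1 * l1


def build_cost_matrix(
    gt_boxes, pred_probs, pred_boxes, cfg: LossConfig, tie_break_boxes=None
) -> np.ndarray:
    """N x N matching-cost matrix for M real particles padded to N with ∅.

    Rows 0..M-1 are real particles (class = particle, index 0 of the class
    distribution); rows M..N-1 are ∅ padding and cost 0 against every slot.

    ``tie_break_boxes`` (N, 4), when given, adds an epsilon-scaled center
    distance between the ground truth and each slot's reference box. It is
    far below the scale of any real cost difference and only decides ties:
    without it, two slots that have both learned a particle's exact box are
    interchangeable, the assignment flips between them from step to step,
    and — with the ∅ term down-weighted — both converge to confident
    duplicate predictions instead of one of them yielding.
    """
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    pred_probs = np.asarray(pred_probs, dtype=np.float64)
    pred_boxes_arr = np.asarray(
        pred_boxes.data if isinstance(pred_boxes, Tensor) else pred_boxes, dtype=np.float64
    )
    m = gt_boxes.shape[0]
    n = pred_probs.shape[0]
    if m > n:
        raise ValueError(f"{m} particles exceed {n} prediction slots")
    cost = np.zeros((n, n))
    if m:
        l1 = np.abs(gt_boxes[:, None, :] - pred_boxes_arr[None, :, :]).sum(axis=-1)
        giou = giou_loss_pairwise(gt_boxes, pred_boxes_arr).data
        cost[:m] = -pred_probs[None, :, 0] + cfg.lambda_iou * giou + cfg.lambda_l1 * l1
        if tie_break_boxes is not None:
            tb = np.asarray(tie_break_boxes, dtype=np.float64).reshape(-1, 4)
            dist = np.linalg.norm(
                gt_boxes[:, None, :2] - tb[None, :, :2], axis=-1
            )
            cost[:m] += TIE_BREAK_WEIGHT * dist
    return cost


def optimal_assignment(cost_matrix) -> MatchAssignment:
    """Exact minimum-cost one-to-one assignment (Hungarian algorithm)."""
    cost = np.asarray(cost_matrix, dtype=np.float64)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError(f"cost matrix must be square, got {cost.shape}")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix contains non-finite entries")
    rows, cols = linear_sum_assignment(cost)
    sigma = np.empty(cost.shape[0], dtype=np.int64)
    sigma[rows] = cols
    return MatchAssignment(sigma=sigma, total_cost=float(cost[rows, cols].sum()))


# ---------------------------------------------------------------------------
# Hungarian loss
# ---------------------------------------------------------------------------

def hungarian_loss(
    gt_boxes,
    pred_probs: Tensor,
    pred_boxes: Tensor,
    cfg: LossConfig | None = None,
    assignment: MatchAssignment | None = None,
    tie_break_boxes=None,
) -> tuple[Tensor, LossBreakdown]:
    """Set-prediction loss of one micrograph.

    Parameters
    ----------
    gt_boxes : array (M, 4)
        Normalized cxcywh ground-truth boxes (all of class particle).
    pred_probs : Tensor (N, 2)
        Per-slot class distribution, column 0 = particle, column 1 = ∅.
    pred_boxes : Tensor (N, 4)
        Per-slot normalized boxes.

    Returns the differentiable total and a float breakdown. The matching is
    recomputed here (on detached values) unless one is supplied.
    """
    cfg = cfg or LossConfig()
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    m = gt_boxes.shape[0]
    n = pred_probs.shape[0]
    if assignment is None:
        cost = build_cost_matrix(
            gt_boxes, pred_probs.data, pred_boxes.data, cfg, tie_break_boxes=tie_break_boxes
        )
        assignment = optimal_assignment(cost)
    sigma = assignment.sigma

    log_probs = pred_probs.clip_min(_LOG_CLAMP).log()
    matched_slots = sigma[:m]
    unmatched_slots = sigma[m:]
    class_terms = []
    if m:
        class_terms.append(-log_probs[matched_slots, 0].sum())
    if n - m:
        class_terms.append(-log_probs[unmatched_slots, 1].sum() * cfg.eos_downweight)
    class_term = class_terms[0] if len(class_terms) == 1 else class_terms[0] + class_terms[1]

    if m:
        matched_boxes = pred_boxes[matched_slots]
        gt_t = Tensor(gt_boxes)
        l1_term = (matched_boxes - gt_t).abs().sum()
        giou_term = _giou_terms(gt_t, matched_boxes).sum()
        total = class_term + cfg.lambda_l1 * l1_term + cfg.lambda_iou * giou_term
        breakdown = LossBreakdown(
            class_loss=float(class_term.data),
            l1_loss=float(cfg.lambda_l1 * l1_term.data),
            giou_loss=float(cfg.lambda_iou * giou_term.data),
            total=float(total.data),
        )
    else:
        total = class_term
        breakdown = LossBreakdown(
            class_loss=float(class_term.data), l1_loss=0.0, giou_loss=0.0, total=float(total.data)
        )
    return total, breakdown
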