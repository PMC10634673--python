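"""Matching cost, Hungarian assignment, GIoU and Hungarian-loss oracles."""

import itertools

import numpy as np
import pytest

from cryopicker.autodiff import Tensor
from cryopicker.loss import (
    LossConfig,
    build_cost_matrix,
    giou_loss,
    giou_loss_pairwise,
    hungarian_loss,
    match_cost,
    optimal_assignment,
)


def brute_force_min_cost(cost: np.ndarray) -> float:
    n = cost.shape[0]
    return min(
        sum(cost[i, p[i]] for i in range(n)) for p in itertools.permutations(range(n))
    )


class TestGiou:
    def test_identical_boxes_give_zero(self):
        assert giou_loss((0.5, 0.5, 0.2, 0.3), (0.5, 0.5, 0.2, 0.3)) == pytest.approx(0.0, abs=1e-9)

    def test_worked_offset_boxes_example(self):
        # two 0.5x0.5 boxes centred at (0.25, 0.25) and (0.75, 0.75): they
        # touch only at the corner (0.5, 0.5), so the intersection is empty,
        # the union has area 0.5, the enclosing box is the unit square, and
        # the loss is 1 - 0 + (1 - 0.5)/1 = 1.5 exactly
        b1 = (0.25, 0.25, 0.5, 0.5)
        b2 = (0.75, 0.75, 0.5, 0.5)
        assert giou_loss(b1, b2) == pytest.approx(1.5, abs=1e-6)

    def test_worked_example_against_monte_carlo_areas(self, rng):
        # independent area oracle: estimate intersection/union/enclosing-box
        # areas by uniform sampling of the unit square
        b1 = np.array([0.25, 0.25, 0.5, 0.5])
        b2 = np.array([0.75, 0.75, 0.5, 0.5])
        n = 1_000_000
        pts = rng.uniform(0, 1, size=(n, 2))

        def inside(b):
            return (np.abs(pts[:, 0] - b[0]) <= b[2] / 2) & (np.abs(pts[:, 1] - b[1]) <= b[3] / 2)

        in1, in2 = inside(b1), inside(b2)
        inter = (in1 & in2).mean()
        union = (in1 | in2).mean()
        iou_mc = inter / union
        empty_mc = 1.0 - union  # enclosing box is the whole unit square here
        loss_mc = 1.0 - iou_mc + empty_mc
        se = 3.0 / np.sqrt(n)  # conservative 3-sigma band for the area sums
        assert giou_loss(b1, b2) == pytest.approx(loss_mc, abs=3 * se)

    def test_monotone_in_separation_when_disjoint(self):
        losses = [
            giou_loss((0.0, 0.0, 0.1, 0.1), (d, 0.0, 0.1, 0.1)) for d in np.linspace(0.3, 2.0, 12)
        ]
        assert all(l > 1.0 for l in losses)
        assert all(b > a for a, b in zip(losses, losses[1:]))

    def test_symmetry_and_translation_invariance(self, rng):
        for _ in range(25):
            b1 = rng.uniform(0.1, 0.9, 4)
            b2 = rng.uniform(0.1, 0.9, 4)
            assert giou_loss(b1, b2) == pytest.approx(giou_loss(b2, b1))
            shift = np.array([*rng.uniform(-5, 5, 2), 0, 0])
            assert giou_loss(b1 + shift, b2 + shift) == pytest.approx(giou_loss(b1, b2))

    def test_range_and_degenerate_case(self, rng):
        for _ in range(50):
            l = giou_loss(rng.uniform(0, 1, 4), rng.uniform(0, 1, 4))
            assert 0.0 <= l < 2.0
        assert giou_loss((0.5, 0.5, 0, 0), (0.5, 0.5, 0, 0)) == pytest.approx(1.0)


class TestMatchCost:
    CFG = LossConfig(lambda_iou=2.0, lambda_l1=5.0)

    def test_empty_ground_truth_costs_nothing(self):
        yhat = (np.array([0.3, 0.7]), np.array([0.1, 0.2, 0.05, 0.05]))
        assert match_cost((None, None), yhat, self.CFG) == 0.0

    def test_perfect_prediction_costs_minus_one(self):
        box = np.array([0.4, 0.6, 0.1, 0.1])
        assert match_cost((0, box), (np.array([1.0, 0.0]), box), self.CFG) == pytest.approx(-1.0)

    def test_worked_arithmetic_example(self):
        # -p + lambda_iou * giou + lambda_l1 * l1 with p=0.8, giou=0.2, l1=0.1
        box_gt = np.array([0.5, 0.5, 0.2, 0.2])
        # construct a prediction with known L1 distance 0.1
        box_pred = box_gt + np.array([0.025, 0.025, 0.025, 0.025])
        g = giou_loss(box_gt, box_pred)
        got = match_cost((0, box_gt), (np.array([0.8, 0.2]), box_pred), self.CFG)
        assert got == pytest.approx(-0.8 + 2.0 * g + 5.0 * 0.1)


class TestAssignment:
    def test_identity_favoring_matrix(self):
        cost = np.ones((4, 4)) - np.eye(4)
        a = optimal_assignment(cost)
        np.testing.assert_array_equal(a.sigma, np.arange(4))
        assert a.total_cost == 0.0

    @pytest.mark.parametrize(
        "cost, sigma, total",
        [([[1, 2], [2, 1]], [0, 1], 2.0), ([[2, 1], [1, 2]], [1, 0], 2.0)],
    )
    def test_two_by_two_cases(self, cost, sigma, total):
        a = optimal_assignment(np.array(cost, dtype=float))
        np.testing.assert_array_equal(a.sigma, sigma)
        assert a.total_cost == total

    def test_matches_brute_force_on_random_matrices(self, rng):
        for n in (2, 3, 4, 5, 6):
            for _ in range(50):
                cost = rng.normal(size=(n, n))
                a = optimal_assignment(cost)
                assert a.total_cost == pytest.approx(brute_force_min_cost(cost))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="square"):
            optimal_assignment(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="finite"):
            optimal_assignment(np.array([[np.nan, 0], [0, 1]]))


def _uniform_probs(n):
    return Tensor(np.full((n, 2), 0.5))


class TestHungarianLoss:
    def test_no_particles_and_confident_empty_slots(self):
        n = 6
        probs = Tensor(np.column_stack([np.zeros(n), np.ones(n)]))
        boxes = Tensor(np.full((n, 4), 0.5))
        total, bd = hungarian_loss(np.zeros((0, 4)), probs, boxes)
        assert total.item() == pytest.approx(0.0, abs=1e-9)
        assert bd.total == pytest.approx(0.0, abs=1e-9)

    def test_perfect_single_match_is_zero(self):
        n = 5
        gt = np.array([[0.5, 0.5, 0.2, 0.2]])
        probs = np.column_stack([np.zeros(n), np.ones(n)])
        probs[2] = [1.0, 0.0]
        boxes = np.full((n, 4), 0.9)
        boxes[2] = gt[0]
        total, bd = hungarian_loss(gt, Tensor(probs), Tensor(boxes))
        assert total.item() == pytest.approx(0.0, abs=1e-9)

    def test_half_confidence_gives_log_two(self):
        n = 5
        gt = np.array([[0.5, 0.5, 0.2, 0.2]])
        probs = np.column_stack([np.zeros(n), np.ones(n)])
        probs[0] = [0.5, 0.5]
        boxes = np.full((n, 4), 0.9)
        boxes[0] = gt[0]
        total, _ = hungarian_loss(gt, Tensor(probs), Tensor(boxes))
        assert total.item() == pytest.approx(-np.log(0.5), abs=1e-9)

    def test_empty_slot_term_is_downweighted(self):
        n = 4
        cfg = LossConfig(eos_downweight=0.1)
        probs = np.full((n, 2), 0.5)
        boxes = np.full((n, 4), 0.5)
        total, bd = hungarian_loss(np.zeros((0, 4)), Tensor(probs), Tensor(boxes), cfg)
        # all slots matched to padding: n * 0.1 * (-log 0.5)
        assert total.item() == pytest.approx(n * 0.1 * np.log(2.0))

    def test_invariant_under_ground_truth_permutation(self, rng):
        n = 10
        gt = rng.uniform(0.2, 0.8, size=(4, 4))
        probs = Tensor(rng.dirichlet((1, 1), size=n))
        boxes = Tensor(rng.uniform(0, 1, size=(n, 4)))
        t1, _ = hungarian_loss(gt, probs, boxes)
        t2, _ = hungarian_loss(gt[rng.permutation(4)], probs, boxes)
        assert t1.item() == pytest.approx(t2.item())

    def test_each_slot_matched_at_most_once(self, rng):
        cfg = LossConfig()
        gt = rng.uniform(0.3, 0.7, size=(5, 4))
        probs = rng.dirichlet((1, 1), size=8)
        boxes = rng.uniform(0, 1, size=(8, 4))
        cost = build_cost_matrix(gt, probs, boxes, cfg)
        a = optimal_assignment(cost)
        assert len(set(a.sigma.tolist())) == len(a.sigma)

    def test_gradient_matches_finite_differences(self, rng):
        """d(total)/d(box params) on a 3-particle toy, 1e-4 relative."""
        cfg = LossConfig()
        gt = rng.uniform(0.3, 0.7, size=(3, 4))
        n = 6
        probs_data = rng.dirichlet((2, 2), size=n)
        boxes_data = rng.uniform(0.2, 0.8, size=(n, 4))
        cost = build_cost_matrix(gt, probs_data, boxes_data, cfg)
        assignment = optimal_assignment(cost)  # freeze matching for the check

        boxes = Tensor(boxes_data, requires_grad=True)
        total, _ = hungarian_loss(gt, Tensor(probs_data), boxes, cfg, assignment=assignment)
        total.backward()
        grad = boxes.grad.copy()

        eps = 1e-6
        for i, j in [(0, 0), (1, 2), (2, 3), (4, 1), (5, 0)]:
            for sign_delta in (1,):
                bp = boxes_data.copy()
                bp[i, j] += eps
                tp, _ = hungarian_loss(gt, Tensor(probs_data), Tensor(bp), cfg, assignment=assignment)
                bm = boxes_data.copy()
                bm[i, j] -= eps
                tm, _ = hungarian_loss(gt, Tensor(probs_data), Tensor(bm), cfg, assignment=assignment)
                num = (tp.item() - tm.item()) / (2 * eps)
                denom = max(abs(num), abs(grad[i, j]), 1e-8)
                assert abs(grad[i, j] - num) / denom < 1e-4

    def test_pairwise_giou_agrees_with_scalar(self, rng):
        b1 = rng.uniform(0.1, 0.9, size=(3, 4))
        b2 = rng.uniform(0.1, 0.9, size=(5, 4))
        table = giou_loss_pairwise(b1, b2).data
        for i in range(3):
            for j in range(5):
                assert table[i, j] == pytest.approx(giou_loss(b1[i], b2[j]))
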