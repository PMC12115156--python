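"""Box decoding, target assignment and the composite detection loss."""

import math

import numpy as np
import pytest

from seanet import tensor as T
from seanet.assigner import TaskAlignedAssigner
from seanet.boxes import BoxSet, iou_matrix
from seanet.head import decode_boxes_np, make_anchors
from seanet.losses import (BOX_WEIGHT, CLS_WEIGHT, DFL_WEIGHT, DetectionLoss,
                           ciou, dfl_loss, dfl_targets)
from seanet.tensor import Tensor


# ---------------------------------------------------------------------------
# complete IoU
# ---------------------------------------------------------------------------

def test_ciou_identical_boxes_is_one():
    assert ciou([0, 0, 2, 2], [0, 0, 2, 2]) == pytest.approx(1.0, abs=1e-6)


def test_ciou_disjoint_worked_case():
    """IoU 0, enclosing diagonal^2 = 40, centre distance^2 = 16, equal
    aspect so the shape term vanishes: CIoU = -16/40 = -0.4."""
    assert ciou([0, 0, 2, 2], [4, 0, 6, 2]) == pytest.approx(-0.4, abs=1e-6)


def test_ciou_nested_same_center_same_aspect_equals_iou():
    a, b = [1, 1, 3, 3], [0, 0, 4, 4]
    iou = 4.0 / 16.0
    assert ciou(a, b) == pytest.approx(iou, abs=1e-6)


def test_ciou_rejects_degenerate_boxes():
    with pytest.raises(ValueError):
        ciou([0, 0, 0, 2], [0, 0, 1, 1])


def _ciou_reference(a, b, eps=1e-9):
    """Direct formula evaluation, independent of the implementation."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = max(min(ax2, bx2) - max(ax1, bx1), 0)
    ih = max(min(ay2, by2) - max(ay1, by1), 0)
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    iou = inter / (union + eps)
    cw = max(ax2, bx2) - min(ax1, bx1)
    ch = max(ay2, by2) - min(ay1, by1)
    rho2 = ((ax1 + ax2 - bx1 - bx2) ** 2 + (ay1 + ay2 - by1 - by2) ** 2) / 4
    v = 4 / math.pi ** 2 * (math.atan((bx2 - bx1) / (by2 - by1))
                            - math.atan((ax2 - ax1) / (ay2 - ay1))) ** 2
    return iou - rho2 / (cw ** 2 + ch ** 2 + eps) - v ** 2 / (1 - iou + v + eps)


def test_ciou_agrees_with_formula_oracle_on_random_pairs(rng):
    for _ in range(1000):
        a = np.sort(rng.uniform(0, 100, 4).reshape(2, 2), axis=0).T.reshape(4)
        b = np.sort(rng.uniform(0, 100, 4).reshape(2, 2), axis=0).T.reshape(4)
        a = [a[0], a[2], a[1] + 1e-3, a[3] + 1e-3]
        b = [b[0], b[2], b[1] + 1e-3, b[3] + 1e-3]
        got = ciou(a, b)
        assert got == pytest.approx(_ciou_reference(a, b), abs=1e-6)
        assert -2 < got <= 1
        assert got <= iou_matrix([a], [b])[0, 0] + 1e-9


# ---------------------------------------------------------------------------
# distribution focal loss
# ---------------------------------------------------------------------------

def test_dfl_point_mass_at_integer_target_is_zero():
    logits = np.full(16, -20.0)
    logits[5] = 20.0
    assert dfl_loss(logits, 5.0) == pytest.approx(0.0, abs=1e-6)


def test_dfl_uniform_distribution_half_offset_is_log16():
    logits = np.zeros(16)
    assert dfl_loss(logits, 5.5) == pytest.approx(math.log(16), abs=1e-9)


def test_dfl_minimized_by_bracketing_two_point_distribution(rng):
    """Grid search over distributions: the two-bin bracketing distribution
    attains the minimum cross-entropy for a fractional target."""
    target = 3.3
    best = dfl_loss(np.log(dfl_targets([target], 8)[0] + 1e-12), target)
    for _ in range(300):
        p = rng.dirichlet(np.ones(8))
        assert dfl_loss(np.log(p + 1e-12), target) >= best - 1e-9


def test_dfl_out_of_range_target_clamps_with_warning():
    with pytest.warns(UserWarning):
        v = dfl_loss(np.zeros(16), 20.0)
    assert np.isfinite(v)


# ---------------------------------------------------------------------------
# box decoding
# ---------------------------------------------------------------------------

def test_decode_point_mass_at_bin_zero_is_anchor_centred_point():
    logits = np.full((1, 4, 16), -30.0)
    logits[:, :, 0] = 30.0
    pts = np.array([[40.0, 24.0]])
    sts = np.array([8.0])
    box = decode_boxes_np(logits, pts, sts)
    assert np.allclose(box, [[40, 24, 40, 24]], atol=1e-4)


@pytest.mark.parametrize("k", [1, 7, 15])
def test_decode_point_mass_at_bin_k_offsets_by_k_strides(k):
    logits = np.full((1, 4, 16), -30.0)
    logits[:, :, k] = 30.0
    pts = np.array([[64.0, 64.0]])
    sts = np.array([16.0])
    box = decode_boxes_np(logits, pts, sts)
    assert np.allclose(box, [[64 - k * 16, 64 - k * 16,
                              64 + k * 16, 64 + k * 16]], atol=1e-3)


def test_decode_matches_loop_oracle_on_random_logits(rng):
    logits = rng.normal(size=(5, 4, 16))
    pts = rng.uniform(0, 160, size=(5, 2))
    sts = np.array([8, 8, 16, 16, 32], dtype=np.float64)
    got = decode_boxes_np(logits, pts, sts)
    for a in range(5):
        d = []
        for side in range(4):
            z = logits[a, side]
            p = np.exp(z - z.max())
            p /= p.sum()
            d.append(sum(p[i] * i for i in range(16)) * sts[a])
        ref = [pts[a, 0] - d[0], pts[a, 1] - d[1],
               pts[a, 0] + d[2], pts[a, 1] + d[3]]
        assert np.allclose(got[a], ref, atol=1e-9)


def test_make_anchors_cell_centres():
    pts, sts = make_anchors([(2, 2), (1, 1)], [8, 16])
    assert np.allclose(pts[:4], [[4, 4], [12, 4], [4, 12], [12, 12]])
    assert np.allclose(pts[4], [8, 8])
    assert np.allclose(sts, [8, 8, 8, 8, 16])


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _assigner_oracle(scores, boxes, pts, gt, n_classes, topk=10,
                     alpha=0.5, beta=6.0):
    """Brute-force nested-loop re-statement of the assignment rule."""
    A, G = len(pts), len(gt)
    iou = iou_matrix(gt.boxes, boxes).clip(0)
    metric = np.zeros((G, A))
    for g in range(G):
        for a in range(A):
            x, y = pts[a]
            bx = gt.boxes[g]
            if bx[0] < x < bx[2] and bx[1] < y < bx[3]:
                metric[g, a] = (max(scores[a, gt.classes[g]], 1e-9) ** alpha
                                * iou[g, a] ** beta)
    selected = np.zeros((G, A), dtype=bool)
    for g in range(G):
        order = sorted(range(A), key=lambda a: -metric[g, a])[:topk]
        for a in order:
            if metric[g, a] > 0:
                selected[g, a] = True
    for a in range(A):
        claims = [g for g in range(G) if selected[g, a]]
        if len(claims) > 1:
            best = max(range(G), key=lambda g: iou[g, a])
            for g in claims:
                selected[g, a] = g == best
    return selected, metric, iou


def test_assigner_empty_gt_gives_empty_assignment(rng):
    asg = TaskAlignedAssigner()
    out = asg(rng.uniform(size=(20, 3)), rng.uniform(0, 50, (20, 4)),
              rng.uniform(0, 50, (20, 2)), BoxSet.empty(), 3)
    assert out.n_matched == 0
    assert np.all(out.target_scores == 0)


def test_assigner_single_obvious_candidate_matched():
    gt = BoxSet([[10, 10, 30, 30]], [1])
    pts = np.array([[20.0, 20.0], [50.0, 50.0]])
    boxes = np.array([[11, 11, 29, 29], [45, 45, 55, 55]], dtype=float)
    scores = np.array([[0.01, 0.9, 0.01], [0.5, 0.5, 0.5]])
    out = TaskAlignedAssigner()(scores, boxes, pts, gt, 3)
    assert out.matches == [(0, 0)]
    assert out.target_scores[0, 1] > 0
    assert out.target_scores[1].sum() == 0


@pytest.mark.parametrize("seed", range(5))
def test_assigner_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    A, G = 20, 2
    pts = rng.uniform(0, 64, size=(A, 2))
    boxes = np.sort(rng.uniform(0, 64, size=(A, 2, 2)), axis=1)
    boxes = np.concatenate([boxes[:, 0], boxes[:, 1] + 1.0], axis=1)
    gt = BoxSet(np.array([[5, 5, 40, 40], [30, 20, 60, 60]], dtype=float),
                [0, 1])
    scores = rng.uniform(0.01, 0.99, size=(A, 3))
    out = TaskAlignedAssigner()(scores, boxes, pts, gt, 3)
    sel_ref, metric, iou = _assigner_oracle(scores, boxes, pts, gt, 3)
    got = np.zeros_like(sel_ref)
    for a, g in out.matches:
        got[g, a] = True
    assert np.array_equal(got, sel_ref)
    # target scores equal the normalised metric of the oracle
    for g in range(2):
        if sel_ref[g].any():
            norm = metric[g] * np.where(sel_ref[g], iou[g], 0).max() \
                / (np.where(sel_ref[g], metric[g], 0).max() + 1e-9)
            for a in np.flatnonzero(sel_ref[g]):
                assert out.target_scores[a, gt.classes[g]] == \
                    pytest.approx(norm[a], rel=1e-6)


# ---------------------------------------------------------------------------
# composite loss
# ---------------------------------------------------------------------------

def _loss_inputs(rng, A=12, nc=3, reg_max=16):
    cls = Tensor(rng.normal(size=(1, A, nc)).astype(np.float32),
                 requires_grad=True)
    box = Tensor(rng.normal(size=(1, A, 4, reg_max)).astype(np.float32),
                 requires_grad=True)
    pts, sts = make_anchors([(2, 2), (1, 1)], [8, 16])
    pts = np.concatenate([pts, pts + 2, pts[:2] + 4])[:A]
    sts = np.concatenate([sts, sts, sts[:2]])[:A]
    return cls, box, pts, sts


def test_empty_assignment_floors_target_score_sum_at_one(rng):
    cls, box, pts, sts = _loss_inputs(rng)
    lf = DetectionLoss(3)
    asg = TaskAlignedAssigner()(np.full((12, 3), 0.5),
                                np.tile([0, 0, 4, 4.0], (12, 1)), pts,
                                BoxSet.empty(), 3)
    total, bd = lf(cls, box, pts, sts, [asg], [BoxSet.empty()])
    assert bd.target_scores_sum == 1.0
    assert bd.box_loss == 0.0 and bd.dfl_loss == 0.0
    assert bd.cls_loss > 0  # all-zero targets still penalise confidence


def test_total_is_the_weighted_sum_of_components():
    bd_total = BOX_WEIGHT * 1.0 + CLS_WEIGHT * 1.0 + DFL_WEIGHT * 1.0
    assert bd_total == 9.5


def test_perfect_predictions_zero_box_and_dfl_losses(rng):
    """Box logits forming point masses exactly at the target bins decode to
    the ground-truth box, so CIoU = 1 and the focal term is -log(1)."""
    reg_max = 16
    pts, sts = make_anchors([(2, 2)], [8])
    gt = BoxSet([[0.0, 0.0, 8.0, 8.0]], [0])   # anchor (4,4): l=t=r=b=0.5... no
    # choose a gt whose sides are integer bin multiples from anchor (4, 4)
    gt = BoxSet([[4 - 2 * 8, 4 - 8, 4 + 8, 4 + 8.0]], [0])
    cls = Tensor(np.full((1, 4, 2), -6.0, dtype=np.float32), requires_grad=True)
    box_np = np.full((1, 4, 4, reg_max), -30.0, dtype=np.float32)
    for side, off in enumerate((2, 1, 1, 1)):
        box_np[0, 0, side, off] = 30.0
    box = Tensor(box_np, requires_grad=True)
    from seanet.assigner import TargetAssignment
    asg = TargetAssignment([(0, 0)], np.zeros((4, 2)), np.array([1.0]), 1)
    asg.target_scores[0, 0] = 1.0
    total, bd = DetectionLoss(2)(cls, box, pts, sts, [asg], [gt])
    assert bd.box_loss == pytest.approx(0.0, abs=1e-5)
    assert bd.dfl_loss == pytest.approx(0.0, abs=1e-5)


def test_loss_identity_and_positivity_on_random_steps(rng):
    lf = DetectionLoss(3)
    asg_fn = TaskAlignedAssigner()
    for _ in range(5):
        cls, box, pts, sts = _loss_inputs(rng)
        gt = BoxSet([[2, 2, 12, 12], [5, 5, 14, 10]], [0, 2])
        boxes_np = decode_boxes_np(box.data[0].astype(np.float64), pts, sts)
        a = asg_fn(T.sigmoid_np(cls.data[0]), boxes_np, pts, gt, 3)
        total, bd = lf(cls, box, pts, sts, [a], [gt])
        assert bd.box_loss >= 0 and bd.cls_loss >= 0 and bd.dfl_loss >= 0
        assert bd.weighted_identity_residual() < 1e-12
        assert bd.target_scores_sum >= 1.0
        total.backward()
        assert np.isfinite(cls.grad).all() and np.isfinite(box.grad).all()


def test_literal_matched_sum_cls_mode(rng):
    cls, box, pts, sts = _loss_inputs(rng)
    gt = BoxSet([[2, 2, 12, 12]], [1])
    boxes_np = decode_boxes_np(box.data[0].astype(np.float64), pts, sts)
    a = TaskAlignedAssigner()(T.sigmoid_np(cls.data[0]), boxes_np, pts, gt, 3)
    _, bd_norm = DetectionLoss(3, cls_mode="normalized")(
        cls, box, pts, sts, [a], [gt])
    _, bd_lit = DetectionLoss(3, cls_mode="matched_sum")(
        cls, box, pts, sts, [a], [gt])
    assert bd_lit.cls_loss != pytest.approx(bd_norm.cls_loss)
    assert bd_lit.box_loss == pytest.approx(bd_norm.box_loss)
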