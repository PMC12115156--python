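"""Detection evaluation: average precision, precision/recall/F1, PR curves.

Average precision follows the COCO convention: greedy score-ordered
matching per class at a given IoU threshold, the precision envelope
sampled at 101 evenly spaced recall points, and the headline AP averaged
over IoU thresholds 0.50:0.05:0.95. Precision/recall/F1 are reported at
the confidence threshold that maximises F1 at IoU 0.5, macro-averaged
over classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .boxes import BoxSet, iou_matrix

IOU_THRESHOLDS = np.round(np.arange(0.5, 0.96, 0.05), 2)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


@dataclass
class EvalResult:
    ap: float
    ap50: float
    ap75: float
    precision: float
    recall: float
    f1: float
    per_class_ap: dict
    pr_curve: list
    n_images: int = 0
    degenerate: bool = False
    metadata: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def match_detections(preds: BoxSet, gts: BoxSet, iou_threshold: float
                     ) -> tuple[ConfusionCounts, np.ndarray]:
    """Greedy one-to-one matching of score-sorted predictions to ground truth.

    Both sets must already be restricted to one class. Returns confusion
    counts and per-detection TP flags in descending-score order.
    """
    order = np.argsort(-preds.scores) if preds.scores is not None \
        else np.arange(len(preds))
    flags = np.zeros(len(preds), dtype=bool)
    matched_gt = np.zeros(len(gts), dtype=bool)
    if len(gts) and len(preds):
        ious = iou_matrix(preds.boxes[order], gts.boxes)
        for i in range(len(order)):
            cand = np.where(~matched_gt, ious[i], -1.0)
            j = int(cand.argmax())
            if cand[j] >= iou_threshold:
                matched_gt[j] = True
                flags[i] = True
    tp = int(flags.sum())
    return ConfusionCounts(tp, len(preds) - tp, len(gts) - tp), flags


def average_precision(flags: np.ndarray, scores: np.ndarray, n_gt: int,
                      n_points: int = 101) -> float:
    """Interpolated AP from TP flags aligned with detection scores."""
    if n_gt <= 0:
        raise ValueError("average_precision requires n_gt > 0")
    if len(flags) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores))
    f = np.asarray(flags, dtype=np.float64)[order]
    tp_cum = np.cumsum(f)
    fp_cum = np.cumsum(1.0 - f)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope: best precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    rs = np.linspace(0, 1, n_points)
    idx = np.searchsorted(recall, rs, side="left")
    vals = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(vals.mean())


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean F1 = 2PR/(P+R); accepts fractions or percentages."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def prf1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 = 2PR/(P+R); degenerate quantities are 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def _per_class_eval(preds: list[BoxSet], gts: list[BoxSet], cls: int,
                    iou_t: float):
    """Pooled flags/scores/n_gt for one class across images."""
    flags, scores = [], []
    n_gt = 0
    for p, g in zip(preds, gts):
        pm = p.classes == cls
        gm = g.classes == cls
        sub_p = BoxSet(p.boxes[pm], p.classes[pm],
                       p.scores[pm] if p.scores is not None else None)
        sub_g = BoxSet(g.boxes[gm], g.classes[gm])
        _, fl = match_detections(sub_p, sub_g, iou_t)
        order = np.argsort(-sub_p.scores) if sub_p.scores is not None \
            else np.arange(len(sub_p))
        flags.append(fl)
        scores.append(sub_p.scores[order] if sub_p.scores is not None
                      else np.ones(len(sub_p)))
        n_gt += len(sub_g)
    return (np.concatenate(flags) if flags else np.zeros(0, dtype=bool),
            np.concatenate(scores) if scores else np.zeros(0), n_gt)


def evaluate_detections(preds: list[BoxSet], gts: list[BoxSet],
                        n_classes: int) -> EvalResult:
    """Full evaluation of per-image predictions against ground truth."""
    classes = [c for c in range(n_classes)
               if any((g.classes == c).any() for g in gts)]
    ap_by_t = {t: [] for t in IOU_THRESHOLDS}
    per_class_ap = {}
    pr_curve = []
    best_p = best_r = best_f1 = []
    # AP at every IoU threshold, macro over classes with ground truth
    for c in classes:
        aps = []
        for t in IOU_THRESHOLDS:
            flags, scores, n_gt = _per_class_eval(preds, gts, c, t)
            ap = average_precision(flags, scores, n_gt) if n_gt else 0.0
            ap_by_t[t].append(ap)
            aps.append(ap)
        per_class_ap[c] = float(np.mean(aps))
    # P/R/F1 at the F1-optimal confidence threshold (IoU 0.5), macro
    pooled = []
    for c in classes:
        flags, scores, n_gt = _per_class_eval(preds, gts, c, 0.5)
        pooled.append((flags, scores, n_gt))
    cand_thresholds = np.unique(np.concatenate(
        [s for _, s, _ in pooled] + [np.array([0.0])]))
    best = (0.0, 0.0, 0.0)
    for th in cand_thresholds:
        ps, rs = [], []
        for flags, scores, n_gt in pooled:
            m = scores >= th
            tp = int(flags[m].sum())
            fp = int(m.sum()) - tp
            fn = n_gt - tp
            p, r, _ = prf1(ConfusionCounts(tp, fp, fn))
            ps.append(p)
            rs.append(r)
        P, R = float(np.mean(ps)) if ps else 0.0, float(np.mean(rs)) if rs else 0.0
        F1 = 2 * P * R / (P + R) if P + R > 0 else 0.0
        pr_curve.append((R, P))
        if F1 >= best[2]:
            best = (P, R, F1)
    ap50 = float(np.mean(ap_by_t[0.5])) if classes else 0.0
    ap75 = float(np.mean(ap_by_t[0.75])) if classes else 0.0
    ap = float(np.mean([np.mean(v) for v in ap_by_t.values()])) if classes else 0.0
    pr_curve.sort()
    return EvalResult(ap=ap, ap50=ap50, ap75=ap75, precision=best[0],
                      recall=best[1], f1=best[2], per_class_ap=per_class_ap,
                      pr_curve=pr_curve, n_images=len(preds),
                      degenerate=not classes)


def plot_pr_curve(result: EvalResult, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    rs = [r for r, _ in result.pr_curve]
    ps = [p for _, p in result.pr_curve]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(rs, ps, "-o", ms=2)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_title(f"AP50={result.ap50:.3f}  F1={result.f1:.3f}")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
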