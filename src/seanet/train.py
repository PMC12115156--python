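"""Training and evaluation orchestration.

Defaults mirror the reference experimental protocol: 640-pixel inputs,
batch 16, SGD with momentum 0.937, weight decay 5e-4 and initial
learning rate 0.01 for 300 epochs, mosaic augmentation disabled for the
last 10 epochs, early stopping on validation AP50. A "tiny" profile
(quarter widths, 160-pixel inputs, small epoch counts, batch 8, no
early stopping) makes CPU-scale experiments practical; its overrides
are explicit in :meth:`RunConfig.tiny`.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import tensor as T
from .assigner import TaskAlignedAssigner
from .data import DetectionDataset, batches, to_chw
from .head import decode_boxes_np
from .losses import DetectionLoss, LossBreakdown
from .metrics import EvalResult, evaluate_detections
from .model import ModelConfig, SEANet
from .optim import SGD, ModelEMA, warmup_cosine_lr
from .synthetic import DegradationSpec
from .tensor import Tensor


@dataclass
class RunConfig:
    image_size: int = 640
    batch_size: int = 16
    momentum: float = 0.937
    weight_decay: float = 0.0005
    initial_lr: float = 0.01
    epochs: int = 300
    seed: int = 0
    mosaic_disable_last: int = 10
    early_stopping_patience: int = 50
    warmup_epochs: int = 3
    use_ema: bool = True            # evaluate an EMA of the weights
    profile: str = "full"           # "full" | "tiny"

    @staticmethod
    def tiny(epochs: int = 30, seed: int = 0) -> "RunConfig":
        """CPU-scale profile. Overrides vs the full protocol: 160-pixel
        inputs, batch 4, initial LR 0.025 (short schedules need a faster
        effective rate at quarter width), no early stopping."""
        return RunConfig(image_size=160, batch_size=4, initial_lr=0.025,
                         epochs=epochs, seed=seed,
                         early_stopping_patience=0, profile="tiny")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "RunConfig":
        return RunConfig(**yaml.safe_load(text))


@dataclass
class TrainResult:
    model: SEANet
    log: list                      # one dict per epoch
    best_ap50: float
    checkpoint_path: str | None = None


def mosaic_active(epoch: int, cfg: RunConfig) -> bool:
    return epoch < cfg.epochs - cfg.mosaic_disable_last


def train(cfg: RunConfig, train_data: DetectionDataset,
          val_data: DetectionDataset | None = None,
          model_cfg: ModelConfig | None = None,
          out_dir=None, log_every_step: bool = False,
          eval_every: int = 5) -> TrainResult:
    """Run the training loop; returns the model and a per-epoch metric log."""
    if model_cfg is None:
        model_cfg = ModelConfig.tiny() if cfg.profile == "tiny" else ModelConfig()
    rng = np.random.default_rng(cfg.seed)
    model = SEANet(model_cfg, seed=cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.initial_lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    assigner = TaskAlignedAssigner()
    loss_fn = DetectionLoss(model_cfg.n_classes, model_cfg.reg_max)

    ema = ModelEMA(model) if cfg.use_ema else None
    eval_model = SEANet(model_cfg, seed=cfg.seed) if cfg.use_ema else model

    steps_per_epoch = max(int(np.ceil(len(train_data) / cfg.batch_size)), 1)
    total_steps = steps_per_epoch * cfg.epochs
    warmup = cfg.warmup_epochs * steps_per_epoch

    out = Path(out_dir) if out_dir is not None else None
    log_fh = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        log_fh = open(out / "metrics.jsonl", "w")

    log = []
    best_ap50, best_state, since_best = -1.0, None, 0
    step = 0
    for epoch in range(cfg.epochs):
        model.train()
        t0 = time.time()
        ep_losses = []
        for images, gts in batches(train_data, cfg.batch_size, rng,
                                   mosaic=mosaic_active(epoch, cfg)):
            opt.lr = warmup_cosine_lr(step, total_steps, cfg.initial_lr, warmup)
            breakdown = train_step(model, assigner, loss_fn, opt, images, gts)
            if not np.isfinite(breakdown.total):
                raise RuntimeError(
                    f"divergent (non-finite) loss at epoch {epoch} step {step}: "
                    f"{breakdown}")
            if ema is not None:
                ema.update(model)
            ep_losses.append(breakdown)
            if log_fh and log_every_step:
                log_fh.write(json.dumps({"step": step, **asdict(breakdown)}) + "\n")
            step += 1
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            "mosaic": mosaic_active(epoch, cfg),
            "box_loss": float(np.mean([b.box_loss for b in ep_losses])),
            "cls_loss": float(np.mean([b.cls_loss for b in ep_losses])),
            "dfl_loss": float(np.mean([b.dfl_loss for b in ep_losses])),
            "total_loss": float(np.mean([b.total for b in ep_losses])),
            "seconds": time.time() - t0,
        }
        if val_data is not None and (
                epoch % eval_every == eval_every - 1 or epoch == cfg.epochs - 1):
            if ema is not None:
                ema.copy_to(eval_model)
            res = evaluate(eval_model, val_data)
            entry.update(ap50=res.ap50, ap=res.ap)
            if res.ap50 > best_ap50:
                best_ap50, since_best = res.ap50, 0
                best_state = {k: v.copy()
                              for k, v in eval_model.state_dict().items()}
            else:
                since_best += eval_every
            if cfg.early_stopping_patience and \
                    since_best >= cfg.early_stopping_patience:
                log.append(entry)
                if log_fh:
                    log_fh.write(json.dumps(entry) + "\n")
                break
        log.append(entry)
        if log_fh:
            log_fh.write(json.dumps(entry) + "\n")
            log_fh.flush()

    if best_state is not None:
        model.load_state_dict(best_state)
    elif ema is not None:
        ema.copy_to(model)
    ckpt = None
    if out is not None:
        ckpt = str(out / "model.npz")
        model.save(ckpt)
        (out / "run_config.yaml").write_text(cfg.to_yaml())
    if log_fh:
        log_fh.close()
    return TrainResult(model, log, best_ap50 if best_ap50 >= 0 else float("nan"),
                       ckpt)


def train_step(model: SEANet, assigner: TaskAlignedAssigner,
               loss_fn: DetectionLoss, opt: SGD, images: np.ndarray,
               gts: list) -> LossBreakdown:
    """One forward/assign/backward/update step; returns the loss breakdown."""
    cls, box, pts, sts = model(Tensor(images))
    B = images.shape[0]
    scores = T.sigmoid_np(cls.data)
    assignments = []
    for b in range(B):
        boxes_np = decode_boxes_np(box.data[b].astype(np.float64), pts, sts)
        assignments.append(assigner(scores[b], boxes_np, pts, gts[b],
                                    loss_fn.n_classes))
    total, breakdown = loss_fn(cls, box, pts, sts, assignments, gts)
    opt.zero_grad()
    # gradient scale follows the reference convention: the (already
    # target-score-normalised) batch loss is multiplied by the batch size
    (total * float(B)).backward()
    opt.step()
    return breakdown


def evaluate(model: SEANet, data: DetectionDataset,
             degradation: DegradationSpec | None = None, seed: int = 0,
             batch_size: int = 8) -> EvalResult:
    """Evaluate on a dataset, optionally degrading the images first.

    Degradation is applied to evaluation images only, after annotation;
    boxes are never altered.
    """
    preds, gts = [], []
    n_classes = model.cfg.n_classes
    for start in range(0, len(data), batch_size):
        chunk = [data[i] for i in range(start, min(start + batch_size, len(data)))]
        imgs = []
        for j, (img, bs) in enumerate(chunk):
            if degradation is not None:
                img = degradation.apply(img, seed=seed + start + j)
            imgs.append(to_chw(img))
            gts.append(bs)
        preds.extend(model.predict(np.stack(imgs)))
    res = evaluate_detections(preds, gts, n_classes)
    if degradation is not None:
        res.metadata = {"kind": degradation.kind,
                        "severity": degradation.severity,
                        "noise_std": degradation.noise_std,
                        "blur_kernel": degradation.blur_kernel}
    return res


def robustness_sweep(model: SEANet, data: DetectionDataset, seed: int = 0,
                     out_dir=None) -> list[dict]:
    """Evaluate across both degradation kinds x severities 1-5.

    Returns 10 rows of {kind, severity, noise_std, blur_kernel, ap, ap50,
    ap75}; optionally writes a CSV and a bar plot.
    """
    rows = []
    for kind in ("gaussian_noise", "motion_blur"):
        for sev in range(1, 6):
            spec = DegradationSpec.from_severity(kind, sev)
            res = evaluate(model, data, degradation=spec, seed=seed)
            rows.append({"kind": kind, "severity": sev,
                         "noise_std": spec.noise_std,
                         "blur_kernel": spec.blur_kernel,
                         "ap": res.ap, "ap50": res.ap50, "ap75": res.ap75})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = "kind,severity,noise_std,blur_kernel,ap,ap50,ap75"
        lines = [header] + [
            f"{r['kind']},{r['severity']},{r['noise_std']},{r['blur_kernel']},"
            f"{r['ap']:.6f},{r['ap50']:.6f},{r['ap75']:.6f}" for r in rows]
        (out / "robustness.csv").write_text("\n".join(lines) + "\n")
        _plot_sweep(rows, out / "robustness.png")
    return rows


def _plot_sweep(rows, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, kind in zip(axes, ("gaussian_noise", "motion_blur")):
        sub = [r for r in rows if r["kind"] == kind]
        ax.plot([r["severity"] for r in sub], [r["ap50"] for r in sub],
                "-o", label="AP50")
        ax.plot([r["severity"] for r in sub], [r["ap"] for r in sub],
                "-s", label="AP")
        ax.set_title(kind)
        ax.set_xlabel("severity")
        ax.legend()
    axes[0].set_ylabel("metric")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
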