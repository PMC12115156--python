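"""The full detector: backbone -> pyramid neck -> anchor-free head.

Built for scenes where targets blend into the background: the backbone
amplifies fine detail at high resolution, the neck reweights channels by
their fore/background contrast, and the head regresses boxes as offset
distributions at three strides (8/16/32).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import tensor as T
from .backbone import Backbone, BackboneConfig
from .boxes import BoxSet, nms
from .head import DetectionHead, decode_boxes_np, decode_boxes_t, make_anchors
from .layers import Module
from .sefpn import SEFPN
from .tensor import Tensor


@dataclass
class ModelConfig:
    n_classes: int = 3
    reg_max: int = 16
    width_mult: float = 1.0
    backbone_widths: tuple[int, ...] = (32, 64, 96, 192, 384)
    backbone_depths: tuple[int, ...] = (1, 1, 1, 1)
    neck_widths: tuple[int, int, int] = (96, 192, 384)
    cem_repeats: int = 3
    use_mdam: bool = True
    branch_kernels: tuple[int, int, int] = (3, 5, 7)

    @staticmethod
    def tiny(n_classes: int = 3) -> "ModelConfig":
        return ModelConfig(n_classes=n_classes, width_mult=0.25)


class SEANet(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.backbone = Backbone(BackboneConfig(
            stage_widths=cfg.backbone_widths, stage_depths=cfg.backbone_depths,
            width_mult=cfg.width_mult, use_mdam=cfg.use_mdam,
            branch_kernels=cfg.branch_kernels), rng=rng)
        self.neck = SEFPN(self.backbone.tap_widths, widths=cfg.neck_widths,
                          width_mult=cfg.width_mult,
                          cem_repeats=cfg.cem_repeats, rng=rng)
        self.head = DetectionHead(self.neck.widths, cfg.n_classes,
                                  cfg.reg_max, rng=rng)

    def forward(self, images: Tensor):
        p4, p6, p9 = self.backbone(images)
        d1, d2, d3 = self.neck(p4, p6, p9)
        return self.head((d1, d2, d3))

    # -- inference --------------------------------------------------------
    def predict(self, images: np.ndarray, conf_threshold: float = 0.001,
                iou_threshold: float = 0.7, max_det: int = 300) -> list[BoxSet]:
        """Run detection on a [B, 3, H, W] float array in [0, 1].

        Applies a confidence floor and class-wise greedy NMS; boxes are
        clipped to the image.
        """
        self.eval()
        H, W = images.shape[2], images.shape[3]
        with T.no_grad():
            cls, box, pts, sts = self.forward(Tensor(images))
        scores_all = T.sigmoid_np(cls.data)            # [B, A, nc]
        out = []
        for b in range(images.shape[0]):
            boxes = decode_boxes_np(box.data[b].astype(np.float64), pts, sts,
                                    image_size=(W, H))
            scores = scores_all[b]
            cls_id = scores.argmax(axis=1)
            conf = scores.max(axis=1)
            keep = conf >= conf_threshold
            boxes_k, cls_k, conf_k = boxes[keep], cls_id[keep], conf[keep]
            sel = []
            for c in np.unique(cls_k):
                m = np.flatnonzero(cls_k == c)
                kept = nms(boxes_k[m], conf_k[m], iou_threshold, max_det)
                sel.append(m[kept])
            if sel:
                sel = np.concatenate(sel)
                order = np.argsort(-conf_k[sel])[:max_det]
                sel = sel[order]
                out.append(BoxSet(boxes_k[sel], cls_k[sel], conf_k[sel]))
            else:
                out.append(BoxSet.empty())
        return out

    # -- checkpointing ----------------------------------------------------
    def save(self, path):
        import json
        state = {k: v for k, v in self.state_dict().items()}
        cfg_json = json.dumps(asdict(self.cfg))
        np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
                 **state)

    @staticmethod
    def load(path) -> "SEANet":
        import json
        data = np.load(path)
        cfg_raw = json.loads(bytes(data["__config__"]).decode())
        for key in ("backbone_widths", "backbone_depths", "neck_widths",
                    "branch_kernels"):
            cfg_raw[key] = tuple(cfg_raw[key])
        model = SEANet(ModelConfig(**cfg_raw))
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model
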