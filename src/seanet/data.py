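"""In-memory detection dataset, mosaic augmentation and batching."""

from __future__ import annotations

import numpy as np

from .boxes import BoxSet


def to_chw(image: np.ndarray) -> np.ndarray:
    """uint8 [H, W, 3] -> float32 [3, H, W] in [0, 1]."""
    return (image.transpose(2, 0, 1).astype(np.float32) / 255.0)


class DetectionDataset:
    """A list of (uint8 image [H, W, 3], BoxSet) pairs of equal size."""

    def __init__(self, samples):
        self.samples = list(samples)
        if not self.samples:
            raise ValueError("empty dataset")
        self.image_size = self.samples[0][0].shape[0]

    def __len__(self):
        return len(self.samples)

    def __getitem__(self, i):
        return self.samples[i]


def _clip_boxes(boxset: BoxSet, w: int, h: int, min_area_frac: float = 0.1
                ) -> BoxSet:
    """Clip boxes to the canvas, dropping those that lost >= 90% of area."""
    if len(boxset) == 0:
        return boxset
    orig_area = (boxset.boxes[:, 2] - boxset.boxes[:, 0]) * \
        (boxset.boxes[:, 3] - boxset.boxes[:, 1])
    clipped = boxset.boxes.copy()
    clipped[:, 0::2] = clipped[:, 0::2].clip(0, w)
    clipped[:, 1::2] = clipped[:, 1::2].clip(0, h)
    new_area = (clipped[:, 2] - clipped[:, 0]).clip(0) * \
        (clipped[:, 3] - clipped[:, 1]).clip(0)
    keep = new_area >= min_area_frac * orig_area
    keep &= new_area > 0
    return BoxSet(clipped[keep], boxset.classes[keep])


def mosaic_augment(four_samples, canvas_size: int, seed: int,
                   center: tuple[int, int] | None = None):
    """Compose four samples into one canvas around a random centre.

    The four images are laid out on a 2x canvas meeting at the centre
    point, then the canvas_size window around that point is cut out.
    Boxes are offset-translated, clipped, and dropped when less than 10%
    of their area survives.
    """
    rng = np.random.default_rng(seed)
    s = canvas_size
    big = np.zeros((2 * s, 2 * s, 3), dtype=four_samples[0][0].dtype)
    if center is None:
        cx = int(rng.uniform(0.5 * s, 1.5 * s))
        cy = int(rng.uniform(0.5 * s, 1.5 * s))
    else:
        cx, cy = center
    boxes, classes = [], []
    for q, (img, bs) in enumerate(four_samples):
        h, w = img.shape[:2]
        if q == 0:      # top-left: bottom-right corner at (cx, cy)
            x1, y1 = max(cx - w, 0), max(cy - h, 0)
            x2, y2 = cx, cy
        elif q == 1:    # top-right
            x1, y1 = cx, max(cy - h, 0)
            x2, y2 = min(cx + w, 2 * s), cy
        elif q == 2:    # bottom-left
            x1, y1 = max(cx - w, 0), cy
            x2, y2 = cx, min(cy + h, 2 * s)
        else:           # bottom-right
            x1, y1 = cx, cy
            x2, y2 = min(cx + w, 2 * s), min(cy + h, 2 * s)
        cw, ch = x2 - x1, y2 - y1
        if cw <= 0 or ch <= 0:
            continue
        # anchor each image at the mosaic centre corner
        sx = w - cw if q in (0, 2) else 0
        sy = h - ch if q in (0, 1) else 0
        big[y1:y2, x1:x2] = img[sy:sy + ch, sx:sx + cw]
        if len(bs):
            nb = bs.boxes.copy()
            nb[:, 0::2] += x1 - sx
            nb[:, 1::2] += y1 - sy
            boxes.append(nb)
            classes.append(bs.classes)
    all_boxes = BoxSet(np.concatenate(boxes) if boxes else np.zeros((0, 4)),
                       np.concatenate(classes) if classes else
                       np.zeros(0, dtype=np.int64))
    # cut the canvas_size window centred on the mosaic centre
    ox = int(np.clip(cx - s // 2, 0, s))
    oy = int(np.clip(cy - s // 2, 0, s))
    window = big[oy:oy + s, ox:ox + s]
    shifted = BoxSet(all_boxes.boxes - np.array([ox, oy, ox, oy]),
                     all_boxes.classes)
    return window, _clip_boxes(shifted, s, s)


def batches(dataset: DetectionDataset, batch_size: int, rng,
            mosaic: bool = False):
    """Yield (images float32 [B, 3, S, S], [BoxSet]) in shuffled order."""
    idx = rng.permutation(len(dataset))
    s = dataset.image_size
    for start in range(0, len(idx), batch_size):
        chunk = idx[start:start + batch_size]
        imgs, gts = [], []
        for i in chunk:
            if mosaic:
                others = rng.integers(0, len(dataset), size=3)
                four = [dataset[i]] + [dataset[int(j)] for j in others]
                img, bs = mosaic_augment(four, s, seed=int(rng.integers(2 ** 31)))
            else:
                img, bs = dataset[i]
            imgs.append(to_chw(img))
            gts.append(bs)
        yield np.stack(imgs), gts
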