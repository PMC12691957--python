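"""Anchor-based single-class lesion-proposal detector.

Three detection heads operate on feature maps downsampled 32x, 16x and 8x,
each with three anchors per location; every anchor predicts 4 box
coordinates, 1 objectness score and 1 lesion-vs-background logit, so each
head emits ``anchors_per_level * 6`` prediction channels (18 at the
defaults).  The backbone is a small strided conv net with residual blocks:
the cascade downstream is detector-agnostic, and on speckle phantoms a
compact trunk trains on a CPU in minutes while preserving the head
geometry under study.

Boxes are encoded YOLO-style relative to the assigned anchor: sigmoid cell
offsets for the center, log size ratios for width/height.  Training uses a
class-balanced objectness BCE, squared error on the encoded box offsets,
and BCE on the class logit of positive anchors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize
from sklearn.cluster import KMeans

from . import _nn
from .phantom import BilateralPair, Box
from .evaluation import iou

F32 = np.float32

_DEFAULT_ANCHORS = (
    ((116, 90), (156, 198), (373, 326)),  # stride 32
    ((30, 61), (62, 45), (59, 119)),      # stride 16
    ((10, 13), (16, 30), (33, 23)),       # stride 8
)


@dataclass(frozen=True)
class DetectorConfig:
    input_size: int = 544
    strides: tuple[int, ...] = (32, 16, 8)
    anchors_per_level: int = 3
    anchor_sizes: tuple | None = None  # ((w,h)*A per level); None -> k-means over GT
    n_classes: int = 1
    conf_floor: float = 0.01
    nms_iou: float = 0.30
    backbone_channels: tuple[int, int, int, int, int] = (8, 12, 16, 24, 32)
    assign_iou: float = 0.5

    def __post_init__(self) -> None:
        if self.input_size % max(self.strides) != 0:
            raise ValueError("input_size must be divisible by the largest stride")
        if self.anchors_per_level < 1 or self.n_classes < 1:
            raise ValueError("anchors_per_level and n_classes must be >= 1")

    @classmethod
    def desk_scale(cls, **kw) -> "DetectorConfig":
        """Reduced profile for CPU training on 256 px phantoms."""
        kw.setdefault("input_size", 256)
        return cls(**kw)


@dataclass(frozen=True)
class Detection:
    box: Box
    confidence: float
    level: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


def head_channels(cfg: DetectorConfig) -> int:
    """Prediction channels per detection head: A * (4 box + 1 obj + n_classes)."""
    return cfg.anchors_per_level * (4 + 1 + cfg.n_classes)


# ---------------------------------------------------------------------------
# model

class DetectorModel:
    """Backbone with taps at /8, /16, /32 plus one 1x1-conv head per tap."""

    def __init__(self, cfg: DetectorConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4, c5 = cfg.backbone_channels
        nn = _nn

        # plain conv blocks: with the class-balanced per-level loss the small
        # trunk trains stably, and skipping batch statistics keeps single-image
        # inference identical to training-time behavior
        def cbr(ci, co, stride):
            return [nn.Conv2d(ci, co, 3, stride, rng), nn.ReLU()]

        def res(c):
            return nn.Residual(nn.Sequential(
                nn.Conv2d(c, c, 3, 1, rng), nn.ReLU(), nn.Conv2d(c, c, 3, 1, rng)
            ))

        self.to8 = nn.Sequential(
            *cbr(1, c1, 2), *cbr(c1, c2, 2), *cbr(c2, c3, 2), res(c3), nn.ReLU()
        )
        self.to16 = nn.Sequential(*cbr(c3, c4, 2), res(c4), nn.ReLU())
        self.to32 = nn.Sequential(*cbr(c4, c5, 2), res(c5), nn.ReLU())
        hc = head_channels(cfg)
        self.heads = {32: nn.Conv2d(c5, hc, 1, 1, rng),
                      16: nn.Conv2d(c4, hc, 1, 1, rng),
                      8: nn.Conv2d(c3, hc, 1, 1, rng)}
        self.anchors = np.asarray(cfg.anchor_sizes or _DEFAULT_ANCHORS, dtype=F32)
        if self.anchors.shape != (len(cfg.strides), cfg.anchors_per_level, 2):
            raise ValueError("anchor_sizes must be (n_levels, anchors_per_level, 2)")

    def params(self):
        ps = self.to8.params() + self.to16.params() + self.to32.params()
        for h in self.heads.values():
            ps += h.params()
        return ps

    def buffers(self):
        bs = self.to8.buffers() + self.to16.buffers() + self.to32.buffers()
        for h in self.heads.values():
            bs += h.buffers()
        return bs

    def forward(self, x: np.ndarray, train: bool = True) -> dict[int, np.ndarray]:
        """x: (N, 1, S, S) -> {stride: (N, head_channels, S/stride, S/stride)}."""
        if x.shape[2] % max(self.cfg.strides) or x.shape[3] % max(self.cfg.strides):
            raise ValueError("input spatial size must be divisible by every stride")
        f8 = self.to8.forward(x, train)
        f16 = self.to16.forward(f8, train)
        f32 = self.to32.forward(f16, train)
        feats = {8: f8, 16: f16, 32: f32}
        return {s: self.heads[s].forward(feats[s], train) for s in self.cfg.strides}

    def backward(self, grads: dict[int, np.ndarray]) -> None:
        d32 = self.heads[32].backward(grads[32])
        d16 = self.heads[16].backward(grads[16]) + self.to32.backward(d32)
        d8 = self.heads[8].backward(grads[8]) + self.to16.backward(d16)
        self.to8.backward(d8)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = [p for p, _ in self.params()] + self.buffers()
        arrays = {f"p{i}": p for i, p in enumerate(state)}
        np.savez(path.with_suffix(".npz"), anchors=self.anchors, **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.cfg), default=list))

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "DetectorModel":
        path = Path(path)
        raw = json.loads(path.with_suffix(".json").read_text())
        for k in ("strides", "backbone_channels"):
            raw[k] = tuple(raw[k])
        if raw["anchor_sizes"] is not None:
            raw["anchor_sizes"] = tuple(tuple(tuple(a) for a in lv) for lv in raw["anchor_sizes"])
        model = cls(DetectorConfig(**raw), seed=seed)
        data = np.load(path.with_suffix(".npz"))
        model.anchors = data["anchors"]
        own = [p for p, _ in model.params()] + model.buffers()
        for p, i in zip(own, range(len(own))):
            p[...] = data[f"p{i}"].astype(F32)
        return model


def build_detector(cfg: DetectorConfig, seed: int = 0) -> DetectorModel:
    return DetectorModel(cfg, seed=seed)


# ---------------------------------------------------------------------------
# letterboxing

def letterbox(image: np.ndarray, size: int) -> tuple[np.ndarray, float, int, int]:
    """Aspect-preserving resize onto a gray size x size canvas.

    Returns (canvas, scale, pad_x, pad_y) so that original coords map as
    x' = x * scale + pad_x.
    """
    h, w = image.shape
    scale = min(size / h, size / w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    resized = resize(image, (nh, nw), order=1, anti_aliasing=False, preserve_range=True)
    canvas = np.full((size, size), 0.5, dtype=F32)
    py, px = (size - nh) // 2, (size - nw) // 2
    canvas[py : py + nh, px : px + nw] = resized
    return canvas, scale, px, py


# ---------------------------------------------------------------------------
# anchor assignment and box coding

def _shape_iou(wh: tuple[float, float], anchors: np.ndarray) -> np.ndarray:
    """IoU of same-center boxes: anchors (..., 2) vs one (w, h)."""
    w, h = wh
    iw = np.minimum(anchors[..., 0], w)
    ih = np.minimum(anchors[..., 1], h)
    inter = iw * ih
    return inter / (anchors[..., 0] * anchors[..., 1] + w * h - inter)


def assign_anchors(boxes: Sequence[Box], model: DetectorModel) -> list[tuple[int, int, int, int, Box]]:
    """Assign each GT box (input-scale coords) to anchors.

    Anchor choice: the globally best-matching anchor always, plus every
    anchor with shape-IoU above the assignment threshold.  Cell choice: the
    center cell plus its two nearest neighbor cells, representable because
    center offsets decode through a scaled sigmoid spanning (-0.5, 1.5).
    """
    cfg = model.cfg
    out = []
    for b in boxes:
        sims = _shape_iou((b.w, b.h), model.anchors)  # (L, A)
        best = np.unravel_index(int(np.argmax(sims)), sims.shape)
        chosen = {best} | {tuple(idx) for idx in np.argwhere(sims > cfg.assign_iou)}
        for li, ai in chosen:
            s = cfg.strides[li]
            n = cfg.input_size // s
            gx = min(int(b.cx / s), n - 1)
            gy = min(int(b.cy / s), n - 1)
            fx, fy = b.cx / s - gx, b.cy / s - gy
            cells = {(gy, gx)}
            gx2 = gx - 1 if fx < 0.5 else gx + 1
            gy2 = gy - 1 if fy < 0.5 else gy + 1
            if 0 <= gx2 < n:
                cells.add((gy, gx2))
            if 0 <= gy2 < n:
                cells.add((gy2, gx))
            for cy, cx in cells:
                out.append((li, ai, cy, cx, b))
    return out


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def encode_box(b: Box, anchor: tuple[float, float], stride: int,
               cell: tuple[int, int] | None = None) -> tuple[int, int, np.ndarray]:
    """Encode a box against an anchor at a cell: (gy, gx, [tx, ty, tw, th]).

    Center offsets decode as 2*sigmoid(t) - 0.5 (range (-0.5, 1.5), so a
    neighbor cell can own the box); sizes are log ratios to the anchor.
    """
    if cell is None:
        cell = (int(b.cy / stride), int(b.cx / stride))
    gy, gx = cell
    fx, fy = b.cx / stride - gx, b.cy / stride - gy
    tx = _logit(np.asarray((fx + 0.5) / 2.0))
    ty = _logit(np.asarray((fy + 0.5) / 2.0))
    tw = np.log(b.w / anchor[0])
    th = np.log(b.h / anchor[1])
    return gy, gx, np.array([float(tx), float(ty), tw, th])


def decode_box(t: np.ndarray, gy: int, gx: int, anchor: tuple[float, float], stride: int) -> Box:
    """Inverse of :func:`encode_box` (t holds pre-sigmoid offsets and log ratios)."""
    cx = (gx + 2.0 * _nn.sigmoid(np.asarray([t[0]]))[0] - 0.5) * stride
    cy = (gy + 2.0 * _nn.sigmoid(np.asarray([t[1]]))[0] - 0.5) * stride
    w = anchor[0] * np.exp(np.clip(t[2], -6, 6))
    h = anchor[1] * np.exp(np.clip(t[3], -6, 6))
    return Box(x=cx - w / 2, y=cy - h / 2, w=w, h=h)


# ---------------------------------------------------------------------------
# training

def _kmeans_anchors(boxes_wh: np.ndarray, cfg: DetectorConfig, seed: int) -> np.ndarray:
    """Cluster GT sizes (input-scale) into per-level anchors, small to large stride-wise."""
    n = len(cfg.strides) * cfg.anchors_per_level
    if len(boxes_wh) < n:
        return np.asarray(_DEFAULT_ANCHORS, dtype=F32)
    km = KMeans(n_clusters=n, n_init=5, random_state=seed).fit(boxes_wh)
    centers = km.cluster_centers_[np.argsort(km.cluster_centers_.prod(axis=1))]
    # largest stride (coarsest map) gets the largest anchors
    levels = np.argsort(-np.asarray(cfg.strides))
    anchors = np.empty((len(cfg.strides), cfg.anchors_per_level, 2), dtype=F32)
    for rank, li in enumerate(levels):
        anchors[li] = centers[rank * cfg.anchors_per_level : (rank + 1) * cfg.anchors_per_level]
    return np.maximum(anchors, 2.0)


def _scale_box(b: Box, scale: float, px: float, py: float) -> Box:
    return Box(x=b.x * scale + px, y=b.y * scale + py, w=b.w * scale, h=b.h * scale)


def _image_records(dataset: Sequence[BilateralPair], size: int):
    """Flatten pairs into per-side letterboxed training images."""
    recs = []
    for pair in dataset:
        for side in ("left", "right"):
            canvas, scale, px, py = letterbox(pair.image(side), size)
            boxes = [_scale_box(b, scale, px, py) for b in pair.boxes(side)]
            recs.append((canvas.astype(F32), boxes))
    return recs


def _targets_for(model: DetectorModel, boxes: Sequence[Box]):
    """Per-level positive-anchor targets: {stride: (idx arrays, offset targets)}."""
    cfg = model.cfg
    tgt = {s: [] for s in cfg.strides}
    for li, ai, gy, gx, b in assign_anchors(boxes, model):
        s = cfg.strides[li]
        anchor = model.anchors[li, ai]
        _, _, t = encode_box(b, (float(anchor[0]), float(anchor[1])), s, cell=(gy, gx))
        tgt[s].append((ai, gy, gx, t))
    return tgt


def train_detector(
    dataset: Sequence[BilateralPair],
    cfg: DetectorConfig,
    epochs: int = 20,
    seed: int = 0,
    batch_size: int = 8,
    lr: float = 2e-3,
    flip_augment: bool = True,
) -> tuple[DetectorModel, list[float]]:
    """Train on the individual side images of ``dataset``; returns (model, loss trace).

    Anchors default to k-means over the dataset's GT sizes.  Lesion-free
    images stay in training as pure backgrounds; an annotated image whose
    boxes cannot be assigned to any anchor is skipped with a warning.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(seed)
    recs = _image_records(dataset, cfg.input_size)

    if cfg.anchor_sizes is None:
        wh = np.array([[b.w, b.h] for _, boxes in recs for b in boxes], dtype=F32)
        anchors = _kmeans_anchors(wh, cfg, seed) if len(wh) else np.asarray(_DEFAULT_ANCHORS, dtype=F32)
    else:
        anchors = np.asarray(cfg.anchor_sizes, dtype=F32)
    model = DetectorModel(cfg, seed=seed)
    model.anchors = anchors

    kept = []
    for img, boxes in recs:
        if boxes and not assign_anchors(boxes, model):
            warnings.warn("image skipped: no positive anchors assignable", stacklevel=2)
            continue
        kept.append((img, boxes))
    if not kept:
        raise ValueError("no trainable images after anchor assignment")

    opt = _nn.Adam(model.params(), lr=lr)
    trace: list[float] = []
    n = len(kept)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            imgs, tgts = [], []
            for i in idx:
                img, boxes = kept[i]
                if flip_augment and rng.random() < 0.5:
                    img = img[:, ::-1].copy()
                    boxes = [Box(x=cfg.input_size - b.x - b.w, y=b.y, w=b.w, h=b.h) for b in boxes]
                imgs.append(img)
                tgts.append(_targets_for(model, boxes))
            x = np.stack(imgs)[:, None, :, :]
            preds = model.forward(x, train=True)
            loss, grads = _detection_loss(preds, tgts, model)
            opt.zero_grad()
            model.backward(grads)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        if not np.isfinite(trace[-1]):
            raise FloatingPointError("non-finite training loss")
    return model, trace


# negatives vastly outnumber positives even after per-level normalization;
# extra weight on the negative objectness term keeps background calibrated
_NEG_WEIGHT = 4.0
_BOX_WEIGHT = 5.0


def _detection_loss(preds: dict[int, np.ndarray], tgts: list[dict], model: DetectorModel):
    """Class-balanced objectness BCE + box offset SE + class BCE on positives."""
    cfg = model.cfg
    a, nout = cfg.anchors_per_level, 5 + cfg.n_classes
    grads = {}
    pos_terms, obj_ps, obj_ts = [], [], []
    total_box = 0.0
    n_pos_total = 0
    for si, s in enumerate(cfg.strides):
        p = preds[s]  # (N, C, H, W)
        n, c, h, w = p.shape
        pr = p.reshape(n, a, nout, h, w)
        g = np.zeros_like(pr)
        obj_t = np.zeros((n, a, h, w), dtype=F32)
        for bi, tgt in enumerate(tgts):
            for ai, gy, gx, t in tgt[s]:
                obj_t[bi, ai, gy, gx] = 1.0
                # box offsets: squared error; tx, ty compared post-sigmoid
                po = pr[bi, ai, :4, gy, gx]
                # decoded cell offsets: 2*sigmoid - 0.5, squared error
                sg = 2.0 * _nn.sigmoid(po[:2]) - 0.5
                tgt_off = 2.0 * _nn.sigmoid(t[:2].astype(F32)) - 0.5
                # d/dt [2*sig(t)-0.5] = (sg+0.5)*(1.5-sg)/2
                d_xy = _BOX_WEIGHT * (sg - tgt_off) * (sg + 0.5) * (1.5 - sg)
                d_wh = _BOX_WEIGHT * 2.0 * (po[2:4] - t[2:4])
                total_box += _BOX_WEIGHT * float(
                    np.sum((sg - tgt_off) ** 2) + np.sum((po[2:4] - t[2:4]) ** 2)
                )
                g[bi, ai, :4, gy, gx] += np.concatenate([d_xy, d_wh])
                # class logits: BCE toward 1
                cl = pr[bi, ai, 5:, gy, gx]
                g[bi, ai, 5:, gy, gx] += _nn.sigmoid(cl) - 1.0
                n_pos_total += 1
        obj_ps.append(pr[:, :, 4, :, :])
        obj_ts.append(obj_t)
        grads[s] = g

    n_pos = max(n_pos_total, 1)
    loss = total_box / n_pos
    for si, s in enumerate(cfg.strides):
        p_obj = obj_ps[si]
        t_obj = obj_ts[si]
        # negatives normalized within their own level so coarse grids are
        # not drowned out by the 16x larger fine grid
        n_neg = max(int(t_obj.size - t_obj.sum()), 1)
        prob = _nn.sigmoid(p_obj)
        eps = 1e-9
        loss += float(-np.sum(t_obj * np.log(prob + eps)) / n_pos
                      - _NEG_WEIGHT * np.sum((1 - t_obj) * np.log(1 - prob + eps)) / n_neg)
        d_obj = np.where(t_obj > 0, (prob - 1.0) / n_pos, _NEG_WEIGHT * prob / n_neg)
        g = grads[s]
        g[:, :, 4, :, :] += d_obj
        # normalize positive-term grads
        g[:, :, :4, :, :] /= n_pos
        g[:, :, 5:, :, :] /= n_pos
        grads[s] = g.reshape(preds[s].shape).astype(F32)
    return loss, grads


# ---------------------------------------------------------------------------
# inference

def decode_predictions(preds: dict[int, np.ndarray], model: DetectorModel,
                       conf_floor: float) -> list[Detection]:
    """Decode one image's prediction grids into input-scale detections."""
    cfg = model.cfg
    a, nout = cfg.anchors_per_level, 5 + cfg.n_classes
    dets: list[Detection] = []
    for li, s in enumerate(cfg.strides):
        p = preds[s][0].reshape(a, nout, preds[s].shape[2], preds[s].shape[3])
        obj = _nn.sigmoid(p[:, 4])
        cls = _nn.sigmoid(p[:, 5:]).max(axis=1)
        conf = obj * cls
        for ai, gy, gx in zip(*np.nonzero(conf >= conf_floor)):
            t = p[ai, :4, gy, gx]
            anchor = model.anchors[li, ai]
            b = decode_box(t, int(gy), int(gx), (float(anchor[0]), float(anchor[1])), s)
            dets.append(Detection(box=_clip_to(b, cfg.input_size), confidence=float(conf[ai, gy, gx]), level=li))
    return dets


def _clip_to(b: Box, size: int) -> Box:
    x0, y0 = min(max(b.x, 0.0), size - 1.0), min(max(b.y, 0.0), size - 1.0)
    x1, y1 = max(min(b.x + b.w, float(size)), x0 + 1e-3), max(min(b.y + b.h, float(size)), y0 + 1e-3)
    return Box(x=x0, y=y0, w=x1 - x0, h=y1 - y0)


def nms(detections: Sequence[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression on confidence-sorted detections."""
    kept: list[Detection] = []
    for d in detections:
        if all(iou(d.box, k.box) <= iou_threshold for k in kept):
            kept.append(d)
    return kept


def detect(model: DetectorModel, image: np.ndarray, conf_floor: float | None = None) -> list[Detection]:
    """Run the detector on one grayscale image; boxes in original pixel coords."""
    cfg = model.cfg
    floor = cfg.conf_floor if conf_floor is None else conf_floor
    canvas, scale, px, py = letterbox(image, cfg.input_size)
    preds = model.forward(canvas[None, None, :, :].astype(F32), train=False)
    dets = decode_predictions(preds, model, floor)
    dets.sort(key=lambda d: -d.confidence)
    dets = nms(dets[:300], cfg.nms_iou)  # top-k cap before suppression
    h, w = image.shape
    out = []
    for d in dets:
        b = d.box
        ob = Box(
            x=(b.x - px) / scale, y=(b.y - py) / scale, w=b.w / scale, h=b.h / scale
        )
        x0, y0 = min(max(ob.x, 0.0), w - 1.0), min(max(ob.y, 0.0), h - 1.0)
        x1 = max(min(ob.x + ob.w, float(w)), x0 + 1e-3)
        y1 = max(min(ob.y + ob.h, float(h)), y0 + 1e-3)
        out.append(Detection(box=Box(x=x0, y=y0, w=x1 - x0, h=y1 - y0),
                             confidence=d.confidence, level=d.level))
    return out
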