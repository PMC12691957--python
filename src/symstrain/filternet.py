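"""Siamese-style similarity filter (S-CNN) over contralateral patch pairs.

The two patches of a pair are stacked along the channel axis (optionally
together with their HOG maps) and mapped by a compact pre-activation
residual network to a single tanh-bounded score in [-1, 1]: -1 means the
regions look alike (normal mirrored tissue, or a bilateral look-alike
artifact), +1 means they differ (a genuine unilateral lesion).  Training
minimizes mean squared error against the +-1 labels, with the patch-level
augmentations applied on the fly: small rotations and isotropic scalings,
photometric jitter, Gaussian noise, and a random swap of the two channels —
the last only meaningful because the channels are the two sides of the
body, which is why ``gray_pair`` is the default channel composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import _nn
from .hog import HogConfig, hog_map
from .symmetry import PatchPair

F32 = np.float32


@dataclass(frozen=True)
class AugmentConfig:
    rotation: float = 5.0                       # degrees, uniform +-
    scale: tuple[float, float] = (0.9, 1.1)     # isotropic
    photometric: float = 0.10                   # multiplicative jitter, +-fraction
    noise_sd: tuple[float, float] = (0.01, 0.02)
    channel_swap_p: float = 0.5


@dataclass(frozen=True)
class FilterConfig:
    input_size: int = 128
    channel_mode: str = "gray_pair"   # or "grayhog_pair" (adds the two HOG maps)
    backbone_depth: int = 4           # number of downsampling stages with residual blocks
    epochs: int = 1000                # faithful schedule; desk_scale() reduces it
    batch_size: int = 32
    lr: float = 1e-3
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    decision_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_mode not in ("gray_pair", "grayhog_pair"):
            raise ValueError("channel_mode must be 'gray_pair' or 'grayhog_pair'")
        if self.input_size != 128:
            raise ValueError("input_size is fixed at 128")

    @property
    def in_channels(self) -> int:
        return 2 if self.channel_mode == "gray_pair" else 4

    @classmethod
    def desk_scale(cls, **kw) -> "FilterConfig":
        """Reduced profile for CPU training: fewer epochs, shallower trunk."""
        kw.setdefault("epochs", 30)
        kw.setdefault("backbone_depth", 3)
        kw.setdefault("lr", 5e-4)
        return cls(**kw)


@dataclass(frozen=True)
class SimilarityScore:
    value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.value <= 1.0:
            raise ValueError("similarity score must lie in [-1, 1]")


class SCNNModel:
    def __init__(self, cfg: FilterConfig, seed: int | None = None):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        nn = _nn
        chans = [8, 16, 32, 32, 32][: cfg.backbone_depth]
        layers: list[_nn.Layer] = []
        c_prev = cfg.in_channels
        for c in chans:
            layers += [nn.Conv2d(c_prev, c, 3, 2, rng), nn.BatchNorm2d(c), nn.ReLU(),
                       nn.Residual(nn.Sequential(
                           nn.Conv2d(c, c, 3, 1, rng), nn.BatchNorm2d(c), nn.ReLU(),
                           nn.Conv2d(c, c, 3, 1, rng), nn.BatchNorm2d(c))),
                       nn.ReLU()]
            c_prev = c
        layers += [nn.GlobalAvgPool(), nn.Linear(c_prev, 1, rng), nn.Tanh()]
        self.net = nn.Sequential(*layers)

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {x.shape[1]}")
        return self.net.forward(x.astype(F32), train)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        self.net.backward(dy[:, None].astype(F32))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(_nn.state_dict(self.net))}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.cfg), default=list))

    @classmethod
    def load(cls, path: str | Path) -> "SCNNModel":
        path = Path(path)
        cfg_raw = json.loads(path.with_suffix(".json").read_text())
        aug_raw = cfg_raw.pop("augment")
        aug_raw["scale"] = tuple(aug_raw["scale"])
        aug_raw["noise_sd"] = tuple(aug_raw["noise_sd"])
        cfg = FilterConfig(augment=AugmentConfig(**aug_raw), **cfg_raw)
        model = cls(cfg)
        data = np.load(path.with_suffix(".npz"))
        _nn.load_state(model.net, [data[f"p{i}"] for i in range(len(data.files))])
        return model


def build_scnn(cfg: FilterConfig = FilterConfig(), seed: int | None = None) -> SCNNModel:
    return SCNNModel(cfg, seed=seed)


# ---------------------------------------------------------------------------
# input assembly and augmentation

def pair_tensor(p: PatchPair, cfg: FilterConfig, hog_cfg: HogConfig = HogConfig()) -> np.ndarray:
    """Stack a PatchPair into the network input (C, H, W)."""
    chans = [p.index_patch, p.reference_patch]
    if cfg.channel_mode == "grayhog_pair":
        chans += [hog_map(p.index_patch, hog_cfg), hog_map(p.reference_patch, hog_cfg)]
    x = np.stack(chans).astype(F32)
    if x.shape[1] != cfg.input_size or x.shape[2] != cfg.input_size:
        raise ValueError(f"patches must be {cfg.input_size}x{cfg.input_size}")
    return x


def _augment(x: np.ndarray, aug: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply one random draw of the augmentation policy to a (C, H, W) sample."""
    c, h, w = x.shape
    theta = np.deg2rad(rng.uniform(-aug.rotation, aug.rotation))
    s = rng.uniform(*aug.scale)
    # same geometric transform for every channel (the pair must stay aligned)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]) / s
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - rot @ center
    out = np.empty_like(x)
    for i in range(c):
        out[i] = ndimage.affine_transform(x[i], rot, offset=offset, order=1, mode="reflect")
    for i in range(c):
        out[i] = out[i] * (1.0 + rng.uniform(-aug.photometric, aug.photometric))
        out[i] = out[i] + rng.normal(0.0, rng.uniform(*aug.noise_sd), size=(h, w))
    if rng.random() < aug.channel_swap_p:
        if c == 2:
            out = out[::-1]
        else:  # keep each patch with its own HOG map
            out = out[[1, 0, 3, 2]]
    return np.clip(out, 0.0, 1.5).astype(F32)


# ---------------------------------------------------------------------------
# training and scoring

def train_scnn(
    pairs: Sequence[PatchPair],
    cfg: FilterConfig = FilterConfig(),
    hog_cfg: HogConfig = HogConfig(),
    val_fraction: float = 0.2,
) -> tuple[SCNNModel, "pd.DataFrame"]:
    """Train the similarity filter on labeled pairs; returns (model, log).

    The log records per-epoch MSE loss and per-class validation accuracy.
    Classes are rebalanced per epoch by oversampling the minority class.
    """
    import pandas as pd

    labels = np.array([p.label for p in pairs])
    if any(l is None for l in labels):
        raise ValueError("all training pairs must be labeled")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both similar and dissimilar pairs")

    rng = np.random.default_rng(cfg.seed)
    X = np.stack([pair_tensor(p, cfg, hog_cfg) for p in pairs])
    y = labels.astype(F32)

    # stratified train/val split at pair level
    idx_pos = np.flatnonzero(y > 0)
    idx_neg = np.flatnonzero(y < 0)
    rng.shuffle(idx_pos)
    rng.shuffle(idx_neg)
    n_vp = max(1, int(len(idx_pos) * val_fraction))
    n_vn = max(1, int(len(idx_neg) * val_fraction))
    val_idx = np.concatenate([idx_pos[:n_vp], idx_neg[:n_vn]])
    tr_pos, tr_neg = idx_pos[n_vp:], idx_neg[n_vn:]
    if len(tr_pos) == 0 or len(tr_neg) == 0:
        raise ValueError("too few pairs of one class to split off a validation set")

    model = SCNNModel(cfg)
    opt = _nn.Adam(model.params(), lr=cfg.lr)
    rows = []
    # balanced epochs; capped so a very lopsided mine does not blow up epoch cost
    n_half = min(max(len(tr_pos), len(tr_neg)), 4 * min(len(tr_pos), len(tr_neg)))
    for epoch in range(cfg.epochs):
        ep = np.concatenate([rng.choice(tr_pos, n_half), rng.choice(tr_neg, n_half)])
        rng.shuffle(ep)
        losses = []
        for start in range(0, len(ep), cfg.batch_size):
            sel = ep[start : start + cfg.batch_size]
            xb = np.stack([_augment(X[i], cfg.augment, rng) for i in sel])
            yb = y[sel]
            out = model.forward(xb, train=True)
            diff = out - yb
            losses.append(float(np.mean(diff**2)))
            model_grad = 2.0 * diff / len(sel)
            opt.zero_grad()
            model.backward(model_grad)
            opt.step()
        acc_sim, acc_dis = _val_accuracy(model, X[val_idx], y[val_idx], cfg)
        rows.append({"epoch": epoch, "loss": float(np.mean(losses)),
                     "val_acc_similar": acc_sim, "val_acc_dissimilar": acc_dis})
        if not np.isfinite(rows[-1]["loss"]):
            raise FloatingPointError("non-finite S-CNN training loss")
    return model, pd.DataFrame(rows)


def _val_accuracy(model: SCNNModel, X: np.ndarray, y: np.ndarray, cfg: FilterConfig):
    scores = _batched_forward(model, X)
    pred_dis = scores >= cfg.decision_threshold
    is_dis = y > 0
    acc_dis = float(np.mean(pred_dis[is_dis])) if is_dis.any() else np.nan
    acc_sim = float(np.mean(~pred_dis[~is_dis])) if (~is_dis).any() else np.nan
    return acc_sim, acc_dis


def _batched_forward(model: SCNNModel, X: np.ndarray, batch: int = 64) -> np.ndarray:
    outs = [model.forward(X[i : i + batch], train=False) for i in range(0, len(X), batch)]
    return np.concatenate(outs) if outs else np.empty(0)


def score_pair(model: SCNNModel, pair: PatchPair, hog_cfg: HogConfig = HogConfig()) -> SimilarityScore:
    """Similarity score of one patch pair; deterministic in eval mode."""
    x = pair_tensor(pair, model.cfg, hog_cfg)[None]
    return SimilarityScore(value=float(np.clip(model.forward(x, train=False)[0], -1.0, 1.0)))


def classify(score: SimilarityScore | float, decision_threshold: float = 0.0) -> str:
    """'dissimilar' iff score >= threshold (boundary breaks toward dissimilar)."""
    v = score.value if isinstance(score, SimilarityScore) else float(score)
    return "dissimilar" if v >= decision_threshold else "similar"
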