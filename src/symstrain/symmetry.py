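"""Contralateral reference localization and training-pair mining.

For a candidate box on one side of a bilateral pair, the anatomically
corresponding region lies at the mirrored position on the other side — up
to a small translation from probe-placement differences.  Candidate
references are therefore the exact mirror plus three jittered mirrors
(+-jitter px in x and/or y), cropped as fixed-size patches; HOG descriptor
distance picks the best-aligned one.  Training pairs for the similarity
filter are mined by sliding a coarse window over each hemifield (side
image) and labeling windows by their ground-truth overlap on the two sides:
-1 = similar (lesion-free on both sides), +1 = dissimilar (lesion under the
index window, none under its reference).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .hog import HogConfig, hog_descriptor, hog_distance
from .phantom import BilateralPair, Box


@dataclass(frozen=True)
class SymmetryConfig:
    patch_size: int = 128
    jitter: int = 32
    mine_stride: int = 64
    mirror_mode: str = "flip"
    expand_margin: float | None = None  # None -> (patch_size - max(w,h))/2, clamped >= 8

    def __post_init__(self) -> None:
        if self.mirror_mode not in ("flip", "identity"):
            raise ValueError("mirror_mode must be 'flip' or 'identity'")
        if self.patch_size <= 0 or self.jitter < 0 or self.mine_stride <= 0:
            raise ValueError("patch_size/mine_stride must be positive, jitter >= 0")


@dataclass
class PatchPair:
    """Index-side patch stacked with one contralateral reference patch."""

    index_patch: np.ndarray
    reference_patch: np.ndarray
    label: int | None = None          # -1 similar, +1 dissimilar, None unlabeled
    source_box: Box | None = None
    reference_center: tuple[float, float] | None = None  # (x, y)

    def __post_init__(self) -> None:
        if self.index_patch.shape != self.reference_patch.shape:
            raise ValueError("patches must have identical shapes")
        if self.label is not None and self.label not in (-1, 1):
            raise ValueError("label must be -1, +1 or None")


def mirror_box(box: Box, image_width: float, mode: str = "flip") -> Box:
    """Mirrored box position: x' = W - x - w under 'flip'; unchanged under 'identity'."""
    if mode == "identity":
        return box
    if mode != "flip":
        raise ValueError(f"unknown mirror mode {mode!r}")
    return Box(x=image_width - box.x - box.w, y=box.y, w=box.w, h=box.h)


def feature_box(box: Box, cfg: SymmetryConfig) -> Box:
    """Candidate box expanded in all four directions to include context."""
    m = cfg.expand_margin
    if m is None:
        m = max((cfg.patch_size - max(box.w, box.h)) / 2.0, 8.0)
    return Box(x=box.x - m, y=box.y - m, w=box.w + 2 * m, h=box.h + 2 * m)


def crop_patch(image: np.ndarray, center: tuple[float, float], size: int) -> np.ndarray:
    """size x size crop centered at (x, y); out-of-image area reflection-padded."""
    h, w = image.shape
    if size > 2 * min(h, w):
        raise ValueError("crop size too large relative to image")
    cx, cy = int(round(center[0])), int(round(center[1]))
    half = size // 2
    x0, y0 = cx - half, cy - half
    pad = size  # enough for any in-image center
    padded = np.pad(image, pad, mode="reflect")
    return padded[pad + y0 : pad + y0 + size, pad + x0 : pad + x0 + size].copy()


def _jitter_offsets(cfg: SymmetryConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Exact mirror first, then 3 distinct non-zero offsets from {-j, 0, +j}^2."""
    j = cfg.jitter
    pool = [(dx, dy) for dx in (-j, 0, j) for dy in (-j, 0, j) if (dx, dy) != (0, 0)]
    picks = rng.choice(len(pool), size=3, replace=False)
    return [(0, 0)] + [pool[i] for i in picks]


def _contra(side: str) -> str:
    return "right" if side == "left" else "left"


def _oriented_crop(contra_img: np.ndarray, center: tuple[float, float], size: int,
                   mode: str) -> np.ndarray:
    """Crop a reference patch and present it in the index side's orientation.

    Under mirrored acquisition the contralateral image is a left-right flip
    of the index anatomy, so the crop is flipped back before comparison.
    """
    patch = crop_patch(contra_img, center, size)
    return patch[:, ::-1].copy() if mode == "flip" else patch


def reference_candidates(
    box: Box,
    pair: BilateralPair,
    side: str,
    cfg: SymmetryConfig = SymmetryConfig(),
    seed: int = 0,
) -> list[PatchPair]:
    """The four unlabeled candidate patch pairs for one index-side box.

    Pair 1 is centered at the exact mirrored box center; pairs 2-4 at the
    mirror center offset by three seed-drawn distinct non-zero jitters.
    """
    h, w = pair.shape
    index_img = pair.image(side)
    contra_img = pair.image(_contra(side))
    mb = mirror_box(box, w, cfg.mirror_mode)
    index_patch = crop_patch(index_img, (box.cx, box.cy), cfg.patch_size)
    rng = np.random.default_rng(seed)
    out = []
    for dx, dy in _jitter_offsets(cfg, rng):
        center = (mb.cx + dx, mb.cy + dy)
        out.append(
            PatchPair(
                index_patch=index_patch,
                reference_patch=_oriented_crop(contra_img, center, cfg.patch_size,
                                               cfg.mirror_mode),
                source_box=box,
                reference_center=center,
            )
        )
    return out


def refine_reference(
    feature_patch: np.ndarray,
    contralateral_image: np.ndarray,
    mirror_center: tuple[float, float],
    cfg: SymmetryConfig = SymmetryConfig(),
    hog_cfg: HogConfig = HogConfig(),
    seed: int = 0,
) -> tuple[float, float]:
    """Best reference center among mirror + 3 jitters by HOG descriptor distance.

    Ties break toward the earlier candidate (exact mirror first).
    """
    d_feat = hog_descriptor(feature_patch, hog_cfg)
    rng = np.random.default_rng(seed)
    best_center, best_d = None, np.inf
    for dx, dy in _jitter_offsets(cfg, rng):
        center = (mirror_center[0] + dx, mirror_center[1] + dy)
        cand = _oriented_crop(contralateral_image, center, cfg.patch_size, cfg.mirror_mode)
        d = hog_distance(d_feat, hog_descriptor(cand, hog_cfg))
        if d < best_d:
            best_center, best_d = center, d
    return best_center


def hog_best_index(pairs: Sequence[PatchPair], hog_cfg: HogConfig = HogConfig()) -> int:
    """Index of the candidate whose reference is HOG-closest to the index patch."""
    d_feat = hog_descriptor(pairs[0].index_patch, hog_cfg)
    dists = [hog_distance(d_feat, hog_descriptor(p.reference_patch, hog_cfg)) for p in pairs]
    return int(np.argmin(dists))


def _window_centers(dim: int, patch: int, stride: int) -> list[int]:
    return [patch // 2 + k * stride for k in range((dim - patch) // stride + 1)]


def _overlaps_any(b: Box, boxes: Sequence[Box]) -> bool:
    return any(
        not (b.x + b.w <= g.x or g.x + g.w <= b.x or b.y + b.h <= g.y or g.y + g.h <= b.y)
        for g in boxes
    )


def mine_training_pairs(
    pair: BilateralPair,
    cfg: SymmetryConfig = SymmetryConfig(),
    hog_cfg: HogConfig = HogConfig(),
    seed: int = 0,
) -> list[PatchPair]:
    """Slide a coarse window over each hemifield and emit labeled patch pairs.

    Window whose center lies in an index-side GT box and whose refined
    reference region holds no contralateral GT -> +1 (dissimilar); window
    with no GT overlap on either side -> -1 (similar); windows overlapping
    GT on both sides, or overlapping GT without containing a center, are
    discarded as ambiguous.
    """
    h, w = pair.shape
    ps = cfg.patch_size
    rng = np.random.default_rng(seed)
    out: list[PatchPair] = []
    for side in ("left", "right"):
        index_img = pair.image(side)
        contra_img = pair.image(_contra(side))
        gts_index = pair.boxes(side)
        gts_contra = pair.boxes(_contra(side))
        for cy in _window_centers(h, ps, cfg.mine_stride):
            for cx in _window_centers(w, ps, cfg.mine_stride):
                win = Box(x=cx - ps / 2, y=cy - ps / 2, w=ps, h=ps)
                mb = mirror_box(win, w, cfg.mirror_mode)
                feat = crop_patch(index_img, (cx, cy), ps)
                sub_seed = int(rng.integers(0, 2**31 - 1))
                ref_center = refine_reference(
                    feat, contra_img, (mb.cx, mb.cy), cfg, hog_cfg, seed=sub_seed
                )
                ref_win = Box(x=ref_center[0] - ps / 2, y=ref_center[1] - ps / 2, w=ps, h=ps)
                idx_overlap = _overlaps_any(win, gts_index)
                ref_overlap = _overlaps_any(ref_win, gts_contra)
                center_in_gt = any(g.contains(cx, cy) for g in gts_index)
                if center_in_gt and not ref_overlap:
                    label = 1
                elif not idx_overlap and not ref_overlap:
                    label = -1
                else:
                    continue
                out.append(
                    PatchPair(
                        index_patch=feat,
                        reference_patch=_oriented_crop(contra_img, ref_center, ps,
                                                       cfg.mirror_mode),
                        label=label,
                        source_box=win,
                        reference_center=ref_center,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# serialization: paired PNGs + CSV index

def save_patch_pairs(pairs: Sequence[PatchPair], out_dir: str | Path,
                     pair_ids: Sequence[str] | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "index.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["idx", "pair_id", "center_x", "center_y", "label"])
        for i, p in enumerate(pairs):
            for tag, img in (("a", p.index_patch), ("b", p.reference_patch)):
                u8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
                Image.fromarray(u8).save(out / f"{i:05d}_{tag}.png")
            cx, cy = p.reference_center if p.reference_center else (np.nan, np.nan)
            pid = pair_ids[i] if pair_ids else ""
            wr.writerow([i, pid, cx, cy, p.label if p.label is not None else ""])
    return out


def load_patch_pairs(in_dir: str | Path) -> list[PatchPair]:
    root = Path(in_dir)
    pairs = []
    with open(root / "index.csv") as fh:
        for row in csv.DictReader(fh):
            i = int(row["idx"])
            a = np.asarray(Image.open(root / f"{i:05d}_a.png"), dtype=float) / 255.0
            b = np.asarray(Image.open(root / f"{i:05d}_b.png"), dtype=float) / 255.0
            label = int(row["label"]) if row["label"] else None
            center = (float(row["center_x"]), float(row["center_y"]))
            pairs.append(PatchPair(index_patch=a, reference_patch=b, label=label,
                                   reference_center=center))
    return pairs
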