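"""Synthetic bilateral B-mode ultrasound phantoms with known lesion ground truth.

Real bilateral muscle ultrasound shows mirrored anatomy on the two sides of
the body: hypoechoic (dark) fascicles, bright striated connective-tissue
bands, and multiplicative speckle.  A muscle-strain lesion appears as a
focal hypoechoic region that interrupts the striation pattern on ONE side
only, while probe-placement differences introduce a small translation
between the two sides.  This module generates image pairs with exactly that
statistical structure, plus optional *bilateral distractors* — symmetric
hypoechoic spots present on both sides and excluded from ground truth —
which give a contralateral-similarity filter genuine negatives to reject.

Images are stored as float arrays in [0, 1]; on disk they are 8-bit
grayscale PNGs with YOLO-style text annotations and a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, 0-based, half-open: [x, x+w) x [y, y+h)."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive size, got w={self.w}, h={self.h}")

    @property
    def cx(self) -> float:
        return self.x + self.w / 2.0

    @property
    def cy(self) -> float:
        return self.y + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    def contains(self, px: float, py: float) -> bool:
        return self.x <= px < self.x + self.w and self.y <= py < self.y + self.h


@dataclass(frozen=True)
class PhantomParams:
    """Knobs of the phantom generator.

    lesion_contrast is the fraction by which lesion-interior echo intensity
    is reduced; side_offset_sd (px) is the std of the inter-side translation
    emulating probe entry-point deviations; striation_period (px) sets the
    spacing of the bright connective-tissue bands; speckle_scale (px) is the
    correlation length of the multiplicative speckle envelope.
    n_distractors adds bilateral symmetric hypoechoic look-alikes that are
    *not* ground truth.
    """

    image_size: tuple[int, int] = (256, 256)
    n_lesions: int = 2
    lesion_axes_range: tuple[float, float] = (10.0, 26.0)
    lesion_contrast: float = 0.5
    side_offset_sd: float = 4.0
    striation_period: float = 24.0
    speckle_scale: float = 3.0
    n_distractors: int = 2
    distractor_contrast: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 256 or w < 256:
            raise ValueError("image_size must be at least 256x256")
        if not 0 <= self.n_lesions <= 5:
            raise ValueError("n_lesions must be in [0, 5]")
        if not 0.0 < self.lesion_contrast < 1.0:
            raise ValueError("lesion_contrast must be in (0, 1)")
        lo, hi = self.lesion_axes_range
        if not 0 < lo <= hi:
            raise ValueError("lesion_axes_range must satisfy 0 < min <= max")


@dataclass
class BilateralPair:
    left_image: np.ndarray
    right_image: np.ndarray
    left_boxes: list[Box]
    right_boxes: list[Box]
    patient_id: str
    pair_id: str

    def __post_init__(self) -> None:
        if self.left_image.shape != self.right_image.shape:
            raise ValueError("left and right images must have identical shapes")
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        h, w = self.left_image.shape
        for boxes in (self.left_boxes, self.right_boxes):
            for b in boxes:
                if b.x < 0 or b.y < 0 or b.x + b.w > w or b.y + b.h > h:
                    raise ValueError(f"box {b} outside image bounds {h}x{w}")

    def image(self, side: str) -> np.ndarray:
        return self.left_image if _check_side(side) == "left" else self.right_image

    def boxes(self, side: str) -> list[Box]:
        return self.left_boxes if _check_side(side) == "left" else self.right_boxes

    @property
    def shape(self) -> tuple[int, int]:
        return self.left_image.shape


class LesionPlacementError(RuntimeError):
    """Raised when a lesion cannot be placed after bounded retries."""


def _check_side(side: str) -> str:
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return side


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


def _speckle_envelope(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Rayleigh-like envelope: magnitude of low-pass-filtered complex Gaussian noise."""
    re = ndimage.gaussian_filter(rng.standard_normal(shape), scale)
    im = ndimage.gaussian_filter(rng.standard_normal(shape), scale)
    env = np.hypot(re, im)
    return env / env.mean()


def _ellipse_mask(shape: tuple[int, int], cx: float, cy: float, a: float, b: float, theta: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    return ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0).astype(float)


def _ellipse_bbox(cx: float, cy: float, a: float, b: float, theta: float) -> Box:
    # tight axis-aligned extent of a rotated ellipse
    ex = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    ey = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
    x0, y0 = np.floor(cx - ex), np.floor(cy - ey)
    x1, y1 = np.ceil(cx + ex), np.ceil(cy + ey)
    return Box(x=x0, y=y0, w=x1 - x0, h=y1 - y0)


_MAX_PLACEMENT_TRIES = 60


def generate_pair(
    params: PhantomParams,
    patient_id: str = "p000",
    pair_id: str = "s000",
    return_anatomy: bool = False,
):
    """Generate one bilateral pair; identical params (incl. seed) give identical output.

    The right side's base anatomy is the horizontal mirror of the left's,
    shifted by a translation drawn with ``side_offset_sd``; each side then
    receives independent speckle.  Every lesion lands on exactly one side.
    With ``return_anatomy=True`` also returns the pre-speckle anatomy of
    both sides (used by the symmetry tests).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    shape = (h, w)

    # --- mirrored base anatomy -------------------------------------------
    layers = _smooth_field(rng, shape, sigma=max(h, w) / 8.0)
    base = np.clip(0.42 + 0.10 * layers, 0.15, 0.75)

    phase = rng.uniform(0, 2 * np.pi)
    yy = np.arange(h, dtype=float)[:, None]
    bands = 0.5 + 0.5 * np.sin(2 * np.pi * yy / params.striation_period + phase)
    depth_mod = _smooth_field(rng, shape, sigma=max(h, w) / 6.0)
    striation = 0.16 * bands ** 3 * np.clip(1.0 + 0.35 * depth_mod, 0.3, 1.7)
    striation = np.broadcast_to(striation, shape).copy()

    # bilateral distractors are stamped *before* mirroring, so they appear
    # symmetrically on both sides; they are excluded from ground truth
    for _ in range(params.n_distractors):
        a = rng.uniform(*params.lesion_axes_range)
        b = rng.uniform(*params.lesion_axes_range)
        theta = rng.uniform(0, np.pi)
        if 2.4 * a >= w or 2.4 * b >= h:
            continue  # distractor cannot fit; not ground truth, so just skip
        cx = rng.uniform(1.2 * a, w - 1.2 * a)
        cy = rng.uniform(1.2 * b, h - 1.2 * b)
        m = ndimage.gaussian_filter(_ellipse_mask(shape, cx, cy, a, b, theta), 1.0)
        base *= 1.0 - params.distractor_contrast * m
        striation *= 1.0 - m

    base_l, str_l = base, striation
    dy, dx = rng.normal(0.0, params.side_offset_sd, size=2)
    base_r = _shift(np.fliplr(base_l), dy, dx)
    str_r = _shift(np.fliplr(str_l), dy, dx)

    pre = {"left": (base_l.copy(), str_l.copy()), "right": (base_r, str_r)}
    boxes: dict[str, list[Box]] = {"left": [], "right": []}

    # --- unilateral lesions ----------------------------------------------
    for _ in range(params.n_lesions):
        side = "left" if rng.random() < 0.5 else "right"
        placed = False
        for _try in range(_MAX_PLACEMENT_TRIES):
            a = rng.uniform(*params.lesion_axes_range)
            b = rng.uniform(*params.lesion_axes_range)
            theta = rng.uniform(0, np.pi)
            ex = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2) + 2
            ey = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2) + 2
            if 2 * ex >= w or 2 * ey >= h:
                continue
            cx = rng.uniform(ex, w - ex)
            cy = rng.uniform(ey, h - ey)
            bb = _ellipse_bbox(cx, cy, a, b, theta)
            bb = _clip_box(bb, w, h)
            if any(_boxes_overlap(bb, other) for other in boxes[side]):
                continue
            mask = _ellipse_mask(shape, cx, cy, a, b, theta)
            soft = ndimage.gaussian_filter(mask, 1.0)
            bs, st = pre[side]
            bs *= 1.0 - params.lesion_contrast * soft
            st *= 1.0 - mask  # fiber discontinuity: striation interrupted
            pre[side] = (bs, st)
            boxes[side].append(bb)
            placed = True
            break
        if not placed:
            raise LesionPlacementError(
                f"could not place lesion after {_MAX_PLACEMENT_TRIES} tries"
            )

    anatomy = {s: np.clip(pre[s][0] + pre[s][1], 0.0, 1.0) for s in ("left", "right")}

    images = {}
    for side in ("left", "right"):  # independent speckle per side
        env = _speckle_envelope(rng, shape, params.speckle_scale)
        images[side] = np.clip(anatomy[side] * env, 0.0, 1.0)

    pair = BilateralPair(
        left_image=images["left"],
        right_image=images["right"],
        left_boxes=boxes["left"],
        right_boxes=boxes["right"],
        patient_id=patient_id,
        pair_id=pair_id,
    )
    if return_anatomy:
        return pair, anatomy
    return pair


def _shift(img: np.ndarray, dy: float, dx: float) -> np.ndarray:
    if dy == 0.0 and dx == 0.0:
        return img.copy()
    return ndimage.shift(img, (dy, dx), order=1, mode="reflect")


def _clip_box(b: Box, w: int, h: int) -> Box:
    x0, y0 = max(b.x, 0.0), max(b.y, 0.0)
    x1, y1 = min(b.x + b.w, float(w)), min(b.y + b.h, float(h))
    return Box(x=x0, y=y0, w=x1 - x0, h=y1 - y0)


def _boxes_overlap(a: Box, b: Box) -> bool:
    return not (a.x + a.w <= b.x or b.x + b.w <= a.x or a.y + a.h <= b.y or b.y + b.h <= a.y)


def generate_dataset(
    n_patients: int,
    pairs_per_patient: int | Sequence[int],
    params: PhantomParams,
    out_dir: str | Path | None = None,
) -> list[BilateralPair]:
    """Generate a cohort of pairs; patient ids partition the pairs.

    ``pairs_per_patient`` may be a single count or a per-patient sequence
    (e.g. counts summing to 559 for an 86-patient cohort).  When ``out_dir``
    is given, images and annotations are written in the on-disk layout
    (PNG + YOLO txt + manifest.json).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if isinstance(pairs_per_patient, int):
        counts = [pairs_per_patient] * n_patients
    else:
        counts = list(pairs_per_patient)
        if len(counts) != n_patients:
            raise ValueError("pairs_per_patient sequence length must equal n_patients")

    pairs: list[BilateralPair] = []
    k = 0
    for i, c in enumerate(counts):
        for j in range(c):
            p = replace(params, seed=params.seed + 7919 * (k + 1))
            pairs.append(generate_pair(p, patient_id=f"p{i:03d}", pair_id=f"s{j:03d}"))
            k += 1
    if out_dir is not None:
        save_dataset(pairs, out_dir)
    return pairs


def lesion_mask(pair: BilateralPair, side: str) -> np.ndarray:
    """Union of ground-truth box interiors as a boolean mask (for assertions)."""
    h, w = pair.shape
    m = np.zeros((h, w), dtype=bool)
    for b in pair.boxes(side):
        m[int(b.y) : int(b.y + b.h), int(b.x) : int(b.x + b.w)] = True
    return m


# ---------------------------------------------------------------------------
# on-disk layout: {patient}_{pair}_{L|R}.png, YOLO txt, manifest.json

def _to_u8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


def _yolo_lines(boxes: Sequence[Box], w: int, h: int) -> str:
    lines = [
        f"0 {b.cx / w:.6f} {b.cy / h:.6f} {b.w / w:.6f} {b.h / h:.6f}" for b in boxes
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def save_dataset(pairs: Sequence[BilateralPair], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for pair in pairs:
        h, w = pair.shape
        entry = {"pair_id": pair.pair_id, "patient_id": pair.patient_id}
        for side, tag in (("left", "L"), ("right", "R")):
            stem = f"{pair.patient_id}_{pair.pair_id}_{tag}"
            Image.fromarray(_to_u8(pair.image(side))).save(out / f"{stem}.png")
            (out / f"{stem}.txt").write_text(_yolo_lines(pair.boxes(side), w, h))
            entry[side] = {
                "file": f"{stem}.png",
                "boxes": [[b.x, b.y, b.w, b.h] for b in pair.boxes(side)],
            }
        manifest.append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_dataset(in_dir: str | Path) -> list[BilateralPair]:
    """Read a dataset written by :func:`save_dataset`."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    pairs = []
    for entry in manifest:
        imgs, boxes = {}, {}
        for side in ("left", "right"):
            arr = np.asarray(Image.open(root / entry[side]["file"]), dtype=float) / 255.0
            imgs[side] = arr
            boxes[side] = [Box(x=x, y=y, w=w, h=h) for x, y, w, h in entry[side]["boxes"]]
        pairs.append(
            BilateralPair(
                left_image=imgs["left"],
                right_image=imgs["right"],
                left_boxes=boxes["left"],
                right_boxes=boxes["right"],
                patient_id=entry["patient_id"],
                pair_id=entry["pair_id"],
            )
        )
    return pairs
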