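"""Histogram-of-Oriented-Gradients descriptor, per-pixel HOG map, and distance.

HOG is the alignment descriptor of the contralateral-reference search: the
candidate ("feature") patch and each mirrored candidate patch are described
by block-normalized gradient-orientation histograms, and the reference with
the smallest descriptor distance wins.  The descriptor here is the standard
dense variant: centered-difference gradients, unsigned orientations folded
to [0°, 180°), per-cell orientation histograms, and overlapping 2x2-cell
blocks with L2-Hys normalization (L2-normalize, clip, re-normalize).

The implementation is vectorized numpy and numerically matches the
scikit-image reference on shared settings; scikit-image is kept out of the
runtime path so it can serve as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-5


@dataclass(frozen=True)
class HogConfig:
    cell: tuple[int, int] = (8, 8)
    block: tuple[int, int] = (2, 2)
    bins: int = 9
    signed: bool = False
    block_norm: str = "L2-Hys"
    hys_clip: float = 0.2

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if min(self.cell) <= 0 or min(self.block) <= 0:
            raise ValueError("cell and block must be positive")
        if self.block_norm != "L2-Hys":
            raise ValueError("only L2-Hys block normalization is supported")


def _reflect_pad_to_cells(img: np.ndarray, cell: tuple[int, int]) -> np.ndarray:
    h, w = img.shape
    ph = (-h) % cell[0]
    pw = (-w) % cell[1]
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img


def _cell_histograms(image: np.ndarray, cfg: HogConfig) -> np.ndarray:
    """Per-cell orientation histograms, shape (n_cells_y, n_cells_x, bins).

    Gradients are centered differences with zeroed borders; each pixel's
    magnitude votes into the single bin containing its orientation, and the
    histogram is normalized by the cell area.
    """
    img = np.ascontiguousarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale patch")
    img = _reflect_pad_to_cells(img, cfg.cell)

    g_r = np.zeros_like(img)
    g_c = np.zeros_like(img)
    g_r[1:-1, :] = img[2:, :] - img[:-2, :]
    g_c[:, 1:-1] = img[:, 2:] - img[:, :-2]
    mag = np.hypot(g_r, g_c)
    span = 360.0 if cfg.signed else 180.0
    ang = np.rad2deg(np.arctan2(g_r, g_c)) % span

    ch, cw = cfg.cell
    ncy, ncx = img.shape[0] // ch, img.shape[1] // cw
    idx = np.minimum((ang / (span / cfg.bins)).astype(np.intp), cfg.bins - 1)
    hist = np.zeros((ncy, ncx, cfg.bins))
    for b in range(cfg.bins):
        m = np.where(idx == b, mag, 0.0)
        hist[:, :, b] = m.reshape(ncy, ch, ncx, cw).sum(axis=(1, 3))
    return hist / (ch * cw)


def _normalized_blocks(image: np.ndarray, cfg: HogConfig) -> np.ndarray:
    """L2-Hys-normalized blocks, shape (n_by, n_bx, bh, bw, bins), 1-cell stride."""
    hist = _cell_histograms(image, cfg)
    ncy, ncx, _ = hist.shape
    bh, bw = cfg.block
    if ncy < bh or ncx < bw:
        raise ValueError(
            f"image of {image.shape} is smaller than one {bh}x{bw}-cell block"
        )
    n_by, n_bx = ncy - bh + 1, ncx - bw + 1
    # gather overlapping blocks via stride tricks, then normalize per block
    s = hist.strides
    blocks = np.lib.stride_tricks.as_strided(
        hist, shape=(n_by, n_bx, bh, bw, cfg.bins), strides=(s[0], s[1], s[0], s[1], s[2])
    ).copy()
    flat = blocks.reshape(n_by * n_bx, -1)
    flat /= np.sqrt(np.sum(flat**2, axis=1, keepdims=True) + _EPS**2)
    np.minimum(flat, cfg.hys_clip, out=flat)
    flat /= np.sqrt(np.sum(flat**2, axis=1, keepdims=True) + _EPS**2)
    return flat.reshape(blocks.shape)


def hog_descriptor(image: np.ndarray, cfg: HogConfig = HogConfig()) -> np.ndarray:
    """Flat HOG descriptor of ``image``; blocks in row-major order.

    For a 128x128 patch at the defaults (8x8 cells, 2x2 blocks, 9 bins)
    the length is 15*15*2*2*9 = 8100.
    """
    return _normalized_blocks(image, cfg).ravel()


def hog_map(image: np.ndarray, cfg: HogConfig = HogConfig()) -> np.ndarray:
    """Per-pixel gradient-energy map in [0, 1], same height/width as input.

    Each cell's energy is the L2 norm of its normalized histogram, averaged
    over every block containing the cell, then upsampled to pixel
    resolution by nearest neighbor and rescaled to [0, 1].
    """
    img = np.asarray(image, dtype=np.float64)
    blocks = _normalized_blocks(img, cfg)
    n_by, n_bx, bh, bw, _ = blocks.shape
    ncy, ncx = n_by + bh - 1, n_bx + bw - 1

    energy = np.zeros((ncy, ncx))
    count = np.zeros((ncy, ncx))
    norms = np.sqrt(np.sum(blocks**2, axis=-1))  # (n_by, n_bx, bh, bw)
    for i in range(bh):
        for j in range(bw):
            energy[i : i + n_by, j : j + n_bx] += norms[:, :, i, j]
            count[i : i + n_by, j : j + n_bx] += 1.0
    energy /= count

    up = np.kron(energy, np.ones(cfg.cell))[: img.shape[0], : img.shape[1]]
    peak = up.max()
    return up / peak if peak > 0 else up


def hog_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two descriptors of equal length."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"descriptor length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))
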