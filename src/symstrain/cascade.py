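"""Hierarchical decision policy: route by confidence, verify against the other side.

Detections below T1 are suppressed; detections at or above T2 are accepted
outright; the mid-confidence band [T1, T2) is forwarded to the similarity
filter, which compares each candidate with its four contralateral
reference patches and keeps only candidates that look *dissimilar* from
the opposite side.  How the four reference scores combine is the
``aggregation`` policy: ``all_dissimilar`` (default — a genuine lesion
should match none of the references), ``best_reference`` (only the
HOG-closest reference votes), or ``majority`` (>= 3 of 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .detector import Detection, DetectorModel, detect
from .filternet import SCNNModel, classify, score_pair
from .hog import HogConfig
from .phantom import BilateralPair
from .symmetry import SymmetryConfig, hog_best_index, reference_candidates

_AGGREGATIONS = ("all_dissimilar", "best_reference", "majority")


@dataclass(frozen=True)
class CascadeConfig:
    T1: float = 0.01
    T2: float = 0.20
    aggregation: str = "all_dissimilar"
    decision_threshold: float = 0.0
    mirror_mode: str = "flip"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.T1 < self.T2 <= 1.0):
            raise ValueError("thresholds must satisfy 0 <= T1 < T2 <= 1")
        if self.aggregation not in _AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {_AGGREGATIONS}")


@dataclass
class RoutedDetections:
    suppressed: list[Detection] = field(default_factory=list)
    forwarded: list[Detection] = field(default_factory=list)
    accepted: list[Detection] = field(default_factory=list)


def route(detections: Sequence[Detection], cfg: CascadeConfig) -> RoutedDetections:
    """Partition detections: < T1 suppressed, [T1, T2) forwarded, >= T2 accepted."""
    r = RoutedDetections()
    for d in detections:
        if d.confidence < cfg.T1:
            r.suppressed.append(d)
        elif d.confidence < cfg.T2:
            r.forwarded.append(d)
        else:
            r.accepted.append(d)
    return r


def verify(
    forwarded: Sequence[Detection],
    pair: BilateralPair,
    side: str,
    scnn_model: SCNNModel,
    sym_cfg: SymmetryConfig = SymmetryConfig(),
    cfg: CascadeConfig = CascadeConfig(),
    hog_cfg: HogConfig = HogConfig(),
) -> list[Detection]:
    """Keep forwarded detections whose contralateral references score dissimilar."""
    sym_cfg = SymmetryConfig(
        patch_size=sym_cfg.patch_size, jitter=sym_cfg.jitter,
        mine_stride=sym_cfg.mine_stride, mirror_mode=cfg.mirror_mode,
        expand_margin=sym_cfg.expand_margin,
    )
    kept = []
    for i, det in enumerate(forwarded):
        pairs4 = reference_candidates(det.box, pair, side, sym_cfg, seed=cfg.seed + i)
        votes = [
            classify(score_pair(scnn_model, p, hog_cfg), cfg.decision_threshold) == "dissimilar"
            for p in pairs4
        ]
        if cfg.aggregation == "all_dissimilar":
            keep = all(votes)
        elif cfg.aggregation == "best_reference":
            keep = votes[hog_best_index(pairs4, hog_cfg)]
        else:  # majority
            keep = sum(votes) >= 3
        if keep:
            kept.append(det)
    return kept


def run_pipeline(
    pair: BilateralPair,
    detector_model: DetectorModel,
    scnn_model: SCNNModel,
    cfg: CascadeConfig = CascadeConfig(),
    sym_cfg: SymmetryConfig = SymmetryConfig(),
    hog_cfg: HogConfig = HogConfig(),
) -> dict[str, list[tuple[Detection, str]]]:
    """Full two-stage pipeline on one bilateral pair.

    Each side is detected independently; verification consults the opposite
    side.  Returns per-side (detection, stage) lists, stage in
    {"accepted", "verified"}; suppressed detections never appear.
    """
    out: dict[str, list[tuple[Detection, str]]] = {}
    for side in ("left", "right"):
        dets = detect(detector_model, pair.image(side), conf_floor=min(cfg.T1, detector_model.cfg.conf_floor))
        routed = route(dets, cfg)
        final = [(d, "accepted") for d in routed.accepted]
        final += [
            (d, "verified")
            for d in verify(routed.forwarded, pair, side, scnn_model, sym_cfg, cfg, hog_cfg)
        ]
        final.sort(key=lambda ds: -ds[0].confidence)
        out[side] = final
    return out
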