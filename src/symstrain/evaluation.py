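"""Paired detection evaluation protocol.

Covers IoU matching of detections to ground truth, precision/recall and
F-beta scores, all-point-interpolated average precision, patient-level
k-fold cross-validation splits with an a-priori hold-out, patient-level
stratified bootstrap confidence intervals, inter-reader agreement
(Cohen's and Fleiss' kappa), and operating-point sweeps over the cascade's
low-confidence threshold T1.

Matching rule: predictions are taken in descending confidence order and
each claims the still-unclaimed ground-truth box of highest IoU >= the
threshold (one-to-one).  The IoU threshold defaults to 0.5 and is
configurable throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phantom import Box


# ---------------------------------------------------------------------------
# geometry and matching

def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    ix = max(0.0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
    iy = max(0.0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _box_of(p) -> Box:
    return p.box if hasattr(p, "box") else p


def _conf_of(p) -> float:
    return p.confidence if hasattr(p, "confidence") else 1.0


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def match_detections(preds: Sequence, gts: Sequence[Box], iou_threshold: float = 0.5) -> MatchResult:
    """One-to-one greedy matching of confidence-sorted predictions to GT boxes."""
    claimed = [False] * len(gts)
    matched: list[tuple[int, int, float]] = []
    order = sorted(range(len(preds)), key=lambda i: -_conf_of(preds[i]))
    for i in order:
        pb = _box_of(preds[i])
        best_j, best_iou = -1, iou_threshold
        for j, g in enumerate(gts):
            if claimed[j]:
                continue
            v = iou(pb, g)
            if v >= best_iou and v > 0:
                if v > best_iou or best_j < 0:
                    best_j, best_iou = j, v
        if best_j >= 0:
            claimed[best_j] = True
            matched.append((i, best_j, best_iou))
    tp = len(matched)
    return MatchResult(tp=tp, fp=len(preds) - tp, fn=len(gts) - tp, matched_pairs=matched)


# ---------------------------------------------------------------------------
# scalar metrics

def precision_recall(m: MatchResult) -> tuple[float, float]:
    """(precision, recall); 0/0 precision is defined as 0 with a warning."""
    if m.tp + m.fp == 0:
        warnings.warn("no predictions: precision defined as 0", stacklevel=2)
        p = 0.0
    else:
        p = m.tp / (m.tp + m.fp)
    r = m.tp / (m.tp + m.fn) if m.tp + m.fn > 0 else 0.0
    return p, r


def fbeta(p: float, r: float, beta: float = 1.0) -> float:
    """Weighted harmonic mean (1+b^2) p r / (b^2 p + r); F2 weights recall 4x."""
    if p == 0.0 and r == 0.0:
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * p * r / (b2 * p + r)


def average_precision(
    preds_by_image: Mapping[str, Sequence],
    gts_by_image: Mapping[str, Sequence[Box]],
    iou_threshold: float = 0.5,
) -> float:
    """All-point-interpolated AP over ranked detections pooled across images.

    Single foreground class, so mAP = AP.
    """
    n_gt = sum(len(g) for g in gts_by_image.values())
    ranked = sorted(
        ((k, p) for k, ps in preds_by_image.items() for p in ps),
        key=lambda kp: -_conf_of(kp[1]),
    )
    if n_gt == 0:
        return 0.0
    claimed = {k: [False] * len(g) for k, g in gts_by_image.items()}
    tps = np.zeros(len(ranked))
    for i, (k, p) in enumerate(ranked):
        gts = gts_by_image.get(k, [])
        best_j, best_v = -1, iou_threshold
        for j, g in enumerate(gts):
            if claimed[k][j]:
                continue
            v = iou(_box_of(p), g)
            if v >= best_v and (v > best_v or best_j < 0):
                best_j, best_v = j, v
        if best_j >= 0:
            claimed[k][best_j] = True
            tps[i] = 1.0
    if len(ranked) == 0:
        return 0.0
    cum_tp = np.cumsum(tps)
    recall = cum_tp / n_gt
    precision = cum_tp / np.arange(1, len(ranked) + 1)
    # interpolate: precision envelope from the right, integrate over recall steps
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    f2: float
    map50: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_match(cls, m: MatchResult, map50: float | None = None) -> "MetricsReport":
        p, r = precision_recall(m)
        return cls(p, r, fbeta(p, r, 1.0), fbeta(p, r, 2.0), map50)

    def to_dict(self) -> dict:
        d = {"precision": self.precision, "recall": self.recall, "f1": self.f1, "f2": self.f2}
        if self.map50 is not None:
            d["map50"] = self.map50
        if self.ci:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def cv_summary(fold_maps: Sequence[float]) -> tuple[float, float]:
    """Cross-validation summary: (mean, SD across folds) of per-fold mAP."""
    a = np.asarray(fold_maps, dtype=float)
    return float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0


# ---------------------------------------------------------------------------
# patient-level splits

@dataclass
class FoldSplit:
    k: int
    assignments: dict[str, int]  # patient_id -> fold index (dev patients only)
    holdout: set[str]            # hold-out patients, in no fold

    def fold_members(self, f: int) -> list[str]:
        return sorted(p for p, g in self.assignments.items() if g == f)

    def train_patients(self, f: int) -> list[str]:
        return sorted(p for p, g in self.assignments.items() if g != f)


def kfold_split(
    patients: Mapping[str, int] | Sequence[str],
    k: int = 5,
    holdout_pairs: int = 0,
    seed: int = 0,
) -> FoldSplit:
    """Patient-level k-fold split with an a-priori hold-out.

    ``patients`` maps patient_id -> number of bilateral pairs (or is a plain
    id sequence, counting 1 pair each).  Hold-out patients are removed first
    (greedily until their pair count reaches ``holdout_pairs``), then the
    remaining development patients are shuffled into k folds.  All pairs of
    a patient stay together; with k=5 each validation fold is ~20% of the
    development patients.
    """
    if not isinstance(patients, Mapping):
        patients = {p: 1 for p in patients}
    rng = np.random.default_rng(seed)
    ids = sorted(patients)
    rng.shuffle(ids)

    holdout: set[str] = set()
    count = 0
    it = iter(ids)
    while count < holdout_pairs:
        try:
            pid = next(it)
        except StopIteration:
            raise ValueError("not enough pairs to satisfy holdout_pairs")
        holdout.add(pid)
        count += patients[pid]
    dev = [p for p in ids if p not in holdout]
    if k > len(dev):
        raise ValueError(f"k={k} exceeds number of development patients ({len(dev)})")
    assignments = {pid: i % k for i, pid in enumerate(dev)}
    return FoldSplit(k=k, assignments=assignments, holdout=holdout)


# ---------------------------------------------------------------------------
# stratified bootstrap

def bootstrap_ci(
    per_patient_records: Mapping[str, tuple[int, int, int]],
    metric_fn: Callable[[int, int, int], float],
    B: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Patient-level stratified bootstrap percentile interval.

    Records are (tp, fp, fn) per patient; strata are lesion-positive
    (tp + fn > 0) vs lesion-negative patients, resampled with replacement
    within each stratum.  The metric is recomputed from the pooled counts of
    every resample; resamples where it is undefined (NaN) are redrawn.
    """
    if len(per_patient_records) < 2:
        raise ValueError("bootstrap needs at least 2 patients")
    recs = {k: np.asarray(v, dtype=np.int64) for k, v in per_patient_records.items()}
    pos = [k for k, v in recs.items() if v[0] + v[2] > 0]
    neg = [k for k in recs if k not in pos]
    strata = [np.stack([recs[k] for k in s]) for s in (pos, neg) if s]

    rng = np.random.default_rng(seed)
    values = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            pooled = np.zeros(3, dtype=np.int64)
            for s in strata:
                idx = rng.integers(0, len(s), size=len(s))
                pooled += s[idx].sum(axis=0)
            v = metric_fn(int(pooled[0]), int(pooled[1]), int(pooled[2]))
            if np.isfinite(v):
                values[b] = v
                break
            redraws += 1
            if redraws > 100 * B:
                raise RuntimeError("metric undefined in essentially all resamples")
    if redraws:
        warnings.warn(f"redrew {redraws} bootstrap resamples with undefined metric", stacklevel=2)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# inter-reader agreement

def cohen_kappa(r1: Sequence[int], r2: Sequence[int]) -> float:
    """Cohen's kappa (p_o - p_e) / (1 - p_e) with marginal-product chance term."""
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("ratings must be equal-length 1-D vectors")
    cats = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    p_e = sum(float(np.mean(a == c)) * float(np.mean(b == c)) for c in cats)
    if p_e >= 1.0 - 1e-12:
        if p_o >= 1.0 - 1e-12:
            return 1.0
        raise ValueError("chance agreement is 1 with imperfect observed agreement")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class ReaderPanel:
    """Complete reader x case binary rating matrix."""

    ratings: np.ndarray

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings)
        if self.ratings.ndim != 2:
            raise ValueError("ratings must be a reader x case matrix")
        if np.any(~np.isfinite(self.ratings.astype(float))):
            raise ValueError("ratings matrix must be complete")

    @property
    def n_readers(self) -> int:
        return self.ratings.shape[0]


def fleiss_kappa(ratings: np.ndarray | ReaderPanel) -> float:
    """Fleiss' kappa for a complete reader x case matrix (any category codes)."""
    mat = ratings.ratings if isinstance(ratings, ReaderPanel) else np.asarray(ratings)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need a complete matrix with >= 2 readers")
    n_readers, n_cases = mat.shape
    cats = np.unique(mat)
    # counts[i, j] = number of readers assigning category j to case i
    counts = np.stack([(mat == c).sum(axis=0) for c in cats], axis=1)
    p_j = counts.sum(axis=0) / (n_readers * n_cases)
    p_e = float(np.sum(p_j**2))
    p_i = (np.sum(counts**2, axis=1) - n_readers) / (n_readers * (n_readers - 1))
    p_bar = float(p_i.mean())
    if p_e >= 1.0 - 1e-12:
        raise ValueError("all raters constant on all items: kappa undefined")
    return (p_bar - p_e) / (1.0 - p_e)


def panel_macro_average(per_reader_metrics: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Macro-average metric dicts across readers (reader-study convention)."""
    keys = per_reader_metrics[0].keys()
    return {k: float(np.mean([m[k] for m in per_reader_metrics])) for k in keys}


# ---------------------------------------------------------------------------
# operating-point sweep

def threshold_sweep(
    detections_by_pair: Mapping[str, Sequence],
    gts_by_pair: Mapping[str, Sequence[Box]],
    T1_grid: Iterable[float],
    T2_fixed: float = 0.20,
    filter_fn: Callable[[str, list], list] | None = None,
    iou_threshold: float = 0.5,
) -> pd.DataFrame:
    """Re-threshold stored raw detections over a grid of T1 values.

    Each row reports pooled precision/recall/F1/F2 at one T1 (with T2 fixed)
    for the plain detector, and additionally for the verified cascade when
    ``filter_fn(key, forwarded) -> kept`` is given.  No model is re-run: the
    sweep only re-partitions stored confidences.
    """
    rows = []
    for t1 in T1_grid:
        variants = {"detector": None}
        if filter_fn is not None:
            variants["cascade"] = filter_fn
        for name, fn in variants.items():
            total = MatchResult(0, 0, 0)
            for key, dets in detections_by_pair.items():
                kept = [d for d in dets if _conf_of(d) >= t1]
                if fn is not None:
                    accepted = [d for d in kept if _conf_of(d) >= T2_fixed]
                    forwarded = [d for d in kept if _conf_of(d) < T2_fixed]
                    kept = accepted + fn(key, forwarded)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    total = total + match_detections(kept, gts_by_pair.get(key, []), iou_threshold)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p, r = precision_recall(total)
            rows.append(
                {"T1": t1, "method": name, "precision": p, "recall": r,
                 "f1": fbeta(p, r, 1.0), "f2": fbeta(p, r, 2.0)}
            )
    return pd.DataFrame(rows)
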