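"""Evaluation protocol: matching, F-scores, AP, splits, bootstrap, agreement."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa as sm_fleiss

import symstrain as ss
from symstrain.evaluation import (
    MatchResult,
    ReaderPanel,
    average_precision,
    bootstrap_ci,
    cohen_kappa,
    cv_summary,
    fbeta,
    fleiss_kappa,
    iou,
    kfold_split,
    match_detections,
    panel_macro_average,
    precision_recall,
    threshold_sweep,
)
from symstrain.detector import Detection
from symstrain.phantom import Box


def B(x, y, w, h):
    return Box(x=x, y=y, w=w, h=h)


# ---------------------------------------------------------------- iou / matching

def test_iou_basic_cases():
    assert iou(B(0, 0, 2, 2), B(0, 0, 2, 2)) == 1.0
    assert iou(B(0, 0, 2, 2), B(5, 5, 2, 2)) == 0.0
    assert iou(B(0, 0, 2, 2), B(1, 0, 2, 2)) == pytest.approx(2 / 6)


def test_match_perfect_and_empty():
    gts = [B(0, 0, 10, 10), B(50, 50, 10, 10)]
    m = match_detections([Detection(box=g, confidence=0.9) for g in gts], gts)
    assert (m.tp, m.fp, m.fn) == (2, 0, 0)
    m = match_detections([], gts)
    assert (m.tp, m.fp, m.fn) == (0, 0, 2)


def test_match_one_to_one():
    gt = [B(0, 0, 10, 10)]
    preds = [Detection(box=B(0, 0, 10, 10), confidence=0.9),
             Detection(box=B(1, 0, 10, 10), confidence=0.8)]
    m = match_detections(preds, gt)
    assert (m.tp, m.fp) == (1, 1)
    assert m.matched_pairs[0][0] == 0  # the higher-confidence prediction claims it


def test_precision_recall_arithmetic():
    assert precision_recall(MatchResult(2, 5, 0)) == (pytest.approx(2 / 7), 1.0)
    p, r = precision_recall(MatchResult(19, 2, 4))
    assert p == pytest.approx(0.905, abs=5e-4)
    assert r == pytest.approx(0.826, abs=5e-4)


def test_precision_zero_over_zero_warns():
    with pytest.warns(UserWarning):
        p, r = precision_recall(MatchResult(0, 0, 3))
    assert (p, r) == (0.0, 0.0)


# ---------------------------------------------------------------- fbeta

def test_fbeta_symmetric_point():
    for b in (0.5, 1.0, 2.0):
        assert fbeta(0.37, 0.37, b) == pytest.approx(0.37)


def test_fbeta_zero_case():
    assert fbeta(0.0, 0.0, 2.0) == 0.0


@given(st.floats(0.01, 1.0), st.floats(0.01, 1.0), st.floats(0.1, 5.0))
@settings(max_examples=1000, derandomize=True)
def test_fbeta_matches_weighted_harmonic_mean(p, r, beta):
    # independent form: 1 / weighted mean of reciprocals
    w = 1.0 / (1.0 + beta**2)
    expected = 1.0 / (w / p + (1 - w) / r)
    assert fbeta(p, r, beta) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------- average precision

def _brute_force_ap(scored, n_gt):
    """Independent AP: recompute P/R at every rank prefix, integrate the
    right-max precision envelope over recall increments."""
    pts = []
    tp = 0
    for k, is_tp in enumerate(scored, start=1):
        tp += is_tp
        pts.append((tp / n_gt, tp / k))
    ap = 0.0
    prev_r = 0.0
    for i, (r, _) in enumerate(pts):
        p_max = max(p for (rr, p) in pts if rr >= r)
        ap += (r - prev_r) * p_max
        prev_r = r
    return ap


def test_ap_perfect_and_all_wrong():
    gt = {"a": [B(0, 0, 10, 10)]}
    hit = {"a": [Detection(box=B(0, 0, 10, 10), confidence=0.9)]}
    miss = {"a": [Detection(box=B(50, 50, 10, 10), confidence=0.9)]}
    assert average_precision(hit, gt) == 1.0
    assert average_precision(miss, gt) == 0.0


def test_ap_wrong_then_right_is_half():
    gt = {"a": [B(0, 0, 10, 10)]}
    preds = {"a": [Detection(box=B(80, 80, 10, 10), confidence=0.9),
                   Detection(box=B(0, 0, 10, 10), confidence=0.5)]}
    assert average_precision(preds, gt) == pytest.approx(0.5)


def test_ap_equals_brute_force_on_all_outcome_patterns():
    """Oracle equivalence for every TP/FP pattern of up to 6 ranked predictions."""
    import itertools

    for n in range(1, 7):
        for pattern in itertools.product([0, 1], repeat=n):
            n_tp = sum(pattern)
            n_gt = max(n_tp, 1) + 1  # leave at least one unmatched GT
            gts = [B(100 * i, 0, 10, 10) for i in range(n_gt)]
            preds = []
            gt_iter = iter(range(n_gt))
            for rank, is_tp in enumerate(pattern):
                conf = 1.0 - rank * 0.01
                if is_tp:
                    preds.append(Detection(box=gts[next(gt_iter)], confidence=conf))
                else:
                    preds.append(Detection(box=B(0, 500, 5, 5), confidence=conf))
            got = average_precision({"img": preds}, {"img": gts})
            want = _brute_force_ap(list(pattern), n_gt)
            assert got == pytest.approx(want, abs=1e-12)


def test_cv_summary_mean():
    mean, sd = cv_summary([0.3853, 0.3882, 0.4262, 0.4069, 0.3965])
    assert round(mean, 4) == 0.4006
    assert sd > 0


# ---------------------------------------------------------------- splits

def test_kfold_basic_partition():
    split = kfold_split([f"p{i}" for i in range(10)], k=5, seed=1)
    sizes = [len(split.fold_members(f)) for f in range(5)]
    assert sizes == [2, 2, 2, 2, 2]
    all_members = [p for f in range(5) for p in split.fold_members(f)]
    assert sorted(all_members) == sorted(f"p{i}" for i in range(10))


def test_kfold_holdout_disjoint():
    patients = {f"p{i}": 2 for i in range(20)}
    split = kfold_split(patients, k=5, holdout_pairs=6, seed=3)
    assert sum(patients[p] for p in split.holdout) >= 6
    for f in range(5):
        assert not (set(split.fold_members(f)) & split.holdout)
    assert set(split.assignments) | split.holdout == set(patients)


def test_kfold_errors():
    with pytest.raises(ValueError):
        kfold_split(["a", "b"], k=5)
    with pytest.raises(ValueError):
        kfold_split(["a", "b"], k=1, holdout_pairs=10)


# ---------------------------------------------------------------- bootstrap

def test_bootstrap_degenerate_and_deterministic():
    recs = {f"p{i}": (3, 1, 1) for i in range(6)}
    f = lambda tp, fp, fn: tp / (tp + fp)
    lo, hi = bootstrap_ci(recs, f, B=200, seed=5)
    assert lo == hi == pytest.approx(0.75)
    recs["p0"] = (1, 3, 1)
    a = bootstrap_ci(recs, f, B=200, seed=5)
    b = bootstrap_ci(recs, f, B=200, seed=5)
    assert a == b
    lo, hi = a
    assert lo <= 0.75 <= hi or hi <= 0.75  # interval is ordered
    assert lo < hi


def test_bootstrap_needs_two_patients():
    with pytest.raises(ValueError):
        bootstrap_ci({"p": (1, 1, 1)}, lambda *a: 1.0)


# ---------------------------------------------------------------- agreement

def test_cohen_kappa_edge_cases():
    assert cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0
    assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0


def test_cohen_kappa_hand_table():
    # 20 both-positive, 15 both-negative, 5 + 10 disagreements
    r1 = [1] * 20 + [0] * 15 + [1] * 5 + [0] * 10
    r2 = [1] * 20 + [0] * 15 + [0] * 5 + [1] * 10
    n = 50
    p_o = 35 / n
    p_e = (25 / n) * (30 / n) + (25 / n) * (20 / n)
    expected = (p_o - p_e) / (1 - p_e)
    assert cohen_kappa(r1, r2) == pytest.approx(expected)


def test_cohen_kappa_matches_sklearn():
    rng = np.random.default_rng(7)
    for _ in range(10):
        a = rng.integers(0, 2, 60)
        b = np.where(rng.random(60) < 0.7, a, rng.integers(0, 2, 60))
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


def test_cohen_kappa_near_zero_for_independent_raters():
    rng = np.random.default_rng(0)
    a, b = rng.integers(0, 2, 4000), rng.integers(0, 2, 4000)
    assert abs(cohen_kappa(a, b)) < 0.05


def test_fleiss_unanimous_panel():
    ratings = np.array([[1, 0, 1, 0, 1]] * 4)
    assert fleiss_kappa(ratings) == pytest.approx(1.0)


def test_fleiss_matches_statsmodels():
    rng = np.random.default_rng(11)
    truth = rng.integers(0, 2, 40)
    ratings = np.stack([np.where(rng.random(40) < 0.8, truth, rng.integers(0, 2, 40))
                        for _ in range(5)])
    table, _ = aggregate_raters(ratings.T)
    assert fleiss_kappa(ratings) == pytest.approx(sm_fleiss(table), abs=1e-12)


def test_fleiss_random_near_zero_and_constant_errors():
    rng = np.random.default_rng(3)
    ratings = rng.integers(0, 2, size=(6, 2000))
    assert abs(fleiss_kappa(ratings)) < 0.05
    with pytest.raises(ValueError):
        fleiss_kappa(np.ones((4, 10)))


def test_fleiss_two_readers_same_sign_as_cohen():
    rng = np.random.default_rng(19)
    for _ in range(10):
        truth = rng.integers(0, 2, 50)
        a = np.where(rng.random(50) < 0.8, truth, 1 - truth)
        b = np.where(rng.random(50) < 0.8, truth, 1 - truth)
        ck = cohen_kappa(a, b)
        fk = fleiss_kappa(np.stack([a, b]))
        if abs(ck) > 0.1:
            assert np.sign(ck) == np.sign(fk)


def test_reader_panel_and_macro_average():
    panel = ReaderPanel(np.array([[1, 0], [0, 1]]))
    assert panel.n_readers == 2
    avg = panel_macro_average([{"precision": 0.4, "recall": 0.8},
                               {"precision": 0.6, "recall": 0.6}])
    assert avg == {"precision": 0.5, "recall": pytest.approx(0.7)}


# ---------------------------------------------------------------- sweep

def _fake_dets(confs, boxes):
    return [Detection(box=b, confidence=c) for c, b in zip(confs, boxes)]


def test_sweep_degenerate_t1_equals_t2():
    gts = {"a": [B(0, 0, 10, 10)]}
    dets = {"a": _fake_dets([0.5, 0.1], [B(0, 0, 10, 10), B(50, 50, 10, 10)])}
    removed_all = lambda key, fwd: []
    table = threshold_sweep(dets, gts, [0.2], T2_fixed=0.2, filter_fn=removed_all)
    det_row = table[table.method == "detector"].iloc[0]
    casc_row = table[table.method == "cascade"].iloc[0]
    # at T1 = T2 the forwarded band is empty: even an everything-removing
    # filter changes nothing, and only the accepted (0.5) detection survives
    assert casc_row.precision == det_row.precision == pytest.approx(1.0)
    assert casc_row.recall == det_row.recall == pytest.approx(1.0)


def test_sweep_recall_monotone_in_t1():
    rng = np.random.default_rng(2)
    gts, dets = {}, {}
    for i in range(8):
        key = f"img{i}"
        gts[key] = [B(10, 10, 20, 20)]
        boxes = [B(10, 10, 20, 20), B(100, 100, 20, 20), B(60, 150, 25, 25)]
        dets[key] = _fake_dets(rng.random(3), boxes)
    table = threshold_sweep(dets, gts, [0.0, 0.2, 0.4, 0.6, 0.8])
    rec = table[table.method == "detector"].sort_values("T1").recall.to_numpy()
    assert np.all(np.diff(rec) <= 1e-12)
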