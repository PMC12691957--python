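"""Cascade routing semantics, verification policies, end-to-end pipeline."""

import numpy as np
import pytest

import symstrain as ss
from symstrain.cascade import CascadeConfig, route, run_pipeline, verify
from symstrain.detector import Detection
from symstrain.filternet import FilterConfig
from symstrain.phantom import Box, PhantomParams
from symstrain.symmetry import SymmetryConfig


def D(conf, x=10, y=10, w=30, h=30):
    return Detection(box=Box(x=x, y=y, w=w, h=h), confidence=conf)


def test_route_interval_conventions():
    cfg = CascadeConfig()
    r = route([D(0.005), D(0.15), D(0.20)], cfg)
    assert [d.confidence for d in r.suppressed] == [0.005]
    assert [d.confidence for d in r.forwarded] == [0.15]
    assert [d.confidence for d in r.accepted] == [0.20]  # >= T2 accepted


def test_route_boundary_t1():
    r = route([D(0.01)], CascadeConfig())
    assert r.forwarded and not r.suppressed  # T1 itself is forwarded


def test_route_partition_exact():
    rng = np.random.default_rng(0)
    dets = [D(float(c)) for c in rng.random(200)]
    r = route(dets, CascadeConfig())
    assert len(r.suppressed) + len(r.forwarded) + len(r.accepted) == len(dets)
    assert set(map(id, r.suppressed + r.forwarded + r.accepted)) == set(map(id, dets))


def test_route_monotone_in_t1():
    rng = np.random.default_rng(1)
    dets = [D(float(c)) for c in rng.random(300)]
    kept_counts = []
    for t1 in (0.001, 0.01, 0.05, 0.1, 0.19):
        r = route(dets, CascadeConfig(T1=t1))
        kept_counts.append(len(r.forwarded) + len(r.accepted))
    assert kept_counts == sorted(kept_counts, reverse=True)


def test_invalid_thresholds_rejected():
    with pytest.raises(ValueError):
        CascadeConfig(T1=0.3, T2=0.2)
    with pytest.raises(ValueError):
        CascadeConfig(T1=0.2, T2=0.2)


class _AnalyticScorer:
    """Stand-in similarity scorer (synthetic, for plumbing tests): each
    channel's central-region contrast (center mean minus patch mean) drops
    when a hypoechoic lesion sits under the patch center; the pair is
    dissimilar iff the two channels' contrasts differ by more than tau."""

    def __init__(self, tau=0.06):
        self.cfg = FilterConfig()
        self.tau = tau

    @staticmethod
    def _contrast(ch):
        return ch[:, 40:88, 40:88].mean(axis=(1, 2)) - ch.mean(axis=(1, 2))

    def forward(self, x, train=False):
        gap = np.abs(self._contrast(x[:, 0]) - self._contrast(x[:, 1]))
        return np.where(gap > self.tau, 1.0, -1.0)


def _crafted_pair():
    """One unilateral lesion plus bilateral distractors, no noise surprises."""
    return ss.generate_pair(PhantomParams(
        seed=77, n_lesions=1, lesion_contrast=0.6, lesion_axes_range=(20.0, 30.0),
        n_distractors=2, side_offset_sd=0.0))


def test_verify_empty_forwarded():
    pair = _crafted_pair()
    assert verify([], pair, "left", _AnalyticScorer()) == []


def test_verify_keeps_unilateral_drops_bilateral():
    pair = _crafted_pair()
    side = "left" if pair.left_boxes else "right"
    lesion = pair.boxes(side)[0]
    lesion_det = Detection(box=lesion, confidence=0.1)
    kept = verify([lesion_det], pair, side, _AnalyticScorer())
    assert kept == [lesion_det]
    # a detection sitting on mirrored (symmetric) anatomy scores similar
    sym_box = Box(x=30, y=30, w=30, h=30)
    sym_det = Detection(box=sym_box, confidence=0.1)
    assert verify([sym_det], pair, side, _AnalyticScorer()) == []


def test_verify_aggregation_policies(scnn_model, test_pairs):
    pair = test_pairs[0]
    side = "left"
    dets = [D(0.1, x=40, y=40), D(0.15, x=150, y=100)]
    for agg in ("all_dissimilar", "best_reference", "majority"):
        kept = verify(dets, pair, side, scnn_model, cfg=CascadeConfig(aggregation=agg))
        assert set(map(id, kept)) <= set(map(id, dets))
    strict = verify(dets, pair, side, scnn_model, cfg=CascadeConfig(aggregation="all_dissimilar"))
    loose = verify(dets, pair, side, scnn_model, cfg=CascadeConfig(aggregation="majority"))
    assert len(strict) <= len(loose)  # all-of-4 is at least as strict as 3-of-4


def test_pipeline_never_invents_and_respects_routing(detector_model, scnn_model, test_pairs):
    from symstrain.detector import detect

    pair = test_pairs[1]
    cfg = CascadeConfig()
    final = run_pipeline(pair, detector_model, scnn_model, cfg)
    for side in ("left", "right"):
        raw = detect(detector_model, pair.image(side), conf_floor=cfg.T1)
        raw_keys = {(d.confidence, d.box.x, d.box.y) for d in raw}
        for det, stage in final[side]:
            assert det.confidence >= cfg.T1
            assert (det.confidence, det.box.x, det.box.y) in raw_keys
            assert stage == ("accepted" if det.confidence >= cfg.T2 else "verified")


def test_pipeline_degenerate_thresholds(detector_model, scnn_model, test_pairs):
    pair = test_pairs[2]
    # T2 tiny: everything detected is accepted, filter bypassed
    all_accept = run_pipeline(pair, detector_model, scnn_model,
                              CascadeConfig(T1=1e-6, T2=1e-5))
    assert all(stage == "accepted" for side in all_accept.values() for _, stage in side)
    # T1 at maximum: nothing below T2=1.0 survives, and >=1.0 confidences are rare
    none = run_pipeline(pair, detector_model, scnn_model,
                        CascadeConfig(T1=0.9999, T2=1.0))
    assert all(d.confidence >= 0.9999 for side in none.values() for d, _ in side)


def test_crafted_regression_low_confidence_reduction():
    """Seven detections: 2 accepted at T2, 5 forwarded; an exact-comparison
    filter removes the 3 forwarded that sit on symmetric anatomy (60%)."""
    pair = _crafted_pair()
    side = "left" if pair.left_boxes else "right"
    lesion = pair.boxes(side)[0]
    cfg = CascadeConfig()
    dets = [
        Detection(box=lesion, confidence=0.9),                      # accepted
        Detection(box=Box(x=60, y=170, w=30, h=30), confidence=0.5),  # accepted
        Detection(box=lesion, confidence=0.15),                     # forwarded, kept
        Detection(box=Box(x=int(lesion.x) + 4, y=int(lesion.y) + 2, w=lesion.w,
                          h=lesion.h), confidence=0.12),            # forwarded, kept
        Detection(box=Box(x=30, y=30, w=30, h=30), confidence=0.10),   # symmetric
        Detection(box=Box(x=170, y=60, w=30, h=30), confidence=0.05),  # symmetric
        Detection(box=Box(x=150, y=200, w=30, h=30), confidence=0.02), # symmetric
    ]
    routed = route(dets, cfg)
    assert len(routed.accepted) == 2 and len(routed.forwarded) == 5
    scorer = _AnalyticScorer()
    kept = verify(routed.forwarded, pair, side, scorer, cfg=cfg)
    assert len(kept) == 2  # 3 of 5 low-confidence detections removed (60%)
    final = routed.accepted + kept
    assert len(final) == 4
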