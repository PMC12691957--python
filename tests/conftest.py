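"""Shared fixtures: phantom cohorts and trained models, built once per session.

The training fixtures use the desk-scale profiles (256 px phantoms, compact
backbones) so the full suite runs on one CPU; they are shared by the
detector, filter, cascade and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import symstrain as ss
from symstrain.detector import DetectorConfig, train_detector, detect
from symstrain.filternet import FilterConfig, train_scnn
from symstrain.symmetry import mine_training_pairs


@pytest.fixture(scope="session")
def phantom_params():
    return ss.PhantomParams(seed=11)


@pytest.fixture(scope="session")
def train_pairs(phantom_params):
    """30 bilateral pairs (15 patients) for detector training."""
    return ss.generate_dataset(15, 2, phantom_params)


@pytest.fixture(scope="session")
def test_pairs():
    """Fixed-seed held-out cohort of 30 bilateral pairs (15 unseen patients)."""
    return ss.generate_dataset(15, 2, ss.PhantomParams(seed=999))


@pytest.fixture(scope="session")
def detector_model(train_pairs):
    model, trace = train_detector(train_pairs, DetectorConfig.desk_scale(), epochs=60, seed=0)
    model.loss_trace = trace
    return model


@pytest.fixture(scope="session")
def mined_pairs():
    """Labeled patch pairs mined from a lesion-rich 120-pair phantom cohort.

    The mining cohort uses more and larger lesions than the evaluation
    cohort so the coarse sliding-window mine yields roughly class-balanced
    pairs; the evaluation cohorts keep the default phantom conditions.
    """
    cohort = ss.generate_dataset(
        60, 2, ss.PhantomParams(seed=11, n_lesions=4, lesion_axes_range=(14.0, 34.0))
    )
    mined = []
    for i, p in enumerate(cohort):
        mined.extend(mine_training_pairs(p, seed=100 + i))
    return mined


@pytest.fixture(scope="session")
def scnn_trained(mined_pairs):
    """(model, training log) of the similarity filter on mined phantom pairs."""
    return train_scnn(mined_pairs, FilterConfig.desk_scale(seed=0))


@pytest.fixture(scope="session")
def scnn_model(scnn_trained):
    return scnn_trained[0]


@pytest.fixture(scope="session")
def heldout_detections(detector_model, test_pairs):
    """Raw detections at the suppression floor on the held-out cohort.

    Returns (detections_by_key, gts_by_key, pair_lookup); keys are
    "<patient>:<pair>:<side>".
    """
    dets_by, gts_by, lookup = {}, {}, {}
    for pair in test_pairs:
        for side in ("left", "right"):
            key = f"{pair.patient_id}:{pair.pair_id}:{side}"
            dets_by[key] = detect(detector_model, pair.image(side), conf_floor=0.01)
            gts_by[key] = pair.boxes(side)
            lookup[key] = (pair, side)
    return dets_by, gts_by, lookup
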