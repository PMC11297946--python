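import numpy as np
import pytest

from shuttlekit.synthetic_data import PhotometryModel, SessionConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """One modest synthetic session (8 trials) shared across read-only tests."""
    cfg = SessionConfig(n_trials=8, seed=123)
    session, gt = generate_session(cfg)
    return cfg, session, gt


@pytest.fixture(scope="session")
def full_session():
    """A full-length 30-trial session for recovery checks."""
    cfg = SessionConfig(n_trials=30, seed=7)
    session, gt = generate_session(cfg)
    return cfg, session, gt


def bout_f1(truth, detected, iou_min=0.5):
    """F1 of detected vs ground-truth bouts under an IoU >= iou_min match."""
    def iou(a, b):
        inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
        union = max(a[1], b[1]) - min(a[0], b[0])
        return inter / union if union > 0 else 0.0

    used = set()
    tp = 0
    for g in truth:
        scored = sorted(((iou(g, d), i) for i, d in enumerate(detected)
                         if i not in used), reverse=True)
        if scored and scored[0][0] >= iou_min:
            tp += 1
            used.add(scored[0][1])
    precision = tp / len(detected) if detected else 0.0
    recall = tp / len(truth) if truth else 0.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@pytest.fixture(scope="session")
def quiet_pm():
    """Photometry model with transients and artifact switched off."""
    return PhotometryModel(noise_sd=0.0, motion_artifact_sd=0.0,
                           ws_amp_avoidance=0.0, ws_amp_escape=0.0,
                           preshuttle_dip_amp=0.0, rebound_amp=0.0)


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    import logging
    caplog.set_level(logging.ERROR, logger="shuttlekit")
    yield


def rng_for(seed):
    return np.random.default_rng(seed)
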