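import numpy as np
import pytest

import pulseqc as p


@pytest.fixture(scope="session")
def clean_ppg():
    """60-s clean synthetic PPG at 100 Hz, 75 bpm, with ground truth."""
    spec = p.SynthesisSpec(duration_s=60.0, rate=100.0, heart_rate_bpm=75.0,
                           hrv_sd_ms=20.0, noise_sd=0.05, seed=101)
    return p.synth_record(spec)


@pytest.fixture(scope="session")
def clean_ppg_filtered(clean_ppg):
    record, truth = clean_ppg
    return p.bandpass_filter(record), truth


def match_stats(detected, truth, tol):
    """Recall/precision of detected peak indices vs ground truth."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if truth.size == 0 or detected.size == 0:
        return 0.0, 0.0
    recall = np.mean([np.min(np.abs(detected - t)) <= tol for t in truth])
    precision = np.mean([np.min(np.abs(truth - d)) <= tol for d in detected])
    return float(recall), float(precision)
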