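import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the reference simulator

from riskplot import (ECGTemplateParams, SyntheticProfile, generate_ecg,
                      generate_rri)


@pytest.fixture(scope="session")
def healthy_series():
    """2000-beat healthy stream: mean RR 0.8 s, SDNN 50 ms, RSA 25 ms."""
    return generate_rri(SyntheticProfile(mean_rr=0.8, sdnn=0.05, rsa_amp=0.025,
                                         n_beats=2000, seed=1))


@pytest.fixture(scope="session")
def neardeath_series():
    """2000-beat variability-collapse stream: SDNN 5 ms, suppressed RSA."""
    return generate_rri(SyntheticProfile(mean_rr=0.8, sdnn=0.005, rsa_amp=0.005,
                                         trend=-0.003, n_beats=2000, seed=1))


@pytest.fixture(scope="session")
def clean_ecg_60():
    """60-beat clean synthetic ECG at ~75 bpm with ground-truth R peaks."""
    series = generate_rri(SyntheticProfile(mean_rr=0.8, sdnn=0.04, rsa_amp=0.02,
                                           n_beats=60, seed=2))
    return series, generate_ecg(series)


@pytest.fixture(scope="session")
def noisy_ecg_60(clean_ecg_60):
    series, _ = clean_ecg_60
    noisy = generate_ecg(series, ECGTemplateParams(noise_snr_db=10.0, seed=3))
    return series, noisy


def match_peaks(detected, truth, tolerance):
    """Greedy one-to-one matching of detected to truth peaks within tolerance.

    Returns (n_matched, n_detected, n_truth).
    """
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    used = np.zeros(truth.size, dtype=bool)
    matched = 0
    for d in detected:
        diffs = np.abs(truth - d)
        diffs[used] = tolerance + 1
        j = int(np.argmin(diffs)) if truth.size else -1
        if j >= 0 and diffs[j] <= tolerance:
            used[j] = True
            matched += 1
    return matched, detected.size, truth.size
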