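"""ECG preprocessing: mains-interference notch filtering and Daubechies
wavelet denoising.

Both stages are zero-phase and length-preserving so that R-peak timing — the
quantity everything downstream depends on — is not displaced.  The notch is a
narrow second-order IIR band-stop applied forward–backward; the denoiser is a
multilevel discrete wavelet transform with soft universal-threshold shrinkage
applied to the finest detail levels only, which removes broadband noise while
leaving QRS morphology (5–15 Hz energy) essentially untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .io import ECGRecord

__all__ = ["PreprocessConfig", "notch_filter", "wavelet_denoise", "preprocess"]


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    mains_freq : 50 or 60 Hz power-line frequency.
    notch_q : notch quality factor (centre frequency / −3 dB bandwidth).
    wavelet_name : Daubechies family member (``db4`` default).
    decomposition_level : DWT depth; detail shrinkage is applied to the two
        finest levels regardless of depth.
    threshold_rule : only ``universal-soft`` is implemented.
    """

    mains_freq: float = 50.0
    notch_q: float = 30.0
    wavelet_name: str = "db4"
    decomposition_level: int = 4
    threshold_rule: str = "universal-soft"

    def __post_init__(self) -> None:
        if self.mains_freq not in (50, 60, 50.0, 60.0):
            raise ValueError(f"mains_freq must be 50 or 60 Hz, got {self.mains_freq}")
        if not self.notch_q > 0:
            raise ValueError("notch_q must be > 0")
        if self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        if self.threshold_rule != "universal-soft":
            raise ValueError(f"unsupported threshold_rule {self.threshold_rule!r}")


def notch_filter(record: ECGRecord, config: PreprocessConfig | None = None) -> ECGRecord:
    """Remove power-line interference with a zero-phase IIR notch.

    Requires ``record.fs > 2 * mains_freq``.  The filter is applied
    forward–backward (``filtfilt``), which squares the magnitude response —
    deepening the stop-band — and cancels phase so peak positions are
    preserved.
    """
    config = config or PreprocessConfig()
    if record.fs <= 2 * config.mains_freq:
        raise ValueError(
            f"sampling rate {record.fs} Hz cannot represent {config.mains_freq} Hz mains"
        )
    b, a = sps.iirnotch(config.mains_freq, config.notch_q, fs=record.fs)
    filtered = sps.filtfilt(b, a, record.samples)
    return record.replace_samples(filtered)


def wavelet_denoise(record: ECGRecord, config: PreprocessConfig | None = None) -> ECGRecord:
    """Suppress broadband noise by soft-thresholding fine wavelet details.

    The noise scale sigma is estimated from the median absolute deviation of
    the finest detail coefficients (MAD / 0.6745) and the universal threshold
    sigma * sqrt(2 ln N) is applied, by soft shrinkage, to the two finest
    detail levels.  Coarser levels — which carry the QRS complexes and the
    baseline — pass unchanged.
    """
    config = config or PreprocessConfig()
    x = record.samples
    n = x.size
    if n < 2 ** config.decomposition_level:
        raise ValueError(
            f"signal of {n} samples too short for decomposition level "
            f"{config.decomposition_level}"
        )
    coeffs = pywt.wavedec(x, config.wavelet_name, level=config.decomposition_level,
                          mode="symmetric")
    d1 = coeffs[-1]
    sigma = float(np.median(np.abs(d1))) / 0.6745
    threshold = sigma * math.sqrt(2.0 * math.log(max(n, 2)))
    shrink_levels = min(2, config.decomposition_level)
    for j in range(1, shrink_levels + 1):
        coeffs[-j] = pywt.threshold(coeffs[-j], threshold, mode="soft")
    rec = pywt.waverec(coeffs, config.wavelet_name, mode="symmetric")[:n]
    return record.replace_samples(rec)


def preprocess(record: ECGRecord, config: PreprocessConfig | None = None) -> ECGRecord:
    """Full chain: notch filter, then wavelet denoise."""
    config = config or PreprocessConfig()
    return wavelet_denoise(notch_filter(record, config), config)
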