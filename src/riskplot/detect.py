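"""R-peak detection and RR-interval construction.

The detector is a Pan–Tompkins-style chain: 5–15 Hz zero-phase band-pass,
five-point derivative, squaring, 150 ms moving-window integration, then
adaptive dual-threshold peak classification with a search-back pass for
missed beats.  All thresholds are relative to the running signal/noise peak
estimates, so detection is invariant to positive amplitude scaling.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .io import ECGRecord, PeakAnnotation, RRISeries, RRI_MIN_S, RRI_MAX_S

__all__ = ["detect_r_peaks", "compute_rri", "quality_mask"]

REFRACTORY_S = 0.200        # minimum spacing between accepted peaks
_INTEGRATION_S = 0.150      # moving-window integrator width
_BAND_HZ = (5.0, 15.0)      # QRS energy band


def _moving_integrate(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(record: ECGRecord) -> PeakAnnotation:
    """Locate R peaks in a (preferably preprocessed) single-lead ECG.

    Returns strictly increasing sample indices with an enforced 200 ms
    refractory period.  A flat-line record yields zero peaks.  Records
    shorter than 2 s are rejected.
    """
    fs = record.fs
    x = record.samples
    if x.size / fs < 2.0:
        raise ValueError(f"record of {x.size / fs:.2f} s is too short (need >= 2 s)")
    if np.ptp(x) == 0.0:
        return PeakAnnotation(indices=np.empty(0, dtype=np.int64), fs=fs)

    nyq = fs / 2.0
    b, a = sps.butter(2, [_BAND_HZ[0] / nyq, _BAND_HZ[1] / nyq], btype="band")
    bp = sps.filtfilt(b, a, x)

    deriv = np.convolve(bp, np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0), mode="same")
    integ = _moving_integrate(deriv ** 2, max(int(round(_INTEGRATION_S * fs)), 1))

    refractory = max(int(round(REFRACTORY_S * fs)), 1)
    candidates, _ = sps.find_peaks(integ, distance=refractory)
    if candidates.size == 0:
        return PeakAnnotation(indices=np.empty(0, dtype=np.int64), fs=fs)

    # adaptive dual thresholds (running signal / noise peak estimates)
    head = integ[: int(2 * fs)]
    spk = 0.25 * float(head.max())
    npk = 0.5 * float(head.mean())
    qrs: list[int] = []
    rr_history: list[float] = []

    def threshold1() -> float:
        return npk + 0.25 * (spk - npk)

    for c in candidates:
        if integ[c] > threshold1():
            _accept(qrs, rr_history, int(c), fs)
            spk = 0.125 * float(integ[c]) + 0.875 * spk
        else:
            npk = 0.125 * float(integ[c]) + 0.875 * npk
        # search-back: if the gap since the last beat exceeds 1.66x the
        # running RR average, rescan it at half threshold
        if len(qrs) >= 2 and rr_history:
            rr_avg = float(np.mean(rr_history[-8:]))
            if (c - qrs[-1]) / fs > 1.66 * rr_avg:
                lo, hi = qrs[-1] + refractory, int(c) - refractory
                if hi > lo:
                    seg = candidates[(candidates >= lo) & (candidates <= hi)]
                    if seg.size:
                        best = int(seg[np.argmax(integ[seg])])
                        if integ[best] > 0.5 * threshold1():
                            _accept(qrs, rr_history, best, fs)
                            spk = 0.25 * float(integ[best]) + 0.75 * spk

    if not qrs:
        return PeakAnnotation(indices=np.empty(0, dtype=np.int64), fs=fs)

    # refine each integrator peak to the R apex on the band-passed signal
    w_back = int(round(0.15 * fs))
    w_fwd = int(round(0.05 * fs))
    refined = []
    for c in sorted(qrs):
        lo = max(c - w_back, 0)
        hi = min(c + w_fwd + 1, x.size)
        refined.append(lo + int(np.argmax(bp[lo:hi])))

    # dedupe within the refractory period, keeping the taller apex
    refined.sort()
    kept: list[int] = []
    for r in refined:
        if kept and r - kept[-1] < refractory:
            if bp[r] > bp[kept[-1]]:
                kept[-1] = r
        else:
            kept.append(r)
    return PeakAnnotation(indices=np.asarray(kept, dtype=np.int64), fs=fs)


def _accept(qrs: list[int], rr_history: list[float], c: int, fs: float) -> None:
    if qrs:
        rr_history.append((c - qrs[-1]) / fs)
    # keep insertion sorted; search-back may add a beat before the latest one
    qrs.append(c)
    qrs.sort()


def compute_rri(peaks: PeakAnnotation) -> RRISeries:
    """RR intervals from consecutive peak indices, anchored at the first peak."""
    if len(peaks) < 2:
        raise ValueError(f"need at least 2 peaks to form intervals, got {len(peaks)}")
    intervals = np.diff(peaks.indices) / peaks.fs
    t0 = peaks.indices[0] / peaks.fs
    beat_times = t0 + np.concatenate(([0.0], np.cumsum(intervals)))
    return RRISeries(intervals=intervals, beat_times=beat_times)


def quality_mask(series: RRISeries, neighborhood: int = 11,
                 relative_limit: float = 0.5) -> np.ndarray:
    """Flag implausible intervals (True = flagged, excluded from projection).

    An interval is flagged when it lies outside [0.2, 3.0] s or differs from
    the median of the surrounding ``neighborhood`` intervals (centred window,
    truncated at the edges) by more than ``relative_limit`` of that median.
    Flagged intervals stay in the series; downstream stages skip them.
    """
    x = series.intervals
    n = x.size
    flags = (x < RRI_MIN_S) | (x > RRI_MAX_S)
    half = neighborhood // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        med = float(np.median(x[lo:hi]))
        if med > 0 and abs(x[i] - med) > relative_limit * med:
            flags[i] = True
    return flags
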