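"""Synthetic RR-interval streams and ECG waveforms with exact ground truth.

Two physiological regimes are emulated:

* **healthy** — mean RR around 0.8 s, SDNN in the tens of milliseconds, and
  a respiratory sinus-arrhythmia (RSA) sinusoid near 0.25 Hz;
* **variability collapse ("near-death")** — SDNN of a few milliseconds,
  suppressed RSA, optionally drifting further down over the record.

The ECG renderer draws each beat as the sum of five Gaussian waves (P, Q,
R, S, T) scaled to the beat's RR duration, records the exact R-centre
sample of every beat as ground truth, and can add white noise at a chosen
SNR and a mains sinusoid — which is what lets the preprocessing and
detection stages be tested against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import ECGRecord, RRISeries

__all__ = [
    "SyntheticProfile",
    "ECGTemplateParams",
    "generate_rri",
    "generate_ecg",
    "generate_cohort",
    "CohortSubject",
    "HEALTHY_LABEL",
    "RISK_LABEL",
]

HEALTHY_LABEL = "healthy"
RISK_LABEL = "near_death"

#: hard floor applied to every generated interval (s)
MIN_INTERVAL_S = 0.25


@dataclass
class SyntheticProfile:
    """Statistical description of one subject's RR-interval stream.

    mean_rr : mean interval (s).
    sdnn : SD of the beat-to-beat Gaussian component (s).
    rsa_amp : amplitude of the respiratory sinus modulation (s).
    rsa_freq : respiratory frequency (Hz), ~0.25 for resting adults.
    trend : linear drift of sdnn over the record (s per hour); negative
        values emulate variability collapse while approaching death.
    n_beats : number of intervals to generate.
    seed : RNG seed (bit-reproducible output).
    """

    mean_rr: float = 0.8
    sdnn: float = 0.05
    rsa_amp: float = 0.0
    rsa_freq: float = 0.25
    trend: float = 0.0
    n_beats: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_rr > 0:
            raise ValueError(f"mean_rr must be > 0, got {self.mean_rr}")
        if self.sdnn < 0 or self.rsa_amp < 0 or self.rsa_freq < 0:
            raise ValueError("sdnn, rsa_amp and rsa_freq must be >= 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")


@dataclass
class ECGTemplateParams:
    """Gaussian five-wave beat template.

    ``centers`` are fractions of the beat duration; ``widths`` are seconds
    (fixed morphology width, independent of rate); ``amps`` are mV.
    """

    fs: float = 256.0
    amps: dict = field(default_factory=lambda: {
        "P": 0.10, "Q": -0.15, "R": 1.20, "S": -0.25, "T": 0.35})
    centers: dict = field(default_factory=lambda: {
        "P": 0.20, "Q": 0.32, "R": 0.35, "S": 0.38, "T": 0.60})
    widths: dict = field(default_factory=lambda: {
        "P": 0.025, "Q": 0.008, "R": 0.010, "S": 0.008, "T": 0.040})
    noise_snr_db: Optional[float] = None
    mains_amp: float = 0.0
    mains_freq: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if any(w <= 0 for w in self.widths.values()):
            raise ValueError("wave widths must be > 0")


def generate_rri(profile: SyntheticProfile) -> RRISeries:
    """Draw an RR-interval series from ``profile`` (deterministic per seed).

    ``intervals[i] = mean_rr + rsa_amp * sin(2 pi f t_i) + eps_i`` with
    ``eps_i ~ N(0, sdnn_i^2)``, ``sdnn_i = max(sdnn + trend * t_i/3600, 0)``
    and ``t_i`` the beat time accumulated so far; every interval is floored
    at 0.25 s.
    """
    rng = np.random.default_rng(profile.seed)
    intervals = np.empty(profile.n_beats)
    t = 0.0
    for i in range(profile.n_beats):
        sd = max(profile.sdnn + profile.trend * (t / 3600.0), 0.0)
        x = (profile.mean_rr
             + profile.rsa_amp * math.sin(2.0 * math.pi * profile.rsa_freq * t)
             + (rng.normal(0.0, sd) if sd > 0 else 0.0))
        intervals[i] = max(x, MIN_INTERVAL_S)
        t += intervals[i]
    return RRISeries(intervals=intervals)


def generate_ecg(series: RRISeries, params: ECGTemplateParams | None = None) -> ECGRecord:
    """Render an interval series as a synthetic ECG with annotated R peaks.

    The R wave of beat *i* sits at a fixed offset (the template R fraction
    times the series' median RR) after ``beat_times[i]``, so consecutive R
    peaks are spaced by exactly ``intervals[i]`` and a perfect detector
    recovers the generating series.  The surrounding P/Q/S/T waves are
    placed relative to R at template fractions scaled by the local RR, so
    morphology still stretches with rate.
    """
    params = params or ECGTemplateParams()
    fs = params.fs
    total_s = float(series.beat_times[-1] - series.beat_times[0])
    n = int(round(total_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    truth = []
    t_start = series.beat_times - series.beat_times[0]
    r_frac = params.centers["R"]
    r_offset = r_frac * float(np.median(series.intervals))
    for i, rr in enumerate(series.intervals):
        r_center = t_start[i] + r_offset
        for wave in ("P", "Q", "R", "S", "T"):
            c = r_center + (params.centers[wave] - r_frac) * rr
            w = params.widths[wave]
            lo = max(int((c - 5 * w) * fs), 0)
            hi = min(int((c + 5 * w) * fs) + 1, n)
            if hi > lo:
                x[lo:hi] += params.amps[wave] * np.exp(
                    -0.5 * ((t[lo:hi] - c) / w) ** 2)
        r_idx = int(round(r_center * fs))
        if 0 <= r_idx < n:
            truth.append(r_idx)
    clean_power = float(np.mean(x ** 2))
    rng = np.random.default_rng(params.seed)
    if params.mains_amp > 0:
        x = x + params.mains_amp * np.sin(2.0 * np.pi * params.mains_freq * t)
    if params.noise_snr_db is not None:
        noise_power = clean_power / (10.0 ** (params.noise_snr_db / 10.0))
        x = x + rng.normal(0.0, math.sqrt(noise_power), size=n)
    return ECGRecord(samples=x, fs=fs, truth_peaks=np.asarray(truth, dtype=np.int64))


@dataclass
class CohortSubject:
    """One labelled synthetic subject."""

    subject_id: str
    label: str
    profile: SyntheticProfile
    series: RRISeries


def generate_cohort(n_healthy: int = 25, n_risk: int = 25,
                    seed: int = 0, n_beats: int = 2000) -> list[CohortSubject]:
    """Labelled synthetic cohort at the clinical-study scale (default 25+25).

    Healthy subjects: mean RR ~ N(0.8, 0.05^2) s, SDNN ~ U(30, 70) ms, RSA
    amplitude 25 ms.  Near-death subjects: same mean-RR law, SDNN ~
    U(2, 10) ms drifting down at 3 ms/h, RSA amplitude 5 ms.  Per-subject
    seeds derive deterministically from the master seed.
    """
    if n_healthy < 1 or n_risk < 1:
        raise ValueError("cohort needs at least one subject per group")
    rng = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []
    for group, count in ((HEALTHY_LABEL, n_healthy), (RISK_LABEL, n_risk)):
        for j in range(count):
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            mean_rr = float(np.clip(rng.normal(0.8, 0.05), 0.4, 1.4))
            if group == HEALTHY_LABEL:
                profile = SyntheticProfile(
                    mean_rr=mean_rr, sdnn=float(rng.uniform(0.030, 0.070)),
                    rsa_amp=0.025, rsa_freq=0.25,
                    n_beats=n_beats, seed=sub_seed)
            else:
                profile = SyntheticProfile(
                    mean_rr=mean_rr, sdnn=float(rng.uniform(0.002, 0.010)),
                    rsa_amp=0.005, rsa_freq=0.25, trend=-0.003,
                    n_beats=n_beats, seed=sub_seed)
            subjects.append(CohortSubject(
                subject_id=f"{group[:1]}{j:03d}", label=group,
                profile=profile, series=generate_rri(profile)))
    return subjects
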