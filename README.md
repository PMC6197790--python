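# riskplot

Continuous mortality-risk monitoring for ICU cardiovascular patients from a
single-lead ECG, built around a *risk plot* (RP): a nonlinear mapping of the
heart-rate-variability (HRV) signal in which each RR interval is thrown, like
a projectile, onto one of a row of binned "stairs", springs under the stairs
drain the landed tokens into a "valley of life", and a spring that is buried
under too much accumulation fails — the signature of collapsing HRV in the
hours before death.

## Who this is for

Physiological-signal researchers and biomedical engineers who want a
transparent, fully testable implementation of RR-interval binning dynamics as
an ICU risk score: every pipeline stage (denoising, beat detection, the plot
dynamics, the index) is an importable function with synthetic ground truth
available for all of them.

## The method

1. **Preprocessing.** Power-line interference is removed with a zero-phase
   50/60 Hz IIR notch (Q = 30); broadband noise with Daubechies (db4)
   wavelet shrinkage — universal threshold σ√(2 ln N), soft, finest two
   detail levels only.
2. **Beat detection.** A Pan–Tompkins-style chain (5–15 Hz band-pass,
   derivative, squaring, 150 ms integration, adaptive dual thresholds with
   search-back) yields R peaks; consecutive peaks give the RR-interval (RRI)
   series, the HRV signal. Implausible intervals (outside 0.2–3.0 s, or
   >50 % off the local median) are flagged, not deleted.
3. **Risk plot.** Stair *k* covers RRI bin [eₖ, eₖ₊₁) (default: 24 stairs of
   50 ms over 0.275–1.475 s). Each unflagged beat adds one token to its
   stair; then every non-stuck stair drains min(d, occupancy) tokens to the
   valley (default d = 1). A stair whose occupancy reaches capacity C
   (default 8) is stuck and drains nothing until the window reset (every
   W = 300 beats). Conservation holds at every step:
   `projected = Σ occupancy + valley + dropped`.
4. **Risk index.** Per window, with K stairs and projection counts nₖ:

   * concentration `1 − H/ln K`, H the Shannon entropy of nₖ/Σnₖ;
   * stuck fraction — share of beats with ≥ 1 stuck stair;
   * throughput `valley / projected`.

   `risk = 0.4·concentration + 0.4·stuck_fraction + 0.2·(1 − throughput)`,
   clamped to [0, 1]; alarms green < 0.24 ≤ amber < 0.30 ≤ red. Low RRI
   dispersion ⇒ concentrated projections ⇒ high risk.

A synthetic-data module generates RRI streams (mean RR, SDNN, respiratory
sinus modulation, optional variability-collapse trend) and Gaussian-template
ECG waveforms with exact R-peak ground truth, plus a labelled 25 + 25
healthy/near-death cohort.

## Worked example

```sh
$ riskplot synth --profile near-death --beats 700 --seed 1 --out fixtures
$ riskplot rri fixtures/near_death.rri --out report --no-plots
$ cat report/alarms.log
t=0.0s window=0 level=red risk=0.400
t=239.8s window=1 level=red risk=0.400
t=479.9s window=2 level=red risk=0.400
```

The near-death profile (SDNN ≈ 5 ms) lands essentially every beat on one
stair: concentration 1.0, hence risk 0.40 — red. The same run on a healthy
profile (SDNN 50 ms, RSA 25 ms) prints

```
t=0.0s window=0 level=green risk=0.224
t=238.4s window=1 level=green risk=0.215
t=478.5s window=2 level=green risk=0.208
```

and `report/windows.csv` adds the per-window SDNN and index components,
e.g. window 0: `sdnn_s=0.047771, concentration=0.561198, stuck_fraction=0.0,
throughput=1.0, risk=0.224479, green`. With the default drain rate the
springs keep pace with projection (stuck fraction 0, throughput 1), so the
score is driven by how concentrated the projections are — exactly the
dispersion signature the method monitors.

`riskplot analyze rec.hea --format wfdb` runs the same report from a raw ECG
(WFDB or two-column CSV), through preprocessing and beat detection.

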