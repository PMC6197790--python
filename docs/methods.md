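# Methods

## Model

The package treats the RR-interval (RRI) stream as the observable of a
token system. Stairs partition the RRI axis into K bins; beat *i* adds one
indivisible token to the stair containing RRIᵢ ("projection"), after which
each stair's spring moves up to *d* tokens into the valley-of-life sink
("drain"), unless the stair is stuck. A stair sticks when its occupancy
reaches the capacity *C*; a stuck spring moves nothing, and since occupancy
can then never fall below *C*, stuckness is absorbing until the analysis
window resets the whole plot. The per-beat clock is the only timebase: one
projection plus one drain sweep per beat. Tokens are conserved exactly
(`projected = Σ occupancy + valley + dropped` after every event), which is
what makes the engine verifiable against a naive per-token simulator.

The windowed risk index is a convex combination of three bounded readouts
of the plot — projection concentration (1 − normalised Shannon entropy of
the window's per-stair projection counts), the fraction of beats with a
stuck stair, and the complement of drainage throughput — each capturing one
stated failure signature: accumulation on few stairs, spring failure, and
tokens failing to reach the valley. Entropy is computed from projection
counts rather than terminal occupancy because occupancy is confounded by
drainage; the counts directly measure RRI dispersion across stairs.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| stair grid | 24 bins × 50 ms, 0.275–1.475 s | s | covers 40–218 bpm; 0.8 s at a bin centre (see below); 50 ms resolution separates SDNN regimes that 100 ms bins merge |
| drain rate d | 1 | tokens/beat/stair | minimal positive drainage |
| capacity C | 8 | tokens | spring failure level; must exceed d |
| window W | 300 | beats | ≈ 5 min at 60 bpm, the classical short-term HRV horizon |
| out-of-range policy | clamp | — | edge stairs absorb extreme intervals; `drop` available (counted, never silent) |
| index weights | 0.4 / 0.4 / 0.2 | — | one weight per ingredient; throughput down-weighted as it is redundant with stuckness for most configurations |
| alarms | amber 0.24, red 0.30 | — | calibrated on the synthetic regimes (below) |
| notch | 50 Hz (or 60), Q = 30, forward–backward | — | zero phase protects RR timing; Q=30 keeps 5–15 Hz ripple ≪ 1 dB |
| wavelet | db4, level 4 at 256 Hz, universal soft threshold on the finest 2 detail levels | — | conventional ECG choice; shrinking only ≥ 32 Hz details leaves QRS morphology intact |
| detector | Pan–Tompkins-style, 200 ms refractory, ±40 ms evaluation tolerance | — | the standard reference chain; fully specifiable |

**Stair grid and alarm calibration.** With d ≥ 1 a stair hit by one token
per beat drains it the same beat, so occupancy never accumulates on any
input: stuck fraction is identically 0, throughput identically 1, and the
risk score reduces to 0.4 × concentration, with range [0, 0.4]. The default
grid and thresholds are therefore chosen so the concentration term alone
separates the regimes: centring 0.8 s in a bin prevents a near-zero-SDNN
stream from splitting 50/50 across two bins (which would halve its
concentration), and the thresholds 0.24/0.30 sit between the healthy band
(risk ≈ 0.15–0.22 at SDNN 30–70 ms) and the variability-collapse band
(risk ≈ 0.31–0.40 at SDNN ≤ 10 ms). The stuck/throughput terms engage for
configurations with d = 0 or drain applied less often than every beat,
which the config exposes. Quantified behaviour (Spearman link, cohort
separation) is computed by the test suite and `scripts/acceptance.py`, not
asserted here.

## Synthetic data: what it does and does not emulate

`generate_rri` draws intervals as mean RR + an RSA sinusoid (default
0.25 Hz) + Gaussian beat-to-beat noise whose SD may drift linearly
(variability collapse), floored at 0.25 s. `generate_ecg` renders each beat
as five Gaussian waves (P, Q, R, S, T); the R wave sits at a fixed offset
from the beat onset so that R-to-R spacing equals the generating interval
exactly — this is what makes end-to-end interval recovery a sharp test.
Optional white noise at a chosen SNR and a mains sinusoid exercise the
preprocessing stages against known answers.

The cohort generator emulates a 50-subject study scale: 25 healthy
(mean RR ~ N(0.8, 0.05²) s, SDNN ~ U(30, 70) ms, RSA 25 ms) and 25
near-death (SDNN ~ U(2, 10) ms drifting at −3 ms/h, RSA 5 ms) subjects of
2000 beats each, with per-subject seeds derived from one master seed.

Not emulated: ectopy, atrial fibrillation and other arrhythmia
morphologies, baseline wander, electrode motion artefact, non-stationary
mean rate, and real inter-patient morphology variation. Passing tests
therefore demonstrate correctness of the dynamics and robustness to
additive noise, not clinical performance; alarm thresholds are synthetic
calibrations, not clinically validated cut-offs.

## Numerical choices

* Binning is half-open [eₖ, eₖ₊₁) with the last right edge closed; exact
  edge values belong to the bin on their right.
* Quality masking flags intervals outside 0.2–3.0 s or > 50 % off the
  median of a centred 11-interval window (truncated at the series edges);
  flagged beats are skipped but still advance the window clock and inherit
  the current stuck state.
* Entropy uses 0·log 0 ≡ 0 and H_max = ln K.
* SDNN is the ddof = 1 sample standard deviation of unflagged intervals;
  windows with < 2 usable intervals yield NaN.
* Degenerate inputs: a flat-line ECG yields zero peaks (no error); a record
  < 2 s, an empty interval series, or a window with zero projections raise
  validation errors; a series shorter than one window is reported as a
  single `partial=true` row by the CLI.
* WFDB support is a minimal self-contained subset (single signal, format
  16, gain 200 adu/mV, MIT-format annotations with SKIP escapes); CSV and
  plain-text RRI files are the lossless interchange formats.
* Problem sizes in the verification scripts (10⁵-beat conservation runs,
  1000 × 1000-beat oracle comparison, 2000-beat subjects) were chosen as
  the smallest sizes at which the statistical checks are stable.

## Known limitations

* With the default per-beat drain the stuck mechanism is dormant (see
  calibration note); it is exercised explicitly in tests via d = 0
  configurations.
* Stuck stairs recover only at window resets; an in-episode release mode
  is not implemented.
* Single-lead ECG only; no beat-type classification, so sustained ectopy
  would be flagged by the quality mask rather than analysed.
* The detector's adaptive thresholds are tuned for upright R waves;
  inverted-QRS leads would need a sign flip upstream.
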