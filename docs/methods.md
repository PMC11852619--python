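# Methods

## Signal model

A maximal static breath hold is modeled as a sum of additive components on
each of two accelerometer sites (xiphoid process = measurement, sternum =
reference), sampled at a raw rate of 1000 Hz:

- **Cardiac motion**: a pure sinusoid at `cardiac_freq` (default 2.09 Hz,
  ≈125 BPM, the tachycardic rate typical of a stressful hold). The xiphoid
  site sits closer to the heart, so its cardiac gain is higher (defaults 1.0
  vs 0.5). An equal-gain cardiac component would vanish in the differential
  channel, which contradicts the clear cardiac peak observed in real
  differential recordings; the gain asymmetry is the simplest mechanism that
  preserves it.
- **IBM bursts**: raised-cosine (Hann) pulses of width `ibm_burst_width_s`
  (default 0.5 s) repeating at a rate that ramps linearly from `ibm_f0_start`
  to `ibm_f0_end` (defaults 0.6 → 0.75 Hz) across the struggle phase, with
  peak amplitudes ramping from `ibm_amp_start` to `ibm_amp_end` (defaults
  2 → 6 sensor units): IBMs grow in both rate and magnitude as the hold
  progresses. The first burst *is* the physiological breaking point. Bursts
  couple into the xiphoid at gain 1.0 and the sternum at 0.2. Because the
  train is exactly periodic (for fixed rate), its harmonics fall at integer
  multiples of the fundamental (0.68 → 1.36 Hz); in real subjects the
  "harmonic" near 1.28 Hz is a measured feature, not an exact multiple, and
  the simulator does not reproduce that irrational spacing.
- **Postural artifacts**: Hann pulses applied with *identical* gain to both
  sites (`artifact_events`, default one 20-unit, 2 s event at t = 10 s,
  during the pre-hold settling interval). These are the events the
  differential measurement exists to cancel.
- **Noise**: white Gaussian per sensor, independent between sites
  (`noise_sd`, default 0.05 units). Real accelerometer noise is colored and
  includes quantization; white noise is sufficient for the pipeline's
  band-limited view.

Default phase durations are study-like: 30 s pre-hold, 100 s easy phase,
80 s struggle phase (hold start at 30 s, breaking point at 130 s of
acquisition time).

The device data path is emulated exactly as specified by the hardware:
sample-wise difference (xiphoid − sternum, inward contraction positive),
non-overlapping 10-sample block means, logging at raw_rate/10 = 100 Hz with
integer millisecond tick timestamps. Common-mode content cancels to machine
precision because the subtraction happens before any nonlinear stage.

What the generator does **not** emulate: biomechanical thorax dynamics,
heart-rate variability or waveform morphology (the cardiac component is one
line in the spectrum by construction), respiratory effort against a closed
glottis, sensor tilt/rotation artifacts, or oximeter physiology (auxiliary
columns are filled at 1 Hz from a constant with optional dropout). Passing
tests therefore demonstrate that the *pipeline* recovers what the model puts
in — frequencies, landmarks, trends — not that the model captures every
feature of human recordings.

## Pipeline parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| lowpass | corner, order | 50 Hz, 12 | removes high-frequency noise before decimation; "zero-phase 12th order" is realized as a 12th-order design applied forward-backward (effective magnitude = squared response) |
| decimation | factor | raw_rate/100 | subsampling keeping index 0; applied only when the input rate exceeds 100 Hz (device logs arrive already at 100 Hz) |
| normalization | easy window | first 10 s after hold start | anchors the dimensionless scale to the quiet baseline; must precede the first IBM; "max" is of the absolute deviation so the output is bipolar in [−1, 1] |
| bandpass | corners, order | 0.5–3.5 Hz, 5 | brackets the IBM fundamental (~0.68 Hz), its harmonic, and the cardiac peak while rejecting drift and residual noise |
| envelope | squaring | — | rectification that doubles spectral content (up to 7 Hz); hence the envelope is lowpassed at 4 Hz and decimated to 10 Hz before SSA |
| SSA | window | 20 s of samples, capped at n/2 | the embedding must span many IBM periods for trend/oscillation separation; cost grows with window × length, another reason to decimate the envelope first |
| SSA grouping | trend cutoff, energy floor | 0.1 Hz, 0.05 | components whose dominant FFT frequency is sub-cutoff form the trend L; remaining components with ≥5% of total eigenvalue energy form S; the rest is remainder R. Automatic grouping keeps the decomposition reproducible — no interactive pairing |
| detector | k, dwell, smoothing | 3σ, 2 s, 2 s boxcar | see below |
| spectrogram | window, overlap | 10 s Hann, 50% | 0.1 Hz resolution per slice, adequate to separate 0.68 from 1.36 Hz |
| whole-phase FFT | window | rectangular | matches a direct FFT of each phase; amplitude scaled so a unit tone at a bin center reads 1.0 (testable convention) |

## Breaking-point detection

The physiological breaking point is found on a **2 s moving-average (boxcar)
of the squared bandpassed signal**, not on the SSA trend: diagonal averaging
with a 20 s window spreads a step onset by roughly half the window, which
would bias the detected time by several seconds, while a 2 s boxcar both
bridges the gaps between successive bursts (inter-burst interval ≤ 1.7 s at
the default rates) and localizes the onset to well under a second.
`detect_physio_break` itself accepts any trend series, so the SSA trend can
be supplied where smoothness matters more than latency.

The threshold is `mean + 3·std` of the detection envelope over the easy
baseline window, and the excursion must persist for ≥ 2 s. The dwell
requirement is what rejects isolated postural spikes: a single large
common-mode residual crosses any amplitude threshold but not for 2 s
continuously. Detection is reported only after the baseline window ends.

The conventional breaking point is an input (end of record by default), not
detected from signal: breathing resumption is outside the differential
channel's view.

## Numerical choices

- High-order Butterworth filters are designed and applied in cascaded
  second-order sections (`sosfiltfilt`); a order-12 transfer function in
  polynomial form is numerically unstable. Edge handling uses reflective
  ("even") padding at the default settle length.
- SSA reconstructs each elementary component via the identity "anti-diagonal
  sums of an outer product = linear convolution of its factors", i.e.
  `component_i = σ_i · conv(u_i, v_i) / counts`, avoiding materialization of
  rank-one matrices. Eigenvalues are squared singular values of the
  trajectory matrix; their sum equals its squared Frobenius norm, and the
  sum of all elementary components reproduces the input to ~1e-14 relative.
  Degenerate (equal-singular-value) subspaces are rotation-ambiguous; tests
  compare only well-separated components against the naive oracle, plus the
  invariant sums.
- BPM conversion rounds half away from zero. Amplitude-tied spectral peaks
  break toward the lower frequency.
- Device-log gaps: a single dropped sample (interval ≈ 2 nominal periods,
  ±5%) is repaired by linear interpolation; anything larger is an error
  listing positions — silently resampling across long gaps would fabricate
  data.
- The normalization refuses constant input (zero maximum deviation) with an
  error rather than emitting NaN.

## Problem sizes

Tests and the acceptance script run the generator at the default study-like
durations (210 s at 1000 Hz raw, 21 000 logged samples) — small enough that a
full pipeline run takes well under a second — and the landmark-recovery
batches use 20 seeded recordings.

## Known limitations

- Simulator amplitudes are arbitrary sensor units; no physical calibration
  of IBM magnitude exists to target.
- The automatic SSA grouping is frequency/energy-rule based; it is
  reproducible, but its equivalence to any particular interactive grouping
  of real study data cannot be asserted.
- The detector's easy-baseline window must be IBM-free; a subject with IBMs
  inside the first 10 s of the hold would corrupt both the normalization and
  the threshold. The window is an explicit parameter for that reason.
- With a ramping IBM rate the struggle-phase spectrum smears across the ramp,
  and the "fundamental" peak reflects an average rate; single-bin recovery
  holds only for a fixed rate.
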