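# ibmkit

Analysis toolkit for **involuntary breathing movements (IBMs)** measured by
dual-site differential chest accelerometry during maximal breath holds.

During a prolonged static breath hold — the situation free divers train for —
the diaphragm and intercostal muscles eventually begin contracting
involuntarily. A hold divides into four landmarks: the *easy phase* (no
contractions, only cardiac chest motion), the *physiological breaking point*
(the first IBM), the *struggle phase* (IBMs growing in rate and magnitude),
and the *conventional breaking point* (breathing resumes). A low-cost wearable
captures this by placing one single-axis accelerometer on the xiphoid process
(measurement) and one on the sternum (reference): subtracting the reference
cancels postural motion common to both sites, while IBM contractions — which
couple far more strongly into the xiphoid site — survive the difference. The
device averages the differential signal over 10-sample blocks and logs it as
4-column CSV at 100 Hz.

The human recordings behind this method are not publicly deposited, so the
package pairs the analysis pipeline with a first-class synthetic-recording
generator carrying ground-truth annotations, which makes every stage of the
pipeline testable by parameter recovery.

## What it computes

For a recording `y_raw` the pipeline runs, in order:

1. truncation to the start of the hold;
2. zero-phase 12th-order lowpass Butterworth filter (50 Hz corner) and
   decimation from the raw rate (~1000 Hz) to 100 Hz (skipped when the input
   is already a 100 Hz device log);
3. easy-phase baseline normalization
   `y = (y_raw − mean(y_easy)) / max|y_raw − mean(y_easy)|`;
4. per-phase FFT amplitude spectra: the easy-phase peak is the cardiac
   frequency (×60 → heart rate in BPM); the struggle-phase spectrum shows the
   IBM burst fundamental (~0.68 Hz) and its harmonics;
5. zero-phase 5th-order bandpass Butterworth filter (0.5–3.5 Hz) followed by
   squaring, `y_filt ← y_filt²`, giving a non-negative IBM energy envelope;
6. singular spectrum analysis (SSA) of the envelope: the additive
   decomposition `A = L + S + R` (long-term trend, oscillations, remainder)
   whose trend `L` tracks the growth of IBM magnitude across the struggle
   phase;
7. phase segmentation: the physiological breaking point is detected as the
   earliest sustained excursion of the smoothed envelope above the easy-phase
   baseline (mean + k·std, k = 3, dwell 2 s);
8. a Hann-window spectrogram of the envelope for time-resolved frequency
   content.

Small device-arithmetic helpers (battery runtime = capacity/current; bill-of-
materials totals with consistency checking) live in `ibmkit.devicecalc`.

## Worked example

```python
from ibmkit import (BreathHoldModel, PipelineConfig, SimConfig,
                    emulate_device, simulate_breath_hold)

# a 210 s recording: 30 s pre-hold, 100 s easy phase, 80 s struggle phase,
# cardiac component at 2.09 Hz, IBM bursts repeating at 0.68 Hz
config = SimConfig(ibm_f0_start=0.68, ibm_f0_end=0.68, seed=1)
sternum, xiphoid, truth = simulate_breath_hold(config)
log = emulate_device(sternum, xiphoid)          # 10-sample averaging -> 100 Hz

results = BreathHoldModel(log, PipelineConfig(hold_start_s=truth.t_hold_start)).fit()
print(results.summary())
```

prints

```
Breath-hold analysis summary
============================================
hold start (s)                          0.00
physiological breaking point (s)       99.90
easy-phase duration (s)                99.90
conventional breaking point (s)       179.99
easy-phase cardiac peak (Hz)           2.092
heart rate estimate (BPM)                126
struggle-phase peaks (Hz): 1.361, 0.674, 2.085
============================================
```

The true breaking point is at 100 s after hold start, recovered here at
99.90 s. The easy-phase spectral peak recovers the configured 2.09 Hz cardiac
component; the struggle-phase peak list contains the 0.68 Hz IBM fundamental
(0.674 Hz, within one FFT bin of a 80 s window), its first harmonic
(1.36 Hz), and the cardiac peak.

The same three workflows are available from the shell:

```sh
ibmkit simulate --config sim.yaml --out run/       # device log + truth sidecar
ibmkit process run/device_log.csv --out report/    # full pipeline -> report dir
ibmkit report report/                              # figures + text summary
```

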