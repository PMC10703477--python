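# motionlab

A Python toolkit for analysing tracked motion coordinates together with
electrophysiology and sensor signals. It is aimed at movement scientists
who already have point trajectories — from video tracking, markerless pose
estimation (DeepLabCut-style CSV) or motion capture exports — and want a
scriptable path from raw coordinate tables to kinematics, gait-cycle
parameters, EMG envelopes, spectra and signal correlations.

Everything is unit-agnostic: if coordinates are in mm and time in seconds,
speeds come out in mm/s. The vertical axis is y, increasing upward.

## What it computes

**Kinematics.** For each tracked point of interest (POI), speeds are
forward differences `v_i = (p_{i+1} − p_i)/(t_{i+1} − t_i)` (the
frame-to-frame "instant speed" of manual tracking tools) and accelerations
are successive speed differences over the half-span,
`a_i = 2(v_{i+1} − v_i)/(t_{i+2} − t_i)`. Joint angles are the interior
angle at a vertex B between flanking points A and C,
`θ = atan2(‖u×v‖, u·v)` with `u = A−B`, `v = C−B`, in `[0°, 180°]`.
Path length, occupancy heatmaps, descriptive statistics and stick
diagrams (with display-only anchoring to a reference POI) round this out.

**Gait.** The gait cycle is decomposed classically: stance from
heel-strike (HS) to toe-off (TO), swing from TO to the next ipsilateral
HS, so stance + swing = stride. From annotated events the package derives
stride length and duration, step size and duration (to the next
contralateral HS), heel-down duration, toe-lift height/duration/speed,
the bilateral gait diagram with double-support overlap, and a two-phase
variant for stance-free cycles such as swimming power/return strokes.

**Signals.** Time-base repair, resampling, zero-phase Butterworth
filtering, the four standard EMG rectification modes, envelopes (low-pass,
Hilbert, moving mean/RMS), Parseval-normalized power spectra, spectrograms
and area under the curve — with a revertible processing history per trace.

**Correlation.** Normalized auto-/cross-correlation, FFT phase lag and
amplitude ratio at the reference signal's spectral peak, similarity
metrics (Euclidean, cosine, Pearson, Spearman, Kendall tau-b), dynamic
time warping under a Sakoe–Chiba band, and cyclograms.

## Worked example

```python
import numpy as np
from motionlab import synthgen, gait, kinematics, signals, correlation

# A synthetic gait sequence with known geometry: heel-strikes at
# x = 0, 7, 14 at t = 0, 6, 12 s, stance 4 s, toe apex 0.5.
bundle = synthgen.gen_dummy_gait()
cycles = gait.compute_cycles(bundle.elements["left_leg"], bundle.events, "left")
c = cycles[0]
print(c.stride_length, c.toe_lift_height, c.stance_duration, c.swing_duration)
# 7.0 0.5 4.0 2.0   <- stride length, toe-lift height, stance s, swing s

# Two sines, antiphase, amplitude ratio 2:
pair = synthgen.gen_antiphase_pair()
pa = correlation.phase_amplitude(pair.signals["a"], pair.signals["b"])
print(round(pa.amplitude_ratio, 6), round(abs(pa.phase_lag_deg), 6))
# 2.0 180.0          <- FFT amplitude ratio and |phase lag| in degrees

# Three-tone mixture (25/30/35 Hz), band-stop the upper two tones:
s = synthgen.gen_sine_mixture().signals["mixture"]
s = signals.butterworth(s, "stop", (29, 31), order=4)
s = signals.butterworth(s, "stop", (34, 36), order=4)
print(signals.power_spectrum(s).peak_frequency())
# 25.0               <- surviving spectral peak in Hz
```

A `motionlab` command-line interface wraps the same operations
(`motionlab synth dummy-gait --out-dir fix`, `motionlab gait session.mlz
left_leg --events fix/events.csv ...`); see `motionlab --help`. Pipelines
can also be described in a versioned YAML file and executed with
`motionlab run pipeline.yaml` (use `--dry-run` to validate without
touching outputs).

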