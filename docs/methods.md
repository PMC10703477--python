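# Methods

This note documents the models, conventions and numerical choices behind
motionlab, and what the synthetic validation fixtures do and do not show.

## Containers and units

All quantities inherit the units of the input file: no unit conversion is
ever applied, only an explicit time-rescaling helper (`rescale_time`) for
order-of-magnitude fixes (ms → s). Timestamps must be strictly increasing.
Missing samples are an explicit boolean mask on each trajectory — never a
magic number — so dropouts survive file round trips losslessly and are
excluded from every statistic. The coordinate convention is Cartesian
(y up); image-coordinate exports (y down) should be converted with
`preprocess.invert_axis` before gait analysis, whose "maximum toe lift"
logic assumes up-positive vertical. 2D data never receive an implicit
third coordinate in calculations; a constant placeholder z exists only in
the animation renderer.

Signal traces keep an immutable copy of their original samples and an
ordered history of applied operations, so any processing chain can be
reverted exactly. Every preprocessing or signal operation is pure: it
returns a new object and appends exactly one history entry.

## Kinematics

Speed is the forward difference `v_i = (p_{i+1} − p_i)/Δt_i`, timestamped
at the interval midpoint. This matches the frame-to-frame "instant speed"
definition of manual video-tracking tools, and gives the expected
canonical behaviour: a linearly increasing coordinate yields a constant
speed and zero acceleration; a parabolic one yields a linearly increasing
speed and constant acceleration. Acceleration divides successive speed
differences by the half-span of the two intervals,
`a_i = 2(v_{i+1} − v_i)/(t_{i+2} − t_i)` (equal to `Δv/Δt` for uniform
sampling), timestamped at the span midpoint. Central or spline
differentiation was deliberately not used: it smears single-sample
perturbations across neighbours, whereas the forward-difference scheme
confines an injected outlier to exactly the adjacent derivative samples —
a property the test suite checks.

Joint angles use `θ = atan2(‖u×v‖, u·v)`, numerically stabler than
`arccos` of the normalized dot product near 0° and 180°. The angle is the
unsigned interior angle in `[0°, 180°]`; no winding convention. A frame
with a zero-length segment (or a missing point) yields NaN rather than an
error, because single bad frames are routine in tracked data.

Stick-diagram normalization subtracts the reference POI's *displacement
since frame 0* from all POIs on the chosen axes (anchoring), rather than
its absolute position. This preserves the initial pose while suppressing
bulk motion, and it is display-only: kinematics and gait always run on
the raw coordinates, which the tests enforce. Likewise `downsample_view`
returns an element tagged display-only that the kinematics module
refuses, so display thinning can never leak into analysis.

Descriptive statistics use the sample (n−1) standard deviation, define
the mode as the most frequent value after rounding to a configurable
number of decimals (ties → smallest value), and report 0 for the standard
deviation of a single sample by convention.

## Preprocessing

The outlier detector is the robust rule |x − median| > k·1.4826·MAD per
POI and axis, with k = 3 by default; 1.4826 makes the MAD consistent with
the standard deviation under Gaussian noise. The replacement methods
(linear interpolation, nearest, previous, mean window — default width 5,
odd) operate on the surviving samples; already-missing samples are
treated as outliers and filled too. A constant axis (MAD 0) produces no
flags. Interpolation-based replacement is idempotent at a fixed
threshold.

Smoothing (moving mean, moving median, RMS) uses centered windows whose
edges shrink to the available neighbors — no padding, so no data are
fabricated beyond the trajectory ends. Shift, rotation and axis inversion
are exact isometries (pairwise inter-POI distances preserved to 1e-12),
which makes kinematic magnitudes invariant under them; perspective
correction is plain isotropic scaling about a center (no projective
model — lens/perspective distortion must be corrected upstream).

Stitching of two recordings keeps the base strictly before the chosen
transition time and the (rotated, then translated) patch from the
transition on, with no blending; a time gap exceeding twice the median
sampling interval only warns, since slightly lossy hand-offs between
cameras are common. Splitting at any interior time and re-stitching
reconstructs the original exactly.

## Signal processing

Butterworth filters are designed in second-order sections and applied
forward–backward by default (zero phase, doubled effective order). The
default matters because the correlation module compares phases between
filtered signals: single-pass IIR filtering would inject a
frequency-dependent lag. Single-pass is available by flag.

Rectification modes: `mean` removes the mean (the standard EMG baseline
step), `absolute` is |x|, `square_root` is the per-sample √(x²) — which
coincides numerically with the absolute value and is kept as a separate
named mode for interface completeness — and `half_wave` clips negatives
to zero. The low-pass envelope route requires a rectified input (checked
against the trace's history, overridable), since low-passing a biphasic
signal estimates its mean, not its envelope.

The power spectrum is a one-sided periodogram normalized as
`P_k = |X_k|²/n²` with interior bins doubled, so `ΣP_k` equals the mean
square of the signal; this Parseval identity is asserted (1e-6 relative)
across the test suite, which pins the normalization unambiguously. The
peak-frequency helper excludes the DC bin. The spectrogram is a standard
STFT power (Hann window, 256 samples, 50% overlap by default).

## Correlation

Cross-correlation is the normalized cross-covariance
`r(ℓ) = Σ(a_t−ā)(b_{t+ℓ}−b̄)/√(Σ(a−ā)²Σ(b−b̄)²)`; autocorrelation is the
self case with r(0) = 1 exactly. Signals of different rates or spans are
first harmonized: trimmed to the overlap and linearly resampled to the
*lower* of the two rates (downsampling avoids fabricating detail).

The phase lag and amplitude ratio are taken at the peak of the *first*
signal's FFT magnitude (DC excluded) and that frequency is reused for the
second signal — when two spectra peak at different bins a phase
difference is otherwise ill-defined. The lag is the wrapped difference
(phase of the first minus phase of the second) in (−180°, 180°]; the
ratio is second over first, so a probe at twice the reference amplitude
reports 2.

DTW uses cost |a_i − b_j|, the symmetric step set {(1,0),(0,1),(1,1)}
without slope weighting, and a Sakoe–Chiba band of configurable
half-width (must be ≥ |n−m| to be feasible). The implementation is
verified against an exhaustive full-matrix DP oracle on short random
inputs, and with the same cost metric the DTW distance can never exceed
the rigid (diagonal) alignment cost.

## Gait analysis

Events are first-class inputs (frame indices into an element), mirroring
interactive marking. Cycles are delimited by successive ipsilateral
heel-strikes; a heel-strike must open each side's stream. Exactly one
toe-off per cycle is required; heel-off (within stance) and maximum
toe-lift (within swing) are optional refinements. Stride length is the
progression-axis displacement (default x) of the heel POI between
successive heel-strikes — a projection that is robust to vertical
bobbing; the measuring POI is configurable since conventions differ.
Toe-lift height is the vertical coordinate of the toe POI at max-toe-lift
relative to toe-off. Stance intervals are closed-open [HS, TO); bilateral
overlap uses interval intersection with zero-length intersections
discarded.

The heuristic event detector ("grounded" = foot height within 5% of its
range above the minimum AND progression speed below 10% of maximum;
strikes at onsets of heel-grounded runs, toe-offs at ends of
toe-grounded runs) is a convenience for clean recordings, not a validated
gait-event algorithm; a recording that opens mid-stance is treated as
striking at its first frame.

## Synthetic fixtures: what they show

The generators produce the validation conditions with analytically known
answers: polynomial trajectories whose forward-difference derivatives are
computed in closed form (by polynomial coefficient arithmetic, not by
differencing the samples); angle chains placing C at
`B + (cos(180°−θ), sin(180°−θ))` so the interior angle at B is exactly θ;
a dummy gait with heel-strikes at x = 0/7/14 at t = 0/6/12 s, 4 s stance
and a 0.5-unit toe apex at mid-swing (hence stride 7, stance 4 s, swing
2 s, toe-lift 0.5), sampled at 100 Hz and extended one stance past the
last strike so all events are interior, plus a contralateral copy offset
by half a stride; a 25/30/35 Hz unit-amplitude three-tone mixture at
1 kHz for 10 s; and an antiphase sine pair (5 Hz, ratio 2, offset π).
Sine durations are rounded up to an integer number of periods of every
component so spectra are leakage-free. All generators are deterministic;
optional Gaussian noise uses a single explicitly seeded generator.

These fixtures validate the *algebra* of the pipeline — differentiation,
angle measurement, event-to-parameter bookkeeping, filtering and spectral
phase — under ideal sampling. They do not contain tracking jitter,
marker occlusion, soft-tissue artifact, EMG noise floors or non-stationary
rhythms, so passing them demonstrates correctness of the computations,
not robustness on degraded real recordings.

## Session archive and I/O

The session archive is a zip holding a JSON manifest (names, processing
histories, gait events, scalar products) plus one CSV payload per
dataset. Floats are written with 17 significant digits and parsed with
round-trip precision, so save → load is bit-exact, including missing
masks and the raw signal copies. An open container was preferred over a
binary workspace dump because it is language-neutral and diffable.
Delimiters (comma/semicolon/tab) are auto-detected; a decimal comma is
*not* auto-detected (ambiguous with semicolon delimiters) and must be
requested with `decimal=","`. Pose-estimation CSVs need an explicit fps
to convert frame indices to time; the likelihood threshold defaults to 0
(keep everything).

## Problem sizes

The validation fixtures run at their native sizes (10 s of 1 kHz signal,
16 s of 100 Hz gait data); the whole test suite, including property
tests, completes in a few seconds on one core. DTW oracle checks use
length-10 sequences, where exhaustive DP is exact and instant.

## Known limitations

- No camera calibration, lens-distortion correction or 3D triangulation;
  multi-camera reconciliation is limited to rigid/scaling alignment and
  stitching.
- The gait detector is heuristic; annotated events are the primary path.
- `square_root` rectification duplicates `absolute` numerically (kept as
  a distinct named mode of the interface).
- No coherence spectra, Granger causality or spike-level analyses.
- Torque/inverse dynamics are out of scope.
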