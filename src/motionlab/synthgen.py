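"""Deterministic generators for validation fixtures with known ground truth.

Each generator returns a :class:`FixtureBundle` pairing synthetic data
(elements, signals, events) with the analytically known quantities the
analysis modules should recover: polynomial trajectories with closed-form
forward-difference derivatives, segment chains with prescribed joint
angles, a dummy bipedal gait sequence with known stride geometry, sine
mixtures with known spectral peaks, and an antiphase sine pair with known
amplitude ratio and phase lag.

Regeneration with identical parameters (and seed, where noise is added) is
bit-identical; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

import numpy as np
from numpy.polynomial import Polynomial

from .core import Element, PointTrajectory, SignalTrace, build_element
from .errors import ValidationError
from .gait import GaitEvent, events_from_frames

__all__ = [
    "FixtureBundle",
    "gen_polynomial_trajectory",
    "gen_angle_chain",
    "gen_dummy_gait",
    "gen_sine_mixture",
    "gen_antiphase_pair",
    "add_noise",
]


@dataclass
class FixtureBundle:
    """Synthetic data plus its ground truth and the parameters used."""

    elements: dict = field(default_factory=dict)
    signals: dict = field(default_factory=dict)
    events: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int | None = None


def _fwd_diff_poly(p: Polynomial, dt: float) -> Polynomial:
    """Closed-form forward difference quotient (p(t + dt) - p(t)) / dt."""
    shifted = p(Polynomial([dt, 1.0]))  # p evaluated at t + dt
    return (shifted - p) / dt


def gen_polynomial_trajectory(t0: float = 0.0, t1: float = 10.0, dt: float = 1.0,
                              x_coeffs=(0.0, 2.0), y_coeffs=(0.0, 0.0, 1.0),
                              outlier: dict | None = None) -> FixtureBundle:
    """Trajectory with polynomial coordinates and exact derivative truth.

    Defaults give x = 2t (constant speed 2, zero acceleration) and y = t^2
    (forward-difference speed 2t + 1 at dt = 1, constant acceleration 2).
    ``outlier={"index": i, "value": v}`` replaces one y sample AFTER the
    ground truth is computed, so exactly the two adjacent speed samples and
    up to three acceleration samples differ from the truth.
    """
    if not dt > 0:
        raise ValidationError("dt must be positive")
    if len(x_coeffs) > 4 or len(y_coeffs) > 4:
        raise ValidationError("polynomial degree must be <= 3")
    n = int(round((t1 - t0) / dt)) + 1
    t = t0 + dt * np.arange(n)
    px, py = Polynomial(list(x_coeffs)), Polynomial(list(y_coeffs))
    x, y = px(t), py(t)
    vx_p, vy_p = _fwd_diff_poly(px, dt), _fwd_diff_poly(py, dt)
    # forward-difference speeds live on the first n-1 sample times;
    # accelerations divide speed differences by the spanned interval / 2 = dt
    ax_p, ay_p = _fwd_diff_poly(vx_p, dt), _fwd_diff_poly(vy_p, dt)
    truth = {
        "vx": vx_p(t[:-1]), "vy": vy_p(t[:-1]),
        "ax": ax_p(t[:-2]), "ay": ay_p(t[:-2]),
    }
    if outlier is not None:
        i = int(outlier["index"])
        if not 0 <= i < n:
            raise ValidationError(f"outlier index {i} out of range [0, {n})")
        y = y.copy()
        y[i] = float(outlier["value"])
    poi = PointTrajectory("p", t, np.column_stack([x, y]))
    el = build_element("polynomial", [poi])
    return FixtureBundle(
        elements={"polynomial": el},
        truth=truth,
        params=dict(t0=t0, t1=t1, dt=dt, x_coeffs=list(x_coeffs),
                    y_coeffs=list(y_coeffs), outlier=outlier),
    )


def gen_angle_chain(angles_deg=(0.0, 90.0, 135.0)) -> FixtureBundle:
    """Three-POI chain realizing each requested interior angle at vertex B.

    One frame per angle: A = (0,0), B = (1,0) fixed, and
    C = B + (cos(180 - theta), sin(180 - theta)) so the interior angle at B
    is exactly theta.  theta = 90 gives C = (1, 1); theta = 0 folds C back
    onto A; theta = 180 extends the chain collinearly.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValidationError("need at least one angle")
    if np.any((angles < 0) | (angles > 180)):
        raise ValidationError("angles must lie in [0, 180] degrees")
    n = angles.size
    t = np.arange(n, dtype=float)
    a = np.tile([0.0, 0.0], (n, 1))
    b = np.tile([1.0, 0.0], (n, 1))
    phi = np.deg2rad(180.0 - angles)
    c = b + np.column_stack([np.cos(phi), np.sin(phi)])
    el = build_element("angle_chain", [
        PointTrajectory("A", t, a),
        PointTrajectory("B", t, b),
        PointTrajectory("C", t, c),
    ])
    return FixtureBundle(
        elements={"angle_chain": el},
        truth={"angles_deg": angles.copy()},
        params={"angles_deg": angles.tolist()},
    )


def _piecewise_leg(t: np.ndarray, hs_times, hs_pos, stance_s: float,
                   apex: float):
    """Heel-style x(t), y(t): grounded at hs_pos during stance, half-sine
    arc of height ``apex`` while advancing to the next position."""
    x = np.empty_like(t)
    y = np.zeros_like(t)
    x[:] = hs_pos[0]
    for k in range(len(hs_times)):
        t_hs = hs_times[k]
        if k + 1 < len(hs_times):
            t_next = hs_times[k + 1]
            swing = t_next - (t_hs + stance_s)
            in_stance = (t >= t_hs) & (t < t_hs + stance_s)
            in_swing = (t >= t_hs + stance_s) & (t < t_next)
            x[in_stance] = hs_pos[k]
            frac = (t[in_swing] - t_hs - stance_s) / swing
            x[in_swing] = hs_pos[k] + frac * (hs_pos[k + 1] - hs_pos[k])
            y[in_swing] = apex * np.sin(np.pi * frac)
        else:
            x[t >= t_hs] = hs_pos[k]
    return x, y


def gen_dummy_gait(hs_positions=(0.0, 7.0, 14.0), hs_times=(0.0, 6.0, 12.0),
                   stance_s: float = 4.0, toe_apex: float = 0.5,
                   fps: float = 100.0, bipedal: bool = True) -> FixtureBundle:
    """Dummy gait sequence with known stride geometry.

    Defaults: heel-strikes at positions 0, 7, 14 at times 0, 6, 12 s with a
    4 s stance, so each cycle has stride length 7, stance 4 s, swing 2 s,
    and the toe arcs to a maximum lift of 0.5 at mid-swing.  Sampling
    extends one stance past the last heel-strike so that every annotated
    event lies strictly inside the recording.

    With ``bipedal=True`` a contralateral leg offset by half a stride (in
    both time and progression) is included, giving alternating steps of
    half the stride duration and length.
    """
    hs_times = np.asarray(hs_times, dtype=float)
    hs_pos = np.asarray(hs_positions, dtype=float)
    if hs_times.size != hs_pos.size or hs_times.size < 2:
        raise ValidationError("need matching hs_positions/hs_times lists of length >= 2")
    if np.any(np.diff(hs_times) <= 0) or np.any(np.diff(hs_pos) <= 0):
        raise ValidationError("heel-strike times and positions must be increasing")
    strides = np.diff(hs_times)
    if not stance_s < strides.min():
        raise ValidationError("stance duration must be shorter than every stride")
    if not fps > 0:
        raise ValidationError("fps must be positive")

    t_end = hs_times[-1] + stance_s
    n = int(round(t_end * fps)) + 1
    t = np.arange(n) / fps

    def leg_pois(times_hs, pos_hs, suffix=""):
        heel_x, heel_y = _piecewise_leg(t, times_hs, pos_hs, stance_s,
                                        toe_apex / 2.0)
        toe_x, toe_y = _piecewise_leg(t, times_hs, pos_hs, stance_s, toe_apex)
        toe_x = toe_x + 0.5          # toe sits ahead of the heel
        knee_x = heel_x + 0.25
        knee_y = np.full_like(t, 1.0)
        return [
            PointTrajectory("knee" + suffix, t, np.column_stack([knee_x, knee_y])),
            PointTrajectory("heel" + suffix, t, np.column_stack([heel_x, heel_y])),
            PointTrajectory("toe" + suffix, t, np.column_stack([toe_x, toe_y])),
        ]

    def leg_events(times_hs, side, el):
        marks = []
        for k, t_hs in enumerate(times_hs):
            marks.append(("heel_strike", int(round(t_hs * fps))))
            if k + 1 < len(times_hs):
                t_to = t_hs + stance_s
                swing = times_hs[k + 1] - t_to
                marks.append(("toe_off", int(round(t_to * fps))))
                marks.append(("max_toe_lift", int(round((t_to + swing / 2) * fps))))
        return events_from_frames(el, marks, side=side)

    left = Element("left_leg", leg_pois(hs_times, hs_pos))
    elements = {"left_leg": left}
    events = leg_events(hs_times, "left", left)

    truth_cycles = []
    for k in range(len(hs_times) - 1):
        stride_t = hs_times[k + 1] - hs_times[k]
        truth_cycles.append({
            "stride_length": float(hs_pos[k + 1] - hs_pos[k]),
            "stride_duration": float(stride_t),
            "stance_duration": float(stance_s),
            "swing_duration": float(stride_t - stance_s),
            "toe_lift_height": float(toe_apex),
        })
    truth = {"cycles_left": truth_cycles}

    if bipedal:
        half_t = strides[0] / 2.0
        half_x = (hs_pos[1] - hs_pos[0]) / 2.0
        # virtual strike before t=0 so the right leg is defined on the
        # whole grid; only in-range events are annotated
        rt = np.concatenate([[hs_times[0] - (strides[0] - half_t)],
                             hs_times + half_t])
        rp = np.concatenate([[hs_pos[0] - (hs_pos[1] - hs_pos[0]) + half_x],
                             hs_pos + half_x])
        right = Element("right_leg", leg_pois(rt, rp, suffix=""))
        elements["right_leg"] = right
        marks = []
        for k in range(1, len(rt)):
            if 0 <= rt[k] <= t_end:
                marks.append(("heel_strike", int(round(rt[k] * fps))))
            if k + 1 < len(rt):
                t_to = rt[k] + stance_s
                swing = rt[k + 1] - t_to
                if 0 <= t_to <= t_end:
                    marks.append(("toe_off", int(round(t_to * fps))))
                mtl = t_to + swing / 2
                if 0 <= mtl <= t_end:
                    marks.append(("max_toe_lift", int(round(mtl * fps))))
        events = events + events_from_frames(right, marks, side="right")
        combined = Element("legs", leg_pois(hs_times, hs_pos, "_left")
                           + leg_pois(rt, rp, "_right"))
        elements["legs"] = combined
        truth["step_duration"] = float(half_t)
        truth["step_size"] = float(half_x)

    return FixtureBundle(
        elements=elements, events=events, truth=truth,
        params=dict(hs_positions=hs_pos.tolist(), hs_times=hs_times.tolist(),
                    stance_s=float(stance_s), toe_apex=float(toe_apex),
                    fps=float(fps), bipedal=bool(bipedal)),
    )


def _integer_period_duration(freqs, duration: float) -> float:
    """Smallest duration >= requested that is an integer number of periods
    of every component frequency."""
    fracs = [Fraction(float(f)).limit_denominator(10 ** 6) for f in freqs]
    # common period: lcm of 1/f = lcm(den)/gcd(num)
    num = fracs[0].denominator
    den = fracs[0].numerator
    for fr in fracs[1:]:
        num = num * fr.denominator // gcd(num, fr.denominator)
        den = gcd(den, fr.numerator)
    period = Fraction(num, den)
    k = int(np.ceil(duration / float(period) - 1e-12))
    return float(max(k, 1) * period)


def gen_sine_mixture(freqs=(25.0, 30.0, 35.0), amps=None, fs: float = 1000.0,
                     duration: float = 10.0, phases=None) -> FixtureBundle:
    """Sum of sine waves with known spectral peaks.

    Defaults give the three-tone 25/30/35 Hz validation mixture sampled at
    1 kHz for 10 s.  The duration is rounded up to an integer number of
    periods of every component so the spectrum has no leakage.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValidationError("need at least one component frequency")
    if np.any(freqs >= fs / 2):
        raise ValidationError("all frequencies must be below Nyquist")
    amps = np.ones_like(freqs) if amps is None else np.asarray(amps, dtype=float)
    phases = np.zeros_like(freqs) if phases is None else np.asarray(phases, dtype=float)
    duration = _integer_period_duration(freqs, duration)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    v = np.zeros(n)
    for f, a, ph in zip(freqs, amps, phases):
        v += a * np.sin(2 * np.pi * f * t + ph)
    sig = SignalTrace("mixture", t, v)
    return FixtureBundle(
        signals={"mixture": sig},
        truth={"peak_freqs": freqs.copy(), "amps": amps.copy()},
        params=dict(freqs=freqs.tolist(), amps=amps.tolist(), fs=float(fs),
                    duration=duration, phases=phases.tolist()),
    )


def gen_antiphase_pair(f: float = 5.0, fs: float = 1000.0, duration: float = 10.0,
                       amp_ratio: float = 2.0,
                       phase_offset: float = np.pi) -> FixtureBundle:
    """Two sines a = sin(2 pi f t), b = r sin(2 pi f t + phi).

    Defaults reproduce the antiphase validation pair: amplitude ratio 2 and
    phase shift of pi radians, i.e. a 180-degree phase lag and negative
    correlation at lag 0.
    """
    if not f < fs / 2:
        raise ValidationError("frequency must be below Nyquist")
    duration = _integer_period_duration([f], duration)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    a = np.sin(2 * np.pi * f * t)
    b = amp_ratio * np.sin(2 * np.pi * f * t + phase_offset)
    lag_deg = (np.rad2deg(-phase_offset) + 180.0) % 360.0 - 180.0
    if lag_deg == -180.0:
        lag_deg = 180.0
    return FixtureBundle(
        signals={"a": SignalTrace("a", t, a), "b": SignalTrace("b", t, b)},
        truth={"amplitude_ratio": float(amp_ratio),
               "phase_lag_deg": float(lag_deg),
               "frequency": float(f)},
        params=dict(f=float(f), fs=float(fs), duration=duration,
                    amp_ratio=float(amp_ratio), phase_offset=float(phase_offset)),
    )


def add_noise(bundle: FixtureBundle, sd: float, seed: int) -> FixtureBundle:
    """Add i.i.d. Gaussian noise to all signals and coordinates.

    Ground truth is carried over unchanged; the same seed reproduces the
    same noise exactly.
    """
    if sd < 0:
        raise ValidationError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = FixtureBundle(truth=dict(bundle.truth),
                        params=dict(bundle.params, noise_sd=float(sd)),
                        events=list(bundle.events), seed=int(seed))
    for name, el in bundle.elements.items():
        noisy = el.copy()
        if sd > 0:
            for p in noisy.pois:
                p.coords = p.coords + rng.normal(0.0, sd, p.coords.shape)
        out.elements[name] = noisy
    for name, s in bundle.signals.items():
        vals = s.values + (rng.normal(0.0, sd, s.n) if sd > 0 else 0.0)
        out.signals[name] = SignalTrace(s.label, s.times.copy(), vals)
    return out
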