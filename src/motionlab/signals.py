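"""Electrophysiology and sensor signal processing.

Covers time-base repair, resampling, Butterworth filtering, the four EMG
rectification modes, envelope extraction, spectra and area under the curve.
Filtering defaults to zero-phase (forward-backward) so downstream phase
comparisons are not biased by filter group delay; single-pass filtering is
available via ``zero_phase=False``.

Spectral convention: one-sided periodogram with power |X_k|^2 / n^2 and
doubling of interior bins, so the total power equals the mean square of the
signal (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .core import SignalTrace
from .errors import ContractError, ValidationError

__all__ = [
    "SpectrumResult",
    "SpectrogramResult",
    "set_time_base",
    "resample",
    "butterworth",
    "rectify",
    "envelope",
    "power_spectrum",
    "spectrogram",
    "area_under_curve",
]


def _require_uniform(s: SignalTrace, op: str) -> float:
    if not s.is_uniform():
        raise ContractError(
            f"{op} requires uniform sampling; repair the time base with "
            "set_time_base or resample first"
        )
    return s.fs


def set_time_base(s: SignalTrace, fs: float) -> SignalTrace:
    """Replace the time array with i/fs (sample rate known, times absent)."""
    if not fs > 0:
        raise ValidationError(f"sampling rate must be positive, got {fs}")
    times = np.arange(s.n, dtype=float) / fs
    return s.derive(s.values.copy(), "set_time_base", times=times, fs=float(fs))


def resample(s: SignalTrace, new_fs: float, method: str = "linear") -> SignalTrace:
    """Resample a uniform trace to ``new_fs`` over the same closed time span."""
    if not new_fs > 0:
        raise ValidationError(f"sampling rate must be positive, got {new_fs}")
    if method not in ("linear", "cubic"):
        raise ValidationError(f"method must be 'linear' or 'cubic', got {method!r}")
    _require_uniform(s, "resample")
    t0, t1 = s.times[0], s.times[-1]
    n_out = int(round((t1 - t0) * new_fs)) + 1
    new_t = t0 + np.arange(n_out, dtype=float) / new_fs
    new_t = new_t[new_t <= t1 + 1e-12 * max(1.0, abs(t1))]
    if method == "linear":
        new_v = np.interp(new_t, s.times, s.values)
    else:
        new_v = CubicSpline(s.times, s.values)(new_t)
    return s.derive(new_v, "resample", times=new_t, new_fs=float(new_fs),
                    method=method)


def butterworth(s: SignalTrace, kind: str, cutoffs, order: int = 4,
                zero_phase: bool = True) -> SignalTrace:
    """Digital Butterworth filter: low, high, band(-pass) or (band-)stop.

    ``cutoffs`` is a scalar for low/high and a (f_lo, f_hi) pair for
    band/stop, all in the signal's frequency unit (1/time unit) and strictly
    below Nyquist.  Zero-phase runs the filter forward and backward,
    doubling the effective order but cancelling group delay.
    """
    kinds = {"low": "lowpass", "high": "highpass", "band": "bandpass",
             "stop": "bandstop"}
    if kind not in kinds:
        raise ValidationError(f"kind must be one of {sorted(kinds)}, got {kind!r}")
    if order < 1:
        raise ValidationError(f"filter order must be >= 1, got {order}")
    fs = _require_uniform(s, "butterworth")
    nyq = fs / 2.0
    wn = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    if kind in ("band", "stop"):
        if wn.size != 2 or not wn[0] < wn[1]:
            raise ValidationError("band/stop filters need cutoffs (f_lo, f_hi) with f_lo < f_hi")
    elif wn.size != 1:
        raise ValidationError("low/high filters take a single cutoff")
    if np.any(wn <= 0) or np.any(wn >= nyq):
        raise ValidationError(
            f"cutoffs must lie strictly inside (0, {nyq:g}) for fs={fs:g}"
        )
    wn_arg = float(wn[0]) if wn.size == 1 else wn
    sos = sps.butter(order, wn_arg, btype=kinds[kind], fs=fs, output="sos")
    if zero_phase:
        out = sps.sosfiltfilt(sos, s.values)
    else:
        out = sps.sosfilt(sos, s.values)
    return s.derive(out, "butterworth", kind=kind, cutoffs=wn.tolist(),
                    order=int(order), zero_phase=bool(zero_phase))


_RECTIFIERS = {
    "mean": lambda x: x - np.mean(x),          # DC/baseline removal
    "absolute": np.abs,
    "square_root": lambda x: np.sqrt(x ** 2),  # per-sample sqrt(x^2)
    "half_wave": lambda x: np.maximum(x, 0.0),
}


def rectify(s: SignalTrace, method: str = "absolute") -> SignalTrace:
    """EMG rectification: ``mean`` (subtract the mean), ``absolute``,
    ``square_root`` (per-sample sqrt of the square, numerically equal to the
    absolute value) or ``half_wave`` (negative samples clipped to 0)."""
    if method not in _RECTIFIERS:
        raise ValidationError(f"unknown rectification {method!r}")
    return s.derive(_RECTIFIERS[method](s.values), "rectify", method=method)


def _was_rectified(s: SignalTrace) -> bool:
    return any(m.get("op") == "rectify" for m in s.meta)


def envelope(s: SignalTrace, method: str = "lowpass", cutoff: float = 10.0,
             order: int = 4, window: int = 101, force: bool = False) -> SignalTrace:
    """Amplitude envelope of an oscillatory signal.

    Methods: ``lowpass`` (Butterworth low-pass of a rectified signal),
    ``hilbert`` (magnitude of the analytic signal), ``moving_mean`` and
    ``moving_rms`` (centered windows, shrinking at the edges).  The lowpass
    route expects a rectified input; pass ``force=True`` to override.
    """
    if method == "lowpass":
        if not _was_rectified(s) and not force:
            raise ContractError(
                "lowpass envelope expects a rectified signal; rectify first "
                "or pass force=True"
            )
        out = butterworth(s, "low", cutoff, order=order)
        out.meta[-1] = {"op": "envelope", "params": {"method": "lowpass",
                                                     "cutoff": float(cutoff),
                                                     "order": int(order)}}
        return out
    if method == "hilbert":
        _require_uniform(s, "hilbert envelope")
        vals = np.abs(sps.hilbert(s.values))
        return s.derive(vals, "envelope", method="hilbert")
    if method in ("moving_mean", "moving_rms"):
        if window % 2 == 0 or window < 3:
            raise ValidationError(f"window must be odd and >= 3, got {window}")
        half = window // 2
        n = s.n
        fn = (np.mean if method == "moving_mean"
              else lambda v: float(np.sqrt(np.mean(v ** 2))))
        vals = np.empty(n)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            vals[i] = fn(s.values[lo:hi])
        return s.derive(vals, "envelope", method=method, window=int(window))
    raise ValidationError(f"unknown envelope method {method!r}")


@dataclass
class SpectrumResult:
    """One-sided power spectrum; sum(power) equals the signal's mean square."""

    frequencies: np.ndarray
    power: np.ndarray
    n: int
    fs: float

    def peak_frequency(self) -> float:
        """Frequency of the largest non-DC bin."""
        return float(self.frequencies[1:][np.argmax(self.power[1:])])


def power_spectrum(s: SignalTrace) -> SpectrumResult:
    """One-sided periodogram, Parseval-normalized (power = |X_k|^2/n^2,
    interior bins doubled)."""
    fs = _require_uniform(s, "power_spectrum")
    if s.n < 8:
        raise ValidationError("power spectrum needs at least 8 samples")
    n = s.n
    X = np.fft.rfft(s.values)
    power = np.abs(X) ** 2 / n ** 2
    power[1:] *= 2.0
    if n % 2 == 0:  # Nyquist bin is unique, undo the doubling
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return SpectrumResult(freqs, power, n, fs)


@dataclass
class SpectrogramResult:
    times: np.ndarray           # window centers
    frequencies: np.ndarray
    power: np.ndarray           # (n_freqs, n_windows)
    window_len: int
    overlap_frac: float
    window_fn: str


def spectrogram(s: SignalTrace, window_len: int = 256, overlap_frac: float = 0.5,
                window_fn: str = "hann") -> SpectrogramResult:
    """Short-time Fourier magnitude-squared per window."""
    fs = _require_uniform(s, "spectrogram")
    if window_len > s.n:
        raise ValidationError(f"window_len {window_len} exceeds {s.n} samples")
    if not 0 <= overlap_frac < 1:
        raise ValidationError("overlap_frac must be in [0, 1)")
    if window_fn not in ("hann", "rect"):
        raise ValidationError(f"window_fn must be 'hann' or 'rect', got {window_fn!r}")
    win = "hann" if window_fn == "hann" else "boxcar"
    noverlap = int(round(window_len * overlap_frac))
    f, t, Sxx = sps.spectrogram(s.values, fs=fs, window=win, nperseg=window_len,
                                noverlap=noverlap, mode="psd")
    return SpectrogramResult(t + s.times[0], f, Sxx, window_len, overlap_frac,
                             window_fn)


def area_under_curve(s: SignalTrace, t0: float | None = None,
                     t1: float | None = None) -> float:
    """Trapezoidal integral of the signal over [t0, t1]."""
    if t0 is None:
        t0 = float(s.times[0])
    if t1 is None:
        t1 = float(s.times[-1])
    if not t0 < t1:
        raise ValidationError(f"need t0 < t1, got {t0} >= {t1}")
    if t0 < s.times[0] - 1e-12 or t1 > s.times[-1] + 1e-12:
        raise ValidationError("integration bounds outside the signal's range")
    # include exact endpoint values by interpolation
    ts = s.times[(s.times > t0) & (s.times < t1)]
    ts = np.concatenate([[t0], ts, [t1]])
    vs = np.interp(ts, s.times, s.values)
    return float(np.trapezoid(vs, ts))
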