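"""Signal/kinematics comparison machinery.

Auto- and cross-correlation (normalized cross-covariance), FFT phase lag
and amplitude ratio, scalar similarity metrics, band-constrained dynamic
time warping and cyclograms, plus harmonization of traces with different
sampling rates.

Conventions
-----------
* Correlation coefficients are the normalized cross-covariance
  r(l) = sum (a_t - a_bar)(b_{t+l} - b_bar) / sqrt(sum (a-a_bar)^2 sum (b-b_bar)^2);
  autocorrelation is the self case with r(0) = 1 exactly.
* The phase-lag reference frequency is the peak of the FIRST signal's
  spectrum (excluding DC) and is reused for the second signal so the phase
  difference is well defined; the lag is wrapped to (-180, 180] degrees.
* The amplitude ratio is second over first at that frequency.
* DTW uses cost |a_i - b_j|, the symmetric step set {(1,0),(0,1),(1,1)}
  and a Sakoe-Chiba band of a given half-width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .core import SignalTrace
from .errors import ContractError, ValidationError
from .kinematics import AngleSeries

__all__ = [
    "CorrelationResult",
    "PhaseAmplitudeResult",
    "DTWResult",
    "harmonize",
    "autocorrelation",
    "cross_correlation",
    "phase_amplitude",
    "similarity",
    "dtw",
    "cyclogram",
]


def _as_values(x) -> np.ndarray:
    if isinstance(x, SignalTrace):
        return np.asarray(x.values, dtype=float)
    if isinstance(x, AngleSeries):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def _fs_of(x, default=None):
    if isinstance(x, SignalTrace):
        return x.fs
    if isinstance(x, AngleSeries):
        dt = np.diff(x.times)
        return 1.0 / dt[0]
    return default


@dataclass
class HarmonizeReport:
    t0: float
    t1: float
    fs: float
    resampled_a: bool
    resampled_b: bool


def harmonize(a: SignalTrace, b: SignalTrace):
    """Trim two traces to their common time span and resample both
    (linearly) to the lower of the two rates, so lengths and rates match.

    Returns ``(a', b', report)``.
    """
    t0 = max(a.times[0], b.times[0])
    t1 = min(a.times[-1], b.times[-1])
    if not t0 < t1:
        raise ValidationError("signals do not overlap in time")
    fs = min(a.fs, b.fs)
    n_out = int(round((t1 - t0) * fs)) + 1
    new_t = t0 + np.arange(n_out, dtype=float) / fs
    new_t = new_t[new_t <= t1 + 1e-12 * max(1.0, abs(t1))]

    def _on(s: SignalTrace):
        if len(s.times) == len(new_t) and np.allclose(s.times, new_t, atol=1e-12):
            return s, False
        vals = np.interp(new_t, s.times, s.values)
        return s.derive(vals, "harmonize", times=new_t.copy(), fs=fs), True

    a2, ra = _on(a)
    b2, rb = _on(b)
    return a2, b2, HarmonizeReport(float(t0), float(t1), float(fs), ra, rb)


@dataclass
class CorrelationResult:
    """Normalized correlation as a function of lag (samples and time)."""

    lags: np.ndarray            # in samples, symmetric about 0
    lag_times: np.ndarray       # same lags in time units
    coefficients: np.ndarray

    @property
    def at_zero(self) -> float:
        return float(self.coefficients[len(self.coefficients) // 2])

    @property
    def peak_lag(self) -> int:
        return int(self.lags[np.argmax(self.coefficients)])

    @property
    def peak_coefficient(self) -> float:
        return float(np.max(self.coefficients))


def _xcorr(a: np.ndarray, b: np.ndarray, max_lag: int, dt: float) -> CorrelationResult:
    n = len(a)
    if len(b) != n:
        raise ValidationError("cross-correlation needs equal lengths (harmonize first)")
    if max_lag >= n:
        raise ValidationError(f"max_lag {max_lag} must be < n = {n}")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt(np.sum(da ** 2) * np.sum(db ** 2))
    if denom == 0:
        raise ValidationError("zero-variance input has no defined correlation")
    full = np.correlate(db, da, mode="full")  # index n-1+l == sum a_t b_{t+l}
    lags = np.arange(-max_lag, max_lag + 1)
    coeff = full[n - 1 - max_lag: n + max_lag] / denom
    return CorrelationResult(lags, lags * dt, coeff)


def cross_correlation(a, b, max_lag: int | None = None) -> CorrelationResult:
    """Normalized cross-covariance of two equal-length series.

    ``r(l)`` correlates ``a_t`` with ``b_{t+l}``; a positive peak lag means
    ``b`` leads ``a``.
    """
    va, vb = _as_values(a), _as_values(b)
    if max_lag is None:
        max_lag = len(va) - 1
    fs = _fs_of(a, None)
    dt = 1.0 / fs if fs else 1.0
    return _xcorr(va, vb, int(max_lag), dt)


def autocorrelation(s, max_lag: int | None = None) -> CorrelationResult:
    """Self cross-correlation; r(0) = 1 exactly, rhythmic signals show
    repeating maxima at multiples of their period."""
    return cross_correlation(s, s, max_lag)


@dataclass
class PhaseAmplitudeResult:
    peak_frequency: float
    phase_a_deg: float
    phase_b_deg: float
    phase_lag_deg: float        # wrapped to (-180, 180]
    amplitude_ratio: float      # |B(f*)| / |A(f*)|


def _wrap_deg(x: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    w = (x + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def phase_amplitude(a: SignalTrace, b: SignalTrace) -> PhaseAmplitudeResult:
    """Phase lag and amplitude ratio at the first signal's spectral peak.

    f* is the argmax of |FFT(a)| excluding DC; phases are the complex
    arguments of both FFTs at f*, the lag their wrapped difference
    (phase of a minus phase of b), and the ratio |FFT(b)|/|FFT(a)| there.
    """
    va, vb = _as_values(a), _as_values(b)
    if len(va) != len(vb):
        raise ValidationError("phase_amplitude needs equal lengths (harmonize first)")
    if len(va) < 8:
        raise ValidationError("phase_amplitude needs at least 8 samples")
    fs_a, fs_b = _fs_of(a, 1.0), _fs_of(b, 1.0)
    if fs_a and fs_b and not np.isclose(fs_a, fs_b, rtol=1e-9):
        raise ValidationError("phase_amplitude needs equal sampling rates")
    A = np.fft.rfft(va)
    B = np.fft.rfft(vb)
    mags = np.abs(A)
    if np.allclose(mags[1:], 0):
        raise ValidationError("flat reference spectrum: no peak frequency")
    k = 1 + int(np.argmax(mags[1:]))
    freqs = np.fft.rfftfreq(len(va), d=1.0 / fs_a)
    lag = _wrap_deg(np.rad2deg(np.angle(A[k]) - np.angle(B[k])))
    if np.abs(A[k]) == 0:
        raise ValidationError("reference FFT vanishes at the peak frequency")
    return PhaseAmplitudeResult(
        peak_frequency=float(freqs[k]),
        phase_a_deg=float(np.rad2deg(np.angle(A[k]))),
        phase_b_deg=float(np.rad2deg(np.angle(B[k]))),
        phase_lag_deg=float(lag),
        amplitude_ratio=float(np.abs(B[k]) / np.abs(A[k])),
    )


def similarity(a, b, metric: str = "pearson") -> float:
    """Scalar similarity between two equal-length series.

    Metrics: ``euclidean`` (distance), ``cosine``, ``pearson``,
    ``spearman``, ``kendall`` (tau-b, tie-corrected).
    """
    va, vb = _as_values(a), _as_values(b)
    if len(va) != len(vb):
        raise ValidationError("similarity needs equal lengths")
    if len(va) < 2:
        raise ValidationError("similarity needs at least 2 samples")
    if metric == "euclidean":
        return float(np.linalg.norm(va - vb))
    if metric == "cosine":
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            raise ValidationError("cosine similarity undefined for a zero vector")
        return float(np.dot(va, vb) / (na * nb))
    if metric in ("pearson", "spearman", "kendall"):
        if np.std(va) == 0 or np.std(vb) == 0:
            raise ValidationError(f"{metric} undefined for zero-variance input")
        if metric == "pearson":
            return float(sstats.pearsonr(va, vb).statistic)
        if metric == "spearman":
            return float(sstats.spearmanr(va, vb).statistic)
        return float(sstats.kendalltau(va, vb).statistic)
    raise ValidationError(f"unknown similarity metric {metric!r}")


@dataclass
class DTWResult:
    distance: float
    path: list                  # (i, j) pairs from (0,0) to (n-1, m-1)
    band: int


def dtw(a, b, band: int | None = None) -> DTWResult:
    """Dynamic time warping under a Sakoe-Chiba band.

    Cost is |a_i - b_j|; the cumulative distance is minimized over paths
    with steps (1,0), (0,1), (1,1) staying within |i - j| <= band.  The
    band bounds memory/computation; it must be at least |n - m| for a
    feasible path.
    """
    va, vb = _as_values(a), _as_values(b)
    n, m = len(va), len(vb)
    if band is None:
        band = max(n, m)
    band = int(band)
    if band < abs(n - m):
        raise ValidationError(
            f"band {band} infeasible: must be >= |n - m| = {abs(n - m)}"
        )
    INF = np.inf
    D = np.full((n + 1, m + 1), INF)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        j_lo = max(1, i - band)
        j_hi = min(m, i + band)
        for j in range(j_lo, j_hi + 1):
            c = abs(va[i - 1] - vb[j - 1])
            D[i, j] = c + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    dist = D[n, m]
    # traceback from (n, m) to (1, 1) in the padded matrix
    path = []
    i, j = n, m
    while i >= 1 and j >= 1:
        path.append((i - 1, j - 1))
        if i == 1 and j == 1:
            break
        steps = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
        costs = [D[p] for p in steps]
        i, j = steps[int(np.argmin(costs))]
    path.reverse()
    return DTWResult(float(dist), path, band)


def cyclogram(angle1: AngleSeries, angle2: AngleSeries):
    """Ordered (theta1(t), theta2(t)) pairs for angle-angle loop plots."""
    if len(angle1.values) != len(angle2.values) or not np.allclose(
            angle1.times, angle2.times, atol=1e-9):
        raise ContractError("cyclogram needs a common time base (harmonize first)")
    return np.column_stack([angle1.values, angle2.values])
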