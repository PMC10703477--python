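import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from motionlab import correlation as C
from motionlab import synthgen
from motionlab.core import SignalTrace
from motionlab.errors import ContractError, ValidationError
from motionlab.kinematics import AngleSeries


def _trace(values, fs=100.0, label="s", t0=0.0):
    values = np.asarray(values, dtype=float)
    t = t0 + np.arange(len(values)) / fs
    return SignalTrace(label, t, values)


def _dtw_oracle(a, b):
    """Textbook unconstrained DTW distance by full-matrix DP."""
    n, m = len(a), len(b)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = abs(a[i - 1] - b[j - 1]) + min(
                D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    return D[n, m]


class TestHarmonize:
    def test_mixed_rates_downsample_to_lower(self):
        a = _trace(np.sin(np.arange(1001) / 100), fs=100.0)
        b = _trace(np.cos(np.arange(1201) / 120), fs=120.0)
        a2, b2, rep = C.harmonize(a, b)
        assert a2.n == b2.n == 1001
        assert rep.fs == 100.0

    def test_identical_traces_untouched(self):
        a = _trace(np.sin(np.arange(100)))
        a2, b2, rep = C.harmonize(a, a.copy())
        assert not rep.resampled_a and not rep.resampled_b
        assert np.array_equal(a2.values, a.values)

    def test_disjoint_ranges_rejected(self):
        a = _trace(np.zeros(50) + 1, t0=0.0)
        b = _trace(np.zeros(50) + 1, t0=2.0)
        with pytest.raises(ValidationError):
            C.harmonize(a, b)


class TestCorrelation:
    def test_autocorrelation_is_one_at_zero_lag(self):
        s = _trace(np.random.default_rng(3).normal(size=256))
        res = C.autocorrelation(s, 50)
        assert res.at_zero == pytest.approx(1.0, abs=1e-12)

    def test_sine_autocorrelation_peaks_at_period_multiples(self):
        fs, f = 100.0, 2.0
        s = _trace(np.sin(2 * np.pi * f * np.arange(1000) / fs), fs=fs)
        res = C.autocorrelation(s, 200)
        period_samples = int(fs / f)
        center = len(res.lags) // 2
        k = center + period_samples
        assert res.coefficients[k] > res.coefficients[k - 10]
        assert res.coefficients[k] > res.coefficients[k + 10]
        # decaying envelope: the lag-T peak is below the lag-0 peak
        assert res.coefficients[k] < res.at_zero

    def test_antiphase_pair_negative_at_zero_lag(self, antiphase_bundle):
        res = C.cross_correlation(antiphase_bundle.signals["a"],
                                  antiphase_bundle.signals["b"], 100)
        assert res.at_zero == pytest.approx(-1.0, abs=1e-6)

    def test_cross_of_self_equals_autocorrelation(self):
        s = _trace(np.random.default_rng(4).normal(size=128))
        auto = C.autocorrelation(s, 30)
        cross = C.cross_correlation(s, s, 30)
        assert np.array_equal(auto.coefficients, cross.coefficients)

    def test_argument_swap_mirrors_lags(self):
        rng = np.random.default_rng(5)
        a = _trace(rng.normal(size=64), label="a")
        b = _trace(rng.normal(size=64), label="b")
        ab = C.cross_correlation(a, b, 20)
        ba = C.cross_correlation(b, a, 20)
        assert np.allclose(ab.coefficients, ba.coefficients[::-1], atol=1e-12)

    def test_coefficients_bounded(self):
        rng = np.random.default_rng(6)
        res = C.cross_correlation(_trace(rng.normal(size=200)),
                                  _trace(rng.normal(size=200)), 150)
        assert np.all(np.abs(res.coefficients) <= 1 + 1e-9)

    def test_delayed_copy_peaks_at_the_delay(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=300)
        a = _trace(base[:-10])
        b = _trace(base[10:])   # b(t) == a(t + 10 samples): a leads
        res = C.cross_correlation(a, b, 50)
        assert abs(res.peak_lag) == 10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            C.autocorrelation(_trace(np.ones(32)), 4)


class TestPhaseAmplitude:
    def test_antiphase_defaults_ratio_2_lag_180(self, antiphase_bundle):
        pa = C.phase_amplitude(antiphase_bundle.signals["a"],
                               antiphase_bundle.signals["b"])
        assert pa.amplitude_ratio == pytest.approx(2.0, abs=1e-3)
        assert abs(pa.phase_lag_deg) == pytest.approx(180.0, abs=0.5)

    def test_identical_signals_ratio_1_lag_0(self, antiphase_bundle):
        a = antiphase_bundle.signals["a"]
        pa = C.phase_amplitude(a, a.copy())
        assert pa.amplitude_ratio == pytest.approx(1.0)
        assert pa.phase_lag_deg == pytest.approx(0.0, abs=1e-9)

    def test_quarter_period_delay_gives_90_degrees(self):
        fs, f = 1000.0, 5.0
        t = np.arange(int(fs * 2)) / fs
        a = SignalTrace("a", t, np.sin(2 * np.pi * f * t))
        b = SignalTrace("b", t, np.sin(2 * np.pi * f * (t - 1 / (4 * f))))
        pa = C.phase_amplitude(a, b)
        assert abs(pa.phase_lag_deg) == pytest.approx(90.0, abs=1.0)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scaled_copy_ratio_k_lag_0(self, k):
        t = np.arange(256) / 64.0
        a = SignalTrace("a", t, np.sin(2 * np.pi * 2 * t))
        b = SignalTrace("b", t, k * a.values)
        pa = C.phase_amplitude(a, b)
        assert pa.amplitude_ratio == pytest.approx(k, rel=1e-6)
        assert pa.phase_lag_deg == pytest.approx(0.0, abs=1e-6)

    def test_flat_reference_rejected(self):
        t = np.arange(64) / 8.0
        flat = SignalTrace("flat", t, np.full(64, 2.0))
        with pytest.raises(ValidationError):
            C.phase_amplitude(flat, flat)


class TestSimilarity:
    def test_identical_series(self):
        a = _trace([1.0, 2.0, 3.0, 4.0])
        assert C.similarity(a, a, "euclidean") == 0.0
        assert C.similarity(a, a, "cosine") == pytest.approx(1.0)
        assert C.similarity(a, a, "pearson") == pytest.approx(1.0)

    def test_scaled_copy(self):
        a = np.array([1.0, 2.0, 3.0])
        assert C.similarity(a, 2 * a, "cosine") == pytest.approx(1.0)
        assert C.similarity(a, 2 * a, "pearson") == pytest.approx(1.0)
        assert C.similarity(a, 2 * a, "euclidean") == pytest.approx(np.linalg.norm(a))

    def test_monotone_decreasing_rank_metrics(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        b = -np.exp(a)  # strictly decreasing in a, nonlinear
        assert C.similarity(a, b, "spearman") == pytest.approx(-1.0)
        assert C.similarity(a, b, "kendall") == pytest.approx(-1.0)

    def test_zero_variance_rank_metrics_rejected(self):
        with pytest.raises(ValidationError):
            C.similarity(np.ones(5), np.arange(5.0), "pearson")


class TestDTW:
    def test_self_distance_zero_diagonal_path(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        res = C.dtw(x, x, band=4)
        assert res.distance == 0.0
        assert res.path == [(i, i) for i in range(4)]

    def test_duplicate_sample_absorbed_at_zero_cost(self):
        res = C.dtw([1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 3.0], band=2)
        assert res.distance == 0.0

    def test_matches_exhaustive_oracle_on_random_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            res = C.dtw(a, b, band=10)
            assert res.distance == pytest.approx(_dtw_oracle(a, b), abs=1e-12)

    def test_distance_bounded_by_manhattan_alignment(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        assert C.dtw(a, b).distance <= np.sum(np.abs(a - b)) + 1e-12

    def test_path_endpoints_and_steps_within_band(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=12), rng.normal(size=9)
        res = C.dtw(a, b, band=5)
        assert res.path[0] == (0, 0) and res.path[-1] == (11, 8)
        for (i0, j0), (i1, j1) in zip(res.path[:-1], res.path[1:]):
            assert (i1 - i0, j1 - j0) in {(1, 0), (0, 1), (1, 1)}
            assert abs(i1 - j1) <= 5

    def test_infeasible_band_rejected(self):
        with pytest.raises(ValidationError, match="band"):
            C.dtw(np.zeros(10), np.zeros(3), band=2)


class TestCyclogram:
    def test_identity_diagonal(self):
        t = np.arange(10.0)
        ang = AngleSeries("A", "B", "C", t, np.linspace(10, 70, 10))
        pairs = C.cyclogram(ang, ang)
        assert np.array_equal(pairs[:, 0], pairs[:, 1])

    def test_sine_vs_cosine_traces_a_circle(self):
        t = np.arange(0, 1, 0.001)
        th1 = AngleSeries("A", "B", "C", t, 90 + 30 * np.sin(2 * np.pi * t))
        th2 = AngleSeries("D", "E", "F", t, 90 + 30 * np.cos(2 * np.pi * t))
        pairs = C.cyclogram(th1, th2)
        r = np.hypot(pairs[:, 0] - 90, pairs[:, 1] - 90)
        assert np.max(np.abs(r - 30)) < 0.3  # within 1% of the radius

    def test_mismatched_bases_rejected(self):
        t = np.arange(10.0)
        a = AngleSeries("A", "B", "C", t, t)
        b = AngleSeries("A", "B", "C", t[:5], t[:5])
        with pytest.raises(ContractError):
            C.cyclogram(a, b)
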