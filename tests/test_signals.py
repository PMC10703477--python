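import numpy as np
import pytest

from motionlab import signals as S
from motionlab import synthgen
from motionlab.core import SignalTrace
from motionlab.errors import ContractError, ValidationError


def _sine(f=5.0, fs=1000.0, dur=2.0, amp=1.0):
    t = np.arange(int(fs * dur)) / fs
    return SignalTrace(f"sine{f:g}", t, amp * np.sin(2 * np.pi * f * t))


class TestTimeBase:
    def test_set_time_base_builds_uniform_clock(self):
        s = SignalTrace("s", [0, 1, 2, 3, 4], np.zeros(5))
        out = S.set_time_base(s, 100.0)
        assert np.allclose(out.times, [0, 0.01, 0.02, 0.03, 0.04])
        assert np.array_equal(out.values, s.values)

    def test_idempotent(self):
        s = S.set_time_base(SignalTrace("s", [0, 1, 2], np.ones(3)), 50.0)
        again = S.set_time_base(s, 50.0)
        assert np.array_equal(s.times, again.times)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValidationError):
            S.set_time_base(SignalTrace("s", [0, 1], [0, 0]), 0.0)


class TestResample:
    def test_halving_rate_halves_samples(self):
        s = _sine(fs=100.0, dur=1.0)  # 100 samples, span 0..0.99
        t = np.arange(101) / 100.0
        s = SignalTrace("s", t, np.sin(t))
        out = S.resample(s, 50.0)
        assert out.n == 51
        assert out.times[0] == s.times[0] and out.times[-1] == s.times[-1]

    def test_same_rate_is_identity(self):
        s = _sine()
        out = S.resample(s, 1000.0)
        assert np.allclose(out.values, s.values, atol=1e-12)

    @pytest.mark.parametrize("method", ["linear", "cubic"])
    def test_constant_signal_stays_constant(self, method):
        t = np.arange(11) / 10.0
        s = SignalTrace("s", t, np.full(11, 3.3))
        assert np.allclose(S.resample(s, 7.0, method).values, 3.3)

    def test_nonuniform_input_rejected_with_guidance(self):
        s = SignalTrace("s", [0.0, 0.1, 0.5], [0, 1, 2])
        with pytest.raises(ContractError, match="set_time_base"):
            S.resample(s, 10.0)


class TestButterworth:
    def test_bandstop_removes_tone(self):
        s = _sine(30.0, 1000.0, 10.0)
        rms_before = np.sqrt(np.mean(s.values ** 2))
        out = S.butterworth(s, "stop", (29.0, 31.0), order=4)
        rms_after = np.sqrt(np.mean(out.values ** 2))
        assert rms_after < 0.1 * rms_before

    def test_passband_identity_within_1pct(self):
        s = _sine(5.0, 1000.0, 4.0)
        out = S.butterworth(s, "low", 100.0)
        core = slice(200, -200)  # exclude edges
        err = np.sqrt(np.mean((out.values[core] - s.values[core]) ** 2))
        assert err < 0.01 * np.sqrt(np.mean(s.values[core] ** 2))

    def test_zero_phase_has_no_group_delay(self):
        s = _sine(10.0, 1000.0, 2.0)
        out = S.butterworth(s, "low", 50.0, zero_phase=True)
        xc = np.correlate(out.values - out.values.mean(),
                          s.values - s.values.mean(), mode="full")
        assert np.argmax(xc) == s.n - 1  # peak at zero lag

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            S.butterworth(_sine(), "low", 600.0)


class TestRectify:
    @pytest.mark.parametrize("method, data, expected", [
        ("half_wave", [-1, 2, -3], [0, 2, 0]),
        ("absolute", [-1, 2, -3], [1, 2, 3]),
        ("mean", [1, 2, 3], [-1, 0, 1]),
    ])
    def test_definitions(self, method, data, expected):
        s = SignalTrace("s", np.arange(len(data), dtype=float), data)
        assert np.allclose(S.rectify(s, method).values, expected)

    def test_square_root_equals_absolute(self):
        s = _sine()
        assert np.allclose(S.rectify(s, "square_root").values,
                           S.rectify(s, "absolute").values)

    def test_history_appends_one_entry(self):
        s = _sine()
        out = S.rectify(s, "half_wave")
        assert len(out.meta) == len(s.meta) + 1


class TestEnvelope:
    def test_hilbert_of_unit_sine_is_one(self):
        s = _sine(5.0, 1000.0, 2.0)
        env = S.envelope(s, "hilbert")
        margin = s.n // 20
        assert np.max(np.abs(env.values[margin:-margin] - 1.0)) < 0.01

    def test_moving_rms_midpoint(self):
        s = SignalTrace("s", [0.0, 1.0, 2.0], [0.0, 3.0, 0.0])
        env = S.envelope(s, "moving_rms", window=3)
        assert env.values[1] == pytest.approx(np.sqrt(3.0))

    def test_moving_rms_of_stationary_sine_is_amp_over_sqrt2(self):
        s = _sine(10.0, 1000.0, 2.0, amp=2.0)
        env = S.envelope(s, "moving_rms", window=201)
        interior = env.values[300:-300]
        assert np.allclose(interior, 2.0 / np.sqrt(2.0), rtol=0.01)

    def test_lowpass_requires_rectified_history(self):
        s = _sine()
        with pytest.raises(ContractError):
            S.envelope(s, "lowpass", cutoff=5.0)
        rect = S.rectify(s, "absolute")
        env = S.envelope(rect, "lowpass", cutoff=5.0)
        assert env.meta[-1]["op"] == "envelope"

    def test_constant_signal_fixed_point(self):
        s = SignalTrace("s", np.arange(10.0), np.full(10, 4.0))
        assert np.allclose(S.envelope(s, "moving_mean", window=3).values, 4.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            S.envelope(_sine(), "moving_rms", window=4)


class TestSpectrum:
    def test_single_tone_peak_within_one_bin(self):
        s = _sine(25.0, 1000.0, 10.0)
        spec = S.power_spectrum(s)
        assert spec.peak_frequency() == pytest.approx(25.0, abs=0.1)

    def test_three_tone_mixture_has_three_local_maxima(self, mixture_bundle):
        spec = S.power_spectrum(mixture_bundle.signals["mixture"])
        for f in (25.0, 30.0, 35.0):
            k = int(round(f / (spec.fs / spec.n)))
            assert spec.power[k] > spec.power[k - 2]
            assert spec.power[k] > spec.power[k + 2]

    def test_notch_filters_silence_stopped_bins(self, mixture_bundle):
        s = mixture_bundle.signals["mixture"]
        s = S.butterworth(s, "stop", (29.0, 31.0), order=4)
        s = S.butterworth(s, "stop", (34.0, 36.0), order=4)
        spec = S.power_spectrum(s)
        df = spec.fs / spec.n
        p25 = spec.power[int(round(25 / df))]
        assert spec.peak_frequency() == pytest.approx(25.0, abs=0.1)
        assert spec.power[int(round(30 / df))] < 0.01 * p25
        assert spec.power[int(round(35 / df))] < 0.01 * p25

    @pytest.mark.parametrize("make", [
        lambda: _sine(7.0, 200.0, 3.0),
        lambda: SignalTrace("noise", np.arange(512) / 64.0,
                            np.random.default_rng(1).normal(size=512)),
        lambda: SignalTrace("dc", np.arange(64) / 8.0, np.full(64, 2.0)),
    ])
    def test_parseval_holds(self, make):
        s = make()
        spec = S.power_spectrum(s)
        ms = np.mean(s.values ** 2)
        assert spec.power.sum() == pytest.approx(ms, rel=1e-6)

    def test_nonuniform_rejected(self):
        s = SignalTrace("s", np.cumsum(np.random.default_rng(2).uniform(0.5, 1.5, 32)),
                        np.zeros(32))
        with pytest.raises(ContractError):
            S.power_spectrum(s)


class TestSpectrogram:
    def test_stationary_tone_peaks_in_every_column(self):
        s = _sine(25.0, 200.0, 5.0)
        sg = S.spectrogram(s, window_len=128, overlap_frac=0.5)
        rows = np.argmax(sg.power, axis=0)
        assert np.allclose(sg.frequencies[rows], 25.0, atol=2.0)

    def test_frequency_step_is_visible_in_time(self):
        fs = 200.0
        t = np.arange(int(fs * 4)) / fs
        v = np.where(t < 2.0, np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 40 * t))
        sg = S.spectrogram(SignalTrace("step", t, v), 128, 0.5)
        early = sg.frequencies[np.argmax(sg.power[:, 0])]
        late = sg.frequencies[np.argmax(sg.power[:, -1])]
        assert early < 20 < late

    def test_column_count_formula(self):
        s = SignalTrace("s", np.arange(1024) / 256.0,
                        np.sin(np.arange(1024) * 0.3))
        sg = S.spectrogram(s, window_len=256, overlap_frac=0.5)
        assert sg.power.shape[1] == 7

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValidationError):
            S.spectrogram(_sine(dur=0.1), window_len=4096)


class TestAUC:
    def test_constant_one_over_two_units(self):
        s = SignalTrace("s", [0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert S.area_under_curve(s, 0, 2) == pytest.approx(2.0)

    def test_full_period_sine_integrates_to_zero(self):
        s = _sine(5.0, 1000.0, 1.0)
        assert abs(S.area_under_curve(s, 0.0, 0.999)) < 1e-3

    def test_triangle_area(self):
        s = SignalTrace("s", [0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert S.area_under_curve(s) == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        s = SignalTrace("s", [0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValidationError):
            S.area_under_curve(s, 0.0, 5.0)
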