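"""Conditioning chain: referencing, filters, features, SNR, spectra."""

import numpy as np
import pytest
from scipy import signal as sps

from myospc.conditioning import (
    FilterSpec,
    StreamingConditioner,
    amplitude_spectrum,
    apply_bandpass,
    apply_comb,
    common_mean_reference,
    condition,
    design_bandpass,
    design_comb,
    estimate_snr,
    rms_windows,
    window_samples,
)
from myospc.protocols import make_rest_protocol
from myospc.synth import synthesize_session

FS = 2048.0


def _sine(f, dur=4.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * f * t)


def _tail_rms(x, fs=FS, skip=1.0):
    return np.sqrt(np.mean(x[int(skip * fs):] ** 2))


class TestCommonMeanReference:
    def test_identical_channels_cancel(self):
        x = np.tile(np.sin(np.linspace(0, 10, 500)), (2, 1))
        assert np.allclose(common_mean_reference(x, [[0, 1]]), 0.0)

    def test_zero_sum_group_unchanged(self, rng):
        a = rng.standard_normal((2, 300))
        x = np.vstack([a, -a.sum(axis=0, keepdims=True)])
        assert np.allclose(common_mean_reference(x, [[0, 1, 2]]), x)

    def test_mean_subtraction_example(self):
        x = np.array([[1.0], [2.0], [3.0]])
        assert np.allclose(common_mean_reference(x, [[0, 1, 2]]),
                           [[-1.0], [0.0], [1.0]])

    def test_groups_are_independent(self, rng):
        x = rng.standard_normal((4, 200))
        both = common_mean_reference(x, [[0, 1], [2, 3]])
        first = common_mean_reference(x[:2], [[0, 1]])
        assert np.allclose(both[:2], first)

    def test_singleton_group_rejected(self, rng):
        with pytest.raises(ValueError):
            common_mean_reference(rng.standard_normal((3, 50)), [[0], [1, 2]])

    def test_non_partition_rejected(self, rng):
        with pytest.raises(ValueError):
            common_mean_reference(rng.standard_normal((3, 50)), [[0, 1]])


class TestBandpass:
    def test_midband_tone_preserved(self):
        # frequency-response oracle and time-domain path must agree
        w, h = sps.sosfreqz(design_bandpass(), worN=[100.0], fs=FS)
        assert abs(h[0]) == pytest.approx(1.0, abs=0.05)
        y = apply_bandpass(_sine(100.0))
        assert _tail_rms(y) * np.sqrt(2) == pytest.approx(1.0, abs=0.05)

    def test_low_frequency_attenuated_20db(self):
        w, h = sps.sosfreqz(design_bandpass(), worN=[5.0], fs=FS)
        assert 20 * np.log10(abs(h[0])) < -20
        y = apply_bandpass(_sine(5.0))
        assert _tail_rms(y) * np.sqrt(2) < 0.1

    def test_zero_in_zero_out(self):
        assert np.allclose(apply_bandpass(np.zeros(1000)), 0.0)

    def test_band_edge_validation(self):
        with pytest.raises(ValueError):
            design_bandpass(30.0, 1100.0, 4, FS)
        with pytest.raises(ValueError):
            FilterSpec("bandpass", band=(30.0, 1100.0))


class TestComb:
    def test_powerline_tone_notched_20db(self):
        y = apply_comb(_sine(50.0))
        assert 20 * np.log10(_tail_rms(y, skip=2.0) * np.sqrt(2) + 1e-12) < -20

    @pytest.mark.parametrize("harmonic", [2, 5, 10])
    def test_harmonics_notched(self, harmonic):
        y = apply_comb(_sine(50.0 * harmonic))
        assert _tail_rms(y, skip=2.0) * np.sqrt(2) < 0.1

    def test_off_notch_tone_preserved(self):
        y = apply_comb(_sine(73.0))
        assert _tail_rms(y) * np.sqrt(2) == pytest.approx(1.0, abs=0.05)

    def test_notch_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_comb(50.0, 25, 35.0, FS)


class TestRmsWindows:
    def test_constant_signal_gives_constant_features(self):
        fm = rms_windows(np.full((1, 4096), -3.0))
        assert np.allclose(fm.values, 3.0)

    def test_window_count_for_one_second(self):
        fm = rms_windows(np.zeros((2, 2048)))
        assert window_samples() == (410, 82)
        assert fm.n_windows == (2048 - 410) // 82 + 1 == 20

    def test_square_wave_rms_is_amplitude(self):
        x = 2.0 * (-1.0) ** np.arange(4096)
        assert np.allclose(rms_windows(x[None]).values, 2.0)

    def test_sign_flip_invariance(self, rng):
        x = rng.standard_normal((3, 3000))
        assert np.allclose(rms_windows(x).values, rms_windows(-x).values)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            rms_windows(np.zeros((1, 100)))


class TestSnr:
    def test_direct_ratio_on_constructed_signal(self):
        fs = FS
        x = np.zeros(int(20 * fs))
        x[: int(5 * fs)] = 180.0 * (-1.0) ** np.arange(int(5 * fs))
        x[int(5 * fs):] = 15.0 * (-1.0) ** np.arange(int(15 * fs))
        snr = estimate_snr(x[None], fs, [(0.0, 5.0)], [(6.0, 19.0)])
        assert snr[0] == pytest.approx(12.0, rel=1e-6)

    def test_identical_statistics_give_unit_snr(self, rng):
        x = rng.standard_normal(int(20 * FS))[None]
        snr = estimate_snr(x, FS, [(0.0, 5.0)], [(10.0, 15.0)])
        assert snr[0] == pytest.approx(1.0, abs=0.1)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((2, int(16 * FS)))
        args = (FS, [(0.0, 4.0)], [(8.0, 12.0)])
        assert np.allclose(estimate_snr(x, *args), estimate_snr(7.3 * x, *args))

    def test_zero_rest_is_an_error(self):
        x = np.zeros((1, int(10 * FS)))
        x[0, : int(4 * FS)] = 1.0
        with pytest.raises(ZeroDivisionError):
            estimate_snr(x, FS, [(0.0, 4.0)], [(5.0, 9.0)])


class TestAmplitudeSpectrum:
    def test_tone_peaks_at_its_frequency(self):
        f, amp = amplitude_spectrum(_sine(50.0, dur=8.0), FS)
        assert abs(f[np.argmax(amp)] - 50.0) <= f[1] - f[0]

    def test_white_noise_is_flat_across_bands(self, rng):
        x = rng.standard_normal(int(60 * FS))
        f, amp = amplitude_spectrum(x, FS)
        p = amp ** 2
        bands = [np.sum(p[(f >= a) & (f < a + 200)]) for a in (100, 400, 700)]
        assert max(bands) / min(bands) < 1.1

    def test_parseval_consistency(self, rng):
        x = rng.standard_normal(int(30 * FS))
        _, amp = amplitude_spectrum(x, FS)
        assert np.sum(amp ** 2) == pytest.approx(np.var(x), rel=0.05)

    def test_zero_signal_zero_spectrum(self):
        _, amp = amplitude_spectrum(np.zeros(8192), FS)
        assert np.allclose(amp, 0.0)


class TestChain:
    def test_full_chain_is_linear(self, rng):
        x = rng.standard_normal((4, 4096))
        y = rng.standard_normal((4, 4096))
        groups = [[0, 1], [2, 3]]
        lhs = condition(2.5 * x - 1.5 * y, groups=groups)
        rhs = 2.5 * condition(x, groups=groups) - 1.5 * condition(y, groups=groups)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_dry_baseline_cleaned_below_20_uv(self):
        ses = synthesize_session(make_rest_protocol(10.0), "dry", rng_seed=13)
        raw = np.sqrt(np.mean(ses.signal[:, 1024:] ** 2))
        clean = condition(ses.signal, ses.fs, groups=ses.type_groups())
        out = np.sqrt(np.mean(clean[:, 1024:] ** 2, axis=1))
        assert raw == pytest.approx(500.0, rel=0.15)
        assert np.all(out < 20.0)

    def test_streaming_matches_offline(self, rng):
        x = rng.standard_normal((4, 4096))
        groups = [[0, 1, 2, 3]]
        offline = condition(x, groups=groups)
        sc = StreamingConditioner(4, FS, groups=groups)
        online = np.concatenate([sc.process(x[:, :1000]),
                                 sc.process(x[:, 1000:])], axis=1)
        assert np.allclose(offline, online)
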