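"""The synthetic EMG generator: calibration, noise, spectra, artifacts."""

import numpy as np
import pytest

from myospc.conditioning import amplitude_spectrum, condition, _centered_rms
from myospc.protocols import make_force_protocol, make_rest_protocol, mvc_to_amplitude
from myospc.synth import (
    EmgPlant,
    NoiseConfig,
    add_vibration,
    default_mixing,
    synthesize_session,
)


def _raw_rms(session, skip_s=0.5):
    x = session.signal[:, int(skip_s * session.fs):]
    return np.sqrt(np.mean(x ** 2, axis=1))


class TestDeterminism:
    def test_same_seed_gives_identical_sessions(self):
        p = make_rest_protocol(2.0)
        a = synthesize_session(p, "dry", rng_seed=5)
        b = synthesize_session(p, "dry", rng_seed=5)
        assert np.array_equal(a.signal, b.signal)

    def test_different_seeds_differ(self):
        p = make_rest_protocol(2.0)
        a = synthesize_session(p, "dry", rng_seed=5)
        b = synthesize_session(p, "dry", rng_seed=6)
        assert not np.array_equal(a.signal, b.signal)

    def test_streaming_plant_matches_itself_across_block_sizes(self):
        act = np.zeros((4, 2048))
        one = EmgPlant("implant", seed=3).emit(act)
        plant = EmgPlant("implant", seed=3)
        blocks = np.concatenate([plant.emit(act[:, :1024]),
                                 plant.emit(act[:, 1024:])], axis=1)
        assert np.allclose(one, blocks)


class TestBaselineNoise:
    def test_dry_raw_rest_rms_near_500_uv(self):
        ses = synthesize_session(make_rest_protocol(20.0), "dry", rng_seed=11)
        rms = np.sqrt(np.mean(_raw_rms(ses) ** 2))
        assert rms == pytest.approx(500.0, rel=0.15)

    def test_noise_disabled_rest_is_silent(self):
        ses = synthesize_session(make_rest_protocol(2.0), "implant",
                                 noise=NoiseConfig.disabled(), rng_seed=1)
        assert np.max(np.abs(ses.signal[:, 1024:])) < 1e-9

    def test_noise_ordering_follows_impedance(self):
        rms = {}
        for kind in ("implant", "gelled", "dry"):
            ses = synthesize_session(make_rest_protocol(5.0), kind, rng_seed=2)
            rms[kind] = np.mean(_raw_rms(ses))
        assert rms["implant"] < rms["gelled"] < rms["dry"]


class TestAmplitudeCalibration:
    @pytest.mark.parametrize("level", [10.0, 50.0])
    def test_conditioned_contraction_rms_matches_calibration(self, level):
        proto = make_force_protocol([level], reps_per_level=10)
        ses = synthesize_session(proto, "implant", rng_seed=21)
        cond = condition(ses.signal, ses.fs, groups=ses.type_groups())
        rms = _centered_rms(cond, ses.fs, ses.intervals("contraction"), 3.0)
        assert rms[1] == pytest.approx(mvc_to_amplitude(level), rel=0.10)

    def test_generator_core_is_linear_in_activation(self):
        # doubling all activations must double the noise-free EMG RMS
        act = np.zeros((4, 4096))
        act[1, 2048:] = 20.0
        lo = EmgPlant("implant", noise=NoiseConfig.disabled(), seed=9).emit(act)
        hi = EmgPlant("implant", noise=NoiseConfig.disabled(), seed=9).emit(
            np.where(act > 0, 40.0, 0.0))
        r = lambda x: np.sqrt(np.mean(x[1, 3072:] ** 2))
        amp_ratio = mvc_to_amplitude(40.0) / mvc_to_amplitude(20.0)
        assert r(hi) / r(lo) == pytest.approx(amp_ratio, rel=1e-6)


class TestSpectra:
    def test_dry_rest_spectrum_dominated_by_powerline_harmonics(self):
        ses = synthesize_session(make_rest_protocol(10.0), "dry", rng_seed=31)
        f, amp = amplitude_spectrum(ses.signal[0], ses.fs)
        df = f[1] - f[0]
        in_harm = np.zeros(f.size, dtype=bool)
        for k in range(1, 11):
            in_harm |= np.abs(f - 50.0 * k) <= 2 * df
        assert np.sum(amp[in_harm] ** 2) > 0.9 * np.sum(amp ** 2)
        # fundamental is the single dominant peak
        assert abs(f[np.argmax(amp)] - 50.0) <= df

    def test_emg_energy_concentrated_in_band(self):
        act = np.full((4, 8 * 2048), 30.0)
        sig = EmgPlant("implant", noise=NoiseConfig.disabled(), seed=4).emit(act)
        f, amp = amplitude_spectrum(sig[1, 2048:], 2048.0)
        band = (f >= 20) & (f <= 500)
        assert np.sum(amp[band] ** 2) > 0.95 * np.sum(amp ** 2)


@pytest.fixture(scope="module")
def vib_session():
    base = synthesize_session(make_rest_protocol(65.0), "dry", rng_seed=41)
    return base, add_vibration(base, rng_seed=42)


class TestVibration:
    def test_filtered_artifact_exceeds_moderate_contraction_amplitude(self, vib_session):
        _, ses = vib_session
        cond = condition(ses.signal, ses.fs, groups=ses.type_groups())
        on_rms = _centered_rms(cond, ses.fs, ses.intervals("vibration"), 3.0)
        assert np.all(on_rms > mvc_to_amplitude(30.0))

    def test_artifact_spectrum_peaks_below_20_hz(self, vib_session):
        base, ses = vib_session
        art = ses.signal - base.signal
        on = ses.intervals("vibration")[0]
        seg = art[0, int(on[0] * ses.fs): int(on[1] * ses.fs)]
        f, amp = amplitude_spectrum(seg, ses.fs, nperseg=2048)
        assert f[np.argmax(amp)] < 20.0
        assert np.sum(amp[f <= 100] ** 2) > 0.95 * np.sum(amp ** 2)

    def test_off_phases_and_zero_coupling_unchanged(self, vib_session):
        base, ses = vib_session
        art = ses.signal - base.signal
        for a, b in ses.intervals("vibration"):
            # 0.5 s guard after each on-phase for the filter tail
            i0 = int((b + 0.5) * ses.fs)
            i1 = int((b + 14.0) * ses.fs)
            if i1 <= art.shape[1]:
                assert np.max(np.abs(art[:, i0:i1])) < 1.0
        zeroed = add_vibration(base, couplings=np.zeros(4), rng_seed=42)
        assert np.array_equal(zeroed.signal, base.signal)


class TestValidation:
    def test_mixing_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            EmgPlant("implant", mixing=default_mixing(3))

    def test_activation_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            EmgPlant("implant", seed=0).emit(np.zeros((3, 10)))
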