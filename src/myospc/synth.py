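"""Synthetic multichannel EMG generation.

The generator emulates the acquisition setup of the electrode comparison
study: four channels per electrode type sampled at 2048 Hz through a
hardware chain with a 3 Hz high-pass (DC removal) and a 900 Hz 4th-order
anti-aliasing low-pass.

The EMG core is the standard amplitude-modulated surrogate: per virtual
muscle, Gaussian noise shaped by a fixed band-pass prototype (20–450 Hz)
is modulated by an amplitude envelope derived from the cue protocol and
mixed into channels. Four virtual muscles (wrist flexor, extensor,
radial and ulnar deviator) each project dominantly onto one channel with
small crosstalk. The envelope is calibrated so that the contraction RMS
measured *after* the full conditioning chain (referencing + band-pass +
comb) matches the %MVC-to-amplitude curve.

Electrode-dependent noise: a powerline series at 50 Hz and harmonics
(amplitude tied to the electrode impedance; shared phase within an
electrode-type group so group referencing cancels most of it) plus a
per-channel broadband noise floor. Mechanical vibration artifacts
(0–100 Hz band, spectral peak below 20 Hz, 15 s on / 15 s off) can be
injected with per-type couplings.

All randomness flows from a single integer seed; identical inputs give
bit-identical sessions. ``EmgPlant`` exposes the same generator as a
streaming block source for the closed-loop task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .conditioning import software_chain_sos
from .electrodes import (
    ElectrodeModel,
    MixingPerturbation,
    donning_multiplier,
    load_preset,
)
from .protocols import CueProtocol, mvc_to_amplitude

__all__ = [
    "FS",
    "MUSCLES",
    "NoiseConfig",
    "Event",
    "RecordingSession",
    "default_mixing",
    "activation_from_labels",
    "EmgPlant",
    "synthesize_session",
    "add_vibration",
]

FS = 2048.0

#: Virtual muscles and the DoF direction each one drives.
#: Rows of ``_MUSCLE_PULL``: flexor (-x), extensor (+x), radial deviator
#: (+y), ulnar deviator (-y).
MUSCLES = ("flexor", "extensor", "radial_dev", "ulnar_dev")
_MUSCLE_PULL = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])

#: Crosstalk share of the default muscle-to-channel mixing: the dominant
#: channel picks up the muscle with weight 1, the remaining channels share
#: a total of 0.25 (dominance ratio 0.8 / 0.2).
_CROSSTALK_TOTAL = 0.25


@dataclass(frozen=True)
class NoiseConfig:
    """Noise and interference settings for the generator."""

    powerline_f0: float = 50.0
    n_harmonics: int = 10
    amplifier_noise_uvrms: float = 3.0  # instrumentation floor, < 4 μV_RMS
    vibration_band: tuple = (3.0, 80.0)  # Hz; PSD peak sits below 20 Hz
    vibration_pattern: tuple = (15.0, 15.0)  # on s, off s
    vibration_amplitude_uvrms: float = 1000.0  # raw, at coupling 1
    powerline: bool = True
    broadband: bool = True

    @classmethod
    def disabled(cls) -> "NoiseConfig":
        return cls(powerline=False, broadband=False, amplifier_noise_uvrms=0.0)


@dataclass(frozen=True)
class Event:
    kind: str
    start_s: float
    stop_s: float
    meta: dict = field(default_factory=dict)


@dataclass
class RecordingSession:
    """A multichannel recording with aligned cue labels and annotations."""

    signal: np.ndarray  # channels × samples, μV
    fs: float
    channel_types: tuple  # electrode kind per channel
    labels: np.ndarray  # samples × 2, DoF cue trajectory in [-1, 1]^2
    events: tuple = ()
    day: int = 1
    seed: int | None = None
    channel_names: tuple = ()

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("session signal contains non-finite values")
        if self.labels.shape != (self.signal.shape[1], 2):
            raise ValueError("labels must be samples × 2, aligned to the signal")
        if not self.channel_names:
            self.channel_names = tuple(
                f"{k}{i}" for i, k in enumerate(self.channel_types)
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs

    def type_groups(self) -> list:
        """Channel-index groups per electrode type (referencing groups)."""
        out: dict[str, list[int]] = {}
        for i, k in enumerate(self.channel_types):
            out.setdefault(k, []).append(i)
        return list(out.values())

    def intervals(self, kind: str):
        return [(e.start_s, e.stop_s) for e in self.events if e.kind == kind]


def default_mixing(n_channels: int = 4, n_muscles: int = 4,
                   crosstalk_total: float = _CROSSTALK_TOTAL) -> np.ndarray:
    """Muscle-to-channel mixing: identity dominance plus spread crosstalk."""
    m = np.full((n_channels, n_muscles), crosstalk_total / max(n_channels - 1, 1))
    for i in range(min(n_channels, n_muscles)):
        m[i, i] = 1.0
    return m


def activation_from_labels(labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Muscle activation (%MVC), muscles × samples, from a cue trajectory.

    Each muscle is driven by the rectified projection of the cue direction
    onto its pull direction, scaled by the cued contraction level.
    """
    lab = np.asarray(labels, dtype=float)
    lev = np.asarray(levels, dtype=float)
    norm = np.linalg.norm(lab, axis=1)
    dirhat = np.divide(lab.T, norm, out=np.zeros_like(lab.T), where=norm > 0)
    return np.clip(_MUSCLE_PULL @ dirhat, 0.0, None) * lev


# -- deterministic filter-gain calibrations ----------------------------

@lru_cache(maxsize=None)
def _hardware_sos(fs: float = FS) -> np.ndarray:
    hp = sps.butter(1, 3.0, btype="highpass", fs=fs, output="sos")
    lp = sps.butter(4, min(900.0, 0.999 * fs / 2), btype="lowpass", fs=fs,
                    output="sos")
    return np.vstack([hp, lp])


@lru_cache(maxsize=None)
def _emg_proto_sos(fs: float = FS) -> np.ndarray:
    return sps.butter(4, (20.0, 450.0), btype="bandpass", fs=fs, output="sos")


@lru_cache(maxsize=None)
def _vibration_sos(band: tuple = (3.0, 80.0), fs: float = FS) -> np.ndarray:
    # band-pass plus a gentle low-pass tilt: broad 0-100 Hz artifact with
    # its spectral peak well below 20 Hz
    bp = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    tilt = sps.butter(1, 25.0, btype="lowpass", fs=fs, output="sos")
    return np.vstack([bp, tilt])


def _rms_gain(sos_list, fs: float, worn: int = 8192) -> float:
    """RMS gain of cascaded filters for white input (frequency-domain)."""
    h = np.ones(worn, dtype=complex)
    for sos in sos_list:
        _, hk = sps.sosfreqz(sos, worN=worn, fs=fs)
        h *= hk
    return float(np.sqrt(np.mean(np.abs(h) ** 2)))


@lru_cache(maxsize=None)
def _gains(fs: float = FS) -> dict:
    hw, sw, proto = _hardware_sos(fs), software_chain_sos(fs), _emg_proto_sos(fs)
    g_proto_raw = _rms_gain((proto, hw), fs)
    return {
        # unit-RMS shaped EMG (after hardware) -> RMS after software chain
        "emg_cond": _rms_gain((proto, hw, sw), fs) / g_proto_raw,
        "proto_raw": g_proto_raw,  # white -> shaped EMG RMS incl. hardware
        "white_cond": _rms_gain((hw, sw), fs),  # white -> post-chain RMS
        "white_raw": _rms_gain((hw,), fs),  # white -> raw (hardware only) RMS
    }


# -- the generator -----------------------------------------------------

class EmgPlant:
    """Streaming EMG source: feed muscle activations, get signal blocks.

    The same object backs offline session synthesis (one big block) and
    the closed-loop task (one 40 ms block per control update); filter
    states, powerline phases and noise streams persist across calls, so a
    fixed seed plus a fixed call sequence is bit-reproducible.
    """

    def __init__(self, models, mixing: np.ndarray | None = None,
                 noise: NoiseConfig | None = None,
                 perturbation: MixingPerturbation | None = None,
                 t_donning_min: float = 120.0, seed: int = 0,
                 fs: float = FS):
        if isinstance(models, (str, ElectrodeModel)):
            models = [models] * 4
        self.models = [load_preset(m) if isinstance(m, str) else m for m in models]
        self.n_channels = len(self.models)
        self.fs = fs
        self.noise = noise if noise is not None else NoiseConfig()
        self.mixing = (np.asarray(mixing, dtype=float) if mixing is not None
                       else default_mixing(self.n_channels))
        if self.mixing.shape[0] != self.n_channels:
            raise ValueError(
                f"mixing has {self.mixing.shape[0]} rows for "
                f"{self.n_channels} channels"
            )
        self.n_muscles = self.mixing.shape[1]
        self.perturbation = perturbation
        self.mixing_eff = (
            perturbation.as_matrix() @ self.mixing
            if perturbation is not None else self.mixing
        )
        self.t_donning_min = t_donning_min
        self.seed = seed

        ss = np.random.SeedSequence(seed)
        keys = ("phases", "heterogeneity")
        nm = self.n_muscles
        streams = ss.spawn(len(keys) + nm + self.n_channels)
        self._rng = {k: np.random.default_rng(s) for k, s in zip(keys, streams)}
        # one stream per muscle and per channel keeps generation invariant
        # to how the recording is partitioned into blocks
        self._rng_emg = [np.random.default_rng(s)
                         for s in streams[len(keys):len(keys) + nm]]
        self._rng_bb = [np.random.default_rng(s)
                        for s in streams[len(keys) + nm:]]

        g = _gains(fs)
        groups = self._type_groups()
        self._group_of = {}
        for grp in groups:
            for c in grp:
                self._group_of[c] = grp
        # CMR retention of each muscle on its dominant channel: the group
        # mean subtraction removes part of the muscle's own signal.
        self._cmr_retention = np.empty(self.n_muscles)
        for m in range(self.n_muscles):
            dom = int(np.argmax(np.abs(self.mixing[:, m])))
            grp = self._group_of[dom]
            self._cmr_retention[m] = (
                self.mixing[dom, m] - self.mixing[grp, m].mean()
            )
        if np.any(self._cmr_retention <= 0):
            raise ValueError("mixing leaves no referenced signal on a dominant channel")
        self._emg_cond_gain = g["emg_cond"]

        rng_h = self._rng["heterogeneity"]
        het = np.array([mdl.heterogeneity for mdl in self.models])
        jit_pl = 1.0 + het * rng_h.standard_normal(self.n_channels)
        jit_bb = 1.0 + het * rng_h.standard_normal(self.n_channels)
        dm = np.array([donning_multiplier(mdl, t_donning_min) for mdl in self.models])

        # powerline: target *raw* RMS of the full harmonic series per channel
        self._pl_rms = np.array([
            mdl.powerline_coupling_uvrms for mdl in self.models
        ]) * np.abs(jit_pl) * dm
        # broadband: white-noise sigma such that the post-chain, post-CMR
        # RMS equals the preset's in-band floor (amplifier noise acts as a
        # lower bound)
        cmr_fac = np.array([
            np.sqrt(1.0 - 1.0 / len(self._group_of[c]))
            for c in range(self.n_channels)
        ])
        target_bb = np.array([
            max(mdl.broadband_noise_uvrms, self.noise.amplifier_noise_uvrms)
            for mdl in self.models
        ]) * np.abs(jit_bb) * np.sqrt(dm)
        self._bb_sigma = target_bb / (g["white_cond"] * cmr_fac)

        # shared powerline phase per electrode-type group
        self._pl_phase = {}
        for grp in groups:
            self._pl_phase[tuple(grp)] = self._rng["phases"].uniform(
                0.0, 2 * np.pi, size=self.noise.n_harmonics
            )
        k = np.arange(1, self.noise.n_harmonics + 1, dtype=float)
        w = k ** -np.array([mdl.harmonic_rolloff for mdl in self.models])[:, None]
        # scale so the summed series has the target RMS (sin RMS = 1/sqrt2)
        self._pl_amps = (w / np.sqrt(np.sum(w ** 2, axis=1, keepdims=True) / 2.0)
                         ) * self._pl_rms[:, None]

        # streaming filter states
        proto = _emg_proto_sos(fs)
        self._proto_sos = proto
        self._proto_zi = [np.zeros((proto.shape[0], 2)) for _ in range(self.n_muscles)]
        hw = _hardware_sos(fs)
        self._hw_sos = hw
        self._hw_zi = np.zeros((hw.shape[0], self.n_channels, 2))
        self._g_proto = _rms_gain((proto,), fs)
        self._sample_index = 0
        self._last_act = np.zeros(self.n_muscles)

    def _type_groups(self):
        out: dict[str, list[int]] = {}
        for i, mdl in enumerate(self.models):
            out.setdefault(mdl.kind, []).append(i)
        return list(out.values())

    @property
    def referencing_groups(self):
        return self._type_groups()

    def amplitude_envelope(self, act_levels: np.ndarray) -> np.ndarray:
        """Per-muscle envelope (μV) from activations (%MVC), calibrated so
        the dominant channel's conditioned contraction RMS matches
        ``mvc_to_amplitude``."""
        amp = mvc_to_amplitude(np.clip(act_levels, 0.0, 100.0))
        return amp / (self._cmr_retention[:, None] * self._emg_cond_gain)

    def emit(self, act_levels: np.ndarray) -> np.ndarray:
        """Generate the next block. ``act_levels`` is muscles × samples
        (%MVC); returns channels × samples (μV, hardware-filtered)."""
        act = np.atleast_2d(np.asarray(act_levels, dtype=float))
        if act.shape[0] != self.n_muscles:
            raise ValueError(f"expected {self.n_muscles} muscle activations")
        n = act.shape[1]
        env = self.amplitude_envelope(act)

        emg_src = np.empty((self.n_muscles, n))
        for m in range(self.n_muscles):
            w = self._rng_emg[m].standard_normal(n)
            shaped, self._proto_zi[m] = sps.sosfilt(
                self._proto_sos, w, zi=self._proto_zi[m]
            )
            emg_src[m] = shaped / self._g_proto * env[m]
        raw = self.mixing_eff @ emg_src

        if self.noise.powerline:
            t = (self._sample_index + np.arange(n)) / self.fs
            k = np.arange(1, self.noise.n_harmonics + 1)
            arg = 2 * np.pi * self.noise.powerline_f0 * np.outer(k, t)
            for grp in self._type_groups():
                ph = self._pl_phase[tuple(grp)]
                series = np.sin(arg + ph[:, None])  # harmonics × samples
                raw[grp] += self._pl_amps[grp] @ series
        if self.noise.broadband:
            for c in range(self.n_channels):
                raw[c] += self._bb_sigma[c] * self._rng_bb[c].standard_normal(n)

        out = np.empty_like(raw)
        for c in range(self.n_channels):
            out[c], self._hw_zi[:, c] = sps.sosfilt(
                self._hw_sos, raw[c], zi=self._hw_zi[:, c]
            )
        self._sample_index += n
        return out


def synthesize_session(protocol: CueProtocol, models,
                       mixing: np.ndarray | None = None,
                       noise: NoiseConfig | None = None,
                       perturbation: MixingPerturbation | None = None,
                       rng_seed: int = 0, t_donning_min: float = 120.0,
                       day: int = 1, fs: float = FS) -> RecordingSession:
    """Synthesize a full cued recording session.

    ``models`` may be a single preset name/model (expanded to 4 channels)
    or a per-channel list. See :class:`EmgPlant` for the signal model.
    """
    plant = EmgPlant(models, mixing=mixing, noise=noise,
                     perturbation=perturbation, t_donning_min=t_donning_min,
                     seed=rng_seed, fs=fs)
    n = int(round(protocol.duration_s * fs))
    times = np.arange(n) / fs
    labels, levels = protocol.sample(times)
    act = activation_from_labels(labels, levels)
    signal = plant.emit(act)
    events = tuple(
        Event(kind, a, b)
        for kind in ("contraction", "rest")
        for a, b in protocol.intervals(kind)
    )
    return RecordingSession(
        signal=signal, fs=fs,
        channel_types=tuple(m.kind for m in plant.models),
        labels=labels, events=events, day=day, seed=rng_seed,
    )


def add_vibration(session: RecordingSession, couplings=None,
                  noise: NoiseConfig | None = None,
                  rng_seed: int = 12345) -> RecordingSession:
    """Return a copy of the session with vibration artifacts injected.

    Artifacts are independent per channel: band-limited noise (PSD peak
    below 20 Hz, energy up to ~100 Hz) at
    ``vibration_amplitude_uvrms × coupling``, present only during the
    alternating on-phases of ``vibration_pattern``. Couplings default to
    each channel's electrode model (dry ≫ gelled ≈ implant).
    """
    cfg = noise if noise is not None else NoiseConfig()
    if couplings is None:
        couplings = [load_preset(k).vibration_coupling
                     for k in session.channel_types]
    couplings = np.asarray(couplings, dtype=float)
    if couplings.size != session.n_channels:
        raise ValueError("one vibration coupling per channel required")

    n = session.signal.shape[1]
    fs = session.fs
    rng = np.random.default_rng(rng_seed)
    sos = _vibration_sos(cfg.vibration_band, fs)
    gain = _rms_gain((sos,), fs)
    artifact = sps.sosfilt(sos, rng.standard_normal((session.n_channels, n)),
                           axis=-1) / gain
    artifact *= cfg.vibration_amplitude_uvrms * couplings[:, None]

    on_s, off_s = cfg.vibration_pattern
    mask = np.zeros(n)
    t = 0.0
    events = list(session.events)
    while t < n / fs:
        i0, i1 = int(t * fs), min(int((t + on_s) * fs), n)
        if i1 > i0:
            mask[i0:i1] = 1.0
            events.append(Event("vibration", i0 / fs, i1 / fs))
        t += on_s + off_s
    # hardware chain shapes mechanical pickup like any other input
    shaped = sps.sosfilt(_hardware_sos(fs), artifact * mask, axis=-1)
    return replace(
        session, signal=session.signal + shaped, events=tuple(events)
    )
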