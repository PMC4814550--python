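"""Parametric models of the three electrode classes.

The testbed compares three ways of picking up forearm EMG: a chronically
implanted percutaneous titanium electrode, a gelled Ag/AgCl surface
electrode, and the dry metal electrode used in active prosthesis modules.
Each class is summarised by a small parametric model: an impedance
magnitude spectrum |Z|(f) anchored at 100 Hz, a donning transient (surface
electrode impedance settles after placement; the implant has none), noise
coupling strengths, and a cross-day repositioning scale that perturbs the
muscle-to-channel mixing when surface electrodes are re-donned.

Default anchors (100 Hz, settled state): implant 250 Ω, gelled 15 kΩ,
dry 150 kΩ — midpoints of the measured ranges, separated by at least an
order of magnitude as observed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "ElectrodeModel",
    "MixingPerturbation",
    "ELECTRODE_KINDS",
    "load_preset",
    "impedance_at",
    "donning_decay",
    "sample_day_perturbation",
]

ELECTRODE_KINDS = ("implant", "gelled", "dry")

#: Frequency range over which the impedance model is defined (Hz).
F_MIN, F_MAX = 0.0, 900.0

#: Donning state at which noise couplings are anchored (minutes). Surface
#: electrodes are conventionally left to settle for two hours before
#: measurements, so coupling values are referenced to that state.
REFERENCE_DONNING_MIN = 120.0


@dataclass(frozen=True)
class ElectrodeModel:
    """One electrode class, as seen by the signal generator.

    Parameters
    ----------
    kind:
        One of ``implant``, ``gelled``, ``dry``.
    z_100hz_ohm:
        Settled impedance magnitude at 100 Hz (Ω).
    z_alpha:
        Exponent of the power-law impedance spectrum (unitless, >= 0).
    z_corner_hz:
        Low-frequency corner keeping |Z|(0) finite (Hz).
    powerline_coupling_uvrms:
        RMS of the injected 50 Hz interference series (all harmonics
        combined, μV_RMS, raw) at the reference donning state.
    harmonic_rolloff:
        Harmonic k of the powerline series is scaled by ``1/k**rolloff``.
    broadband_noise_uvrms:
        In-band (30–500 Hz) residual noise floor after the full
        conditioning chain (μV_RMS).
    vibration_coupling:
        Unitless gain for mechanically coupled vibration artifacts.
    donning_floor:
        Asymptote of the donning decay factor (1 for the implant).
    donning_tau_min:
        Time constant of the donning transient (minutes).
    day_shift_sd:
        Scale of the cross-day repositioning perturbation (unitless;
        0 for the implant, which cannot move).
    heterogeneity:
        Relative per-channel spread of noise couplings within a type.
    """

    kind: str
    z_100hz_ohm: float
    z_alpha: float = 0.5
    z_corner_hz: float = 10.0
    powerline_coupling_uvrms: float = 0.0
    harmonic_rolloff: float = 1.0
    broadband_noise_uvrms: float = 5.0
    vibration_coupling: float = 0.0
    donning_floor: float = 1.0
    donning_tau_min: float = 40.0
    day_shift_sd: float = 0.0
    heterogeneity: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ELECTRODE_KINDS:
            raise ValueError(f"unknown electrode kind {self.kind!r}")
        if self.z_100hz_ohm <= 0:
            raise ValueError("z_100hz_ohm must be positive")
        if not 0 < self.donning_floor <= 1:
            raise ValueError("donning_floor must be in (0, 1]")
        if self.day_shift_sd < 0:
            raise ValueError("day_shift_sd must be non-negative")

    # -- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ElectrodeModel":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def load_preset(name: str) -> ElectrodeModel:
    """Load one of the packaged presets: ``implant``, ``gelled``, ``dry``."""
    if name not in ELECTRODE_KINDS:
        raise KeyError(f"no electrode preset named {name!r}")
    ref = importlib.resources.files("myospc").joinpath(f"presets/{name}.yaml")
    return ElectrodeModel(**yaml.safe_load(ref.read_text()))


def donning_decay(model: ElectrodeModel, t_min) -> np.ndarray | float:
    """Impedance decay factor relative to the freshly donned state.

    Returns a factor in (0, 1]: 1 at t=0, decreasing asymptotically to
    ``donning_floor``. The implant is chronically in place and returns 1
    for every t. Dry electrodes approximately halve over 120 minutes;
    the effect is weaker for gelled electrodes.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("donning time must be non-negative")
    if model.kind == "implant":
        out = np.ones_like(t)
    else:
        floor = model.donning_floor
        out = floor + (1.0 - floor) * np.exp(-t / model.donning_tau_min)
    return out if out.ndim else float(out)


def _spectrum_shape(model: ElectrodeModel, f: np.ndarray) -> np.ndarray:
    c = model.z_corner_hz
    return ((100.0 + c) / (f + c)) ** model.z_alpha


def impedance_at(model: ElectrodeModel, f_hz, t_donning_min: float = REFERENCE_DONNING_MIN):
    """Impedance magnitude |Z| at frequency ``f_hz`` (Ω).

    The spectrum is a monotone-decreasing power law anchored so that the
    settled (fully decayed) value at 100 Hz equals ``z_100hz_ohm``; the
    donning multiplier decays from 1/donning_floor toward 1. For the
    implant the result does not depend on ``t_donning_min``.
    """
    f = np.asarray(f_hz, dtype=float)
    if np.any((f < F_MIN) | (f > F_MAX)):
        raise ValueError(f"frequency must be within [{F_MIN}, {F_MAX}] Hz")
    decay = donning_decay(model, t_donning_min)
    out = model.z_100hz_ohm * _spectrum_shape(model, f) * (decay / model.donning_floor)
    return out if np.ndim(out) else float(out)


def donning_multiplier(model: ElectrodeModel, t_donning_min: float) -> float:
    """Noise/impedance scale relative to the reference donning state."""
    return float(
        donning_decay(model, t_donning_min)
        / donning_decay(model, REFERENCE_DONNING_MIN)
    )


@dataclass(frozen=True)
class MixingPerturbation:
    """Cross-day change of the muscle-to-channel map.

    Re-donning a surface electrode grid shifts each electrode slightly, which
    shows up as per-channel gain changes plus extra crosstalk between
    channels. The implant cannot move, so its perturbation is the identity.
    """

    channel_gain: np.ndarray
    crosstalk: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.channel_gain, dtype=float)
        c = np.asarray(self.crosstalk, dtype=float)
        if c.shape != (g.size, g.size):
            raise ValueError("crosstalk must be square with one row per channel")
        object.__setattr__(self, "channel_gain", g)
        object.__setattr__(self, "crosstalk", c)

    @property
    def n_channels(self) -> int:
        return self.channel_gain.size

    @classmethod
    def identity(cls, n_channels: int) -> "MixingPerturbation":
        return cls(np.ones(n_channels), np.zeros((n_channels, n_channels)))

    def as_matrix(self) -> np.ndarray:
        """Channel-space perturbation matrix: diag(gain) + crosstalk."""
        return np.diag(self.channel_gain) + self.crosstalk

    def magnitude(self) -> float:
        """Frobenius distance from the identity (unitless)."""
        return float(np.linalg.norm(self.as_matrix() - np.eye(self.n_channels)))


def sample_day_perturbation(
    model: ElectrodeModel, n_channels: int, rng_seed
) -> MixingPerturbation:
    """Draw a reproducible cross-day repositioning perturbation.

    Per-channel gains are log-normal around 1 with log-sd ``day_shift_sd``;
    off-diagonal crosstalk entries are Gaussian with sd ``day_shift_sd / 2``.
    For the implant (day_shift_sd = 0) the identity is returned.
    """
    if model.day_shift_sd == 0:
        return MixingPerturbation.identity(n_channels)
    rng = np.random.default_rng(rng_seed)
    sd = model.day_shift_sd
    gains = np.exp(rng.normal(0.0, sd, size=n_channels))
    crosstalk = rng.normal(0.0, sd / 2.0, size=(n_channels, n_channels))
    np.fill_diagonal(crosstalk, 0.0)
    return MixingPerturbation(gains, crosstalk)
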