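"""Signal conditioning and signal-quality statistics.

The software chain applied to every recording before feature extraction:

1. group-wise common-mean referencing (per electrode type), cancelling
   interference shared within a group;
2. a 4th-order Butterworth band-pass, 30–500 Hz;
3. a 50 Hz comb filter (cascade of IIR notches at 50·k Hz up to 500 Hz)
   removing powerline interference and its harmonics.

Filtering is causal (second-order sections with streaming state) so the
same chain runs in the real-time control loop; a zero-phase variant is
available for offline spectra. Features are windowed RMS values (200 ms
windows, 40 ms increments). The SNR statistic is the ratio of contraction
RMS to rest RMS over centered 3 s intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "FeatureMatrix",
    "design_bandpass",
    "design_comb",
    "software_chain_sos",
    "common_mean_reference",
    "apply_bandpass",
    "apply_comb",
    "condition",
    "rms_windows",
    "estimate_snr",
    "amplitude_spectrum",
    "window_samples",
]

FS_DEFAULT = 2048.0
BAND_DEFAULT = (30.0, 500.0)
COMB_F0 = 50.0
COMB_Q = 35.0
WINDOW_S = 0.200
STEP_S = 0.040
#: Initial samples excluded from RMS/SNR statistics (filter transients).
TRANSIENT_S = 0.5


@dataclass(frozen=True)
class FilterSpec:
    kind: str  # "bandpass" | "comb" | "highpass" | "lowpass"
    order: int = 4
    band: tuple = BAND_DEFAULT  # (low, high) Hz, or (f0,) for comb
    fs: float = FS_DEFAULT
    causal: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        for f in self.band:
            if not 0 < f < self.fs / 2:
                raise ValueError("band edges must lie in (0, fs/2)")


@lru_cache(maxsize=None)
def design_bandpass(low: float = 30.0, high: float = 500.0, order: int = 4,
                    fs: float = FS_DEFAULT) -> np.ndarray:
    """SOS of an ``order``-pole Butterworth band-pass (order/2 per edge)."""
    if not 0 < low < high < fs / 2:
        raise ValueError("band edges must satisfy 0 < low < high < fs/2")
    if order % 2:
        raise ValueError("bandpass order must be even")
    return sps.butter(order // 2, (low, high), btype="bandpass", fs=fs, output="sos")


@lru_cache(maxsize=None)
def design_comb(f0: float = COMB_F0, n_harmonics: int = 10, q: float = COMB_Q,
                fs: float = FS_DEFAULT) -> np.ndarray:
    """SOS cascade of IIR notches at f0, 2 f0, …, n_harmonics · f0."""
    if f0 * n_harmonics >= fs / 2:
        raise ValueError("highest notch must be below Nyquist")
    sections = []
    for k in range(1, n_harmonics + 1):
        b, a = sps.iirnotch(k * f0, q, fs=fs)
        sections.append(np.hstack([b, a]))
    return np.array(sections)


@lru_cache(maxsize=None)
def software_chain_sos(fs: float = FS_DEFAULT) -> np.ndarray:
    """Band-pass + comb as one SOS stack (for streaming use)."""
    return np.vstack([design_bandpass(fs=fs), design_comb(fs=fs)])


def _filt(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    return sps.sosfiltfilt(sos, x, axis=-1) if zero_phase else sps.sosfilt(sos, x, axis=-1)


def common_mean_reference(signal: np.ndarray, groups) -> np.ndarray:
    """Subtract the instantaneous within-group mean from each channel.

    ``groups`` is an iterable of channel-index lists partitioning the
    channels. Each group needs at least two members (referencing a
    singleton would null the channel).
    """
    x = np.asarray(signal, dtype=float)
    seen: list[int] = []
    out = x.copy()
    for g in groups:
        g = list(g)
        if len(g) < 2:
            raise ValueError(f"referencing group {g} has fewer than 2 channels")
        seen += g
        out[g] -= x[g].mean(axis=0, keepdims=True)
    if sorted(seen) != list(range(x.shape[0])):
        raise ValueError("groups must partition the channels exactly once")
    return out


def apply_bandpass(signal: np.ndarray, fs: float = FS_DEFAULT,
                   band=BAND_DEFAULT, order: int = 4,
                   zero_phase: bool = False) -> np.ndarray:
    return _filt(design_bandpass(band[0], band[1], order, fs), np.asarray(signal, float),
                 zero_phase)


def apply_comb(signal: np.ndarray, fs: float = FS_DEFAULT, f0: float = COMB_F0,
               n_harmonics: int = 10, zero_phase: bool = False) -> np.ndarray:
    return _filt(design_comb(f0, n_harmonics, COMB_Q, fs), np.asarray(signal, float),
                 zero_phase)


def condition(signal: np.ndarray, fs: float = FS_DEFAULT, groups=None,
              zero_phase: bool = False) -> np.ndarray:
    """Full chain: optional group referencing, band-pass, comb."""
    x = np.asarray(signal, dtype=float)
    if groups is not None:
        x = common_mean_reference(x, groups)
    return _filt(software_chain_sos(fs), x, zero_phase)


class StreamingConditioner:
    """Causal conditioning chain with persistent filter state.

    Used by the closed-loop task to process 40 ms blocks exactly as the
    offline :func:`condition` does (referencing is memoryless; the SOS
    cascade carries its state across blocks).
    """

    def __init__(self, n_channels: int, fs: float = FS_DEFAULT, groups=None):
        self.fs = fs
        self.groups = groups
        sos = software_chain_sos(fs)
        self._sos = sos
        self._zi = np.zeros((sos.shape[0], n_channels, 2))

    def process(self, block: np.ndarray) -> np.ndarray:
        x = np.asarray(block, dtype=float)
        if self.groups is not None:
            x = common_mean_reference(x, self.groups)
        out = np.empty_like(x)
        for c in range(x.shape[0]):
            out[c], self._zi[:, c] = sps.sosfilt(self._sos, x[c],
                                                 zi=self._zi[:, c])
        return out


def session_features(session, zero_phase: bool = False) -> "FeatureMatrix":
    """Condition a recording session and extract windowed RMS features."""
    y = condition(session.signal, session.fs, groups=session.type_groups(),
                  zero_phase=zero_phase)
    return rms_windows(y, session.fs, channel_names=session.channel_names)


# -- features ----------------------------------------------------------

def window_samples(fs: float = FS_DEFAULT, window_s: float = WINDOW_S,
                   step_s: float = STEP_S) -> tuple[int, int]:
    """(window, step) lengths in samples, round-half-up (410, 82 at 2048 Hz)."""
    return int(np.floor(window_s * fs + 0.5)), int(np.floor(step_s * fs + 0.5))


@dataclass(frozen=True)
class FeatureMatrix:
    """Windowed RMS features: ``values`` is windows × channels (μV)."""

    values: np.ndarray
    window_start_times: np.ndarray
    window_s: float = WINDOW_S
    step_s: float = STEP_S
    channel_names: tuple = ()

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def window_centers(self) -> np.ndarray:
        return self.window_start_times + self.window_s / 2.0

    def to_frame(self):
        import pandas as pd

        names = self.channel_names or tuple(
            f"ch{i}" for i in range(self.values.shape[1])
        )
        df = pd.DataFrame(self.values, columns=list(names))
        df.insert(0, "t_start_s", self.window_start_times)
        return df


def rms_windows(signal: np.ndarray, fs: float = FS_DEFAULT,
                window_s: float = WINDOW_S, step_s: float = STEP_S,
                channel_names=()) -> FeatureMatrix:
    """Sliding-window RMS per channel; no partial trailing window."""
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    win, step = window_samples(fs, window_s, step_s)
    n = x.shape[1]
    if n < win:
        raise ValueError(f"signal ({n} samples) shorter than one window ({win})")
    n_win = (n - win) // step + 1
    sq = x ** 2
    csum = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(sq, axis=1)], axis=1)
    starts = np.arange(n_win) * step
    vals = np.sqrt((csum[:, starts + win] - csum[:, starts]) / win).T
    return FeatureMatrix(vals, starts / fs, window_s, step_s, tuple(channel_names))


# -- statistics --------------------------------------------------------

def _centered_rms(x: np.ndarray, fs: float, intervals, interval_s: float) -> np.ndarray:
    """Per-channel RMS over the centered ``interval_s`` of each interval,
    averaged across intervals."""
    vals = []
    for start, stop in intervals:
        if stop - start < interval_s:
            raise ValueError("interval shorter than the analysis length")
        mid = (start + stop) / 2.0
        i0 = int(round((mid - interval_s / 2.0) * fs))
        i1 = i0 + int(round(interval_s * fs))
        vals.append(np.sqrt(np.mean(x[:, i0:i1] ** 2, axis=1)))
    return np.mean(vals, axis=0)


def estimate_snr(signal: np.ndarray, fs: float, contraction_intervals,
                 rest_intervals, interval_s: float = 3.0) -> np.ndarray:
    """SNR per channel: mean contraction RMS / mean rest RMS.

    RMS is computed over the centered ``interval_s`` of each interval
    (ramps at contraction edges are excluded by construction). Assumes
    noise is small enough that contraction RMS is signal-dominated.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if not contraction_intervals or not rest_intervals:
        raise ValueError("need at least one contraction and one rest interval")
    num = _centered_rms(x, fs, contraction_intervals, interval_s)
    den = _centered_rms(x, fs, rest_intervals, interval_s)
    if np.any(den == 0):
        raise ZeroDivisionError("rest RMS is zero; SNR undefined")
    return num / den


def amplitude_spectrum(signal: np.ndarray, fs: float = FS_DEFAULT,
                       nperseg: int = 4096):
    """One-sided amplitude spectrum via averaged periodograms (Welch).

    Returns (frequencies, amplitude) with Parseval-consistent scaling:
    the sum of squared amplitudes approximates the signal variance.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    nperseg = min(nperseg, x.shape[-1])
    f, pxx = sps.welch(x, fs=fs, nperseg=nperseg, axis=-1)
    return f, np.sqrt(pxx * (f[1] - f[0]))
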