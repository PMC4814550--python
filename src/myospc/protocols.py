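"""Cue protocols and the %MVC-to-amplitude calibration.

A protocol is an ordered list of segments, each with a 2-DoF direction
target in [-1, 1]^2 (x: flexion(-)/extension(+), y: ulnar(-)/radial(+)),
a contraction level in %MVC, and a duration. Two builders cover the two
recording paradigms: a graded isometric force series (for signal-quality
statistics) and a four-direction cued training run (for decoder
calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CueSegment",
    "CueProtocol",
    "make_force_protocol",
    "make_rest_protocol",
    "make_training_protocol",
    "mvc_to_amplitude",
    "DIRECTIONS",
]

#: The four cued movement directions (unit vectors in DoF space).
DIRECTIONS = {
    "extension": np.array([1.0, 0.0]),
    "flexion": np.array([-1.0, 0.0]),
    "radial": np.array([0.0, 1.0]),
    "ulnar": np.array([0.0, -1.0]),
}

#: Default contraction level cued during decoder training (%MVC).
TRAINING_LEVEL_MVC = 30.0

#: Trapezoid shape as fractions of the segment duration: ramp up, hold,
#: ramp down. A 5 s segment gives 1 s / 3 s / 1 s, so a centered 3 s
#: sub-interval sits entirely on the hold.
TRAPEZOID_FRACTIONS = (0.2, 0.6, 0.2)


@dataclass(frozen=True)
class CueSegment:
    direction: np.ndarray  # 2-vector in [-1, 1]^2
    duration_s: float
    level_mvc: float = 0.0  # 0 => rest
    kind: str = "rest"  # "rest" | "contraction"

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (2,) or np.any(np.abs(d) > 1.0):
            raise ValueError("direction must be a 2-vector within [-1, 1]^2")
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class CueProtocol:
    """Ordered cue segments plus the label sampling convention."""

    segments: tuple
    fs_cue: float = 2048.0

    @property
    def duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    @property
    def n_contractions(self) -> int:
        return sum(1 for s in self.segments if s.kind == "contraction")

    def trapezoid_value(self, seg: CueSegment, tau: float) -> float:
        """Normalized cue envelope in [0, 1] at time tau within a segment."""
        if seg.kind == "rest":
            return 0.0
        up, hold, down = TRAPEZOID_FRACTIONS
        t_up = up * seg.duration_s
        t_down = down * seg.duration_s
        if tau < t_up:
            return tau / t_up
        if tau > seg.duration_s - t_down:
            return max(0.0, (seg.duration_s - tau) / t_down)
        return 1.0

    def sample(self, times_s: np.ndarray):
        """Sample the protocol on a time grid.

        Returns ``(labels, levels)``: per-sample 2-DoF label in [-1,1]^2
        (direction scaled by the trapezoid envelope) and per-sample
        contraction level in %MVC (the cued level scaled the same way).
        """
        times_s = np.asarray(times_s, dtype=float)
        labels = np.zeros((times_s.size, 2))
        levels = np.zeros(times_s.size)
        starts = np.cumsum([0.0] + [s.duration_s for s in self.segments])
        idx = np.clip(np.searchsorted(starts, times_s, side="right") - 1, 0,
                      len(self.segments) - 1)
        up, _, down = TRAPEZOID_FRACTIONS
        for k, seg in enumerate(self.segments):
            sel = idx == k
            if seg.kind == "rest" or not np.any(sel):
                continue
            tau = times_s[sel] - starts[k]
            t_up, t_down = up * seg.duration_s, down * seg.duration_s
            env = np.minimum(
                np.clip(tau / t_up, 0.0, 1.0),
                np.clip((seg.duration_s - tau) / t_down, 0.0, 1.0),
            )
            labels[sel] = np.outer(env, seg.direction)
            levels[sel] = seg.level_mvc * env
        return labels, levels

    def intervals(self, kind: str):
        """(start, stop) times of all segments of the given kind."""
        out, t = [], 0.0
        for s in self.segments:
            if s.kind == kind:
                out.append((t, t + s.duration_s))
            t += s.duration_s
        return out


def make_rest_protocol(duration_s: float) -> CueProtocol:
    """A single rest segment — baseline-noise recordings."""
    return CueProtocol(
        (CueSegment(np.zeros(2), duration_s, 0.0, "rest"),)
    )


def make_force_protocol(
    levels_mvc=(10.0, 20.0, 30.0, 40.0, 50.0),
    reps_per_level: int = 10,
    on_s: float = 5.0,
    off_s: float = 5.0,
    direction: str = "extension",
) -> CueProtocol:
    """Graded isometric series: ``reps`` contractions per %MVC level,
    each ``on_s`` long, interleaved with ``off_s`` of rest."""
    levels = list(levels_mvc)
    if not levels:
        raise ValueError("levels_mvc must not be empty")
    if any(not 0 < lv <= 100 for lv in levels):
        raise ValueError("levels must be in (0, 100] %MVC")
    if on_s <= 0 or off_s <= 0:
        raise ValueError("durations must be positive")
    d = DIRECTIONS[direction]
    segs = []
    for lv in levels:
        for _ in range(reps_per_level):
            segs.append(CueSegment(d, on_s, float(lv), "contraction"))
            segs.append(CueSegment(np.zeros(2), off_s, 0.0, "rest"))
    return CueProtocol(tuple(segs))


def make_training_protocol(
    reps: int = 3,
    level_mvc: float = TRAINING_LEVEL_MVC,
    move_s: float = 5.0,
    rest_s: float = 3.0,
) -> CueProtocol:
    """Decoder-calibration run: ``reps`` repetitions of all four cued
    directions (default 3 x 4 = 12 movements), rest in between."""
    segs = [CueSegment(np.zeros(2), rest_s, 0.0, "rest")]
    for _ in range(reps):
        for name in ("extension", "flexion", "radial", "ulnar"):
            segs.append(CueSegment(DIRECTIONS[name], move_s, level_mvc, "contraction"))
            segs.append(CueSegment(np.zeros(2), rest_s, 0.0, "rest"))
    return CueProtocol(tuple(segs))


#: Calibration knots: (%MVC, μV_RMS). Measured contraction amplitudes
#: span 180 μV_RMS at 10 %MVC to 350 μV_RMS at 50 %MVC; zero force gives
#: zero EMG, and the curve is extrapolated linearly above 50 %MVC.
_MVC_KNOTS = np.array([[0.0, 0.0], [10.0, 180.0], [50.0, 350.0], [100.0, 562.5]])


def mvc_to_amplitude(level_mvc):
    """EMG amplitude (μV_RMS) produced at a contraction level (%MVC).

    Piecewise-linear, monotone increasing, with amplitude(10) = 180 and
    amplitude(50) = 350 μV_RMS.
    """
    lv = np.asarray(level_mvc, dtype=float)
    if np.any((lv < 0) | (lv > 100)):
        raise ValueError("contraction level must be within [0, 100] %MVC")
    out = np.interp(lv, _MVC_KNOTS[:, 0], _MVC_KNOTS[:, 1])
    return out if out.ndim else float(out)
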