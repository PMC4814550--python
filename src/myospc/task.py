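"""Closed-loop 2-D target-acquisition task with a simulated user.

The decoder output positions a cursor in a 2-D workspace; the goal is to
move it into a circular target and stay there for the dwell time (1 s)
before the trial times out (10 s). The loop runs at the feature rate
(25 Hz for 40 ms window increments):

    user -> muscle activations -> EMG plant -> conditioning -> RMS
    features -> decoder -> cursor -> (visual feedback) -> user

The human subject is replaced by a simulated user with an integrating
pursuit policy: the commanded 2-DoF drive accumulates a gain times the
(reaction-delayed) cursor error. This is stable under feedback delay,
reaches targets exactly when the plant-decoder map is well conditioned,
and degrades when cross-day electrode shifts distort that map — the
phenomenon the two-day protocol quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .conditioning import StreamingConditioner, rms_windows, window_samples
from .decoding import LinearDecoder, build_labels, train_decoder
from .electrodes import load_preset, sample_day_perturbation
from .protocols import make_training_protocol
from .synth import FS, EmgPlant, NoiseConfig, _MUSCLE_PULL, synthesize_session
from .conditioning import session_features

__all__ = [
    "TaskConfig",
    "SimulatedUser",
    "TrialResult",
    "SessionMetrics",
    "make_targets",
    "run_trial",
    "run_block",
    "run_protocol",
    "completion_rate",
    "completion_time",
]


@dataclass(frozen=True)
class TaskConfig:
    dwell_s: float = 1.0
    timeout_s: float = 10.0
    target_radius: float = 0.15
    target_distance: float = 0.6
    target_jitter: float = 0.05
    workspace_halfwidth: float = 1.0
    n_targets: int = 40
    step_s: float = 0.040  # feature increment -> 25 Hz update rate
    window_s: float = 0.200
    warmup_s: float = 1.0  # rest before each trial; settles filters
    cursor_mapping: str = "position"  # "position" | "velocity"
    velocity_gain: float = 1.5  # workspace units/s per unit output

    def __post_init__(self):
        if not self.dwell_s < self.timeout_s:
            raise ValueError("dwell time must be below the timeout")
        if self.target_distance + self.target_radius > self.workspace_halfwidth:
            raise ValueError("targets must fit inside the workspace")

    @property
    def update_rate(self) -> float:
        return 1.0 / self.step_s

    @property
    def n_dwell_steps(self) -> int:
        return int(np.ceil(self.dwell_s / self.step_s))

    @property
    def max_steps(self) -> int:
        return int(round(self.timeout_s / self.step_s))


@dataclass(frozen=True)
class SimulatedUser:
    """Integrating pursuit policy standing in for the human subject.

    ``gain`` is the per-update integration gain on the cursor error;
    ``reaction_delay_s`` delays the visual feedback; ``motor_noise_sd``
    is signal-dependent multiplicative noise on the commanded drive;
    ``max_command`` caps the drive magnitude (units of the cued training
    direction, i.e. 1.0 equals the calibration contraction level).
    """

    gain: float = 0.01
    reaction_delay_s: float = 0.2
    motor_noise_sd: float = 0.10
    max_command: float = 2.0
    command_level_mvc: float = 30.0

    def __post_init__(self):
        if min(self.gain, self.reaction_delay_s, self.motor_noise_sd) < 0:
            raise ValueError("user parameters must be non-negative")


@dataclass(frozen=True)
class TrialResult:
    hit: bool
    time_s: float
    cursor_trace: np.ndarray  # steps × 2
    target_center: np.ndarray
    target_radius: float


@dataclass(frozen=True)
class SessionMetrics:
    electrode_type: str
    day: int
    run: int
    n_targets: int
    completion_rate: float
    completion_time_s: float  # all-targets convention
    completion_time_hits_s: float
    results: tuple = ()


def make_targets(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Target centers: shuffled 8 compass directions with radial jitter,
    cycled until ``n_targets`` targets are produced."""
    ang = np.arange(8) * (np.pi / 4.0)
    base = config.target_distance * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    out = []
    while len(out) < config.n_targets:
        order = rng.permutation(8)
        for i in order:
            c = base[i] + rng.normal(0.0, config.target_jitter, size=2)
            lim = config.workspace_halfwidth - config.target_radius
            out.append(np.clip(c, -lim, lim))
    return np.array(out[: config.n_targets])


def _activations(user: SimulatedUser, command: np.ndarray) -> np.ndarray:
    """Rectified muscle drive (%MVC) for a 2-DoF command."""
    return np.clip(_MUSCLE_PULL @ command, 0.0, None) * user.command_level_mvc


def run_trial(decoder: LinearDecoder, user: SimulatedUser, plant: EmgPlant,
              target_center, config: TaskConfig,
              rng: np.random.Generator) -> TrialResult:
    """Run one closed-loop trial on a (stateful) plant.

    The plant emits ``warmup_s`` of rest first (inter-trial pause with the
    cursor at rest), then the loop runs at the update rate until the dwell
    requirement is met or the trial times out.
    """
    if decoder.W.shape[1] != plant.n_channels:
        raise ValueError("decoder channel count does not match the plant")
    target = np.asarray(target_center, dtype=float)
    win, step = window_samples(plant.fs, config.window_s, config.step_s)
    conditioner = StreamingConditioner(plant.n_channels, plant.fs,
                                       groups=plant.referencing_groups)
    buffer = np.zeros((plant.n_channels, win))

    def push(act_now: np.ndarray, act_prev: np.ndarray, n: int) -> None:
        nonlocal buffer
        ramp = np.linspace(0.0, 1.0, n, endpoint=True)
        act = act_prev[:, None] + (act_now - act_prev)[:, None] * ramp
        block = conditioner.process(plant.emit(act))
        buffer = np.concatenate([buffer[:, n:], block[:, -win:]], axis=1)

    n_warm = int(round(config.warmup_s * plant.fs))
    rest = np.zeros(plant.n_muscles)
    push(rest, rest, max(n_warm, win))

    delay_steps = int(round(user.reaction_delay_s / config.step_s))
    command = np.zeros(2)
    prev_act = rest
    cursor_hist: list[np.ndarray] = []
    trace = []
    streak = 0
    hit = False
    velocity_cursor = np.zeros(2)

    for k in range(config.max_steps):
        feat = np.sqrt(np.mean(buffer ** 2, axis=1))
        out = decoder.W @ feat + decoder.bias
        if config.cursor_mapping == "velocity":
            velocity_cursor = np.clip(
                velocity_cursor + config.velocity_gain * config.step_s * out,
                -config.workspace_halfwidth, config.workspace_halfwidth)
            cursor = velocity_cursor.copy()
        else:
            cursor = np.clip(out, -config.workspace_halfwidth,
                             config.workspace_halfwidth)
        cursor_hist.append(cursor)
        trace.append(cursor)

        if np.linalg.norm(cursor - target) <= config.target_radius:
            streak += 1
        else:
            streak = 0
        if streak >= config.n_dwell_steps:
            hit = True
            break

        seen = cursor_hist[k - delay_steps] if k >= delay_steps else np.zeros(2)
        command = command + user.gain * (target - seen)
        nrm = np.linalg.norm(command)
        if nrm > user.max_command:
            command = command * (user.max_command / nrm)
        noisy = command * (1.0 + user.motor_noise_sd * rng.standard_normal(2))
        act = _activations(user, noisy)
        push(act, prev_act, step)
        prev_act = act

    time_s = (len(trace)) * config.step_s if hit else config.timeout_s
    return TrialResult(hit, float(time_s), np.array(trace), target,
                       config.target_radius)


def run_block(decoder: LinearDecoder, user: SimulatedUser, plant: EmgPlant,
              config: TaskConfig, rng: np.random.Generator,
              targets: np.ndarray | None = None) -> list:
    """One run: ``n_targets`` consecutive trials on a shared plant."""
    if targets is None:
        targets = make_targets(config, rng)
    return [run_trial(decoder, user, plant, c, config, rng) for c in targets]


def completion_rate(results) -> float:
    """Fraction of targets hit before timeout."""
    results = list(results)
    if not results:
        raise ValueError("no trials")
    return sum(r.hit for r in results) / len(results)


def completion_time(results, convention: str = "all") -> float:
    """Mean time per target (s). ``convention='all'`` counts timed-out
    targets at the timeout; ``'hits'`` averages hit trials only."""
    results = list(results)
    if not results:
        raise ValueError("no trials")
    if convention == "hits":
        times = [r.time_s for r in results if r.hit]
        return float(np.mean(times)) if times else float("nan")
    return float(np.mean([r.time_s for r in results]))


def train_decoder_for_type(kind: str, seed: int, reps: int = 3,
                           fs: float = FS) -> LinearDecoder:
    """Day-1 calibration: cued training session -> features -> OLS fit."""
    protocol = make_training_protocol(reps=reps)
    session = synthesize_session(protocol, kind, rng_seed=seed, fs=fs)
    feats = session_features(session)
    labels = build_labels(protocol, feats.window_centers)
    return train_decoder(feats, labels, trained_on=f"{kind}/seed{seed}")


def run_protocol(electrode_types=("implant", "gelled", "dry"),
                 n_days: int = 2, runs_per_day: int = 2,
                 config: TaskConfig | None = None,
                 user: SimulatedUser | None = None,
                 seed: int = 0, day_shift_override: dict | None = None,
                 keep_traces: bool = False, training_reps: int = 3) -> list:
    """The two-day robustness protocol.

    One decoder per electrode type is trained on a day-1 session and then
    reused without retraining. Day-2 plants apply a freshly sampled
    repositioning perturbation (identity for the implant) and a fresh
    donning state. ``day_shift_override`` maps electrode kind to a
    replacement ``day_shift_sd`` (e.g. 0.0 to switch perturbations off).

    Returns one :class:`SessionMetrics` per (type, day, run).
    """
    config = config or TaskConfig()
    user = user or SimulatedUser()
    out = []
    for t_idx, kind in enumerate(electrode_types):
        model = load_preset(kind)
        if day_shift_override and kind in day_shift_override:
            model = dc_replace(model, day_shift_sd=day_shift_override[kind])
        root = np.random.SeedSequence([seed, t_idx])
        train_seed, pert_seed, *run_seeds = [
            int(s.generate_state(1)[0] % (2 ** 31))
            for s in root.spawn(2 + n_days * runs_per_day)
        ]
        decoder = train_decoder_for_type(kind, train_seed, reps=training_reps)
        for day in range(1, n_days + 1):
            perturbation = None
            if day > 1:
                perturbation = sample_day_perturbation(model, 4, pert_seed + day)
            for run in range(1, runs_per_day + 1):
                s = run_seeds[(day - 1) * runs_per_day + (run - 1)]
                plant = EmgPlant([model] * 4, perturbation=perturbation,
                                 seed=s)
                rng = np.random.default_rng(s + 1)
                results = run_block(decoder, user, plant, config, rng)
                out.append(SessionMetrics(
                    electrode_type=kind, day=day, run=run,
                    n_targets=len(results),
                    completion_rate=completion_rate(results),
                    completion_time_s=completion_time(results, "all"),
                    completion_time_hits_s=completion_time(results, "hits"),
                    results=tuple(results) if keep_traces else (),
                ))
    return out
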