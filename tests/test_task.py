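"""Closed-loop task: trial mechanics, metrics, two-day robustness."""

import numpy as np
import pytest

from myospc.synth import EmgPlant
from myospc.task import (
    SimulatedUser,
    TaskConfig,
    TrialResult,
    completion_rate,
    completion_time,
    make_targets,
    run_block,
    run_protocol,
    run_trial,
)


def _mk(hit, t):
    return TrialResult(hit, t, np.zeros((1, 2)), np.zeros(2), 0.15)


class TestMetrics:
    def test_completion_rate_fraction(self):
        res = [_mk(True, 3.0)] * 9 + [_mk(False, 10.0)]
        assert completion_rate(res) == pytest.approx(0.9)
        assert completion_rate([_mk(True, 1.0)] * 4) == 1.0

    def test_completion_time_conventions(self):
        res = [_mk(True, 4.0), _mk(False, 10.0)]
        assert completion_time(res) == pytest.approx(7.0)
        assert completion_time(res, "hits") == pytest.approx(4.0)
        assert completion_time([_mk(True, 4.0), _mk(True, 5.0)]) == 4.5

    def test_permutation_invariance(self, rng):
        res = [_mk(bool(h), float(t))
               for h, t in zip(rng.integers(0, 2, 20), rng.uniform(1, 10, 20))]
        perm = [res[i] for i in rng.permutation(20)]
        assert completion_rate(res) == completion_rate(perm)
        assert completion_time(res) == pytest.approx(completion_time(perm))

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            completion_rate([])
        with pytest.raises(ValueError):
            completion_time([])


class TestTrialMechanics:
    def test_target_over_start_hits_in_dwell_time(self, implant_decoder):
        cfg = TaskConfig(target_radius=0.3)
        plant = EmgPlant("implant", seed=50)
        res = run_trial(implant_decoder, SimulatedUser(), plant,
                        np.zeros(2), cfg, np.random.default_rng(1))
        assert res.hit
        assert res.time_s == pytest.approx(cfg.dwell_s, abs=3 * cfg.step_s)

    def test_immobile_user_times_out(self, implant_decoder):
        cfg = TaskConfig()
        plant = EmgPlant("implant", seed=51)
        res = run_trial(implant_decoder, SimulatedUser(gain=0.0), plant,
                        np.array([0.6, 0.0]), cfg, np.random.default_rng(1))
        assert not res.hit
        assert res.time_s == cfg.timeout_s
        assert len(res.cursor_trace) == cfg.max_steps

    def test_hit_ends_with_exact_dwell_streak(self, implant_decoder):
        cfg = TaskConfig()
        plant = EmgPlant("implant", seed=52)
        res = run_trial(implant_decoder, SimulatedUser(), plant,
                        np.array([0.0, 0.6]), cfg, np.random.default_rng(2))
        assert res.hit
        d = np.linalg.norm(res.cursor_trace - res.target_center, axis=1)
        inside = d <= res.target_radius
        streak = 0
        for v in inside[::-1]:
            if not v:
                break
            streak += 1
        assert streak == cfg.n_dwell_steps
        assert not inside[-cfg.n_dwell_steps - 1]

    def test_full_loop_determinism(self, implant_decoder):
        cfg = TaskConfig(n_targets=3)

        def go():
            plant = EmgPlant("implant", seed=53)
            return run_block(implant_decoder, SimulatedUser(), plant, cfg,
                             np.random.default_rng(3))

        a, b = go(), go()
        assert [r.hit for r in a] == [r.hit for r in b]
        assert np.array_equal(np.concatenate([r.cursor_trace for r in a]),
                              np.concatenate([r.cursor_trace for r in b]))

    def test_channel_mismatch_rejected(self, implant_decoder):
        plant = EmgPlant(["implant"] * 2,
                         mixing=np.array([[1.0, 0.1], [0.1, 1.0]]))
        with pytest.raises(ValueError):
            run_trial(implant_decoder, SimulatedUser(), plant, np.zeros(2),
                      TaskConfig(), np.random.default_rng(0))


class TestTargets:
    def test_targets_fit_in_workspace(self, rng):
        cfg = TaskConfig(n_targets=40)
        t = make_targets(cfg, rng)
        assert t.shape == (40, 2)
        assert np.all(np.abs(t) + cfg.target_radius
                      <= cfg.workspace_halfwidth + 1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TaskConfig(dwell_s=11.0)
        with pytest.raises(ValueError):
            TaskConfig(target_distance=0.95)


class TestTwoDayProtocol:
    def test_zero_perturbation_override_keeps_performance(self):
        cfg = TaskConfig(n_targets=6)
        ms = run_protocol(electrode_types=("dry",), runs_per_day=1,
                          config=cfg, seed=5,
                          day_shift_override={"dry": 0.0},
                          training_reps=2)
        by_day = {m.day: m for m in ms}
        assert by_day[1].completion_rate == by_day[2].completion_rate

    def test_implant_stable_and_dry_degrades(self):
        cfg = TaskConfig(n_targets=8)
        diffs = {"implant": [], "dry": []}
        for seed in range(4):
            ms = run_protocol(electrode_types=("implant", "dry"),
                              runs_per_day=1, config=cfg, seed=seed,
                              training_reps=2)
            for kind in diffs:
                day = {m.day: m for m in ms if m.electrode_type == kind}
                diffs[kind].append(day[2].completion_rate
                                   - day[1].completion_rate)
        assert np.mean(diffs["implant"]) == pytest.approx(0.0, abs=0.05)
        assert np.mean(diffs["dry"]) < -0.1
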