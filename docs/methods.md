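# Methods

This note documents the models behind `myospc`, the defaults and why
they were chosen, and what the synthetic testbed can and cannot show.

## Electrode models

Each electrode class is reduced to a handful of parameters with direct
physical readings.

**Impedance spectrum.** |Z|(f) = z₁₀₀ · ((100 + c)/(f + c))^α, a
monotone-decreasing power law with a low-frequency corner c = 10 Hz that
keeps |Z|(0) finite. z₁₀₀ is the *settled* magnitude at 100 Hz; defaults
are the midpoints of the measured ranges: implant 250 Ω, gelled 15 kΩ,
dry 150 kΩ. The exponents (0.25 / 0.5 / 0.7) give the dry interface the
steepest dispersion, as typical for dry metal-skin contacts. Only the
magnitude is modelled; phase plays no role downstream.

**Donning transient.** Surface-electrode impedance settles after
placement as d(t) = d∞ + (1 − d∞)·exp(−t/τ) with τ = 40 min; d∞ = 0.5
for dry (the impedance roughly halves over 120 min: d(120) ≈ 0.52) and
d∞ = 0.78 for gelled (a weaker transient, ≈ 0.79 at 120 min). The
implant is chronically in place: d ≡ 1. `impedance_at` multiplies the
settled spectrum by d(t)/d∞, so a freshly donned dry electrode reads
about twice its settled value and the settled value matches the printed
range. Noise couplings are referenced to the 120 min state, the
conventional settling time before measurements.

**Cross-day repositioning.** Re-donning perturbs the muscle-to-channel
map: per-channel log-normal gains (log-sd = `day_shift_sd`) plus
Gaussian off-diagonal crosstalk (sd = `day_shift_sd`/2) in channel
space. The magnitude of the shift is not reported anywhere, so the
defaults (dry 0.5, gelled 0.4, implant 0 — it cannot move) were
calibrated once so that day-2 surface performance degrades visibly in
the two-day protocol while day-1 behaviour is untouched.

## Signal generator

**EMG core.** Per virtual muscle, white Gaussian noise is shaped by an
8-pole Butterworth band-pass prototype (20–450 Hz) and
amplitude-modulated. This is the standard surrogate for interference
EMG: it reproduces amplitude, bandwidth and stochasticity, which is all
the RMS-feature pipeline consumes. No motor-unit structure (MUAPs,
recruitment, firing statistics) is simulated, so the testbed cannot
speak to decomposition-based methods.

**Muscles and mixing.** Four virtual muscles (wrist flexor, extensor,
radial and ulnar deviator) each project onto one dominant channel with
weight 1 and a total of 0.25 spread over the other channels (a 0.8/0.2
dominance ratio). Muscle drive is the rectified projection of the cue
direction onto each muscle's pull direction, times the cued %MVC.

**Amplitude calibration.** The %MVC-to-amplitude curve is piecewise
linear through (0, 0), (10 %, 180 μV_RMS) and (50 %, 350 μV_RMS),
extrapolated linearly above 50 %. The envelope is scaled by two
deterministic factors — the RMS gain of the filter cascade (computed
from the frequency responses, not from noise realizations) and the
common-mean-referencing retention of the dominant channel (computable
from the mixing matrix) — so that the *conditioned* contraction RMS
matches the curve within the stochastic fluctuation of an RMS estimate.
The same calibration is applied to all electrode types; types differ
only in noise.

**Noise.** Powerline interference is a 10-harmonic 50 Hz series with
1/k amplitude rolloff and per-session random phase, shared within an
electrode-type group (so group referencing cancels most of it) with 10%
per-channel amplitude heterogeneity (so a residual survives for the comb
filter). Its total RMS per channel is proportional to the electrode's
100 Hz impedance, anchored at 500 μV_RMS raw rest for the dry preset —
hence ≈ 50 μV for gelled and < 1 μV for the implant. The broadband floor
is per-channel white noise scaled so the post-conditioning rest RMS
matches per-type anchors of 15 / 10 / 6 μV_RMS (dry/gelled/implant), all
under the 20 μV_RMS bound; a √impedance trend motivates the ordering but
the three anchors are set directly. The amplifier's own noise (< 4
μV_RMS) acts as a lower bound on that floor. Noise amplitudes scale with
the instantaneous donning state (powerline ∝ impedance, broadband ∝
√impedance).

**Hardware chain.** A causal 1st-order 3 Hz high-pass plus 4th-order
900 Hz low-pass is applied to everything the electrodes pick up.

**Vibration artifacts.** Independent per channel: white noise shaped by
a 3–80 Hz band-pass with an additional 25 Hz first-order tilt, giving a
broad 0–100 Hz spectrum with its peak below 10 Hz. Amplitude is
1000 μV_RMS (raw) times the per-type coupling (dry 1.0, gelled 0.03,
implant 0.015), so the conditioned dry artifact (~500 μV_RMS) exceeds a
moderate 30 %MVC contraction (~265 μV_RMS) while the other types barely
register. Artifacts follow a 15 s on / 15 s off pattern.

**Determinism.** All randomness derives from one integer seed via
spawned bit-generator streams, one per muscle and per channel, so
generation is bit-reproducible and invariant to how a recording is
partitioned into blocks — the offline generator and the streaming
closed-loop plant are the same code path.

## Conditioning chain

Group-wise common-mean referencing per electrode type, then a 4-pole
Butterworth band-pass 30–500 Hz, then a comb of IIR notches at
50·k Hz (k = 1…10, quality factor 35). "4th order band-pass" is read as
four poles total (two per edge). Everything in the control path is
causal second-order-section filtering with streaming state; a zero-phase
variant exists for offline spectra. Window lengths at 2048 Hz round
half-up to 410 samples (200 ms) and 82 samples (40 ms), giving 20
windows per second of signal; the first 0.5 s of any recording is
excluded from RMS statistics to let transients settle. The SNR statistic
divides mean contraction RMS by mean rest RMS over the centered 3 s of
each interval, which keeps the trapezoid ramps out of the estimate. The
amplitude spectrum is Welch-averaged with Parseval-consistent scaling
(summed squared amplitudes ≈ variance).

## Decoder

Ordinary least squares with intercept, both DoFs fitted jointly; no
feature normalization (the fit is gain-equivariant, so global amplifier
gain cancels in the decoded output) and no regularization by default (an
optional ridge parameter exists for ill-conditioned feature sets). Cue
labels are trapezoids — 20% ramp up, 60% hold, 20% ramp down of each
5 s movement at 30 %MVC — sampled at window centers. The %MVC curve is
concave, so the feature-label relation is not exactly linear; the OLS
fit still reaches in-sample R² ≈ 0.98 per DoF on default training
sessions, and the closed-loop user compensates residual static
nonlinearity.

## Closed-loop task and simulated user

Position control: the decoder output is the cursor position in a
[−1, 1]² workspace, updated at 25 Hz. Targets sit at 8 compass
directions at distance 0.6 with 0.05 jitter, radius 0.15; a hit requires
25 consecutive in-target updates (1 s dwell) before the 10 s timeout;
40 targets per run by default, with 1 s of rest (and a settled filter
state) before each trial.

The simulated user integrates: every update, the commanded 2-DoF drive
increases by gain × (target − cursor), using cursor feedback delayed by
200 ms, with 10% multiplicative motor noise and the drive magnitude
capped at 2 (twice the calibration contraction). A purely proportional
policy (command = gain · error) is unstable in a position-mapped loop
with feedback delay at any gain large enough to reach the targets, so
the integrating form — the discrete equivalent of human visual
servoing — was chosen instead. The gain default (0.01 per update) was
set once so that day-1 performance lands at the plausible human level
(~100% completion at ≈ 4.5 s per target with 1 s dwell); the optional
run-to-run adaptation that would mimic within-day learning is off by
default. Degradation on day 2 emerges mechanically: the perturbed mixing
rotates and rescales the plant-decoder map, and because muscle drives
are rectified (no negative activation) and capped, some target
directions become unreachable or unstable — the user cannot integrate
its way out, mirroring the "certain areas not accessible, overshoot in
other directions" phenomenology.

## Problem sizes

Defaults mirror the study protocol: 10 contractions of 5 s per force
level, 3 × 4 training movements, 40 targets per run, 2 days × 2 runs.
The test suite and the analysis drivers use reduced sizes (2–10
contractions, 6–20 targets, 3–10 seeds) chosen as the smallest runs in
which the qualitative effects are stable across seeds.

## Known limitations

- No motor-unit-level EMG, force-sensor dynamics, fatigue, or
  electrode lift-off events.
- Impedance is magnitude-only and noise couplings are stationary within
  a session; real skin conditions drift.
- The simulated user is a low-order control policy: it reproduces
  reach-and-dwell phenomenology and its failure under map distortion,
  not human learning, strategy switching or co-contraction.
- Passing tests show the *pipeline* is correct and the calibrated
  testbed is internally consistent with the printed anchors; they do not
  validate the electrode physics beyond those anchors.
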