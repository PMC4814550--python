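# myospc

A synthetic-EMG testbed for evaluating how the choice of recording
electrode — a percutaneous titanium implant, a gelled Ag/AgCl surface
electrode, or the dry metal electrode used in prosthesis sockets —
affects simultaneous proportional myoelectric control of two wrist
degrees of freedom.

Advanced myoelectric control is rarely used clinically because surface
EMG is fragile: electrode repositioning between days and changing skin
conditions degrade a decoder trained the day before. A chronically
implanted percutaneous electrode bypasses the skin and cannot move, so
its signals should stay decodable without retraining. This package
implements the full acquisition-to-control pipeline around that
comparison, with a calibrated synthetic-signal generator standing in for
the human subject, so every stage can be tested end to end and the
cross-day robustness argument can be exercised quantitatively.

## What is modelled

- **Electrode models** (`myospc.electrodes`): per-type impedance spectra
  |Z|(f) over 0–900 Hz anchored at 100 Hz (implant ≈ 250 Ω, gelled
  ≈ 15 kΩ, dry ≈ 150 kΩ), a donning transient (dry impedance roughly
  halves over 120 min; no transient for the implant), noise couplings,
  and a cross-day repositioning perturbation of the muscle-to-channel
  mixing (identity for the implant).
- **Signal generator** (`myospc.synth`): 4 channels at 2048 Hz through a
  3 Hz high-pass / 900 Hz low-pass hardware chain. The EMG core is
  amplitude-modulated band-shaped Gaussian noise per virtual muscle,
  calibrated so conditioned contraction RMS follows the %MVC curve
  (180 μV_RMS at 10 %MVC, 350 μV_RMS at 50 %MVC). Powerline interference
  at 50 Hz and harmonics scales with electrode impedance (dry rest
  baseline ≈ 500 μV_RMS raw); mechanical vibration artifacts
  (0–100 Hz, peak below 20 Hz, 15 s on/off) couple strongly only to the
  dry electrode.
- **Conditioning** (`myospc.conditioning`): group-wise common-mean
  referencing per electrode type, a 4th-order 30–500 Hz Butterworth
  band-pass, a 50 Hz comb filter, windowed RMS features (200 ms windows,
  40 ms increments) and the contraction/rest SNR statistic.
- **Decoding** (`myospc.decoding`): ordinary least squares fit of
  `y = W x + b` mapping RMS features to the two DoF outputs, trained on
  cued sessions (3 repetitions of 4 directions).
- **Closed loop** (`myospc.task`): a 2-D target-acquisition task (1 s
  dwell, 10 s timeout) closed by a simulated user with an integrating
  pursuit policy, reaction delay and motor noise; metrics are completion
  rate and completion time, including the two-day / two-run protocol
  without retraining.

## Worked example

```
python analysis/01_impedance.py
python analysis/02_signal_quality.py
python analysis/03_closed_loop_control.py --seeds 3 --targets 10
```

prints (abridged):

```
implant |Z|(100 Hz) = 250 Ω (stable)
dry     |Z|(100 Hz): 289 kΩ at 3 min -> 157 kΩ at 120 min (ratio 0.54)

implant  raw rest   10.6 μV | filtered rest  6.00 μV | SNR @10%  28.4, @50%  66.1
gelled   raw rest   55.6 μV | filtered rest 10.35 μV | SNR @10%  17.5, @50%  34.0
dry      raw rest  480.7 μV | filtered rest 14.91 μV | SNR @10%  14.4, @50%  22.3
vibration (conditioned on-phase RMS, μV): {'implant': 9.5, 'gelled': 18.1, 'dry': 504.2}

implant  day 1 run 1: rate 1.00 ... day 2 run 1: rate 1.00
gelled   day 1 run 1: rate 1.00 ... day 2 run 1: rate 0.80
dry      day 1 run 1: rate 1.00 ... day 2 run 1: rate 0.30
```

Reading: the dry electrode's raw baseline (~480 μV_RMS, powerline
dominated) cleans up below 20 μV_RMS after conditioning, so all three
types control well on day 1 (completion ≈ 100% at ~4.5 s per target).
On day 2 the decoder is reused without retraining: the implant's
performance is unchanged, while the re-donned surface electrodes lose a
large fraction of targets. SNR ordering is implant > gelled > dry at
every force level.

The same evaluations are available as a CLI with YAML configs:

```
myospc impedance --out reports/impedance
myospc signal-quality --out reports/sq [--config scenario.yaml]
myospc control --out reports/control --seed 1
myospc make-fixtures --out fixtures/
```

All commands are byte-reproducible under a fixed config; reports carry
the config hash and package version.

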