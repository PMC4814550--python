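"""Signal quality and vibration robustness per electrode type.

Synthesizes the graded force protocol (10-50 %MVC), runs the conditioning
chain, and writes amplitude, SNR and vibration-phase tables to
results/signal_quality/. Expected picture: raw dry baselines near
500 μV_RMS dominated by powerline harmonics; after conditioning all types
rest below 20 μV_RMS; SNR ordering implant > gelled > dry; vibration
artifacts exceed moderate-contraction amplitudes only for dry electrodes.
"""

import argparse
from pathlib import Path

from myospc.experiments import ScenarioConfig, run_signal_quality


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/signal_quality"))
    ap.add_argument("--reps", type=int, default=10,
                    help="contractions per force level")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = ScenarioConfig(seed=args.seed, force_reps=args.reps)
    tables = run_signal_quality(cfg)
    for name, df in tables.items():
        df.to_csv(args.out / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.6g")

    amp = tables["amplitudes"]
    snr = tables["snr"]
    for kind in cfg.electrode_types:
        a = amp[amp.electrode == kind]
        s = snr[snr.electrode == kind]
        print(f"{kind:8s} raw rest {a.raw_rest_uv.mean():6.1f} μV | "
              f"filtered rest {a.filt_rest_uv.mean():5.2f} μV | "
              f"SNR @10% {s[s.level_mvc == 10].snr.iloc[0]:5.1f}, "
              f"@50% {s[s.level_mvc == 50].snr.iloc[0]:5.1f}")
    vib = tables["vibration"].set_index("electrode")
    print("vibration (conditioned on-phase RMS, μV):",
          {k: round(v, 1) for k, v in vib.filt_on_uv.items()})
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
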