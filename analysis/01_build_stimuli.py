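#!/usr/bin/env python
"""Build the stimulus schedules of the three experiments.

Writes per-experiment 243-trial schedules (condition tables + JSON
sidecar) and the per-condition stimulus metrics (entropy, similarity,
spectro-temporal density).  With --wav, renders one example trial per
experiment to 16-bit/44.1 kHz WAV.
"""

import argparse
from pathlib import Path

import numpy as np

from tonemask import quantify, stimulus


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--wav", action="store_true",
                    help="render one example trial per experiment")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for i, exp in enumerate(["I", "II", "III"]):
        sched = stimulus.build_schedule(exp, master_seed=args.seed + i)
        sched.write(args.out, events=False)
        metrics = quantify.metrics_table(exp)
        metrics.to_csv(args.out / f"stimulus_metrics_{exp}.csv", index=False)
        df = sched.conditions_frame()
        print(f"Experiment {exp}: {len(df)} trials "
              f"({int(df.target_present.sum())} target / "
              f"{int((~df.target_present).sum())} catch), "
              f"entropy {metrics.entropy_nats.min():.2f}-"
              f"{metrics.entropy_nats.max():.2f} nats, "
              f"density {metrics['std'].min():.0f}-"
              f"{metrics['std'].max():.0f} s^-1 oct^-1")
        if args.wav:
            trial = sched.trials[0]
            full = stimulus.build_trial(trial.masker, trial.target,
                                        np.random.default_rng(trial.seed))
            wav = stimulus.render_audio(full)
            path = args.out / f"example_trial_{exp}.wav"
            stimulus.write_wav(path, wav)
            print(f"  wrote {path} ({len(full.events)} tone events)")


if __name__ == "__main__":
    main()
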