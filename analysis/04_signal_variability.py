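#!/usr/bin/env python
"""Scenario 3: coding differences can co-occur with learning differences.

Pairing a low learning rate with strong neural coding (alpha=0.05,
phi=2) against the opposite profile (alpha=0.5, phi=0.5) flips the
signal-variability ordering of scenario 1: now the slow learner has the
more variable neural signal, driven by the larger phi.
"""

import argparse
from pathlib import Path

from latentsim.scenarios import scenario3

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--fast", action="store_true")
    args = p.parse_args()
    s3 = scenario3(n_replicates=5 if args.fast else 50, seed=args.seed)
    s3.save(OUT)
    for subj, sd in s3.stats["mean_signal_sd_by_subject"].items():
        print(f"{subj}: noiseless signal SD {sd:.3f}")
    print("Finding: the low-learning-rate/high-coding subject produces the "
          "more variable neural signal — fMRI adds information that "
          "behavior alone cannot give.")


if __name__ == "__main__":
    main()
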