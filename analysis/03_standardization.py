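#!/usr/bin/env python
"""Scenario 2: standardizing the PE regressor manufactures phi differences.

The same data are analyzed with raw and with SD-standardized PE
regressors.  The standardized estimate equals the raw one multiplied by
the subject's PE standard deviation — so any learning-rate-driven
difference in PE variability reappears, spuriously, as a difference in
neural coding.
"""

import argparse
from pathlib import Path

from latentsim.scenarios import scenario2

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--fast", action="store_true")
    args = p.parse_args()
    s2 = scenario2(n_replicates=5 if args.fast else 50, seed=args.seed)
    s2.save(OUT)
    raw = s2.stats["mean_phi_hat_raw_by_subject"]
    std = s2.stats["mean_phi_hat_standardized_by_subject"]
    for subj in raw:
        print(f"{subj}: phi raw {raw[subj]:.3f} | standardized {std[subj]:.3f}")
    print(f"max |ratio - PE sd| across fits: {s2.stats['max_abs_ratio_minus_sd']:.2e}")
    print("Finding: raw estimates agree across subjects; standardized ones "
          "differ exactly by the subjects' PE standard deviations.")


if __name__ == "__main__":
    main()
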