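#!/usr/bin/env python
"""Scenario 1: learning-rate differences without neural-coding differences.

Two choice-free learners share identical outcome sequences and the same
neural-coding parameter phi.  The high-learning-rate subject produces
more variable prediction errors (and hence a more variable neural
signal), yet the estimated phi does not differ between subjects.
"""

import argparse
from pathlib import Path

from latentsim.scenarios import scenario1

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--fast", action="store_true")
    args = p.parse_args()
    s1 = scenario1(n_replicates=5 if args.fast else 50, seed=args.seed)
    s1.save(OUT)
    pe = s1.stats["mean_pe_variance_by_subject"]
    phi = s1.stats["mean_phi_hat_by_subject"]
    print(f"mean PE variance:  alpha=0.05 -> {pe['alpha=0.05']:.3f}, "
          f"alpha=0.5 -> {pe['alpha=0.5']:.3f}")
    print(f"mean phi estimate: alpha=0.05 -> {phi['alpha=0.05']:.3f}, "
          f"alpha=0.5 -> {phi['alpha=0.5']:.3f}")
    flagged = s1.flags["alpha=0.05 vs alpha=0.5"]
    print(f"phi contrast flagged at 3 SE: {flagged}")
    print("Finding: behavioral PE variability differs with the learning "
          "rate while the neural-coding estimate does not — the "
          "individual differences live in the regressor, not in phi.")


if __name__ == "__main__":
    main()
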