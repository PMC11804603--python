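#!/usr/bin/env python
"""Scenario 6: unmodeled outcome sensitivity is spuriously coded.

Data are generated under a sweep of the outcome-sensitivity parameter
gamma but fitted with gamma fixed at 1 (the common, silently incorrect,
assumption).  Because choices identify only the product beta*gamma, the
sensitivity loads onto the estimated inverse temperature; and because
the true PEs scale with gamma while the fitted ones do not, it also
loads onto the estimated neural coding.
"""

import argparse
from pathlib import Path

from latentsim.scenarios import scenario6

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--fast", action="store_true")
    args = p.parse_args()
    s6 = scenario6(n_datasets=12 if args.fast else 102, seed=args.seed)
    s6.save(OUT)
    print(s6.tables["cells"].round(3).to_string(index=False))
    print(f"Spearman rho(gamma, beta estimate): {s6.stats['spearman_gamma_beta_hat']:+.2f}")
    print(f"Spearman rho(gamma, phi estimate):  {s6.stats['spearman_gamma_phi_hat']:+.2f}")
    print("Finding: both the inverse-temperature and the neural-coding "
          "estimates rise monotonically with true outcome sensitivity — "
          "spurious coding differences that model comparison cannot "
          "detect (the likelihood only sees beta*gamma).")


if __name__ == "__main__":
    main()
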