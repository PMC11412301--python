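"""Simulate the torque-matching cohort.

Generates a 10-participant cohort under the default protocol — three
blocks of ten trials (two practice) at 10/30/50 % MVT_SABD shoulder
loads, elbow target 25 % MVT_EF — and writes it as per-trial CSVs with
JSON sidecars under results/cohort/.
"""

import sys
from pathlib import Path

from torquematch.config import GeneratorConfig
from torquematch.io import write_cohort
from torquematch.synthetic import generate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/cohort")


def main() -> None:
    cfg = GeneratorConfig(n_participants=10, seed=SEED)
    cohort = generate_cohort(cfg)
    write_cohort(cohort, OUT)
    n_trials = sum(len(trials) for _, trials in cohort)
    print(f"simulated {len(cohort)} participants, {n_trials} trials "
          f"({cfg.trials_per_block} per block, first {cfg.n_practice} "
          f"practice) -> {OUT}")


if __name__ == "__main__":
    main()
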