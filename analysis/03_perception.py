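"""Perceptual outcomes: constant and variable matching error.

Reads results/trial_features.tsv and writes per-participant, per-load CE
and VE to results/perception.tsv.  With the default generator, mean CE
should rise with the shoulder abduction load (the injected load-dependent
perceptual bias) while VE stays roughly constant near the injected
match-noise SD.
"""

from pathlib import Path

import pandas as pd

from torquematch.perception import summarize_perception

FEATURES = Path("results/trial_features.tsv")
OUT = Path("results/perception.tsv")


def main() -> None:
    features = pd.read_csv(FEATURES, sep="\t")
    perception = summarize_perception(features)
    perception.to_csv(OUT, sep="\t", index=False)
    print(f"{len(perception)} participant x load cells -> {OUT}")
    for load, grp in perception.groupby("load"):
        print(f"  load {load:.0%}: CE {grp['ce_nm'].mean():+.2f} "
              f"+/- {grp['ce_nm'].std(ddof=1):.2f} Nm | "
              f"VE {grp['ve_nm'].mean():.2f} Nm")


if __name__ == "__main__":
    main()
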