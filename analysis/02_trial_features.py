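"""Extract per-trial torque and EMG features from the simulated cohort.

Reads results/cohort/, runs the EMG preprocessing chain (250 Hz low-pass,
60 Hz notch, rectification, 250 ms RMS window, MVC normalization) and the
torque segment analysis, applies the validity rules (practice exclusion,
10 % MVT_SABD match-phase shoulder limit), and writes the tidy per-trial
table to results/trial_features.tsv.
"""

from pathlib import Path

import pandas as pd

from torquematch.features import compute_trial_features, features_table
from torquematch.io import read_cohort

COHORT = Path("results/cohort")
OUT = Path("results/trial_features.tsv")


def main() -> None:
    cohort = read_cohort(COHORT)
    tables = []
    for ref, trials in cohort:
        feats = [compute_trial_features(t, ref) for t in trials]
        tables.append(features_table(feats))
    df = pd.concat(tables, ignore_index=True)
    df.to_csv(OUT, sep="\t", index=False)
    valid = df[df["valid"]]
    print(f"{len(df)} trials, {len(valid)} valid -> {OUT}")
    for load, grp in valid.groupby("load"):
        print(f"  load {load:.0%}: CV {grp['cv'].mean():.2f}% | "
              f"coactivation {grp['coactivation'].mean():.1f}% | "
              f"T_ref {grp['t_ref'].mean():.2f} s")


if __name__ == "__main__":
    main()
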