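"""Spearman correlations between torque-generation features and the
matching error.

For each participant and shoulder load, correlates CV, coactivation and
T_ref with tau_err across the eight valid testing trials (exact
permutation p-values at this n).  With the default generator these
features are independent of the matching error, so significant cells
should appear at roughly the 5 % false-positive rate.
"""

from pathlib import Path

import pandas as pd

from torquematch.stats import correlate_features

FEATURES = Path("results/trial_features.tsv")
OUT = Path("results/correlations.tsv")


def main() -> None:
    features = pd.read_csv(FEATURES, sep="\t")
    corr = correlate_features(features)
    corr.to_csv(OUT, sep="\t", index=False)
    tested = corr.dropna(subset=["p_value"])
    sig = tested[tested["p_value"] < 0.05]
    print(f"{len(tested)} feature x participant x load cells -> {OUT}")
    print(f"significant at p<0.05: {len(sig)}/{len(tested)} "
          f"({100 * len(sig) / max(len(tested), 1):.1f}%)")
    if len(sig):
        print(sig.to_string(index=False))


if __name__ == "__main__":
    main()
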