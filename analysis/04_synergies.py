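"""Muscle-synergy decomposition and cross-participant matching.

For each participant: assemble the 8 x 48 activity matrix (2 phases x 8
analyzed trials x 3 loads), normalize rows (max, then unit variance),
factorize with NMF for n = 1..8 and keep the smallest model with VAF >=
95 %.  Then match synergies across participants against the 95th
percentile of 10^6 random-synergy scalar products.  Writes W/H tables,
VAF curves and the group result under results/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from torquematch.features import compute_trial_features
from torquematch.io import read_cohort
from torquematch.synergy import (
    assemble_matrix,
    match_synergies,
    normalize_matrix,
    random_synergy_threshold,
    select_synergy_count,
    synergy_tables,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    cohort = read_cohort(COHORT)
    models, vaf_rows = {}, []
    (OUT / "synergies").mkdir(parents=True, exist_ok=True)
    for ref, trials in cohort:
        feats = [compute_trial_features(t, ref) for t in trials]
        matrix = normalize_matrix(assemble_matrix(feats))
        model = select_synergy_count(matrix.values, seed=SEED)
        models[ref.participant_id] = model
        for n, vaf in enumerate(model.vaf_curve, start=1):
            vaf_rows.append({"participant": ref.participant_id,
                             "n_synergies": n, "vaf": vaf})
        w_df, h_df = synergy_tables(model, matrix.column_labels)
        w_df.to_csv(OUT / "synergies" / f"{ref.participant_id}_W.tsv",
                    sep="\t")
        h_df.to_csv(OUT / "synergies" / f"{ref.participant_id}_H.tsv",
                    sep="\t")
        print(f"  {ref.participant_id}: n = {model.n}, "
              f"VAF = {100 * model.vaf:.1f}%")
    pd.DataFrame(vaf_rows).to_csv(OUT / "vaf_curves.tsv", sep="\t",
                                  index=False)
    threshold = random_synergy_threshold(seed=SEED)
    group = match_synergies(models, threshold, sorted(models)[0])
    (OUT / "group_synergies.json").write_text(json.dumps({
        "threshold": group.threshold,
        "reference_participant": group.reference_participant,
        "matches": {p: {str(k): v for k, v in m.items()}
                    for p, m in group.matches.items()},
        "mean_W": group.mean_W.tolist(),
        "n_matched": group.n_matched.tolist(),
    }, indent=1))
    counts = [m.n for m in models.values()]
    vafs = [m.vaf for m in models.values()]
    print(f"synergy counts: {counts}")
    print(f"selected-model VAF: mean {100 * sum(vafs) / len(vafs):.1f}%, "
          f"min {100 * min(vafs):.1f}%")
    print(f"similarity threshold {threshold:.3f}; "
          f"matched per reference synergy: {group.n_matched.tolist()}")


if __name__ == "__main__":
    main()
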