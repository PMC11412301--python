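"""End-to-end orchestration: simulate (or load) -> EMG envelopes ->
trial features -> perception outcomes -> muscle synergies ->
feature/error correlations -> tidy exports and a summary report.

All stage outputs are plain TSV/JSON so any downstream stats environment
(e.g. a mixed-effects model fit) can consume them directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from torquematch.config import GeneratorConfig
from torquematch.features import compute_trial_features, features_table
from torquematch.io import read_cohort
from torquematch.perception import summarize_perception
from torquematch.stats import correlate_features
from torquematch.synergy import (
    assemble_matrix,
    match_synergies,
    normalize_matrix,
    random_synergy_threshold,
    select_synergy_count,
    synergy_tables,
)
from torquematch.synthetic import generate_cohort

log = logging.getLogger("torquematch")


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    output_dir: Path = Path("results")
    input_dir: Path | None = None          # read trials instead of simulating
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    vaf_threshold: float = 0.95
    n_random: int = 1000
    seed: int = 0
    strict_completeness: bool = False      # skip vs fail incomplete subjects
    nmf_restarts: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf_threshold < 1.0:
            raise ValueError("vaf_threshold must lie in (0, 1)")
        if self.n_random < 2:
            raise ValueError("n_random must be >= 2")
        self.output_dir = Path(self.output_dir)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary.

    Per-participant failures at the synergy stage are logged and skipped
    (unless ``strict_completeness``); the torque/perception stages always
    cover every participant.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    if config.input_dir is not None:
        cohort = read_cohort(config.input_dir)
        log.info("loaded %d participants from %s", len(cohort),
                 config.input_dir)
    else:
        cohort = generate_cohort(config.generator)
        log.info("simulated %d participants", len(cohort))

    # --- per-trial features ----------------------------------------------
    all_feats = {}
    for ref, trials in cohort:
        all_feats[ref.participant_id] = [
            compute_trial_features(t, ref) for t in trials]
    features = pd.concat(
        [features_table(f) for f in all_feats.values()], ignore_index=True)
    features.to_csv(out / "trial_features.tsv", sep="\t", index=False)

    # --- perception -------------------------------------------------------
    perception = summarize_perception(features)
    perception.to_csv(out / "perception.tsv", sep="\t", index=False)

    # --- synergies --------------------------------------------------------
    have_emg = any(f.mean_norm_emg is not None
                   for feats in all_feats.values() for f in feats)
    models, group, vaf_rows = {}, None, []
    if have_emg:
        for pid, feats in all_feats.items():
            try:
                matrix = normalize_matrix(
                    assemble_matrix(feats,
                                    strict=config.strict_completeness))
            except ValueError as exc:
                if config.strict_completeness:
                    raise
                log.warning("skipping %s at synergy stage: %s", pid, exc)
                continue
            model = select_synergy_count(
                matrix.values, vaf_threshold=config.vaf_threshold,
                seed=config.seed, restarts=config.nmf_restarts)
            models[pid] = model
            for n, vaf in enumerate(model.vaf_curve, start=1):
                vaf_rows.append({"participant": pid, "n_synergies": n,
                                 "vaf": vaf})
            w_df, h_df = synergy_tables(model, matrix.column_labels)
            syn_dir = out / "synergies"
            syn_dir.mkdir(exist_ok=True)
            w_df.to_csv(syn_dir / f"{pid}_W.tsv", sep="\t")
            h_df.to_csv(syn_dir / f"{pid}_H.tsv", sep="\t")
        pd.DataFrame(vaf_rows).to_csv(out / "vaf_curves.tsv", sep="\t",
                                      index=False)
        if models:
            threshold = random_synergy_threshold(
                n_random=config.n_random, seed=config.seed)
            reference = sorted(models)[0]
            group = match_synergies(models, threshold, reference)
            group_json = {
                "threshold": group.threshold,
                "reference_participant": group.reference_participant,
                "matches": {p: {str(k): v for k, v in m.items()}
                            for p, m in group.matches.items()},
                "mean_W": group.mean_W.tolist(),
                "mean_H": group.mean_H.tolist(),
                "n_matched": group.n_matched.tolist(),
            }
            (out / "group_synergies.json").write_text(
                json.dumps(group_json, indent=1))

    # --- correlations -----------------------------------------------------
    correlations = correlate_features(features)
    correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)

    # --- summary ----------------------------------------------------------
    summary = _summarize(features, perception, models)
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _per_load_stats(df: pd.DataFrame, col: str) -> list[dict]:
    rows = []
    for load, grp in df.groupby("load", sort=True):
        vals = grp[col].dropna()
        rows.append({"load": float(load), "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)), "n": int(len(vals))})
    return rows


def _summarize(features: pd.DataFrame, perception: pd.DataFrame,
               models: dict) -> dict:
    valid = features[features["valid"]]
    summary = {
        "n_participants": int(features["participant"].nunique()),
        "n_trials": int(len(features)),
        "n_valid_trials": int(len(valid)),
        "per_load": {col: _per_load_stats(valid, col)
                     for col in ("cv", "coactivation", "t_ref", "tau_err")},
        "perception_per_load": {col: _per_load_stats(perception, col)
                                for col in ("ce_nm", "ve_nm")},
    }
    if models:
        counts = np.array([m.n for m in models.values()])
        vafs = np.array([m.vaf for m in models.values()])
        summary["synergy"] = {
            "count_histogram": {int(k): int((counts == k).sum())
                                for k in np.unique(counts)},
            "vaf_mean": float(vafs.mean()),
            "vaf_sd": float(vafs.std(ddof=1)) if len(vafs) > 1 else 0.0,
            "vaf_min": float(vafs.min()),
        }
    return summary
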