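import numpy as np
import pytest

from torquematch.config import GeneratorConfig
from torquematch.features import compute_trial_features
from torquematch.synergy import (
    assemble_matrix,
    normalize_matrix,
    select_synergy_count,
)
from torquematch.synthetic import generate_cohort, generate_participant


@pytest.fixture(scope="session")
def default_cohort():
    """Four participants under the default generator configuration."""
    cfg = GeneratorConfig(n_participants=4, seed=42)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def lownoise_cohort():
    """Three participants with 1 % EMG line-noise and noise-floor levels."""
    cfg = GeneratorConfig(n_participants=3, seed=7,
                          emg_line_noise_amp=0.01, emg_noise_floor=0.01)
    return cfg, generate_cohort(cfg)


def _analyze(cfg, cohort):
    out = {}
    for ref, trials in cohort:
        feats = [compute_trial_features(t, ref) for t in trials]
        matrix = normalize_matrix(assemble_matrix(feats))
        model = select_synergy_count(matrix.values, seed=0)
        out[ref.participant_id] = (feats, matrix, model)
    return out


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Features, normalized matrix and selected synergy model per
    participant of the default cohort."""
    cfg, cohort = default_cohort
    return cfg, _analyze(cfg, cohort)


@pytest.fixture(scope="session")
def lownoise_analysis(lownoise_cohort):
    cfg, cohort = lownoise_cohort
    return cfg, _analyze(cfg, cohort)


@pytest.fixture(scope="session")
def single_participant():
    """One default-noise participant with reference and trials."""
    cfg = GeneratorConfig(n_participants=1, seed=5)
    ref, trials = generate_participant("P01", 123, cfg)
    return cfg, ref, trials


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
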