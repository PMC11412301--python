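"""Synergy pipeline: matrix assembly and normalization, NMF correctness
against an independent oracle, VAF model selection, the random-synergy
null, and cross-participant matching."""

import numpy as np
import pytest

from torquematch.config import default_ground_truth_w
from torquematch.features import TrialFeatures
from torquematch.synergy import (
    ActivityMatrix,
    SynergyModel,
    assemble_matrix,
    compute_vaf,
    match_synergies,
    nmf_decompose,
    normalize_matrix,
    random_synergy_products,
    random_synergy_threshold,
    select_synergy_count,
)


def make_features(n_loads=3, n_trials=8, seed=0, drop=None):
    rng = np.random.default_rng(seed)
    feats = []
    for load in [0.1, 0.3, 0.5][:n_loads]:
        for trial in range(2, 2 + n_trials):
            if drop and (load, trial) in drop:
                continue
            feats.append(TrialFeatures(
                participant_id="P01", load_condition=load,
                trial_index=trial, valid=True,
                mean_norm_emg=rng.uniform(1.0, 30.0, (8, 2))))
    return feats


class TestAssembly:
    def test_complete_participant_gives_8x48(self):
        a = assemble_matrix(make_features())
        assert a.values.shape == (8, 48)

    def test_column_order_is_deterministic(self):
        f = make_features()
        a1 = assemble_matrix(f)
        a2 = assemble_matrix(list(reversed(f)))
        np.testing.assert_array_equal(a1.values, a2.values)
        assert a1.column_labels == a2.column_labels
        # load ascending, trial ascending, phase reference-then-match
        assert a1.column_labels[0] == ("reference", 2, 0.1)
        assert a1.column_labels[1] == ("match", 2, 0.1)
        assert a1.column_labels[-1] == ("match", 9, 0.5)

    def test_missing_cell_rejected_in_strict_mode(self):
        feats = make_features(drop={(0.3, 4)})
        with pytest.raises(ValueError, match=r"load=0.3"):
            assemble_matrix(feats, strict=True)
        a = assemble_matrix(feats, strict=False)
        assert a.values.shape == (8, 46)

    def test_invalid_trials_ignored(self):
        feats = make_features()
        feats[0].valid = False
        with pytest.raises(ValueError):
            assemble_matrix(feats, strict=True)


class TestNormalization:
    def test_stage1_row_max_one(self):
        a = ActivityMatrix(np.array([[2.0, 4.0], [1.0, 3.0]] * 4),
                           [("reference", 0, 0.1), ("match", 0, 0.1)])
        out = normalize_matrix(a)
        # stage 1 scales [2, 4] to [0.5, 1] before variance scaling
        np.testing.assert_allclose(out.values[0] * out.row_scale[0],
                                   [2.0, 4.0])

    def test_stage2_unit_sample_variance(self):
        a = assemble_matrix(make_features())
        out = normalize_matrix(a)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1.0,
                                   atol=1e-9)

    def test_stage1_idempotent(self):
        a = assemble_matrix(make_features())
        once = normalize_matrix(a)
        twice = normalize_matrix(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_constant_row_rejected(self):
        vals = np.abs(np.random.default_rng(0).standard_normal((8, 48)))
        vals[3] = 5.0
        a = ActivityMatrix(vals, [("reference", i, 0.1) for i in range(48)])
        with pytest.raises(ValueError, match="MedDel"):
            normalize_matrix(a)

    def test_zero_row_rejected(self):
        vals = np.abs(np.random.default_rng(0).standard_normal((8, 48)))
        vals[0] = 0.0
        a = ActivityMatrix(vals, [("reference", i, 0.1) for i in range(48)])
        with pytest.raises(ValueError, match="BIC"):
            normalize_matrix(a)


class TestNmf:
    def test_exact_rank_one_reconstruction(self, rng):
        w = rng.uniform(0.1, 1.0, (8, 1))
        h = rng.uniform(0.1, 1.0, (1, 12))
        a = w @ h
        wf, hf, _ = nmf_decompose(a, 1, seed=0)
        assert compute_vaf(a, wf, hf) == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_als_oracle(self, rng):
        """Multiplicative updates reach the reconstruction error of an
        independent alternating-NNLS factorization within 1 %."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        a = rng.uniform(0.0, 1.0, (4, 6))
        w, h, _ = nmf_decompose(a, 2, seed=0, restarts=10)
        err = np.linalg.norm(a - w @ h)
        best = np.inf
        for seed in range(5):
            model = sklearn.NMF(n_components=2, init="random",
                                solver="cd", max_iter=5000, tol=1e-10,
                                random_state=seed)
            wo = model.fit_transform(a)
            best = min(best, np.linalg.norm(a - wo @ model.components_))
        assert err <= best * 1.01

    def test_seed_determinism(self, rng):
        a = rng.uniform(0.0, 1.0, (8, 20))
        r1 = nmf_decompose(a, 3, seed=5, restarts=3)
        r2 = nmf_decompose(a, 3, seed=5, restarts=3)
        np.testing.assert_array_equal(r1[0], r2[0])
        np.testing.assert_array_equal(r1[1], r2[1])

    def test_unit_norm_columns(self, rng):
        a = rng.uniform(0.0, 1.0, (8, 20))
        w, h, _ = nmf_decompose(a, 3, seed=0, restarts=3)
        np.testing.assert_allclose(np.linalg.norm(w, axis=0), 1.0,
                                   atol=1e-9)
        assert np.all(w >= 0) and np.all(h >= 0)

    def test_negative_matrix_rejected(self):
        with pytest.raises(ValueError):
            nmf_decompose(-np.ones((4, 4)), 1)

    def test_factor_recovery_under_noise(self, rng):
        """With <= 5 % rectified Gaussian noise, recovered columns align
        with the true synergies at cosine >= 0.9."""
        wt = default_ground_truth_w()
        ht = rng.uniform(0.0, 1.0, (2, 48))
        a = wt @ ht
        a = np.clip(a + 0.05 * a.mean() * rng.standard_normal(a.shape),
                    0.0, None)
        w, _, _ = nmf_decompose(a, 2, seed=0, restarts=10)
        sims = w.T @ wt
        # optimal column matching over the 2x2 similarity matrix
        best = max(sims[0, 0] * 0 + min(sims[0, 0], sims[1, 1]),
                   min(sims[0, 1], sims[1, 0]))
        assert best >= 0.9


class TestVaf:
    def test_exact_reconstruction_gives_one(self, rng):
        w = rng.uniform(0, 1, (8, 2))
        h = rng.uniform(0, 1, (2, 10))
        assert compute_vaf(w @ h, w, h) == pytest.approx(1.0)

    def test_zero_model_gives_zero(self, rng):
        a = rng.uniform(0.1, 1, (4, 5))
        assert compute_vaf(a, np.zeros((4, 1)), np.zeros((1, 5))) == 0.0

    def test_hand_arithmetic(self):
        a = np.eye(2)
        wh = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert compute_vaf(a, wh, np.eye(2)) == pytest.approx(0.5)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_vaf(np.zeros((2, 2)), np.zeros((2, 1)),
                        np.zeros((1, 2)))


class TestSelection:
    def test_noiseless_two_synergy_matrix_selects_two(self, rng):
        wt = default_ground_truth_w()
        ht = rng.uniform(0.0, 1.0, (2, 48))
        model = select_synergy_count(wt @ ht, seed=0, restarts=10)
        assert model.n == 2
        assert model.vaf >= 0.95
        assert model.vaf_curve[0] < 0.95  # one synergy is insufficient

    def test_zero_threshold_selects_one(self, rng):
        a = rng.uniform(0.1, 1.0, (8, 48))
        model = select_synergy_count(a, vaf_threshold=1e-12, seed=0,
                                     restarts=3)
        assert model.n == 1

    def test_vaf_curve_monotone_within_restart_tolerance(self, rng):
        a = rng.uniform(0.1, 1.0, (8, 24))
        model = select_synergy_count(a, vaf_threshold=0.9999, seed=0,
                                     restarts=5)
        diffs = np.diff(model.vaf_curve)
        assert np.all(diffs > -1e-3)


class TestRandomThreshold:
    def test_distribution_has_n_squared_values(self):
        products = random_synergy_products(n_random=100, seed=0)
        assert products.size == 100 * 100
        off = random_synergy_products(n_random=100, seed=0,
                                      include_self_pairs=False)
        assert off.size == 100 * 99

    def test_output_in_unit_interval(self):
        thr = random_synergy_threshold(n_random=200, seed=1)
        assert 0.0 < thr <= 1.0

    def test_percentile_stable_across_seeds(self):
        """Monte Carlo stability: thresholds from independent draws at
        n_random = 10^4 agree within 0.01."""
        t1 = random_synergy_threshold(n_random=10_000, seed=1)
        t2 = random_synergy_threshold(n_random=10_000, seed=2)
        assert abs(t1 - t2) < 0.01

    def test_threshold_exceeds_median(self):
        products = random_synergy_products(n_random=500, seed=3)
        thr = random_synergy_threshold(n_random=500, seed=3)
        assert thr > np.median(products)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            random_synergy_threshold(dim=1)
        with pytest.raises(ValueError):
            random_synergy_threshold(n_random=1)


def _model(w, pid_seed=0):
    n = w.shape[1]
    return SynergyModel(W=w, H=np.ones((n, 48)), n=n, vaf=1.0,
                        vaf_curve=np.ones(n), converged=True,
                        seed=pid_seed)


class TestMatching:
    def test_permuted_identical_synergies_fully_matched(self):
        w = default_ground_truth_w()
        models = {"P01": _model(w), "P02": _model(w[:, ::-1])}
        res = match_synergies(models, threshold=0.9, reference="P01")
        assert res.matches["P02"] == {0: 1, 1: 0}
        np.testing.assert_allclose(res.mean_W, w, atol=1e-9)

    def test_dissimilar_synergies_unmatched_and_excluded(self):
        w = default_ground_truth_w()
        other = np.zeros_like(w)
        other[6, 0] = other[7, 1] = 1.0  # trapezius-only vectors
        models = {"P01": _model(w), "P02": _model(other)}
        res = match_synergies(models, threshold=0.95, reference="P01")
        assert all(v is None for v in res.matches["P02"].values())
        np.testing.assert_allclose(res.mean_W, w, atol=1e-9)
        assert list(res.n_matched) == [1, 1]

    def test_reference_synergy_used_at_most_once(self):
        w = default_ground_truth_w()
        dup = np.column_stack([w[:, 0], w[:, 0] * 0.999 + 1e-3])
        dup /= np.linalg.norm(dup, axis=0)
        models = {"P01": _model(w), "P02": _model(dup)}
        res = match_synergies(models, threshold=0.5, reference="P01")
        assigned = [v for v in res.matches["P02"].values()
                    if v is not None]
        assert len(assigned) == len(set(assigned))

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            match_synergies({"P01": _model(default_ground_truth_w())},
                            0.9, "P99")

    def test_cohort_mean_synergies_match_ground_truth(self,
                                                      default_analysis):
        """On the default synthetic cohort, group-mean synergies align
        with the generator's ground truth (expressed in the normalized
        matrix space) above the random-similarity threshold."""
        cfg, analysis = default_analysis
        models = {pid: model for pid, (_, _, model) in analysis.items()}
        thr = random_synergy_threshold(seed=0)
        res = match_synergies(models, thr, sorted(models)[0])
        mean_w = res.mean_W / np.linalg.norm(res.mean_W, axis=0)
        scales = np.mean([m.row_scale for _, m, _ in analysis.values()],
                         axis=0)
        wt = cfg.ground_truth_w / scales[:, None]
        wt /= np.linalg.norm(wt, axis=0)
        best = (mean_w.T @ wt).max(axis=1)
        assert np.all(best >= thr), best
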