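import numpy as np
import pytest

import erpsem
from erpsem.encoding import (
    augment_features,
    compare_models,
    encode_cv,
    fit_encoder,
    make_folds,
    signed_r2,
    window_average,
)
from erpsem.simulate import Covariates


class TestMakeFolds:
    @pytest.mark.parametrize("n,k,size", [(150, 10, 15), (960, 10, 96)])
    def test_equal_fold_sizes(self, n, k, size):
        folds = make_folds([f"w{i}" for i in range(n)], k, seed=0)
        counts = np.bincount(folds.assignments)
        assert np.all(counts == size)

    def test_folds_partition_items(self):
        folds = make_folds([f"w{i}" for i in range(47)], 10, seed=3)
        seen = np.concatenate([folds.split(f)[1] for f in range(10)])
        assert sorted(seen) == list(range(47))

    def test_deterministic_given_seed(self):
        words = [f"w{i}" for i in range(50)]
        a = make_folds(words, 5, seed=9)
        b = make_folds(words, 5, seed=9)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_too_many_folds(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], 4, seed=0)


class TestSignedR2:
    def test_perfect_and_inverted(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        assert signed_r2(v, v) == pytest.approx(1.0)
        assert signed_r2(-v, v) == pytest.approx(-1.0)

    def test_exact_half_correlation(self):
        # Gram-Schmidt construction: observed = r*u + sqrt(1-r^2)*w with
        # u, w orthonormal and mean-free, so the sample correlation is
        # exactly 0.5 and the signed square exactly 0.25.
        rng = np.random.default_rng(0)
        u = rng.normal(size=10)
        u -= u.mean()
        u /= np.linalg.norm(u)
        w = rng.normal(size=10)
        w -= w.mean()
        w -= (w @ u) * u
        w /= np.linalg.norm(w)
        obs = 0.5 * u + np.sqrt(1 - 0.25) * w
        assert signed_r2(u, obs) == pytest.approx(0.25, abs=1e-12)

    def test_constant_vector_scores_zero(self):
        assert signed_r2(np.ones(5), np.array([1.0, 2.0, 3.0, 4.0, 5.0])) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            signed_r2([1.0, 2.0, 3.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def noiseless_encoding(noiseless_erp, small_space, folds_300):
    space, _ = small_space
    erp, _ = noiseless_erp
    return encode_cv(erp, space.matrix, folds_300, penalty=1e-6, n_boot=500)


class TestEncodeCV:
    def test_noiseless_window_recovery(self, noiseless_encoding):
        win = window_average(noiseless_encoding, 300.0, 500.0)
        pre = window_average(noiseless_encoding, -100.0, 0.0)
        assert win.mean() >= 0.99
        assert abs(pre.mean()) <= 0.01

    def test_scores_bounded(self, noiseless_encoding):
        assert np.all(noiseless_encoding.scores >= -1.0)
        assert np.all(noiseless_encoding.scores <= 1.0)

    def test_broken_pairing_scores_near_zero(self, noisy_erp, small_space, folds_300):
        space, _ = small_space
        erp, _ = noisy_erp
        perm = np.random.default_rng(99).permutation(space.n_words)
        res = encode_cv(erp, space.matrix[perm], folds_300, n_boot=200)
        assert abs(res.mean_window_score) < 0.05

    def test_primal_dual_prediction_identity(self):
        space, truth = erpsem.generate_embeddings(40, 10, 4, 4.0, seed=3)
        erpsem.plant_forward_model(truth, 8, planted_factors=(0, 1), noise_sd=1.0)
        erp = erpsem.generate_erp(space, truth, 8)
        folds = make_folds(space.words, 10, seed=3)
        _, pred_p = encode_cv(erp, space.matrix, folds, 1.0,
                              return_predictions=True, n_boot=100)
        _, pred_d = encode_cv(erp, space.matrix, folds, 1.0, solver="dual",
                              return_predictions=True, n_boot=100)
        assert np.max(np.abs(pred_p - pred_d)) < 1e-6

    def test_window_score_nonincreasing_in_noise(self, small_space, folds_300):
        space, truth0 = small_space
        means = []
        for sd in (0.5, 2.0, 5.0):
            truth = erpsem.GroundTruth(
                factor_loadings=truth0.factor_loadings,
                loading_directions=truth0.loading_directions,
                seed=truth0.seed,
            )
            erpsem.plant_forward_model(truth, 28, noise_sd=sd)
            erp = erpsem.generate_erp(space, truth, 28)
            res = encode_cv(erp, space.matrix, folds_300, n_boot=100)
            means.append(res.mean_window_score)
        assert means[0] > means[1] > means[2]

    def test_deterministic_result(self, noisy_erp, small_space, folds_300):
        space, _ = small_space
        erp, _ = noisy_erp
        a = encode_cv(erp, space.matrix, folds_300, n_boot=300)
        b = encode_cv(erp, space.matrix, folds_300, n_boot=300)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.ci, b.ci)
        assert a.test.p_value == b.test.p_value

    def test_misaligned_features_error(self, noisy_erp, folds_300):
        erp, _ = noisy_erp
        with pytest.raises(ValueError):
            encode_cv(erp, np.zeros((10, 5)), folds_300)


class TestFitEncoder:
    def test_model_predictions_match_cv_fold(self, small_space):
        space, truth0 = small_space
        truth = erpsem.GroundTruth(
            factor_loadings=truth0.factor_loadings,
            loading_directions=truth0.loading_directions,
            seed=truth0.seed,
        )
        erpsem.plant_forward_model(truth, 8)
        erp = erpsem.generate_erp(space, truth, 8)
        folds = make_folds(space.words, 10, seed=4)
        train, test = folds.split(0)
        model = fit_encoder(erp, space.matrix, train, penalty=1.0)
        _, preds = encode_cv(erp, space.matrix, folds, 1.0,
                             return_predictions=True, n_boot=100)
        np.testing.assert_allclose(model.predict(space.matrix)[test],
                                   preds[test], atol=1e-8)


class TestWindowAverage:
    def test_window_timepoint_count(self, noiseless_encoding):
        mask = (noiseless_encoding.time_ms >= 300.0) & (
            noiseless_encoding.time_ms <= 500.0
        )
        assert mask.sum() == 41

    def test_whole_epoch_equals_row_means(self, noiseless_encoding):
        whole = window_average(noiseless_encoding, -100.0, 920.0)
        np.testing.assert_allclose(whole, noiseless_encoding.scores.mean(axis=1))

    def test_constant_scores_average_to_constant(self, noiseless_encoding):
        import copy

        res = copy.copy(noiseless_encoding)
        res.scores = np.full_like(noiseless_encoding.scores, 0.07)
        np.testing.assert_allclose(window_average(res, 300.0, 500.0), 0.07)

    def test_empty_window_error(self, noiseless_encoding):
        with pytest.raises(ValueError):
            window_average(noiseless_encoding, 2000.0, 3000.0)


class TestCompareModels:
    def test_self_comparison_is_degenerate(self, noiseless_encoding):
        cmp_res = compare_models(noiseless_encoding, noiseless_encoding)
        np.testing.assert_array_equal(cmp_res.fold_differences, 0.0)
        assert cmp_res.test.degenerate and cmp_res.test.p_value == 1.0

    def test_swap_negates_differences(self, noisy_erp, small_space, folds_300):
        space, _ = small_space
        erp, _ = noisy_erp
        tax = erpsem.generate_taxonomy(space, fidelity=0.5, seed=2)
        tax_feat = erpsem.path_similarity_matrix(tax, space.words).values
        a = encode_cv(erp, space.matrix, folds_300, n_boot=100)
        b = encode_cv(erp, tax_feat, folds_300, n_boot=100)
        ab = compare_models(a, b)
        ba = compare_models(b, a)
        np.testing.assert_allclose(ab.fold_differences, -ba.fold_differences)
        np.testing.assert_allclose(ab.diff_timecourse, -ba.diff_timecourse)

    def test_mismatched_folds_error(self, noisy_erp, small_space, folds_300):
        space, _ = small_space
        erp, _ = noisy_erp
        other = make_folds(space.words, 10, seed=555)
        a = encode_cv(erp, space.matrix, folds_300, n_boot=100)
        b = encode_cv(erp, space.matrix, other, n_boot=100)
        with pytest.raises(ValueError):
            compare_models(a, b)

    def test_rank_sum_variant_runs(self, noisy_erp, small_space, folds_300):
        space, _ = small_space
        erp, _ = noisy_erp
        tax = erpsem.generate_taxonomy(space, fidelity=0.5, seed=2)
        tax_feat = erpsem.path_similarity_matrix(tax, space.words).values
        a = encode_cv(erp, space.matrix, folds_300, n_boot=100)
        b = encode_cv(erp, tax_feat, folds_300, n_boot=100)
        res = compare_models(a, b, test="rank_sum")
        assert res.test.name == "wilcoxon_rank_sum"
        assert 0.0 <= res.test.p_value <= 1.0


class TestAugmentFeatures:
    def test_appends_two_columns(self):
        words = [f"w{i}" for i in range(150)]
        rng = np.random.default_rng(1)
        cov = Covariates(words, rng.normal(size=150), rng.normal(size=150))
        out = augment_features(rng.normal(size=(150, 300)), words, cov)
        assert out.shape == (150, 302)
        np.testing.assert_array_equal(out[:, 300], cov.log_frequency)

    def test_zero_covariates_leave_scores_unchanged(self, noisy_erp, small_space,
                                                    folds_300):
        space, _ = small_space
        erp, _ = noisy_erp
        cov = Covariates(space.words, np.zeros(space.n_words),
                         np.zeros(space.n_words))
        base = encode_cv(erp, space.matrix, folds_300, n_boot=100)
        aug = encode_cv(erp, augment_features(space.matrix, space.words, cov),
                        folds_300, n_boot=100)
        np.testing.assert_allclose(aug.scores, base.scores, atol=1e-8)

    def test_word_mismatch_error(self):
        cov = Covariates(["a", "b"], np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            augment_features(np.zeros((2, 3)), ["a", "c"], cov)
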