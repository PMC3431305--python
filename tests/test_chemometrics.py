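"""PCA, OPLS-DA, cross-validation, classification and Fisher probabilities."""

import numpy as np
import pytest
from scipy import stats

import metaboprof as mp
from metaboprof.chemometrics import (cross_validate, dummy_code,
                                     fisher_exact_probability,
                                     misclassification_table, stratified_folds)


class TestPca:
    def test_rank_one_matrix_fully_explained_by_first_component(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=6))
        model = mp.fit_pca(X, n_components=1)
        assert model.r2x_cum == pytest.approx(1.0, abs=1e-10)

    def test_explained_variance_non_increasing(self, rng):
        X = rng.normal(size=(20, 8))
        model = mp.fit_pca(X, n_components=5)
        assert np.all(np.diff(model.r2x_per_component) <= 1e-12)

    def test_matches_eigendecomposition_oracle_up_to_sign(self, rng):
        """Scores/loadings agree with a dense eigensolver on the covariance."""
        X = rng.normal(size=(10, 6))
        model = mp.fit_pca(X, n_components=4)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        P_oracle = evecs[:, order[:4]]
        T_oracle = Xc @ P_oracle
        for a in range(4):
            s = np.sign(P_oracle[np.argmax(np.abs(model.loadings[:, a])), a])
            np.testing.assert_allclose(model.loadings[:, a],
                                       s * P_oracle[:, a], atol=1e-8)
            np.testing.assert_allclose(model.scores[:, a],
                                       s * T_oracle[:, a], atol=1e-8)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(15, 7))
        model = mp.fit_pca(X, n_components=4)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            mp.fit_pca(np.zeros((5, 3)), n_components=1)


class TestHotellingEllipse:
    def test_equal_spread_gives_circle(self, rng):
        T = rng.normal(size=(50, 2))
        T = (T - T.mean(0)) / T.std(0, ddof=1)   # force s1 == s2
        ell = mp.hotelling_ellipse(T)
        assert ell.semi_axes[0] == pytest.approx(ell.semi_axes[1])

    def test_scale_equivariance(self, rng):
        T = rng.normal(size=(30, 2))
        a = mp.hotelling_ellipse(T).semi_axes
        b = mp.hotelling_ellipse(2 * T).semi_axes
        assert b[0] == pytest.approx(2 * a[0])
        assert b[1] == pytest.approx(2 * a[1])

    def test_flags_match_direct_t2_oracle(self, rng):
        """n = 45: flagged set equals points with T2 above the F-based
        critical value, computed independently point by point."""
        T = rng.normal(size=(45, 2)) * [2.0, 0.5]
        ell = mp.hotelling_ellipse(T, alpha=0.05)
        n = 45
        crit = 2 * (n ** 2 - 1) / (n * (n - 2)) * stats.f.ppf(0.95, 2, n - 2)
        s2 = T.var(axis=0, ddof=1)
        t2 = (((T - T.mean(0)) ** 2) / s2).sum(axis=1)
        np.testing.assert_array_equal(ell.outliers, t2 > crit)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            mp.hotelling_ellipse(np.zeros((2, 2)))


def _two_class_data(rng, n=12, m=8, sep=4.0, noise=0.5):
    y = np.array(["A"] * (n // 2) + ["B"] * (n // 2), dtype=object)
    X = noise * rng.normal(size=(n, m))
    X[y == "A", 0] += sep
    return X, y


class TestOplsda:
    def test_perfect_predictor_feature_dominates_weights(self, rng):
        X, y = _two_class_data(rng, noise=1e-6)
        model = mp.fit_oplsda(X, y, n_pred=1, n_orth=0, k_folds=3, seed=0,
                              _with_cv=False)
        w = np.abs(model.Wp[:, 0])
        assert w[0] > 0.99
        assert model.r2y_cum > 0.999

    def test_structured_orthogonal_variation_leaves_tp_unchanged(self, rng):
        """Adding a strong component whose loadings are identical in both
        classes raises r2x_o but does not move the predictive scores."""
        X, y = _two_class_data(rng)
        base = mp.fit_oplsda(X, y, n_pred=1, n_orth=0, k_folds=3, seed=0,
                             _with_cv=False)
        # structured variation on fresh features, scores orthogonal to the
        # class contrast and to the base predictive score
        t_o = rng.normal(size=len(y))
        contrast = (y == "A").astype(float) - (y == "A").mean()
        for v in (contrast, base.Tp[:, 0]):
            t_o -= (t_o @ v) / (v @ v) * v
        p_o = rng.normal(size=4)
        X_aug = np.hstack([X, 5.0 * np.outer(t_o, p_o)])
        aug = mp.fit_oplsda(X_aug, y, n_pred=1, n_orth=1, k_folds=3, seed=0,
                            _with_cv=False)
        assert aug.r2x_o > 0.5
        sign = np.sign(aug.Tp[:, 0] @ base.Tp[:, 0])
        np.testing.assert_allclose(aug.Tp[:, 0], sign * base.Tp[:, 0],
                                   atol=0.15 * np.abs(base.Tp[:, 0]).max())

    def test_zero_orth_single_component_equals_pls2_oracle(self, rng):
        """With no orthogonal filtering, predictions equal an independent
        single-component PLS2 (sklearn NIPALS) on the dummy response."""
        from sklearn.cross_decomposition import PLSRegression
        X, y = _two_class_data(rng, n=12, m=8, sep=2.0, noise=1.0)
        model = mp.fit_oplsda(X, y, n_pred=1, n_orth=0, k_folds=3, seed=0,
                              _with_cv=False)
        Yhat = model.predict_response(X)
        Y01, _ = dummy_code(y, model.class_levels)
        oracle = PLSRegression(n_components=1, scale=False).fit(X, Y01)
        np.testing.assert_allclose(Yhat, oracle.predict(X), atol=1e-8)

    def test_predictive_and_orthogonal_scores_orthogonal(self, scaled):
        X, y = scaled
        model = mp.fit_oplsda(X, y, n_pred=2, n_orth=2, k_folds=7, seed=0,
                              _with_cv=False)
        Tp = model.Tp / np.linalg.norm(model.Tp, axis=0)
        To = model.To / np.linalg.norm(model.To, axis=0)
        assert np.abs(Tp.T @ To).max() < 1e-6

    def test_r2x_partition_sums_to_explained_variance(self, scaled):
        """R2Xp + R2Xo equals the total explained X variation computed from
        the reconstruction residual."""
        X, y = scaled
        model = mp.fit_oplsda(X, y, n_pred=2, n_orth=2, k_folds=7, seed=0,
                              _with_cv=False)
        Xc = X - X.mean(axis=0)
        E = Xc - model.Tp @ model.Pp.T - model.To @ model.Po.T
        r2x_recon = 1 - (E ** 2).sum() / (Xc ** 2).sum()
        assert model.r2x_p + model.r2x_o == pytest.approx(r2x_recon, abs=1e-8)

    def test_q2_not_above_r2y_with_margin(self, scaled):
        X, y = scaled
        model = mp.fit_oplsda(X, y, n_pred=2, n_orth=0, k_folds=7, seed=0)
        assert model.q2y_cum <= model.r2y_cum + 0.05

    def test_singleton_class_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        y = np.array(["A", "A", "A", "A", "B"], dtype=object)
        with pytest.raises(ValueError, match="fewer than 2"):
            mp.fit_oplsda(X, y, n_pred=1, n_orth=0, k_folds=2, seed=0)


class TestCrossValidation:
    def test_separable_classes_give_high_q2(self, rng):
        X, y = _two_class_data(rng, n=28, m=10, sep=6.0, noise=0.2)
        cv = cross_validate(X, y, k=7, seed=0, n_pred=1, n_orth=0)
        assert cv.q2_cum > 0.9

    def test_permuted_labels_give_null_q2(self, scaled):
        """Random label permutations destroy predictability: Q2 stays below
        0.2 in every one of 20 seeded permutations."""
        X, y = scaled
        prng = np.random.default_rng(42)
        q2s = [cross_validate(X, prng.permutation(y), k=7, seed=i,
                              n_pred=2, n_orth=0).q2_cum for i in range(20)]
        assert np.mean(q2s) < 0.0
        assert max(q2s) < 0.2

    def test_leave_one_out_matches_brute_force_oracle(self, rng):
        """k = n on a tiny table equals explicitly enumerating each
        held-out observation."""
        X, y = _two_class_data(rng, n=8, m=5, sep=2.0, noise=1.0)
        cv = cross_validate(X, y, k=8, seed=3, n_pred=1, n_orth=0)
        Y01, levels = dummy_code(y)
        press = 0.0
        for i in range(8):
            keep = np.arange(8) != i
            from metaboprof.chemometrics import _fit_oplsda_fixed
            m_i = _fit_oplsda_fixed(X[keep], Y01[keep], levels, 1, 0)
            press += ((Y01[i] - m_i.predict_response(X[i:i + 1])[0]) ** 2).sum()
        ssy = ((Y01 - Y01.mean(0)) ** 2).sum()
        assert cv.q2_cum == pytest.approx(1 - press / ssy, abs=1e-10)

    def test_folds_partition_and_are_deterministic(self, scaled):
        _, y = scaled
        a1 = stratified_folds(y, 7, seed=5)
        a2 = stratified_folds(y, 7, seed=5)
        np.testing.assert_array_equal(a1, a2)
        assert set(a1) == set(range(7))
        # every class appears in every training split
        for fold in range(7):
            train = y[a1 != fold]
            assert set(train) == set(y)


class TestClassification:
    def test_training_set_consistency_at_strong_separation(self, rng):
        X, y = _two_class_data(rng, n=20, m=6, sep=8.0, noise=0.3)
        model = mp.fit_oplsda(X, y, n_pred=1, n_orth=0, k_folds=5, seed=0,
                              _with_cv=False)
        pred, _ = mp.classify(model, X)
        assert (pred == y).all()

    def test_centroid_observation_scores_equal(self, rng):
        X, y = _two_class_data(rng, n=10, m=4, sep=3.0, noise=0.5)
        model = mp.fit_oplsda(X, y, n_pred=1, n_orth=0, k_folds=5, seed=0,
                              _with_cv=False)
        _, probs = mp.classify(model, X.mean(axis=0, keepdims=True))
        assert probs[0, 0] == pytest.approx(probs[0, 1], abs=1e-6)

    def test_synthetic_study_confusion_table_is_diagonal(self, scaled):
        X, y = scaled
        model = mp.fit_oplsda(X, y, n_pred=2, n_orth=0, k_folds=7, seed=0,
                              _with_cv=False)
        pred, _ = mp.classify(model, X)
        conf = misclassification_table(y, pred, model.class_levels)
        assert conf.n_misclassified == 0
        assert np.all(conf.counts == np.diag(np.diag(conf.counts)))

    def test_feature_mismatch_rejected(self, rng):
        X, y = _two_class_data(rng)
        model = mp.fit_oplsda(X, y, n_pred=1, n_orth=0, k_folds=3, seed=0,
                              _with_cv=False)
        with pytest.raises(ValueError, match="mismatch"):
            mp.classify(model, X[:, :4])


class TestMisclassificationTable:
    def test_identical_vectors_diagonal_accuracy_one(self):
        y = ["A"] * 3 + ["B"] * 2
        conf = misclassification_table(y, y)
        assert conf.accuracy == 1.0
        assert np.all(conf.counts == [[3, 0], [0, 2]])

    def test_all_one_class_single_column(self):
        conf = misclassification_table(["A", "B", "B"], ["A", "A", "A"])
        assert conf.counts[:, 0].sum() == 3
        assert conf.counts[:, 1:].sum() == 0

    def test_planted_errors_counted(self, rng):
        true = np.array(["A"] * 20 + ["B"] * 25, dtype=object)
        pred = true.copy()
        flip = rng.choice(45, size=10, replace=False)
        pred[flip] = np.where(pred[flip] == "A", "B", "A")
        conf = misclassification_table(true, pred)
        assert conf.accuracy == pytest.approx(35 / 45)

    def test_unseen_predicted_label_rejected(self):
        with pytest.raises(ValueError):
            misclassification_table(["A", "A"], ["A", "C"])


class TestFisherExactProbability:
    @pytest.mark.parametrize("diag, expected", [
        ((6, 27, 12), 3.1e-17),   # three-class market model
        ((6, 2, 4), 7.2e-05),     # soft-bread subclass model
        ((27, 12), 2.6e-10),      # hard-vs-soft model
    ])
    def test_diagonal_tables_match_published_values(self, diag, expected):
        p = fisher_exact_probability(np.diag(diag))
        assert p == pytest.approx(expected, rel=0.05)

    def test_two_by_two_enumeration(self):
        """Margins (2,2)/(2,2) admit three tables with point probabilities
        1/6, 4/6, 1/6; the diagonal one has 1/6."""
        assert fisher_exact_probability(np.array([[2, 0], [0, 2]])) == \
            pytest.approx(1 / 6)
        assert fisher_exact_probability(np.array([[1, 1], [1, 1]])) == \
            pytest.approx(4 / 6)

    def test_matches_hypergeometric_oracle_2x2(self):
        table = np.array([[3, 2], [1, 4]])
        p = fisher_exact_probability(table)
        oracle = stats.hypergeom.pmf(3, 10, 5, 4)
        assert p == pytest.approx(oracle)

    def test_permutation_invariance_and_1x1(self, rng):
        t = rng.integers(0, 9, size=(3, 3))
        t[0, 0] += 1
        perm = rng.permutation(3)
        assert fisher_exact_probability(t[perm][:, perm]) == \
            pytest.approx(fisher_exact_probability(t))
        assert fisher_exact_probability(np.array([[7]])) == pytest.approx(1.0)
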