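import numpy as np
import pytest

from aquaphot import models as m

from conftest import make_spectra


class TestPCA:
    def test_rank1_data_pc1_explains_everything(self, rng):
        v = rng.normal(size=30)
        coef = rng.normal(size=10)
        x = np.outer(coef, v) + 0.5
        model = m.pca_fit(x)
        assert model.explained_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_identical_spectra_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            m.pca_fit(np.ones((5, 10)))

    def test_explained_matches_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(10, 50))
        model = m.pca_fit(x)
        # independent oracle: eigenvalues of the covariance matrix
        cov = np.cov(x, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        want = 100 * eig[:9] / eig.sum()
        np.testing.assert_allclose(model.explained_pct[:9], want, atol=1e-8)

    def test_reconstruction_at_full_rank(self, rng):
        x = rng.normal(size=(8, 20))
        model = m.pca_fit(x)
        xc = x - x.mean(axis=0)
        np.testing.assert_allclose(model.scores @ model.loadings.T, xc, atol=1e-8)

    def test_loadings_orthonormal_and_sign_fixed(self, rng):
        x = rng.normal(size=(12, 30))
        model = m.pca_fit(x)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-9)
        for j in range(model.n_components):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_accepts_spectra_set(self, rng):
        s = make_spectra(rng.uniform(0.1, 1.0, (6, 25)))
        model = m.pca_fit(s)
        assert model.scores.shape[0] == 6

    def test_explained_non_increasing_sums_100(self, rng):
        model = m.pca_fit(rng.normal(size=(9, 40)))
        assert np.all(np.diff(model.explained_pct) <= 1e-9)
        assert model.explained_pct.sum() == pytest.approx(100.0)


class TestSelectComponents:
    def test_threshold_99_needs_three(self):
        model = m.PCAModel(np.zeros(4), np.eye(4), np.zeros((5, 4)),
                           np.array([93.0, 5.0, 1.0, 1.0]))
        assert m.select_components(model, 99) == 3

    def test_single_component(self):
        model = m.PCAModel(np.zeros(1), np.eye(1), np.zeros((3, 1)),
                           np.array([100.0]))
        assert m.select_components(model, 99) == 1

    def test_threshold_100_takes_all(self):
        model = m.PCAModel(np.zeros(2), np.eye(2), np.zeros((4, 2)),
                           np.array([60.0, 40.0]))
        assert m.select_components(model, 100) == 2

    def test_bad_threshold(self):
        model = m.PCAModel(np.zeros(1), np.eye(1), np.zeros((3, 1)), np.array([100.0]))
        with pytest.raises(ValueError):
            m.select_components(model, 0)


class TestHotelling:
    def test_mean_spectrum_has_zero_t2(self, rng):
        # rows come in +/- pairs around a center, plus the center itself:
        # the center row IS the column mean, so its scores and T2 are 0
        center = rng.normal(size=6)
        deltas = rng.normal(size=(5, 6))
        x = np.vstack([center + deltas, center - deltas, center])
        model = m.pca_fit(x)
        t2, limit, flags = m.hotelling_t2(model, 3, alpha=0.05)
        assert t2[-1] == pytest.approx(0.0, abs=1e-18)

    def test_matches_mahalanobis_oracle(self, rng):
        x = rng.normal(size=(15, 8))
        model = m.pca_fit(x)
        k = 4
        t2, limit, flags = m.hotelling_t2(model, k, alpha=0.05)
        sc = model.scores[:, :k]
        cov = np.diag(sc.var(axis=0, ddof=1))
        inv = np.linalg.inv(cov)
        want = np.array([v @ inv @ v for v in sc])
        np.testing.assert_allclose(t2, want, atol=1e-9)

    def test_alpha_to_one_flags_everything(self, rng):
        x = rng.normal(size=(12, 5))
        model = m.pca_fit(x)
        t2, limit, flags = m.hotelling_t2(model, 2, alpha=1 - 1e-12)
        assert limit == pytest.approx(0.0, abs=1e-6)
        assert flags.sum() >= 11  # all non-central samples

    def test_n_leq_k_is_error(self, rng):
        model = m.pca_fit(rng.normal(size=(4, 10)))
        with pytest.raises(ValueError):
            m.hotelling_t2(model, 4, 0.05)


class TestLDA:
    def test_separated_classes_loo_perfect(self, rng):
        x = np.r_[rng.normal(-5, 1, 20), rng.normal(5, 1, 20)][:, None]
        y = np.array(["a"] * 20 + ["b"] * 20)
        correct = 0
        for i in range(40):
            keep = np.arange(40) != i
            model = m.lda_fit(x[keep], y[keep])
            correct += model.predict(x[[i]])[0] == y[i]
        assert correct == 40

    def test_identical_distributions_collapse_to_prior(self):
        # 1-D equal-n classes drawn identically: accuracy ~ majority fraction 0.5
        accs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = r.normal(size=(40, 1))
            y = np.array(["a"] * 20 + ["b"] * 20)
            model = m.lda_fit(x, y)
            xt = r.normal(size=(100, 1))
            yt = np.array(["a"] * 50 + ["b"] * 50)
            accs.append(np.mean(model.predict(xt) == yt))
        mean_acc = np.mean(accs)
        # 5000 trials around p=0.5: binomial 99% band is ~ +-0.018
        assert abs(mean_acc - 0.5) < 0.03

    def test_tie_breaks_to_first_sorted_class(self):
        x = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array(["b", "b", "a", "a"])
        model = m.lda_fit(x, y)
        pred = model.predict(np.array([[0.0]]))[0]
        assert pred == "a"  # exactly equidistant, equal priors -> sorted first

    def test_matches_sklearn_on_random_data(self, rng):
        pytest.importorskip("sklearn")
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        x = rng.normal(size=(60, 3)) + np.repeat([[0, 0, 0], [2, 1, 0]], 30, axis=0)
        y = np.array(["a"] * 30 + ["b"] * 30)
        ours = m.lda_fit(x, y)
        theirs = LinearDiscriminantAnalysis(store_covariance=True).fit(x, y)
        xt = rng.normal(size=(50, 3)) + 1.0
        np.testing.assert_array_equal(ours.predict(xt), theirs.predict(xt))

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            m.lda_fit(np.zeros((3, 2)), ["a", "a", "b"])


class TestQDA:
    def test_equals_lda_under_equal_covariances(self, rng):
        # classes share the *empirical* covariance (same deviations, shifted),
        # so pooled = per-class covariance and QDA must equal LDA exactly
        dev = rng.normal(size=(50, 2)) @ np.array([[1.0, 0.3], [0.0, 0.5]])
        a = dev + [0.0, 0.0]
        b = dev + [3.0, 1.0]
        x = np.vstack([a, b])
        y = np.array(["a"] * 50 + ["b"] * 50)
        lda = m.lda_fit(x, y)
        qda = m.qda_fit(x, y)
        xt = rng.normal(size=(300, 2)) * 2 + [1.5, 0.5]
        np.testing.assert_array_equal(lda.predict(xt), qda.predict(xt))

    def test_wide_class_wins_far_from_both_means(self, rng):
        x = np.r_[rng.normal(0, 1, 50), rng.normal(0, 100, 50)][:, None]
        y = np.array(["narrow"] * 50 + ["wide"] * 50)
        qda = m.qda_fit(x, y)
        assert qda.predict(np.array([[50.0]]))[0] == "wide"
        # closed-form check: at x=50 the narrow-class discriminant is astronomically lower
        d = qda.discriminants(np.array([[50.0]]))[0]
        assert d[list(qda.class_names).index("wide")] > d[list(qda.class_names).index("narrow")]

    def test_smallest_determinant_wins_at_shared_mean(self, rng):
        a = rng.normal(0, 0.1, (50, 2))
        b = rng.normal(0, 5.0, (50, 2))
        x = np.vstack([a, b])
        y = np.array(["tight"] * 50 + ["loose"] * 50)
        qda = m.qda_fit(x, y, priors="uniform")
        assert qda.predict(np.array([[0.0, 0.0]]))[0] == "tight"

    def test_matches_sklearn_qda(self, rng):
        pytest.importorskip("sklearn")
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
        x = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(2, 3, (40, 2))])
        y = np.array(["a"] * 40 + ["b"] * 40)
        ours = m.qda_fit(x, y)
        theirs = QuadraticDiscriminantAnalysis(reg_param=0.0).fit(x, y)
        xt = rng.normal(1, 2, size=(60, 2))
        np.testing.assert_array_equal(ours.predict(xt), theirs.predict(xt))


class TestSVM:
    def test_linearly_separable_toy(self):
        x = np.array([[0, 0], [0, 1], [1, 0], [1, 1],
                      [3, 0], [3, 1], [4, 0], [4, 1]], dtype=float)
        y = np.array(["L"] * 4 + ["R"] * 4)
        model = m.svm_fit(x, y, kernel="linear", c=100.0, standardize=False)
        assert list(model.predict(x)) == list(y)
        # analytic maximum-margin separator: x0 = 2, margin 1 each side
        machine = model.machines[("L", "R")]
        dec_left = machine.decision(np.array([[1.0, 0.5]]), "linear", model.gamma)[0]
        dec_right = machine.decision(np.array([[3.0, 0.5]]), "linear", model.gamma)[0]
        assert dec_left == pytest.approx(1.0, abs=1e-3)
        assert dec_right == pytest.approx(-1.0, abs=1e-3)
        assert machine.decision(np.array([[2.0, 0.5]]), "linear", model.gamma)[0] == \
            pytest.approx(0.0, abs=1e-3)

    def test_xor_with_rbf(self):
        x = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array(["a", "a", "b", "b"])
        model = m.svm_fit(x, y, kernel="rbf", c=10.0, gamma=1.0)
        assert list(model.predict(x)) == list(y)

    def test_three_class_one_vs_one(self, rng):
        centers = {"healthy": [0, 0], "UC": [6, 0], "CD": [0, 6]}
        xs, ys = [], []
        for cls, c in centers.items():
            xs.append(rng.normal(size=(15, 2)) * 0.5 + c)
            ys += [cls] * 15
        x = np.vstack(xs)
        y = np.array(ys)
        model = m.svm_fit(x, y, kernel="linear", c=10.0)
        assert np.mean(model.predict(x) == y) == 1.0

    def test_perfect_fit_r2_100_rmsec_0(self, rng):
        x = np.r_[rng.normal(-3, 0.5, 10), rng.normal(3, 0.5, 10)][:, None]
        y = np.array(["healthy"] * 10 + ["IBD"] * 10)
        model = m.svm_fit(x, y, kernel="linear", c=10.0)
        r2, rmsec = m.svm_regression_stats(model, x, y)
        assert r2 == pytest.approx(100.0)
        assert rmsec == pytest.approx(0.0)

    def test_matches_sklearn_on_separable_data(self, rng):
        pytest.importorskip("sklearn")
        from sklearn.svm import SVC
        x = np.vstack([rng.normal(-2, 0.5, (20, 2)), rng.normal(2, 0.5, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        ours = m.svm_fit(x, y, kernel="linear", c=1.0, standardize=False)
        theirs = SVC(kernel="linear", C=1.0).fit(x, y)
        xt = rng.normal(0, 2, size=(80, 2))
        assert np.mean(ours.predict(xt) == theirs.predict(xt)) > 0.97

    def test_class_codes_canonical(self):
        assert m.class_codes(["IBD", "healthy"]) == {"healthy": 0, "IBD": 1}
        assert m.class_codes(["CD", "UC", "healthy"]) == {"healthy": 0, "UC": 1, "CD": 2}

    def test_invalid_c_rejected(self):
        with pytest.raises(ValueError):
            m.svm_fit(np.zeros((4, 1)), ["a", "a", "b", "b"], c=0.0)


class TestAffineInvariance:
    """Discriminant predictions are invariant under invertible affine maps
    applied identically to train and test scores."""

    def test_lda_qda_affine_invariant(self, rng):
        x = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(1.5, 1.2, (25, 3))])
        y = np.array(["a"] * 25 + ["b"] * 25)
        xt = rng.normal(0.7, 1.5, size=(40, 3))
        a_mat = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        shift = rng.normal(size=3)
        for fit in (m.lda_fit, m.qda_fit):
            base = fit(x, y).predict(xt)
            mapped = fit(x @ a_mat + shift, y).predict(xt @ a_mat + shift)
            np.testing.assert_array_equal(base, mapped)

    def test_svm_scale_invariant_with_rescaled_gamma(self, rng):
        x = np.vstack([rng.normal(-2, 0.5, (15, 2)), rng.normal(2, 0.5, (15, 2))])
        y = np.array(["a"] * 15 + ["b"] * 15)
        xt = rng.normal(0, 2, size=(30, 2))
        scale = 4.0
        # raw margin problem: rescaling features requires rescaling gamma
        base = m.svm_fit(x, y, kernel="rbf", c=5.0, gamma=0.5,
                         standardize=False).predict(xt)
        mapped = m.svm_fit(x * scale, y, kernel="rbf", c=5.0,
                           gamma=0.5 / scale**2, standardize=False).predict(xt * scale)
        np.testing.assert_array_equal(base, mapped)
        # with internal standardization the same gamma is already invariant
        std_base = m.svm_fit(x, y, kernel="rbf", c=5.0, gamma=0.5).predict(xt)
        std_mapped = m.svm_fit(x * scale, y, kernel="rbf", c=5.0,
                               gamma=0.5).predict(xt * scale)
        np.testing.assert_array_equal(std_base, std_mapped)
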