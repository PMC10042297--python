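"""Classifier building blocks (PCA, SAM, KNN) and the evaluation protocol."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA as SkPCA

from swirclass import classify as cl
from swirclass import preprocess as pp


def make_labeled(X, y, normalization="none", cube_id=None):
    return pp.LabeledSpectra(np.asarray(X, float), np.asarray(y), normalization,
                             cube_id)


def gaussian_blobs(seed=0, n=60, sep=10.0, F=6):
    """Three well-separated spherical classes in F dimensions."""
    rng = np.random.default_rng(seed)
    means = np.zeros((3, F))
    means[0, 0], means[1, 1], means[2, 2] = sep, sep, sep
    X = np.vstack([rng.normal(means[c], 1.0, size=(n, F)) for c in range(3)])
    y = np.repeat([1, 2, 3], n)
    return X, y


class TestPca:
    def test_recovers_dominant_axis_of_a_line(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=200)
        direction = np.array([3.0, 0.0, 4.0]) / 5.0
        X = 10.0 + t[:, None] * direction * 5.0 + rng.normal(scale=1e-3,
                                                             size=(200, 3))
        m = cl.fit_pca(X)
        np.testing.assert_allclose(np.abs(m.loadings[:, 0]), np.abs(direction),
                                   atol=1e-3)
        assert m.explained_variance[0] > 1e4 * m.explained_variance[1]

    def test_full_projection_preserves_pairwise_distances(self):
        X, _ = gaussian_blobs(seed=2)
        m = cl.fit_pca(X, n_retained=X.shape[1])
        P = cl.project_pca(m, X)
        np.testing.assert_allclose(cdist(P, P), cdist(X, X), rtol=1e-9, atol=1e-9)

    def test_matches_sklearn_explained_variance(self):
        X, _ = gaussian_blobs(seed=3)
        mine = cl.fit_pca(X)
        sk = SkPCA().fit(X)
        np.testing.assert_allclose(mine.explained_variance, sk.explained_variance_,
                                   rtol=1e-9)
        # components agree up to sign
        dots = np.abs(np.sum(mine.loadings.T * sk.components_, axis=1))
        np.testing.assert_allclose(dots, 1.0, atol=1e-9)

    def test_sign_convention_largest_loading_positive(self):
        X, _ = gaussian_blobs(seed=4)
        m = cl.fit_pca(X)
        for j in range(m.loadings.shape[1]):
            col = m.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_training_mean_projects_to_origin(self):
        X, _ = gaussian_blobs(seed=5)
        m = cl.fit_pca(X, n_retained=4)
        np.testing.assert_allclose(cl.project_pca(m, X.mean(axis=0)[None, :]),
                                   0.0, atol=1e-9)

    def test_contracts(self):
        with pytest.raises(ValueError):
            cl.fit_pca(np.ones((4, 6)))        # N <= F
        X, _ = gaussian_blobs()
        with pytest.raises(ValueError):
            cl.fit_pca(X, n_retained=7)
        m = cl.fit_pca(X, n_retained=2)
        with pytest.raises(ValueError):
            cl.project_pca(m, np.ones((3, 5)))

    def test_rank_deficiency_is_flagged(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 6))
        X[:, 5] = X[:, 0]                       # linearly dependent channel
        assert cl.fit_pca(X).rank_deficient


class TestSpectralAngles:
    def test_closed_form_angles(self):
        ref = cl.SamReference(np.array([[1.0, 0.0, 0.0],
                                        [1.0, 1.0, 0.0],
                                        [0.0, 0.0, 1.0]]))
        feats = cl.spectral_angles(np.array([[2.0, 0.0, 0.0]]), ref)
        np.testing.assert_allclose(feats.angles[0],
                                   [0.0, np.pi / 4, np.pi / 2], atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        ref = cl.SamReference(rng.uniform(0.1, 1.0, size=(3, 6)))
        X = rng.uniform(0.1, 5.0, size=(20, 6))
        a = cl.spectral_angles(X, ref).angles
        b = cl.spectral_angles(X * 137.0, ref).angles
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_rows_flagged_with_right_angles(self):
        ref = cl.SamReference(np.eye(3))
        feats = cl.spectral_angles(np.zeros((2, 3)), ref)
        assert feats.zero_rows.all()
        np.testing.assert_array_equal(feats.angles, np.pi / 2)

    def test_zero_class_reference_refused(self):
        X = np.vstack([np.ones((5, 4)), np.zeros((5, 4)), np.ones((5, 4))])
        y = np.repeat([1, 2, 3], 5)
        with pytest.raises(ValueError, match="zero reference"):
            cl.fit_sam_reference(X, y)

    def test_references_are_class_means(self):
        X, y = gaussian_blobs(seed=8)
        ref = cl.fit_sam_reference(X, y)
        for i, c in enumerate((1, 2, 3)):
            np.testing.assert_allclose(ref.reference_spectra[i],
                                       X[y == c].mean(axis=0))


class TestKnnOracle:
    @staticmethod
    def brute_force(Ftr, ytr, Fte, k):
        """Literal restatement of the rule: majority vote, ties to the class
        with the smaller mean neighbor distance, then to the lower label."""
        out = []
        for x in Fte:
            d = np.linalg.norm(Ftr - x, axis=1)
            nb = np.argsort(d, kind="stable")[:k]
            scored = []
            for c in sorted(set(ytr.tolist())):
                sel = [i for i in nb if ytr[i] == c]
                if sel:
                    scored.append((-len(sel), np.mean(d[sel]), c))
            scored.sort()
            out.append(scored[0][2])
        return np.array(out)

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            Ftr = rng.normal(size=(60, 4))
            ytr = rng.integers(1, 4, size=60)
            Fte = rng.normal(size=(40, 4))
            knn = cl._KNNClassifier(k=5).fit(Ftr, ytr)
            np.testing.assert_array_equal(knn.predict(Fte),
                                          self.brute_force(Ftr, ytr, Fte, 5))

    def test_matches_brute_force_with_duplicate_points(self):
        # duplicated training rows force distance ties; the stable-sort rule
        # must agree with the literal oracle
        rng = np.random.default_rng(10)
        base = rng.integers(0, 3, size=(30, 3)).astype(float)
        Ftr = np.vstack([base, base])
        ytr = np.concatenate([np.full(30, 1), np.full(30, 2)])
        Fte = rng.integers(0, 3, size=(25, 3)).astype(float)
        knn = cl._KNNClassifier(k=5).fit(Ftr, ytr)
        np.testing.assert_array_equal(knn.predict(Fte),
                                      self.brute_force(Ftr, ytr, Fte, 5))

    def test_k_one_is_nearest_neighbor(self):
        Ftr = np.array([[0.0], [10.0]])
        ytr = np.array([1, 3])
        knn = cl._KNNClassifier(k=1).fit(Ftr, ytr)
        np.testing.assert_array_equal(knn.predict([[1.0], [9.0]]), [1, 3])


class TestFitPredict:
    def test_all_methods_separate_distant_blobs(self):
        Xtr, ytr = gaussian_blobs(seed=11, sep=10.0)
        Xte, yte = gaussian_blobs(seed=12, sep=10.0)
        train = make_labeled(Xtr, ytr)
        test = make_labeled(Xte, yte)
        for method in cl.METHODS:
            clf = cl.fit(method, train, cl.ClassifierConfig(seed=0))
            acc = np.mean(cl.predict(clf, test) == yte)
            assert acc > 0.95, f"{method} accuracy {acc:.3f}"

    def test_sam_min_picks_nearest_reference_angle(self):
        Xtr, ytr = gaussian_blobs(seed=13, sep=10.0)
        train = make_labeled(Xtr, ytr)
        clf = cl.fit("SAM-min", train)
        labels = cl.predict(clf, clf.sam.reference_spectra)
        np.testing.assert_array_equal(labels, [1, 2, 3])

    def test_sam_min_assigns_zero_spectra_to_background(self):
        Xtr, ytr = gaussian_blobs(seed=14)
        clf = cl.fit("SAM-min", make_labeled(np.abs(Xtr) + 0.1, ytr))
        labels = cl.predict(clf, np.zeros((3, 6)))
        np.testing.assert_array_equal(labels, pp.CLASS_BACKGROUND)

    def test_missing_class_refused(self):
        X, y = gaussian_blobs(seed=15)
        with pytest.raises(ValueError, match="all three classes"):
            cl.fit("PCA-LDA", make_labeled(X[y != 3], y[y != 3]))

    def test_k_larger_than_smallest_class_refused(self):
        X, y = gaussian_blobs(seed=16, n=4)
        with pytest.raises(ValueError, match="smallest class"):
            cl.fit("PCA-KNN", make_labeled(X, y), cl.ClassifierConfig(k=5))

    def test_unknown_method_refused(self):
        X, y = gaussian_blobs(seed=17)
        with pytest.raises(ValueError, match="unknown method"):
            cl.fit("SVM", make_labeled(X, y))

    def test_normalization_mismatch_refused(self):
        X, y = gaussian_blobs(seed=18)
        clf = cl.fit("PCA-LDA", make_labeled(np.abs(X) + 0.1, y, "auc"))
        with pytest.raises(ValueError, match="normalization mismatch"):
            cl.predict(clf, make_labeled(X, y, "snv"))

    def test_pc_truncation_changes_the_feature_space(self):
        X, y = gaussian_blobs(seed=19)
        train = make_labeled(X, y)
        for n in (4, 5, 6):
            clf = cl.fit("PCA-KNN", train, cl.ClassifierConfig(n_retained=n))
            assert clf.pca.n_retained == n
            assert cl._features("PCA-KNN", X, clf.pca, clf.sam).shape[1] == n

    def test_nn_is_deterministic_given_a_seed(self):
        X, y = gaussian_blobs(seed=20, n=40)
        train = make_labeled(X, y)
        a = cl.fit("NN", train, cl.ClassifierConfig(seed=7))
        b = cl.fit("NN", train, cl.ClassifierConfig(seed=7))
        probe, _ = gaussian_blobs(seed=21, n=30)
        np.testing.assert_array_equal(cl.predict(a, probe), cl.predict(b, probe))

    def test_save_load_round_trip(self, tmp_path):
        X, y = gaussian_blobs(seed=22)
        clf = cl.fit("PCA-KNN", make_labeled(X, y, cube_id="cube-0"))
        path = tmp_path / "clf.joblib"
        cl.save_classifier(clf, path)
        back = cl.load_classifier(path)
        assert back.describe() == clf.describe()
        probe, _ = gaussian_blobs(seed=23)
        np.testing.assert_array_equal(cl.predict(back, probe),
                                      cl.predict(clf, probe))
        joblib_path = tmp_path / "other.joblib"
        import joblib
        joblib.dump({"format": "something-else"}, joblib_path)
        with pytest.raises(ValueError):
            cl.load_classifier(joblib_path)


class TestCrossValidation:
    def _datasets(self, n=4, seed0=30):
        return [make_labeled(*gaussian_blobs(seed=seed0 + i, n=30),
                             cube_id=f"cube-{i}") for i in range(n)]

    def test_bookkeeping_four_cubes(self):
        data = self._datasets(4)
        res = cl.cross_validate(data, "PCA-KNN")
        assert len(res.per_permutation) == 4
        train_ids = [p.train_cube for p in res.per_permutation]
        assert sorted(train_ids) == [f"cube-{i}" for i in range(4)]
        for p in res.per_permutation:
            assert p.n_test == 3 * 90            # pooled three test cubes
            assert p.confusion.sum() == p.n_test
        assert res.confusion.sum() == 4 * 3 * 90
        assert np.isclose(res.overall_accuracy,
                          np.mean([p.accuracy for p in res.per_permutation]))

    def test_network_permutations_hold_out_a_validation_cube(self):
        data = self._datasets(4)
        res = cl.cross_validate(data, "NN", cl.ClassifierConfig(seed=1))
        for i, p in enumerate(res.per_permutation):
            assert p.train_cube == f"cube-{i}"
            assert p.validation_cube == f"cube-{(i + 1) % 4}"
            assert p.n_test == 2 * 90            # two cubes test, one validates
        for p in res.per_permutation:
            assert p.validation_cube != p.train_cube

    def test_identical_cubes_give_identical_permutations(self):
        one = make_labeled(*gaussian_blobs(seed=40, n=30), cube_id="same")
        res = cl.cross_validate([one, one, one, one], "SAM-KNN")
        accs = [p.accuracy for p in res.per_permutation]
        assert len(set(accs)) == 1

    def test_cross_validation_is_deterministic(self):
        data = self._datasets(4)
        r1 = cl.cross_validate(data, "PCA-LDA")
        r2 = cl.cross_validate(data, "PCA-LDA")
        assert r1.overall_accuracy == r2.overall_accuracy
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_too_few_cubes_refused(self):
        data = self._datasets(2)
        cl.cross_validate(data, "PCA-KNN")       # 2 is enough for non-NN
        with pytest.raises(ValueError):
            cl.cross_validate(data, "NN")
        with pytest.raises(ValueError):
            cl.cross_validate(data[:1], "PCA-KNN")

    def test_mixed_normalizations_refused(self):
        a = make_labeled(*gaussian_blobs(seed=41), "none")
        b = make_labeled(np.abs(gaussian_blobs(seed=42)[0]) + 0.1,
                         gaussian_blobs(seed=42)[1], "auc")
        with pytest.raises(ValueError, match="normalization"):
            cl.cross_validate([a, b], "PCA-KNN")

    def test_training_pixels_never_tested(self):
        # plant a sentinel spectrum unique to cube 0; when cube 0 trains, the
        # pooled test labels must not contain its row count
        data = self._datasets(4)
        for p in cl.cross_validate(data, "PCA-KNN").per_permutation:
            tested = sum(d.X.shape[0] for d in data
                         if d.source_cube_id != p.train_cube)
            assert p.n_test == tested


class TestMethodGrid:
    def test_grid_shape_and_ordering(self, small_cubes, small_study):
        datasets = [(c, out.rois) for c, out in
                    zip(small_cubes[:4], small_study[:4])]
        df = cl.method_grid(datasets, methods=("PCA-KNN", "SAM-min"),
                            normalizations=("auc",), n_retained_list=(4,))
        assert len(df) == 2                      # one PC count + one plain row
        assert (df["overall_accuracy"].values[:-1]
                >= df["overall_accuracy"].values[1:]).all()
        assert set(df["normalization"]) == {"auc"}

    def test_grid_cell_reproduces_direct_cross_validation(self, small_cubes,
                                                          small_study):
        datasets = [(c, out.rois) for c, out in
                    zip(small_cubes[:4], small_study[:4])]
        df = cl.method_grid(datasets, methods=("PCA-KNN",),
                            normalizations=("auc",), n_retained_list=(4,))
        labeled = [pp.extract_labeled_spectra(c, r, "auc") for c, r in datasets]
        direct = cl.cross_validate(labeled, "PCA-KNN",
                                   cl.ClassifierConfig(n_retained=4))
        assert df["overall_accuracy"].iloc[0] == pytest.approx(
            direct.overall_accuracy, abs=0)
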