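"""LDA, majority vote, 1NN-DTW and template-reduction contracts."""

import itertools

import numpy as np
import pytest

from emgdisc.classifiers import (
    DecisionStream,
    DiscretePrediction,
    MVLDAClassifier,
    Standardizer,
    dtw_1nn,
    fit_lda,
    majority_vote,
    predict_stream,
    reduce_templates_closest,
    reduce_templates_mean,
)
from emgdisc.dataio import GestureTemplate
from emgdisc.dtw import dtw_distance
from emgdisc.features import WindowingConfig


def _blob_data(rng, means, n=40, sd=0.3):
    X, y = [], []
    for label, mu in means.items():
        X.append(rng.normal(mu, sd, size=(n, len(mu))))
        y.extend([label] * n)
    return np.vstack(X), np.array(y)


class TestLDA:
    def test_separable_classes_fit_perfectly(self, rng):
        X, y = _blob_data(rng, {"a": [0, 0], "b": [5, 5]}, sd=0.2)
        model = fit_lda(X, y)
        assert model.predict(X) == list(y)

    def test_equidistant_tie_breaks_to_lowest_class(self):
        # symmetric point masses with tiny isotropic jitter; the origin is
        # equidistant from both class means with equal priors
        X = np.array(
            [[-1.0, 0.0], [-1.0, 1e-9], [1.0, 0.0], [1.0, -1e-9]]
        )
        y = np.array(["a", "a", "b", "b"])
        model = fit_lda(X, y)
        assert model.predict(np.array([[0.0, 0.0]])) == ["a"]

    def test_affine_invariance(self, rng):
        X, y = _blob_data(rng, {"a": [0, 0, 0], "b": [2, 1, 0],
                                "c": [0, 3, 1]})
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        query = rng.normal(0.5, 2.0, size=(50, 3))
        base = fit_lda(X, y).predict(query)
        mapped = fit_lda(X @ A.T + b, y).predict(query @ A.T + b)
        assert base == mapped

    def test_matches_sklearn_posteriors(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = _blob_data(rng, {"a": [0, 0], "b": [2, 1], "c": [1, 3]})
        model = fit_lda(X, y)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        q = rng.normal(1, 2, size=(30, 2))
        assert model.predict(q) == sk.predict(q).tolist()
        # covariance normalization differs (n - k here vs n in sklearn),
        # so posteriors agree approximately at this sample size
        np.testing.assert_allclose(
            model.posterior(q), sk.predict_proba(q), atol=5e-3
        )

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="two classes"):
            fit_lda(X, np.array(["a"] * 10))


class TestMajorityVote:
    def _stream(self, labels, classes=("A", "B", "C")):
        n = len(labels)
        return DecisionStream(
            labels=list(labels), classes=classes,
            scores=np.full((n, len(classes)), 1 / len(classes)),
        )

    def test_unanimous(self):
        pred = majority_vote(self._stream("AAA"))
        assert pred.label == "A"
        assert pred.confidence[0] == 1.0

    def test_counting_confidence(self):
        pred = majority_vote(self._stream(["A", "B", "A", "C"]))
        assert pred.label == "A"
        np.testing.assert_allclose(pred.confidence, [0.5, 0.25, 0.25])

    def test_tie_breaks_to_lowest_class(self):
        assert majority_vote(self._stream(["B", "A"])).label == "A"

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            majority_vote(self._stream(""))

    def test_exclude_rest_variant(self):
        s = self._stream(
            ["rest", "rest", "rest", "A", "A"], classes=("A", "B", "rest")
        )
        assert majority_vote(s).label == "rest"
        assert majority_vote(s, exclude_rest=True).label == "A"
        # all-rest stream falls back to rest
        s2 = self._stream(["rest", "rest"], classes=("A", "rest"))
        assert majority_vote(s2, exclude_rest=True).label == "rest"

    def test_exhaustive_mode_equivalence(self):
        """Vote equals the argmax of the exact count table for every stream
        of length <= 8 over 3 classes (with index tie-break)."""
        classes = ("A", "B", "C")
        for n in range(1, 9):
            for labels in itertools.product(classes, repeat=n):
                pred = majority_vote(self._stream(labels))
                counts = [labels.count(c) for c in classes]
                want = classes[int(np.argmax(counts))]
                assert pred.label == want
                np.testing.assert_allclose(
                    pred.confidence, np.array(counts) / n
                )


class TestPredictStream:
    def test_stream_lengths(self, rng):
        X, y = _blob_data(rng, {"a": list(range(8)), "b": [3] * 8}, n=30)
        model = fit_lda(X, y)
        t40 = GestureTemplate(rng.integers(-5, 5, (8, 40)), label="a")
        t100 = GestureTemplate(rng.integers(-5, 5, (8, 100)), label="a")
        cfg = WindowingConfig(40, 5)
        assert len(predict_stream(model, t40, cfg)) == 1
        assert len(predict_stream(model, t100, cfg)) == 13

    def test_rest_template_votes_rest(self, tiny_templates):
        clf = MVLDAClassifier().fit(
            [t for t in tiny_templates if t.user_id != "user0000"]
        )
        rests = [t for t in tiny_templates
                 if t.user_id == "user0000" and t.label == "rest"]
        preds = [clf.predict(t).label for t in rests]
        assert np.mean([p == "rest" for p in preds]) > 0.5


class TestDTW1NN:
    def test_query_in_bank(self, rng):
        bank = [("a", rng.normal(size=(5, 3))), ("b", rng.normal(size=(4, 3)))]
        pred = dtw_1nn(bank[1][1], bank)
        assert pred.label == "b"
        assert pred.confidence[1] == pred.max_confidence

    def test_matches_double_loop_oracle(self, rng):
        bank = [(l, rng.normal(size=(int(rng.integers(3, 8)), 2)))
                for l in "aabbcc"]
        for _ in range(10):
            q = rng.normal(size=(5, 2))
            pred = dtw_1nn(q, bank)
            dists = [(dtw_distance(q, s), l) for l, s in bank]
            want = min(dists, key=lambda p: (p[0], p[1]))[1]
            assert pred.label == want

    def test_empty_bank(self):
        with pytest.raises(ValueError, match="empty"):
            dtw_1nn(np.ones((2, 2)), [])

    def test_generative_one_template_per_class(self, rng):
        """Noise-free envelopes: each query lands on its own class."""
        from emgdisc.synth import CohortConfig, generate_cohort
        from emgdisc.evaluate import cohort_templates
        from emgdisc.classifiers import DTW1NNClassifier

        cfg = CohortConfig(n_users=1, n_reps=2, inter_user_gain_sd=0,
                           speed_factor_sd=0, rotation_sd=0, seed=21)
        temps = cohort_templates(generate_cohort(cfg))
        train = [t for t in temps if t.rep == 0]
        test = [t for t in temps if t.rep == 1]
        clf = DTW1NNClassifier().fit(train)
        assert all(clf.predict(t).label == t.label for t in test)


class TestTemplateReduction:
    def test_single_template_is_its_own_medoid(self, rng):
        t = rng.normal(size=(4, 2))
        out = reduce_templates_closest({"a": [t]})
        np.testing.assert_array_equal(out["a"], t)

    def test_outlier_excluded(self, rng):
        t = rng.normal(size=(4, 2))
        far = t + 100
        out = reduce_templates_closest({"a": [t, t.copy(), far]})
        np.testing.assert_array_equal(out["a"], t)

    def test_medoid_matches_brute_force(self, rng):
        seqs = [rng.normal(size=(int(rng.integers(3, 7)), 2))
                for _ in range(10)]
        out = reduce_templates_closest({"a": seqs})
        D = np.array([[dtw_distance(x, y) for y in seqs] for x in seqs])
        want = seqs[int(np.argmin(D.sum(axis=1)))]
        np.testing.assert_array_equal(out["a"], want)

    def test_mean_of_identical_templates(self, rng):
        t = rng.normal(size=(5, 3))
        out = reduce_templates_mean({"a": [t, t.copy()]}, target_len=5)
        np.testing.assert_allclose(out["a"], t)

    def test_mean_equal_lengths(self, rng):
        a, b = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        out = reduce_templates_mean({"x": [a, b]}, target_len=5)
        np.testing.assert_allclose(out["x"], (a + b) / 2)

    def test_interpolation_closed_form(self):
        # lengths 2 and 3 to 3 rows: [p, q] -> [p, (p+q)/2, q]
        a = np.array([[0.0], [2.0]])
        b = np.array([[1.0], [2.0], [3.0]])
        out = reduce_templates_mean({"x": [a, b]}, target_len=3)
        want = (np.array([[0.0], [1.0], [2.0]]) + b) / 2
        np.testing.assert_allclose(out["x"], want)


def test_standardizer_roundtrip(rng):
    X = rng.normal(3, 5, size=(100, 4))
    s = Standardizer.fit(X)
    Z = s.transform(X)
    np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(Z.std(axis=0), 1, rtol=1e-12)


def test_discrete_prediction_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        DiscretePrediction("a", ("a", "b"), np.array([0.6, 0.6]))


class TestBundleSerialization:
    def test_mvlda_roundtrip(self, tiny_templates, tmp_path):
        from emgdisc.classifiers import MVLDAClassifier

        clf = MVLDAClassifier().fit(tiny_templates[:72])
        clf.save(tmp_path / "m")
        back = MVLDAClassifier.load(tmp_path / "m")
        for t in tiny_templates[80:100]:
            a, b = clf.predict(t), back.predict(t)
            assert a.label == b.label
            np.testing.assert_allclose(a.confidence, b.confidence, atol=1e-12)

    def test_dtw_roundtrip(self, tiny_templates, tmp_path):
        from emgdisc.classifiers import DTW1NNClassifier

        clf = DTW1NNClassifier(reduction="mean").fit(tiny_templates[:72])
        clf.save(tmp_path / "d")
        back = DTW1NNClassifier.load(tmp_path / "d")
        for t in tiny_templates[80:90]:
            a, b = clf.predict(t), back.predict(t)
            assert a.label == b.label
            np.testing.assert_allclose(a.confidence, b.confidence, atol=1e-12)
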