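"""Classifier interface, AUROC oracle agreement, metrics, grid search."""

import numpy as np
import pytest

import m7gsub as m


def brute_force_auroc(scores, labels):
    """O(n^2) concordant-pair count with the half-tie convention."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def separable_toy(n_per_class=20, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 0.5, (n_per_class, 2)), rng.normal(4, 0.5, (n_per_class, 2))]
    )
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestAuroc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),
            ([0.9, 0.4, 0.6, 0.3], [1, 1, 0, 0], 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert m.auroc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            m.auroc([0.1, 0.9], [1, 1])

    def test_exact_agreement_with_pair_counting_oracle(self):
        """Rank-based AUROC matches O(n^2) pair counting on 100 random sets."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(4, 201))
            # discretized scores force plenty of ties
            scores = rng.integers(0, 8, n) / 7.0
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert m.auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=150)
        labels = rng.integers(0, 2, 150)
        labels[:2] = [0, 1]
        a = m.auroc(scores, labels)
        assert m.auroc(np.exp(3 * scores) + 5, labels) == pytest.approx(a)

    def test_label_permutation_null_centres_on_half(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=200)
        labels = np.array([0] * 100 + [1] * 100)
        aucs = []
        for _ in range(30):
            aucs.append(m.auroc(scores, rng.permutation(labels)))
        assert abs(np.mean(aucs) - 0.5) < 0.05


class TestTrainPredict:
    @pytest.mark.parametrize("algorithm", m.ALGORITHMS)
    def test_separable_toy_perfect_training_auroc(self, algorithm):
        X, y = separable_toy()
        hp = {"C": 1.0, "gamma": 1.0} if algorithm == "SVM_RBF" else None
        model = m.train(algorithm, X, y, hp, seed=0)
        scores = m.predict(model, X)
        assert np.all((scores >= 0) & (scores <= 1))
        assert m.auroc(scores, y) == 1.0
        assert scores[y == 1].min() > scores[y == 0].max()

    @pytest.mark.parametrize("algorithm", ["SVM_RBF", "GLM"])
    def test_permuted_labels_give_chance_auroc(self, algorithm):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(200, 5))
        y = np.array([0, 1] * 100)
        X_test = rng.normal(size=(200, 5))
        y_test = np.array([0, 1] * 100)
        model = m.train(algorithm, X, y, seed=0)
        assert 0.35 <= m.auroc(m.predict(model, X_test), y_test) <= 0.65

    def test_same_seed_same_manifest(self):
        X, y = separable_toy(seed=3)
        a = m.train("SVM_RBF", X, y, seed=4)
        b = m.train("SVM_RBF", X, y, seed=4)
        assert a.manifest == b.manifest

    def test_batch_equals_one_by_one(self):
        X, y = separable_toy(seed=5)
        model = m.train("RF", X, y, seed=0)
        batch = m.predict(model, X)
        single = np.concatenate([m.predict(model, X[i : i + 1]) for i in range(len(X))])
        assert np.allclose(batch, single)

    def test_all_constant_matrix_rejected(self):
        X = np.ones((20, 3))
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError, match="constant"):
            m.train("GLM", X, y)

    def test_layout_mismatch_rejected(self, small_benchmark):
        fm = m.encode_windows(small_benchmark.train, ("NAC", "EIIP"))
        model = m.train("GLM", fm, seed=0)
        other = m.encode_windows(small_benchmark.test, ("NAC", "CP"))
        with pytest.raises(ValueError, match="layout"):
            m.predict(model, other)

    def test_model_archive_round_trip(self, tmp_path, small_benchmark):
        fm = m.encode_windows(small_benchmark.train, ("NAC",))
        model = m.train("GLM", fm, seed=0, window_length=61)
        path = tmp_path / "model.joblib"
        m.save_model(model, path)
        loaded = m.load_model(path)
        assert loaded.manifest == model.manifest
        assert loaded.encoder_combo == ("NAC",)
        fm_test = m.encode_windows(small_benchmark.test, ("NAC",))
        assert np.allclose(m.predict(loaded, fm_test), m.predict(model, fm_test))


class TestEvaluate:
    def test_confusion_formula_arithmetic(self):
        """TP=3, FP=1, TN=3, FN=1 yields Sn = Sp = ACC = 0.75."""

        class FixedScorer:
            def __init__(self, scores):
                self.scores = np.asarray(scores)

            def predict_proba(self, X):
                return np.column_stack([1 - self.scores, self.scores])

        scores = [0.9, 0.9, 0.9, 0.2, 0.8, 0.1, 0.1, 0.1]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        model = m.TrainedModel("GLM", {}, FixedScorer(scores))
        rep = m.evaluate(model, np.zeros((8, 1)), labels, threshold=0.5)
        assert rep.confusion == (3, 1, 3, 1)
        assert (rep.sn, rep.sp, rep.acc) == (0.75, 0.75, 0.75)

    def test_report_self_consistency_on_real_model(self, small_benchmark):
        fm_train = m.encode_windows(small_benchmark.train, m.DEFAULT_COMBO)
        fm_test = m.encode_windows(small_benchmark.test, m.DEFAULT_COMBO)
        model = m.train("SVM_RBF", fm_train, seed=0)
        rep = m.evaluate(model, fm_test)
        n = rep.tp + rep.fp + rep.tn + rep.fn
        assert n == len(small_benchmark.test)
        assert rep.acc == pytest.approx((rep.tp + rep.tn) / n)
        assert rep.sn == pytest.approx(rep.tp / (rep.tp + rep.fn))
        assert rep.sp == pytest.approx(rep.tn / (rep.tn + rep.fp))

    def test_perfect_scores_all_ones(self):
        X, y = separable_toy(10, seed=8)
        model = m.train("SVM_RBF", X, y, {"C": 10.0, "gamma": 1.0}, seed=0)
        rep = m.evaluate(model, X, y)
        assert rep.auroc == 1.0
        assert (rep.acc, rep.sn, rep.sp) == (1.0, 1.0, 1.0)

    def test_single_class_test_set_reports_nan_auroc(self):
        X, y = separable_toy(10, seed=9)
        model = m.train("GLM", X, y, seed=0)
        with pytest.warns(UserWarning, match="single-class"):
            rep = m.evaluate(model, X[y == 1], np.ones(10, dtype=int))
        assert np.isnan(rep.auroc)
        assert rep.sn == 1.0


class TestGridSearch:
    def test_default_grid_spans_printed_ranges(self):
        grid = m.HyperparameterGrid()
        assert grid.log2_C == (-3, -1, 1, 3, 5, 7, 9)
        assert grid.log2_gamma == (-15, -13, -11, -9, -7, -5, -3)

    def test_one_by_one_grid_returns_that_cell(self):
        X, y = separable_toy(10, seed=1)
        grid = m.HyperparameterGrid(log2_C=(1,), log2_gamma=(-3,))
        res = m.grid_search_svm(X, y, grid, cv=3, seed=0)
        assert (res.best_log2_C, res.best_log2_gamma) == (1, -3)
        assert res.surface.shape == (1, 1)

    def test_surface_shape_and_argmax(self, small_benchmark):
        fm = m.encode_windows(small_benchmark.train, ("NAC", "EIIP"))
        res = m.grid_search_svm(fm, cv=3, seed=0)
        assert res.surface.shape == (7, 7)
        assert res.best_auroc == pytest.approx(float(res.surface.values.max()))
        assert res.surface.loc[res.best_log2_gamma, res.best_log2_C] == pytest.approx(
            res.best_auroc
        )

    def test_tie_break_prefers_smaller_c_then_gamma(self):
        X, y = separable_toy(15, seed=6)  # easy data: many cells reach AUROC 1
        grid = m.HyperparameterGrid(log2_C=(1, 3, 5), log2_gamma=(-3, -1))
        res = m.grid_search_svm(X, y, grid, cv=3, seed=0)
        top = res.best_auroc
        winners = [
            (lc, lg)
            for lc in grid.log2_C
            for lg in grid.log2_gamma
            if res.surface.loc[lg, lc] == top
        ]
        assert (res.best_log2_C, res.best_log2_gamma) == min(winners)
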