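"""Split arithmetic, the AUC-optimizing SVM, baselines, Platt scaling."""

import numpy as np
import pytest

from triagenlp import (
    AucSvm,
    PlattCalibrator,
    compute_auc,
    make_split,
    pairwise_hinge_objective,
    select_model,
    train_baseline,
)
from triagenlp.models import model_scores


def _toy_separable(rng, n=40, d=3, gap=4.0):
    X = rng.normal(size=(n, d))
    y = (rng.random(n) < 0.5).astype(int)
    X[:, 0] += gap * y
    return X, y


class TestMakeSplit:
    def test_cohort_scale_partition_sizes(self):
        split = make_split([str(i) for i in range(230_936)], (0.64, 0.20, 0.16), seed=0)
        sizes = {p: sum(v == p for v in split.assignment.values())
                 for p in ("train", "validate", "test")}
        assert sizes == {"train": 147_799, "validate": 46_187, "test": 36_950}

    def test_all_train_degenerate(self):
        split = make_split(list("abcdefghij"), (1.0, 0.0, 0.0), seed=1)
        assert set(split.assignment.values()) == {"train"}

    def test_deterministic_per_seed(self):
        ids = [str(i) for i in range(1000)]
        assert make_split(ids, seed=5).assignment == make_split(ids, seed=5).assignment
        assert make_split(ids, seed=5).assignment != make_split(ids, seed=6).assignment

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            make_split(["a", "b"], (0.5, 0.2, 0.2), seed=0)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            make_split(["a", "a"], seed=0)


class TestAucSvm:
    def test_separable_reaches_perfect_training_auc(self, rng):
        X, y = _toy_separable(rng, gap=8.0)
        svm = AucSvm(C=1.0, n_epochs=200).fit(X, y)
        assert compute_auc(svm.decision_function(X), y) == 1.0

    def test_single_class_errors(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="AUC undefined"):
            AucSvm().fit(X, np.ones(10))

    def test_objective_decreases(self, rng):
        X, y = _toy_separable(rng, gap=1.0)
        svm = AucSvm(C=1.0, n_epochs=150).fit(X, y)
        path = np.array(svm.objective_path_)
        assert path[-1] < path[0]
        # monotone within a small per-epoch tolerance
        assert np.all(np.diff(path) <= 0.05 * (1 + path[:-1]))

    def test_matches_allpairs_batch_oracle(self, rng):
        """Final objective within 1% of an exact all-pairs hinge solver.

        The pairwise objective equals an ordinary hinge SVM (no intercept)
        over positive-negative difference vectors, which an independent
        solver can optimize exactly.
        """
        from sklearn.svm import LinearSVC

        X = rng.normal(size=(60, 4))
        w_true = np.array([2.0, -1.0, 0.5, 0.0])
        y = (X @ w_true + rng.normal(scale=1.5, size=60) > 0).astype(int)
        C = 1.0
        svm = AucSvm(C=C, n_epochs=300).fit(X, y)
        mine = pairwise_hinge_objective(svm.coef_, X, y, C)
        D = (X[y == 1][:, None, :] - X[y == 0][None, :, :]).reshape(-1, X.shape[1])
        D_sym = np.vstack([D, -D])
        y_sym = np.r_[np.ones(len(D)), np.zeros(len(D))]
        oracle = LinearSVC(
            loss="hinge", fit_intercept=False, C=C / (2 * len(D)),
            tol=1e-10, max_iter=500_000,
        ).fit(D_sym, y_sym)
        reference = pairwise_hinge_objective(oracle.coef_.ravel(), X, y, C)
        assert mine <= reference * 1.01

    def test_vanishing_c_shrinks_weights(self, rng):
        X, y = _toy_separable(rng, gap=0.5)
        svm = AucSvm(C=1e-8, n_epochs=200).fit(X, y)
        assert np.linalg.norm(svm.coef_) < 1e-2

    def test_column_permutation_consistency(self, rng):
        X, y = _toy_separable(rng, d=5, gap=1.0)
        perm = rng.permutation(5)
        a = AucSvm(C=1.0, n_epochs=100).fit(X, y).decision_function(X)
        b = AucSvm(C=1.0, n_epochs=100).fit(X[:, perm], y).decision_function(X[:, perm])
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestBaselines:
    @pytest.mark.parametrize(
        "kind", ["logistic_l2_reweighted", "naive_bayes", "random_forest"]
    )
    def test_separable_perfect_auc(self, rng, kind):
        X, y = _toy_separable(rng, gap=8.0)
        if kind == "naive_bayes":
            # binary design whose first feature equals the label exactly
            X = np.c_[y, rng.integers(0, 2, size=(y.size, 2))].astype(float)
        model = train_baseline(X, y, kind, seed=0)
        assert compute_auc(model_scores(model, X), y) == 1.0

    def test_reweighting_is_identity_at_balance(self, rng):
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(60, 3))
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        X[y == 1, 0] += 1.0
        ours = train_baseline(X, y, "logistic_l2_reweighted")
        plain = LogisticRegression(max_iter=2000, solver="lbfgs").fit(X, y)
        np.testing.assert_allclose(ours.coef_, plain.coef_, atol=1e-6)

    def test_naive_bayes_matches_hand_computation(self):
        """Posterior for a Bernoulli NB with Laplace smoothing, by hand."""
        X = np.array([[1, 0, 0], [1, 1, 0], [0, 0, 1], [0, 1, 1]], dtype=float)
        y = np.array([1, 1, 0, 0])
        model = train_baseline(X, y, "naive_bayes", {"alpha": 1.0})
        # P(x=[1,0,0]|1) = .75*.5*.75, P(x|0) = .25*.5*.25, priors equal
        p1 = 0.75 * 0.5 * 0.75
        p0 = 0.25 * 0.5 * 0.25
        expected = p1 / (p1 + p0)
        got = model.predict_proba(np.array([[1, 0, 0]]))[0, 1]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError, match="unsupported"):
            train_baseline(rng.normal(size=(4, 2)), [0, 1, 0, 1], "deep_net")


class _FixedScores:
    def __init__(self, scores):
        self._s = np.asarray(scores, dtype=float)

    def decision_function(self, X):
        return self._s


class TestSelectModel:
    def test_argmax_on_validation_auc(self):
        y = np.array([0, 0, 1, 1])
        good = _FixedScores([0, 1, 2, 3])      # AUC 1.0
        bad = _FixedScores([3, 2, 1, 0])       # AUC 0.0
        best, auc = select_model([(bad, 1.0), (good, 10.0)], None, y)
        assert best is good and auc == 1.0

    def test_single_candidate(self):
        y = np.array([0, 1])
        only = _FixedScores([0, 1])
        assert select_model([(only, 1.0)], None, y)[0] is only

    def test_tie_breaks_to_stronger_regularization(self):
        y = np.array([0, 1, 0, 1])
        a, b = _FixedScores([0, 1, 0, 1]), _FixedScores([0, 1, 0, 1])
        best, _ = select_model([(a, 10.0), (b, 0.1)], None, y)
        assert best is b  # smaller C = stronger regularization

    def test_grid_equals_bruteforce_reevaluation(self, rng):
        X, y = _toy_separable(rng, n=120, gap=0.8)
        Xv, yv = _toy_separable(rng, n=80, gap=0.8)
        grid = [0.01, 0.1, 1.0, 10.0, 100.0]
        fits = [(AucSvm(C=C, n_epochs=100).fit(X, y), C) for C in grid]
        best, _ = select_model(fits, Xv, yv)
        aucs = [compute_auc(m.decision_function(Xv), yv) for m, _ in fits]
        assert best is fits[int(np.argmax(aucs))][0]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_model([], None, np.array([0, 1]))


class TestPlatt:
    def test_symmetric_scores_give_half_at_zero(self):
        s = np.r_[-np.ones(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        platt = PlattCalibrator().fit(s, y)
        assert platt.transform([0.0])[0] == pytest.approx(0.5, abs=1e-6)

    def test_monotone_over_grid(self, rng):
        s = rng.normal(size=100)
        y = (s + rng.normal(scale=2.0, size=100) > 0).astype(int)
        platt = PlattCalibrator().fit(s, y)
        p = platt.transform(np.linspace(-5, 5, 100))
        assert np.all(np.diff(p) >= 0)
        assert np.all((p > 0) & (p < 1))

    def test_matches_irls_oracle(self, rng):
        """Slope/intercept agree with an independent IRLS logistic fit."""
        import statsmodels.api as sm

        s = rng.normal(size=20)
        y = (s + rng.normal(size=20) > 0).astype(int)
        platt = PlattCalibrator().fit(s, y)
        ref = sm.Logit(y, sm.add_constant(s)).fit(disp=0)
        assert platt.intercept_ == pytest.approx(ref.params[0], rel=1e-3, abs=1e-3)
        assert platt.slope_ == pytest.approx(ref.params[1], rel=1e-3, abs=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            PlattCalibrator().fit([0.1, 0.2], [1, 1])
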