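"""Classifiers and calibration.

The primary learner is a linear scorer trained by directly minimizing a
convex upper bound on 1 − AUC: the pairwise hinge loss

    J(w) = ½‖w‖² + (C / |P||N|) Σ_{i∈P, j∈N} max(0, 1 − (w·x_i − w·x_j))

summed over all positive/negative pairs.  Because only score differences
enter the loss, the objective is insensitive to class imbalance — the
property that motivates AUC optimization when the outcome prevalence is
low.  The optimizer is a subsampled-pair stochastic subgradient method
(Adam updates): when the pair count is small every pair is used each epoch,
making the procedure an exact batch subgradient descent whose objective can
be compared against an independent solver.

Baselines (class-reweighted L2 logistic regression, naïve Bayes, random
forest) are standard scikit-learn estimators behind a small factory, and
raw decision values are mapped to probabilities by Platt scaling — a
one-feature logistic regression on the decision value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import BernoulliNB

__all__ = [
    "SplitAssignment",
    "make_split",
    "AucSvm",
    "pairwise_hinge_objective",
    "train_auc_svm",
    "train_baseline",
    "select_model",
    "PlattCalibrator",
    "fit_platt",
    "apply_platt",
]

SPLIT_NAMES = ("train", "validate", "test")


@dataclass
class SplitAssignment:
    """Fixed train/validate/test partition of visit ids."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, part: str) -> list[str]:
        return [v for v, p in self.assignment.items() if p == part]

    def mask(self, visit_ids, part: str) -> np.ndarray:
        return np.array([self.assignment[v] == part for v in visit_ids])


def make_split(
    visit_ids, fractions=(0.64, 0.20, 0.16), seed: int = 0
) -> SplitAssignment:
    """Randomly partition ids into fixed train/validate/test sets.

    Subset sizes are the largest-remainder rounding of n·fraction, so the
    partition is exhaustive and exactly reproducible per seed.
    """
    visit_ids = list(visit_ids)
    if len(set(visit_ids)) != len(visit_ids):
        raise ValueError("visit ids must be unique")
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(visit_ids)
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainders = [r - s for r, s in zip(raw, sizes)]
    leftover = n - sum(sizes)
    for idx in sorted(range(3), key=lambda i: remainders[i], reverse=True)[:leftover]:
        sizes[idx] += 1
    order = np.random.default_rng(seed).permutation(n)
    assignment: dict[str, str] = {}
    pos = 0
    for part, size in zip(SPLIT_NAMES, sizes):
        for k in order[pos : pos + size]:
            assignment[visit_ids[k]] = part
        pos += size
    return SplitAssignment(assignment=assignment, fractions=fractions, seed=seed)


def pairwise_hinge_objective(w: np.ndarray, X, y, C: float) -> float:
    """Exact all-pairs objective ½‖w‖² + (C/|P||N|) Σ hinge margins."""
    s = np.asarray(X @ w).ravel()
    pos, neg = s[y == 1], s[y == 0]
    margins = 1.0 - (pos[:, None] - neg[None, :])
    hinge = np.maximum(margins, 0.0).sum()
    return 0.5 * float(w @ w) + C * hinge / (pos.size * neg.size)


class AucSvm(BaseEstimator):
    """Linear scorer minimizing the pairwise hinge bound on 1 − AUC.

    Parameters
    ----------
    C : float
        Inverse regularization strength on the (pair-averaged) hinge term.
    n_epochs : int
        Optimizer epochs.
    pairs_per_epoch : int
        Pairs sampled per epoch; if the full positive×negative pair count is
        at most this, all pairs are used (deterministic batch mode).
    learning_rate : float
        Adam step size (decayed 1/√epoch).
    random_state : int
        Seed for pair subsampling.

    Attributes
    ----------
    coef_ : (n_features,) weight vector (no intercept: AUC is invariant to
        score shifts).
    objective_path_ : exact all-pairs objective per epoch when batch mode or
        ``track_objective`` is on.
    """

    def __init__(
        self,
        C: float = 1.0,
        n_epochs: int = 150,
        pairs_per_epoch: int = 200_000,
        learning_rate: float = 0.2,
        random_state: int = 0,
        track_objective: bool = False,
    ):
        self.C = C
        self.n_epochs = n_epochs
        self.pairs_per_epoch = pairs_per_epoch
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.track_objective = track_objective

    def fit(self, X, y):
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("AUC undefined: training labels contain a single class")
        X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X, dtype=float)
        n, d = X.shape
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        n_pairs = pos_idx.size * neg_idx.size
        full_batch = n_pairs <= self.pairs_per_epoch
        rng = np.random.default_rng(self.random_state)

        w = np.zeros(d)
        m = np.zeros(d)
        v = np.zeros(d)
        b1, b2, eps = 0.9, 0.999, 1e-8
        # the optimum's norm grows with C (margins of 1 on weakly separated
        # data need large weights), so the step budget scales with sqrt(C)
        base_step = self.learning_rate * max(1.0, np.sqrt(self.C))
        tail_start = max(1, int(self.n_epochs * 0.75))
        w_tail = np.zeros(d)
        n_tail = 0
        path: list[float] = []
        best_obj, best_w = np.inf, w.copy()
        t = 0
        for epoch in range(self.n_epochs):
            if full_batch:
                pi = np.repeat(pos_idx, neg_idx.size)
                nj = np.tile(neg_idx, pos_idx.size)
            else:
                pi = pos_idx[rng.integers(pos_idx.size, size=self.pairs_per_epoch)]
                nj = neg_idx[rng.integers(neg_idx.size, size=self.pairs_per_epoch)]
            s = np.asarray(X @ w).ravel()
            active = (s[pi] - s[nj]) < 1.0
            z = np.zeros(n)
            scale = self.C / pi.size
            np.add.at(z, pi[active], -scale)
            np.add.at(z, nj[active], scale)
            grad = w + np.asarray(X.T @ z).ravel()
            t += 1
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * grad * grad
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            step = base_step / np.sqrt(1 + epoch)
            w = w - step * mhat / (np.sqrt(vhat) + eps)
            if epoch >= tail_start:
                w_tail += w
                n_tail += 1
            if full_batch or self.track_objective:
                obj = pairwise_hinge_objective(w, X, y, self.C)
                path.append(obj)
                if obj < best_obj:
                    best_obj, best_w = obj, w.copy()
        if full_batch or self.track_objective:
            w = best_w
        elif n_tail:
            # tail (Polyak) average damps the noise of subsampled pairs
            w = w_tail / n_tail
        self.coef_ = w
        self.objective_path_ = path
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X @ self.coef_).ravel()

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


def train_auc_svm(X, y, C: float = 1.0, seed: int = 0, **kwargs) -> AucSvm:
    return AucSvm(C=C, random_state=seed, **kwargs).fit(X, y)


def train_baseline(X, y, kind: str, hyperparams: dict | None = None, seed: int = 0):
    """Fit a comparison learner exposing a continuous score.

    ``logistic_l2_reweighted`` weights classes inversely to prevalence;
    ``naive_bayes`` is Bernoulli NB over binarized features; ``random_forest``
    grids over min_samples_leaf externally.
    """
    hyperparams = dict(hyperparams or {})
    if kind == "logistic_l2_reweighted":
        model = LogisticRegression(
            class_weight="balanced",
            max_iter=2000,
            solver="lbfgs",
            **hyperparams,
        )
    elif kind == "naive_bayes":
        model = BernoulliNB(**hyperparams)
    elif kind == "random_forest":
        hyperparams.setdefault("n_estimators", 200)
        model = RandomForestClassifier(random_state=seed, n_jobs=1, **hyperparams)
    else:
        raise ValueError(f"unsupported baseline kind: {kind!r}")
    model.fit(X, np.asarray(y).astype(int))
    return model


def model_scores(model, X) -> np.ndarray:
    """Continuous score from any fitted learner."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X)).ravel()
    return np.asarray(model.predict_proba(X))[:, 1]


def select_model(candidates, X_val, y_val):
    """Pick the candidate with highest validation AUC.

    ``candidates`` is a list of (model, complexity key) where the key is the
    model's C / inverse-regularization value; ties break toward the smaller
    key (stronger regularization, simpler model).
    """
    from .evaluation import compute_auc

    if not candidates:
        raise ValueError("select_model requires at least one candidate")
    scored = []
    for rank, (model, key) in enumerate(candidates):
        auc = compute_auc(model_scores(model, X_val), y_val)
        scored.append((auc, -key, -rank, model))
    scored.sort(key=lambda item: (item[0], item[1], item[2]))
    best = scored[-1]
    return best[3], best[0]


class PlattCalibrator(BaseEstimator):
    """Platt scaling: logistic map from decision value to probability.

    A logistic regression with a bias term and one feature (the decision
    value); ``predict_proba``-style output is monotone in the score.
    """

    def __init__(self, max_iter: int = 1000):
        self.max_iter = max_iter

    def fit(self, decision_values, y):
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("Platt scaling requires both classes")
        s = np.asarray(decision_values, dtype=float).reshape(-1, 1)
        lr = LogisticRegression(C=1e8, solver="lbfgs", max_iter=self.max_iter)
        lr.fit(s, y)
        self.slope_ = float(lr.coef_[0, 0])
        self.intercept_ = float(lr.intercept_[0])
        return self

    def transform(self, decision_values) -> np.ndarray:
        s = np.asarray(decision_values, dtype=float)
        return 1.0 / (1.0 + np.exp(-(self.slope_ * s + self.intercept_)))


def fit_platt(decision_values, labels) -> PlattCalibrator:
    return PlattCalibrator().fit(decision_values, labels)


def apply_platt(calibrator: PlattCalibrator, decision_values) -> np.ndarray:
    return calibrator.transform(decision_values)
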