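"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Triage notes are summarized as mixtures of "topics" — multinomial word
distributions learned without supervision — giving a low-dimensional dense
representation of the free text.  Fitting uses the collapsed Gibbs sampler:
token t in document d is reassigned to topic k with probability

    p(z_t = k) ∝ (n_dk + α) (n_kw + β) / (n_k + βV)

where n_dk, n_kw, n_k are the current counts excluding token t.  Held-out
documents are folded in with the topic-word counts frozen, and the
document-topic distribution θ_d = (n_dk + α)/(N_d + Kα) is averaged over
post-burn-in sweeps.  Proportions below a small threshold are zeroed (and
not renormalized) to sparsify the feature block.

Defaults follow common practice for short clinical text: symmetric priors
α = 50/K, β = 0.01, 1000 fitting sweeps.  The sampler's inner loop is
numba-compiled; the random stream is numba's own Mersenne generator seeded
inside the kernel, so results are exactly reproducible for a fixed seed.
"""

from __future__ import annotations

import json

import numpy as np
import scipy.sparse as sp
from numba import njit
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["GibbsLDA", "fit_topic_model", "topic_proportions"]


@njit(cache=True)
def _sample_from_cumulative(cum, total):
    u = np.random.random() * total
    for k in range(cum.size):
        if u < cum[k]:
            return k
    return cum.size - 1


@njit(cache=True)
def _gibbs_fit_kernel(doc_ids, word_ids, z, ndk, nkw, nk, alpha, beta, n_iter, seed):
    np.random.seed(seed)
    K, V = nkw.shape
    cum = np.empty(K)
    for _ in range(n_iter):
        for t in range(word_ids.size):
            d = doc_ids[t]
            w = word_ids[t]
            k = z[t]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            total = 0.0
            for kk in range(K):
                total += (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + beta * V)
                cum[kk] = total
            k = _sample_from_cumulative(cum, total)
            z[t] = k
            ndk[d, k] += 1
            nkw[k, w] += 1
            nk[k] += 1


@njit(cache=True)
def _gibbs_infer_kernel(indptr, word_ids, phi, alpha, n_iter, burn_in, seed, theta):
    np.random.seed(seed)
    n_docs = indptr.size - 1
    K = phi.shape[0]
    cum = np.empty(K)
    for d in range(n_docs):
        lo, hi = indptr[d], indptr[d + 1]
        n_d = hi - lo
        if n_d == 0:
            for k in range(K):
                theta[d, k] = 1.0 / K
            continue
        ndk = np.zeros(K)
        z = np.empty(n_d, dtype=np.int64)
        for t in range(n_d):
            k = np.random.randint(0, K)
            z[t] = k
            ndk[k] += 1
        acc = np.zeros(K)
        n_kept = 0
        for it in range(n_iter):
            for t in range(n_d):
                w = word_ids[lo + t]
                k = z[t]
                ndk[k] -= 1
                total = 0.0
                for kk in range(K):
                    total += (ndk[kk] + alpha) * phi[kk, w]
                    cum[kk] = total
                k = _sample_from_cumulative(cum, total)
                z[t] = k
                ndk[k] += 1
            if it >= burn_in:
                n_kept += 1
                for k in range(K):
                    acc[k] += (ndk[k] + alpha) / (n_d + K * alpha)
        for k in range(K):
            theta[d, k] = acc[k] / n_kept


def _expand_tokens(X: sp.spmatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a count matrix to (doc_id, word_id) token streams."""
    X = sp.csr_matrix(X)
    coo = X.tocoo()
    reps = coo.data.astype(np.int64)
    doc_ids = np.repeat(coo.row.astype(np.int64), reps)
    word_ids = np.repeat(coo.col.astype(np.int64), reps)
    order = np.lexsort((word_ids, doc_ids))
    doc_ids, word_ids = doc_ids[order], word_ids[order]
    indptr = np.searchsorted(doc_ids, np.arange(X.shape[0] + 1))
    return doc_ids, word_ids, indptr


class GibbsLDA(BaseEstimator, TransformerMixin):
    """Topic model over term-count matrices (collapsed Gibbs sampling).

    Parameters
    ----------
    n_topics : int
        Number of topics K (>= 1; K = 1 degenerates to the smoothed corpus
        unigram distribution).
    alpha : float or None
        Symmetric document-topic prior; None means 50/K.
    beta : float
        Symmetric topic-word prior.
    n_iter : int
        Gibbs sweeps for fitting.
    infer_iter, infer_burn_in : int
        Sweeps for fold-in inference; θ is averaged over the post-burn-in
        sweeps.
    threshold : float
        Proportions below this are set to 0 in ``transform`` (no
        renormalization).
    random_state : int
        Seed; fixes all outputs exactly.

    Attributes
    ----------
    components_ : (K, V) array, each row a topic-word distribution summing
        to 1.
    """

    def __init__(
        self,
        n_topics: int = 500,
        alpha: float | None = None,
        beta: float = 0.01,
        n_iter: int = 1000,
        infer_iter: int = 300,
        infer_burn_in: int = 200,
        threshold: float = 0.001,
        random_state: int = 0,
    ):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.n_iter = n_iter
        self.infer_iter = infer_iter
        self.infer_burn_in = infer_burn_in
        self.threshold = threshold
        self.random_state = random_state

    @property
    def alpha_(self) -> float:
        return self.alpha if self.alpha is not None else 50.0 / self.n_topics

    def fit(self, X, y=None):
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        X = sp.csr_matrix(X)
        n_docs, n_words = X.shape
        if n_docs < self.n_topics:
            raise ValueError(
                f"corpus has {n_docs} documents, fewer than n_topics={self.n_topics}"
            )
        doc_ids, word_ids, _ = _expand_tokens(X)
        K = self.n_topics
        rng = np.random.default_rng(self.random_state)
        z = rng.integers(0, K, size=word_ids.size)
        ndk = np.zeros((n_docs, K))
        nkw = np.zeros((K, n_words))
        nk = np.zeros(K)
        np.add.at(ndk, (doc_ids, z), 1.0)
        np.add.at(nkw, (z, word_ids), 1.0)
        np.add.at(nk, z, 1.0)
        _gibbs_fit_kernel(
            doc_ids,
            word_ids,
            z,
            ndk,
            nkw,
            nk,
            self.alpha_,
            self.beta,
            self.n_iter,
            self.random_state % (2**31),
        )
        self.topic_word_counts_ = nkw
        self.components_ = (nkw + self.beta) / (
            nkw.sum(axis=1, keepdims=True) + self.beta * n_words
        )
        self.n_features_in_ = n_words
        return self

    def transform(self, X, threshold: float | None = None) -> np.ndarray:
        """Per-document topic proportions, thresholded, not renormalized."""
        X = sp.csr_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("vocabulary width mismatch with the fitted model")
        _, word_ids, indptr = _expand_tokens(X)
        theta = np.empty((X.shape[0], self.n_topics))
        _gibbs_infer_kernel(
            indptr.astype(np.int64),
            word_ids,
            self.components_,
            self.alpha_,
            self.infer_iter,
            self.infer_burn_in,
            (self.random_state + 1) % (2**31),
            theta,
        )
        thr = self.threshold if threshold is None else threshold
        theta[theta < thr] = 0.0
        return theta

    def top_words(self, vocab_tokens: list[str], k: int = 10) -> list[list[str]]:
        """Most probable words per topic (for topic introspection tables)."""
        out = []
        for row in self.components_:
            idx = np.argsort(row)[::-1][:k]
            out.append([vocab_tokens[i] for i in idx])
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_topics": self.n_topics,
                "alpha": self.alpha_,
                "beta": self.beta,
                "n_iter": self.n_iter,
                "random_state": self.random_state,
                "components": self.components_.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GibbsLDA":
        obj = json.loads(text)
        model = cls(
            n_topics=obj["n_topics"],
            alpha=obj["alpha"],
            beta=obj["beta"],
            n_iter=obj["n_iter"],
            random_state=obj["random_state"],
        )
        model.components_ = np.asarray(obj["components"])
        model.n_features_in_ = model.components_.shape[1]
        return model


def fit_topic_model(
    counts, n_topics: int, alpha=None, beta: float = 0.01, n_iter: int = 1000, seed: int = 0
) -> GibbsLDA:
    """Fit a :class:`GibbsLDA` on a document-term count matrix."""
    return GibbsLDA(
        n_topics=n_topics, alpha=alpha, beta=beta, n_iter=n_iter, random_state=seed
    ).fit(counts)


def topic_proportions(counts, model: GibbsLDA, threshold: float = 0.001) -> np.ndarray:
    """Thresholded topic proportions for held-out documents."""
    return model.transform(counts, threshold=threshold)
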