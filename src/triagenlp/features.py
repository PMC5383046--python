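"""Bag-of-words and assembled feature matrices.

The four nested feature models are:

* ``vitals``  — normalized vitals/demographics block only;
* ``cc``      — vitals + term frequencies over the chief complaint;
* ``bow``     — vitals + term frequencies over chief complaint and nursing
  assessment concatenated;
* ``topics``  — vitals + thresholded topic proportions over both text fields.

Term frequency is the raw count of a vocabulary token in the patient's
included free text; the vocabulary keeps every token occurring at least
``min_count`` times in the fitting corpus, ordered lexicographically.
"""

from __future__ import annotations

import json
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["Vocabulary", "fit_vocabulary", "bow_vector", "BowEncoder", "assemble_features"]

MODEL_IDS = ("vitals", "cc", "bow", "topics")


class Vocabulary:
    """Token -> contiguous column index map with a minimum-count filter."""

    def __init__(self, index: dict[str, int], min_count: int, fit_scope: str = "train_only"):
        self.index = index
        self.min_count = min_count
        self.fit_scope = fit_scope

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def tokens(self) -> list[str]:
        out = [None] * len(self.index)
        for tok, i in self.index.items():
            out[i] = tok
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"min_count": self.min_count, "fit_scope": self.fit_scope, "tokens": self.tokens}
        )

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        obj = json.loads(text)
        return cls(
            {tok: i for i, tok in enumerate(obj["tokens"])},
            min_count=obj["min_count"],
            fit_scope=obj.get("fit_scope", "train_only"),
        )


def fit_vocabulary(
    corpus: Iterable[Sequence[str]], min_count: int = 5, fit_scope: str = "train_only"
) -> Vocabulary:
    """Build the vocabulary of tokens occurring >= min_count times.

    Ordering is lexicographic, hence deterministic and independent of
    corpus order.
    """
    counts: Counter[str] = Counter()
    n_docs = 0
    for doc in corpus:
        n_docs += 1
        counts.update(doc)
    if n_docs == 0:
        raise ValueError("fit_vocabulary requires a nonempty corpus")
    kept = sorted(tok for tok, c in counts.items() if c >= min_count)
    return Vocabulary({tok: i for i, tok in enumerate(kept)}, min_count, fit_scope)


def bow_vector(notes, vocab: Vocabulary) -> sp.csr_matrix:
    """Term-frequency matrix (n_docs x |vocab|) over token lists.

    ``notes`` is one token list or an iterable of token lists; out-of-
    vocabulary tokens are ignored.
    """
    docs = [notes] if notes and isinstance(notes[0], str) else list(notes)
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    index = vocab.index
    for doc in docs:
        row: Counter[int] = Counter()
        for tok in doc:
            j = index.get(tok)
            if j is not None:
                row[j] += 1
        for j in sorted(row):
            indices.append(j)
            data.append(row[j])
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.array(data, dtype=np.int64), np.array(indices, dtype=np.int32), indptr),
        shape=(len(docs), len(vocab)),
    )


class BowEncoder(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: fit the vocabulary, transform to counts.

    X is an iterable of token lists (already preprocessed).
    """

    def __init__(self, min_count: int = 5):
        self.min_count = min_count

    def fit(self, X, y=None):
        self.vocabulary_ = fit_vocabulary(X, min_count=self.min_count)
        return self

    def transform(self, X) -> sp.csr_matrix:
        return bow_vector(list(X), self.vocabulary_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.vocabulary_.tokens, dtype=object)


def assemble_features(
    vitals_block: np.ndarray,
    model_id: str,
    cc_counts: sp.csr_matrix | None = None,
    both_counts: sp.csr_matrix | None = None,
    topic_props: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Concatenate the vitals block with the text block for one feature model.

    Raises ``ValueError`` naming the missing artifact when the requested
    model needs a block that was not supplied.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    vit = sp.csr_matrix(np.asarray(vitals_block, dtype=float))
    if model_id == "vitals":
        return vit
    if model_id == "cc":
        if cc_counts is None:
            raise ValueError("model 'cc' requires chief-complaint counts (cc_counts)")
        return sp.hstack([vit, cc_counts.astype(float)], format="csr")
    if model_id == "bow":
        if both_counts is None:
            raise ValueError("model 'bow' requires combined text counts (both_counts)")
        return sp.hstack([vit, both_counts.astype(float)], format="csr")
    if topic_props is None:
        raise ValueError("model 'topics' requires topic proportions (topic_props)")
    return sp.hstack([vit, sp.csr_matrix(np.asarray(topic_props, dtype=float))], format="csr")
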