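"""Free-text preprocessing for triage notes.

Chief complaints and nursing assessments are short, telegraphic clinical
strings ("s/p fall, h/a no LOC").  They are turned into token sequences in
three stages: tokenization (punctuation split off word boundaries, interior
punctuation kept so that "s/p" and "h/a" survive as single words), bigram
joining (frequent collocations such as "sore throat" become one token), and
NegEx-style negation detection (tokens in the scope of a trigger such as
"no" or "denies" receive a ``_neg`` suffix, so "no chest-pain" becomes
"chest-pain_neg").
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TextConfig",
    "AnnotatedNote",
    "tokenize",
    "learn_bigrams",
    "apply_bigrams",
    "apply_negation",
    "preprocess_note",
    "NotePreprocessor",
]

# punctuation characters stripped from word boundaries; interior occurrences
# are preserved ("s/p", "h/a", "n&v" stay whole)
_BOUNDARY_PUNCT = ".,;:!?\"'()[]{}<>"

DEFAULT_NEGATION_TRIGGERS = (
    "no",
    "not",
    "denies",
    "denied",
    "without",
    "neg",
    "w/o",
)
DEFAULT_NEGATION_TERMINATORS = ("but", "however", "except", "although")
# sentence punctuation also terminates a negation scope
_SCOPE_ENDING_PUNCT = (".", ";", ":")


@dataclass
class TextConfig:
    """Configuration for bigram joining and negation detection.

    Parameters
    ----------
    bigram_list : set of (str, str)
        Word pairs to join into single tokens.
    bigram_joiner : str
        Character placed between the two words of a joined bigram.  The
        default is an underscore, matching how joined terms appear in
        model-weight tables (``sore_throat``).
    negation_triggers, negation_terminators : sequence of str
        Trigger words open a negation scope; terminator words close it.
    negation_suffix : str
        Appended to each token inside a negation scope.
    scope_limit : int
        Maximum number of tokens a negation scope may span.
    lowercase : bool
        Case-fold text before tokenizing.
    """

    bigram_list: set[tuple[str, str]] = field(default_factory=set)
    bigram_joiner: str = "_"
    negation_triggers: Sequence[str] = DEFAULT_NEGATION_TRIGGERS
    negation_terminators: Sequence[str] = DEFAULT_NEGATION_TERMINATORS
    negation_suffix: str = "_neg"
    scope_limit: int = 6
    lowercase: bool = True

    def __post_init__(self) -> None:
        if not self.bigram_joiner:
            raise ValueError("bigram_joiner must be nonempty")
        if not self.negation_suffix:
            raise ValueError("negation_suffix must be nonempty")
        if self.scope_limit < 1:
            raise ValueError("scope_limit must be >= 1")
        self.bigram_list = {tuple(p) for p in self.bigram_list}


@dataclass
class AnnotatedNote:
    """A fully preprocessed note: ordered tokens plus their source field."""

    tokens: list[str]
    source_field: str = "chief_complaint"

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Split a raw string into tokens.

    Tokens are whitespace-delimited sequences of symbols with leading and
    trailing punctuation split off as separate tokens.  Interior punctuation
    is preserved, so clinical shorthand like "s/p" and "h/a" are single
    tokens.  Total function: any string (including empty) is accepted.
    """
    if lowercase:
        text = text.lower()
    out: list[str] = []
    for chunk in text.split():
        lead: list[str] = []
        while chunk and chunk[0] in _BOUNDARY_PUNCT:
            lead.append(chunk[0])
            chunk = chunk[1:]
        trail: list[str] = []
        while chunk and chunk[-1] in _BOUNDARY_PUNCT:
            trail.append(chunk[-1])
            chunk = chunk[:-1]
        out.extend(lead)
        if chunk:
            out.append(chunk)
        out.extend(reversed(trail))
    return out


def learn_bigrams(
    corpus: Iterable[Sequence[str]],
    min_pair_count: int = 5,
    min_score: float = 3.0,
) -> set[tuple[str, str]]:
    """Detect frequent collocations in a tokenized corpus.

    A pair of adjacent words is kept when it occurs at least
    ``min_pair_count`` times and its pointwise mutual information
    ``log2(p(a,b) / (p(a) p(b)))`` is at least ``min_score``.  Deterministic
    given the corpus (counts only; order does not matter).
    """
    unigram: Counter[str] = Counter()
    pair: Counter[tuple[str, str]] = Counter()
    n_tokens = 0
    n_pairs = 0
    n_docs = 0
    for doc in corpus:
        n_docs += 1
        unigram.update(doc)
        n_tokens += len(doc)
        for a, b in zip(doc, doc[1:]):
            pair[(a, b)] += 1
            n_pairs += 1
    if n_docs == 0:
        raise ValueError("learn_bigrams requires a nonempty corpus")
    result: set[tuple[str, str]] = set()
    if n_pairs == 0:
        return result
    for (a, b), c in pair.items():
        if c < min_pair_count:
            continue
        pmi = math.log2(
            (c / n_pairs) / ((unigram[a] / n_tokens) * (unigram[b] / n_tokens))
        )
        if pmi >= min_score:
            result.add((a, b))
    return result


def apply_bigrams(tokens: Sequence[str], config: TextConfig) -> list[str]:
    """Join listed word pairs into single tokens, greedily left to right.

    Each non-overlapping occurrence of a pair in ``bigram_list`` is replaced
    by ``a<joiner>b``; the scan resumes after the consumed pair, so where two
    listed pairs overlap (input [a,b,c] with pairs (a,b) and (b,c)) the
    leftmost pair wins and the result is [a_b, c].
    """
    pairs = config.bigram_list
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        if i + 1 < n and (tokens[i], tokens[i + 1]) in pairs:
            out.append(tokens[i] + config.bigram_joiner + tokens[i + 1])
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


def apply_negation(tokens: Sequence[str], config: TextConfig) -> list[str]:
    """Suffix tokens in the scope of a negation trigger.

    Starting at each trigger token, every subsequent token receives the
    negation suffix until a terminator word, a sentence-ending punctuation
    token, or ``scope_limit`` tokens — whichever comes first.  The trigger
    itself is dropped from the output.  Already-suffixed tokens are left
    alone, so the operation is idempotent on its own output.
    """
    triggers = set(config.negation_triggers)
    terminators = set(config.negation_terminators)
    suffix = config.negation_suffix
    out: list[str] = []
    scope = 0  # remaining tokens in the current negation scope
    for tok in tokens:
        if tok in triggers:
            scope = config.scope_limit
            continue  # trigger dropped from output
        if scope > 0 and (tok in terminators or tok in _SCOPE_ENDING_PUNCT):
            scope = 0
            out.append(tok)
            continue
        if scope > 0:
            out.append(tok if tok.endswith(suffix) else tok + suffix)
            scope -= 1
        else:
            out.append(tok)
    return out


def preprocess_note(
    text: str, config: TextConfig | None = None, source_field: str = "chief_complaint"
) -> AnnotatedNote:
    """Full preprocessing: tokenize, join bigrams, detect negation."""
    if config is None:
        config = TextConfig()
    toks = tokenize(text, lowercase=config.lowercase)
    toks = apply_bigrams(toks, config)
    toks = apply_negation(toks, config)
    return AnnotatedNote(tokens=toks, source_field=source_field)


class NotePreprocessor(BaseEstimator, TransformerMixin):
    """Transformer from raw note strings to annotated token lists.

    ``fit`` learns the bigram list from the training corpus (unless a fixed
    ``bigram_list`` is supplied); ``transform`` maps each string to its
    preprocessed token list.  Composes with sklearn pipelines; X is any
    iterable of strings.

    Parameters
    ----------
    bigram_list : set of pairs or None
        Fixed collocation list.  If None, learned at fit time.
    min_pair_count, min_score : thresholds for collocation learning.
    Other parameters mirror :class:`TextConfig`.
    """

    def __init__(
        self,
        bigram_list=None,
        min_pair_count: int = 5,
        min_score: float = 3.0,
        bigram_joiner: str = "_",
        negation_triggers=DEFAULT_NEGATION_TRIGGERS,
        negation_terminators=DEFAULT_NEGATION_TERMINATORS,
        negation_suffix: str = "_neg",
        scope_limit: int = 6,
        lowercase: bool = True,
    ):
        self.bigram_list = bigram_list
        self.min_pair_count = min_pair_count
        self.min_score = min_score
        self.bigram_joiner = bigram_joiner
        self.negation_triggers = negation_triggers
        self.negation_terminators = negation_terminators
        self.negation_suffix = negation_suffix
        self.scope_limit = scope_limit
        self.lowercase = lowercase

    def _make_config(self, bigrams) -> TextConfig:
        return TextConfig(
            bigram_list=set(bigrams),
            bigram_joiner=self.bigram_joiner,
            negation_triggers=self.negation_triggers,
            negation_terminators=self.negation_terminators,
            negation_suffix=self.negation_suffix,
            scope_limit=self.scope_limit,
            lowercase=self.lowercase,
        )

    def fit(self, X, y=None):
        if self.bigram_list is not None:
            bigrams = {tuple(p) for p in self.bigram_list}
        else:
            tokenized = [tokenize(t, lowercase=self.lowercase) for t in X]
            bigrams = learn_bigrams(
                tokenized, min_pair_count=self.min_pair_count, min_score=self.min_score
            )
        self.config_ = self._make_config(bigrams)
        return self

    def transform(self, X) -> list[list[str]]:
        cfg = self.config_
        return [preprocess_note(t, cfg).tokens for t in X]
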