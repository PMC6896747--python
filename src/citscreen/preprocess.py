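"""Text preprocessing and sparse document-term matrices.

Each citation's title and abstract are lowercased, stripped of non-alphabetic
characters, tokenized on whitespace, and Porter-stemmed; adjacent stem pairs
are then added as bigram tokens (joined with ``_``) so a bigram behaves as a
single bag-of-words feature.  The resulting document-term matrix (DTM) holds
raw term-frequency (TF) counts and is typically ~99% sparse on realistic
screening corpora.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer

from .corpus import Corpus
from .errors import DegenerateInputError
from .porter import stem

TOKEN_JOINER = "_"
WEIGHTING_TF = "tf"
WEIGHTING_TFIDF = "tfidf"

_NON_ALPHA = re.compile(r"[^a-z]+")


def preprocess_text(raw: str) -> list[str]:
    """Tokenize free text into stemmed lowercase unigrams.

    Non-alphabetic characters become separators; tokens shorter than two
    characters (punctuation debris) are dropped before stemming.  Total on
    any input: empty text yields an empty list.
    """
    words = _NON_ALPHA.sub(" ", raw.lower()).split()
    return [stem(w) for w in words if len(w) >= 2]


def add_bigrams(tokens: list[str]) -> list[str]:
    """Append adjacent-pair bigram tokens to a unigram sequence.

    Output length is ``2n - 1`` for ``n >= 1`` unigrams, 0 for empty input.
    """
    if not tokens:
        return []
    return list(tokens) + [
        a + TOKEN_JOINER + b for a, b in zip(tokens, tokens[1:])
    ]


def tokenize(raw: str) -> list[str]:
    """Full analyzer: stemmed unigrams plus bigram tokens."""
    return add_bigrams(preprocess_text(raw))


@dataclass
class DocumentTermMatrix:
    """Sparse documents-by-tokens weight matrix with aligned labels.

    ``weighting`` is ``"tf"`` (integer counts) or ``"tfidf"``.  Rows follow
    ``doc_ids``; columns follow ``vocabulary``.
    """

    doc_ids: list[str]
    vocabulary: list[str]
    weights: sp.csr_matrix
    weighting: str
    labels: np.ndarray

    @property
    def n_documents(self) -> int:
        return self.weights.shape[0]

    @property
    def n_tokens(self) -> int:
        return self.weights.shape[1]

    def take_rows(self, idx: np.ndarray) -> "DocumentTermMatrix":
        """Row subset (e.g., one CV fold) with labels and ids kept aligned."""
        idx = np.asarray(idx)
        return DocumentTermMatrix(
            doc_ids=[self.doc_ids[i] for i in idx],
            vocabulary=list(self.vocabulary),
            weights=self.weights[idx],
            weighting=self.weighting,
            labels=self.labels[idx],
        )


def build_dtm(corpus: Corpus) -> DocumentTermMatrix:
    """Build the TF-weighted DTM for one corpus (unigrams + bigrams).

    Vocabulary is the sorted set of distinct tokens across the corpus.
    Raises :class:`DegenerateInputError` if no document yields any token.
    """
    vectorizer = CountVectorizer(analyzer=tokenize, lowercase=False)
    try:
        counts = vectorizer.fit_transform(corpus.texts())
    except ValueError as exc:  # sklearn: "empty vocabulary"
        raise DegenerateInputError(
            f"corpus {corpus.review_id!r} yields no tokens"
        ) from exc
    return DocumentTermMatrix(
        doc_ids=corpus.doc_ids(),
        vocabulary=vectorizer.get_feature_names_out().tolist(),
        weights=sp.csr_matrix(counts),
        weighting=WEIGHTING_TF,
        labels=corpus.labels(),
    )


@dataclass(frozen=True)
class DTMStats:
    """Cell-count summary of a DTM: dimensions, fill, and sparsity."""

    n_documents: int
    n_tokens: int
    n_nonzero: int
    n_zero: int
    sparsity: float

    @classmethod
    def from_counts(
        cls, n_documents: int, n_tokens: int, n_nonzero: int
    ) -> "DTMStats":
        total = n_documents * n_tokens
        n_zero = total - n_nonzero
        return cls(
            n_documents=n_documents,
            n_tokens=n_tokens,
            n_nonzero=n_nonzero,
            n_zero=n_zero,
            sparsity=n_zero / total if total else 0.0,
        )


def dtm_stats(dtm: DocumentTermMatrix) -> DTMStats:
    """Compute dimension, nonzero-cell, and sparsity statistics for a DTM."""
    return DTMStats.from_counts(
        n_documents=dtm.n_documents,
        n_tokens=dtm.n_tokens,
        n_nonzero=int(dtm.weights.count_nonzero()),
    )


def write_vocabulary(vocabulary: list[str], path: str | Path) -> None:
    """Export a vocabulary as plain text, one token per line, order preserved."""
    Path(path).write_text("\n".join(vocabulary) + "\n", encoding="utf-8")


def read_vocabulary(path: str | Path) -> list[str]:
    return [
        line for line in Path(path).read_text(encoding="utf-8").splitlines() if line
    ]
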